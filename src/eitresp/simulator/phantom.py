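"""Thorax-like conductivity phantom with breathing lungs.

Two elliptical lung regions sit on a uniform background; their conductivity
decreases linearly with inhaled volume (air is a poor conductor), which is
what modulates the boundary voltages during breathing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh2D

__all__ = ["PhantomError", "Ellipse", "ThoraxPhantom"]


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float = 0.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        xr = c * pts[..., 0] + s * pts[..., 1]
        yr = -s * pts[..., 0] + c * pts[..., 1]
        a, b = self.semi_axes
        return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


@dataclass(frozen=True)
class ThoraxPhantom:
    """Background + two lungs whose conductivity tracks lung volume.

    ``lung_sigma`` is the end-expiration lung conductivity; during breathing
    the lung conductivity is ``lung_sigma + slope * volume_L`` with a
    negative slope (inspiration lowers conductivity).
    """

    background_sigma: float = 0.48
    lung_sigma: float = 0.24
    slope_s_per_l: float = -0.04
    lungs: tuple[Ellipse, Ellipse] = field(
        default_factory=lambda: (
            Ellipse(center=(0.45, 0.0), semi_axes=(0.30, 0.42)),
            Ellipse(center=(-0.45, 0.0), semi_axes=(0.30, 0.42)),
        )
    )

    def __post_init__(self):
        if self.background_sigma <= 0 or self.lung_sigma <= 0:
            raise PhantomError("conductivities must be strictly positive")

    def lung_mask(self, mesh: Mesh2D) -> np.ndarray:
        cent = mesh.element_centroids()
        mask = np.zeros(mesh.n_elements, dtype=bool)
        for ell in self.lungs:
            mask |= ell.contains(cent)
        return mask

    def lung_conductivity(self, volume_l: float) -> float:
        return self.lung_sigma + self.slope_s_per_l * volume_l

    def check_excursion(self, max_volume_l: float) -> None:
        """Reject configurations whose conductivity goes non-positive."""
        lo = min(self.lung_conductivity(0.0), self.lung_conductivity(max_volume_l))
        if lo <= 0:
            raise PhantomError(
                f"lung conductivity reaches {lo:.4g} S/m at {max_volume_l} L"
            )

    def element_sigma(self, mesh: Mesh2D, volume_l: float = 0.0) -> np.ndarray:
        sig_lung = self.lung_conductivity(volume_l)
        if sig_lung <= 0:
            raise PhantomError(f"non-positive lung conductivity at {volume_l} L")
        sigma = np.full(mesh.n_elements, self.background_sigma)
        sigma[self.lung_mask(mesh)] = sig_lung
        return sigma
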