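"""Linearized difference imaging and pixel-level respiratory analysis.

A sensitivity (Jacobian) matrix at a homogeneous reference conductivity is
built with the adjoint method; conductivity changes are recovered from
voltage differences by a single Tikhonov-regularized Gauss-Newton step and
rasterized onto a square pixel grid (row 0 at the top).  Inspiration makes
lung tissue less conductive, so lung pixels swing negative during inhaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolSpec
from .simulator.forward import DEFAULT_THICKNESS, ForwardModel, element_gradients
from .simulator.mesh import Mesh2D

__all__ = [
    "ReconstructionError",
    "Jacobian",
    "DiffImage",
    "PixelGrid",
    "build_jacobian",
    "reconstruct_diff",
    "pixel_series",
    "correlate_pixels",
]


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class Jacobian:
    """Sensitivity of every measurement to every element conductivity."""

    matrix: np.ndarray = field(repr=False)  # (n_meas, n_elements)
    mesh: Mesh2D
    reference_sigma: float
    current_rms: float

    @property
    def n_measurements(self) -> int:
        return self.matrix.shape[0]


def build_jacobian(
    mesh: Mesh2D,
    reference_sigma: float,
    protocol: ProtocolSpec,
    current_rms: float = 1e-3,
    thickness: float = DEFAULT_THICKNESS,
) -> Jacobian:
    """Adjoint-method sensitivities at a homogeneous reference conductivity.

    Row (pattern p, slot m) holds d(V_pm)/d(sigma_e): minus the integral of
    the drive-field gradient dotted with the measurement lead-field gradient
    over each element.
    """
    if reference_sigma <= 0:
        raise ReconstructionError("reference conductivity must be positive")
    model = ForwardModel(mesh, reference_sigma, thickness=thickness)
    en = mesh.electrode_nodes
    G, areas = element_gradients(mesh)

    # drive fields, one per stimulation pattern (actual current amplitude)
    rhs_d = np.zeros((mesh.n_nodes, protocol.n_patterns))
    for k, (src, snk) in enumerate(protocol.stim_pairs):
        rhs_d[en[src - 1], k] += current_rms
        rhs_d[en[snk - 1], k] -= current_rms
    U_d = model.solve_nodal(rhs_d)

    # unit-current lead fields, one per distinct measurement pair
    pair_ids: dict[tuple[int, int], int] = {}
    for pairs in protocol.meas_pairs:
        for p in pairs:
            pair_ids.setdefault(p, len(pair_ids))
    rhs_m = np.zeros((mesh.n_nodes, len(pair_ids)))
    for (a, b), idx in pair_ids.items():
        rhs_m[en[b - 1], idx] += 1.0  # v+ terminal
        rhs_m[en[a - 1], idx] -= 1.0
    U_m = model.solve_nodal(rhs_m)

    grad_d = np.einsum("ekj,ejp->ekp", G, U_d[mesh.triangles])  # (M, 2, P)
    grad_m = np.einsum("ekj,ejl->ekl", G, U_m[mesh.triangles])  # (M, 2, L)

    rows = np.empty((protocol.n_measurements, mesh.n_elements))
    row = 0
    for k, pairs in enumerate(protocol.meas_pairs):
        for p in pairs:
            l = pair_ids[p]
            rows[row] = -thickness * areas * np.einsum(
                "ek,ek->e", grad_d[:, :, k], grad_m[:, :, l]
            )
            row += 1
    return Jacobian(
        matrix=rows,
        mesh=mesh,
        reference_sigma=float(reference_sigma),
        current_rms=current_rms,
    )


@dataclass(frozen=True)
class PixelGrid:
    """Square raster over the mesh bounding box; row 0 at the top."""

    size: int
    element_of_pixel: np.ndarray = field(repr=False)  # (size, size), -1 = outside

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel lies inside the body domain."""
        return self.element_of_pixel >= 0


def make_pixel_grid(mesh: Mesh2D, size: int = 32) -> PixelGrid:
    if size < 26:
        raise ReconstructionError("pixel grid must be at least 26 x 26")
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    span = (hi - lo).max()
    cx, cy = (hi + lo) / 2.0
    xs = cx - span / 2 + (np.arange(size) + 0.5) * span / size
    ys = cy + span / 2 - (np.arange(size) + 0.5) * span / size  # row 0 on top
    px, py = np.meshgrid(xs, ys)
    pts = np.column_stack([px.ravel(), py.ravel()])

    tri = mesh.triangles
    p0 = mesh.nodes[tri[:, 0]]
    d1 = mesh.nodes[tri[:, 1]] - p0
    d2 = mesh.nodes[tri[:, 2]] - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    owner = np.full(pts.shape[0], -1, dtype=int)
    # barycentric containment, vectorized over elements per point chunk
    rel = pts[:, None, :] - p0[None, :, :]  # (P, M, 2)
    l1 = (rel[..., 0] * d2[None, :, 1] - rel[..., 1] * d2[None, :, 0]) / det
    l2 = (d1[None, :, 0] * rel[..., 1] - d1[None, :, 1] * rel[..., 0]) / det
    inside = (l1 >= -1e-12) & (l2 >= -1e-12) & (l1 + l2 <= 1 + 1e-12)
    has = inside.any(axis=1)
    owner[has] = inside[has].argmax(axis=1)
    return PixelGrid(size=size, element_of_pixel=owner.reshape(size, size))


@dataclass(frozen=True)
class DiffImage:
    """Reconstructed conductivity change on mesh elements and pixels."""

    element_values: np.ndarray = field(repr=False)
    pixels: np.ndarray = field(repr=False)  # (size, size), NaN outside domain
    grid: PixelGrid
    frame_time_s: float = 0.0

    @property
    def size(self) -> int:
        return self.grid.size


def reconstruct_diff(
    v_frame: np.ndarray,
    v_reference: np.ndarray,
    jacobian: Jacobian,
    lam: float = 1e-2,
    grid: PixelGrid | None = None,
    frame_time_s: float = 0.0,
) -> DiffImage:
    """One-step Tikhonov solution of J dsigma = v_frame - v_reference.

    ``lam`` is relative: the identity prior is scaled by ``lam`` times the
    largest eigenvalue of J^T J, so doubling it always shrinks the solution.
    """
    v_frame = np.asarray(v_frame, dtype=float)
    v_reference = np.asarray(v_reference, dtype=float)
    J = jacobian.matrix
    if v_frame.shape != (J.shape[0],) or v_reference.shape != (J.shape[0],):
        raise ReconstructionError(
            f"voltage vectors must have length {J.shape[0]}"
        )
    if lam <= 0:
        raise ReconstructionError("regularization parameter must be positive")
    A = J.T @ J
    scale = np.linalg.norm(A, 2)
    dsig = np.linalg.solve(
        A + lam * scale * np.eye(A.shape[0]), J.T @ (v_frame - v_reference)
    )
    if grid is None:
        grid = make_pixel_grid(jacobian.mesh)
    pixels = np.full((grid.size, grid.size), np.nan)
    inside = grid.mask
    pixels[inside] = dsig[grid.element_of_pixel[inside]]
    return DiffImage(
        element_values=dsig, pixels=pixels, grid=grid, frame_time_s=frame_time_s
    )


def reconstruct_series(
    matrix_values: np.ndarray,
    jacobian: Jacobian,
    lam: float = 1e-2,
    grid: PixelGrid | None = None,
    reference_frame: int = 0,
    frame_rate_hz: float = 2.0,
) -> list[DiffImage]:
    """Difference images for every column of a voltage matrix.

    Same operator as :func:`reconstruct_diff` but the regularized normal
    matrix is factorized once for the whole sequence.
    """
    import scipy.linalg

    V = np.asarray(matrix_values, dtype=float)
    J = jacobian.matrix
    if V.shape[0] != J.shape[0]:
        raise ReconstructionError(f"voltage matrix must have {J.shape[0]} rows")
    if lam <= 0:
        raise ReconstructionError("regularization parameter must be positive")
    if grid is None:
        grid = make_pixel_grid(jacobian.mesh)
    A = J.T @ J
    scale = np.linalg.norm(A, 2)
    cho = scipy.linalg.cho_factor(A + lam * scale * np.eye(A.shape[0]))
    dv = V - V[:, [reference_frame]]
    dsig = scipy.linalg.cho_solve(cho, J.T @ dv)  # (n_el, F)
    images = []
    for f in range(V.shape[1]):
        pixels = np.full((grid.size, grid.size), np.nan)
        inside = grid.mask
        pixels[inside] = dsig[grid.element_of_pixel[inside], f]
        images.append(
            DiffImage(
                element_values=dsig[:, f], pixels=pixels, grid=grid,
                frame_time_s=f / frame_rate_hz,
            )
        )
    return images


def pixel_series(images, row: int, col: int) -> np.ndarray:
    """Per-frame values of one in-domain pixel across a DiffImage sequence."""
    images = list(images)
    if not images:
        raise ReconstructionError("empty image sequence")
    grid = images[0].grid
    if not (0 <= row < grid.size and 0 <= col < grid.size):
        raise ReconstructionError(f"pixel ({row}, {col}) outside the grid")
    if not grid.mask[row, col]:
        raise ReconstructionError(f"pixel ({row}, {col}) is background")
    return np.array([im.pixels[row, col] for im in images])


def correlate_pixels(
    images, volume_series: np.ndarray
) -> tuple[np.ndarray, tuple[int, int]]:
    """Per-pixel Pearson correlation with a volume series at the frame rate.

    Returns (correlation map with NaN outside the domain, (row, col) of the
    pixel with the largest absolute correlation).  Pixels with zero variance
    get correlation 0.
    """
    images = list(images)
    if len(images) < 10:
        raise ReconstructionError("need at least 10 frames to correlate")
    vol = np.asarray(volume_series, dtype=float)
    if vol.shape[0] != len(images):
        raise ReconstructionError("volume series length must equal frame count")
    grid = images[0].grid
    stack = np.stack([im.pixels for im in images])  # (F, size, size)
    sc = stack - stack.mean(axis=0)
    wc = vol - vol.mean()
    denom = np.sqrt((sc**2).sum(axis=0) * (wc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rmap = np.where(denom > 0, np.tensordot(wc, sc, axes=(0, 0)) / denom, 0.0)
    rmap[~grid.mask] = np.nan
    flat = np.where(np.isnan(rmap), -np.inf, np.abs(rmap))
    best = np.unravel_index(int(flat.argmax()), rmap.shape)
    return rmap, (int(best[0]), int(best[1]))
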