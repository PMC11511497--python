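"""Structured 2D triangular meshes for the circular/elliptical body domain.

The mesh is a set of concentric rings with a constant node count per ring,
triangulated with alternating quad diagonals plus a centre fan.  With the
node count a multiple of 2 * n_electrodes this construction is invariant
under rotation by two electrode positions and under reflection through any
electrode axis, which is what makes the homogeneous-medium voltage profiles
of all stimulation patterns exact images of one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MeshError", "Mesh2D", "disk_mesh"]


class MeshError(ValueError):
    pass


@dataclass(frozen=True)
class Mesh2D:
    """Triangle mesh with boundary electrode nodes.

    nodes: (N, 2) coordinates on the unit-radius (or scaled) domain.
    triangles: (M, 3) node indices, positively oriented.
    electrode_nodes: node index of each electrode, 1-based electrode k at
    ``electrode_nodes[k - 1]``; electrode 1 sits at angle 0 and numbering
    runs counter-clockwise.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    electrode_nodes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.electrode_nodes.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)


def disk_mesh(
    n_rings: int = 8,
    n_per_ring: int = 32,
    n_electrodes: int = 16,
    y_scale: float = 1.0,
) -> Mesh2D:
    """Symmetric mesh of the unit disk (optionally squashed into an ellipse).

    ``n_per_ring`` must be a multiple of ``2 * n_electrodes`` so that
    electrode nodes land on ring vertices and the alternating-diagonal
    pattern keeps the full dihedral symmetry of the electrode ring.
    ``y_scale < 1`` gives a thorax-like elliptical cross-section.
    """
    if n_rings < 2:
        raise MeshError("need at least 2 rings")
    if n_per_ring % (2 * n_electrodes) != 0:
        raise MeshError(
            f"n_per_ring must be a multiple of {2 * n_electrodes}, got {n_per_ring}"
        )
    angles = 2 * np.pi * np.arange(n_per_ring) / n_per_ring
    nodes = [np.zeros((1, 2))]
    for i in range(1, n_rings + 1):
        r = i / n_rings
        nodes.append(np.column_stack([r * np.cos(angles), r * np.sin(angles)]))
    nodes = np.vstack(nodes)
    nodes[:, 1] *= y_scale

    def ring_index(i: int, j: int) -> int:
        # ring i >= 1, node j (cyclic)
        return 1 + (i - 1) * n_per_ring + j % n_per_ring

    tris = []
    # centre fan
    for j in range(n_per_ring):
        tris.append((0, ring_index(1, j), ring_index(1, j + 1)))
    # annular strips with alternating diagonals
    for i in range(1, n_rings):
        for j in range(n_per_ring):
            a0, a1 = ring_index(i, j), ring_index(i, j + 1)
            b0, b1 = ring_index(i + 1, j), ring_index(i + 1, j + 1)
            if j % 2 == 0:
                tris.append((a0, b0, b1))
                tris.append((a0, b1, a1))
            else:
                tris.append((a0, b0, a1))
                tris.append((b0, b1, a1))
    triangles = np.array(tris, dtype=int)

    # enforce positive orientation
    p = nodes[triangles]
    sgn = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = sgn < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    step = n_per_ring // n_electrodes
    electrode_nodes = np.array(
        [ring_index(n_rings, k * step) for k in range(n_electrodes)], dtype=int
    )
    return Mesh2D(nodes=nodes, triangles=triangles, electrode_nodes=electrode_nodes)
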