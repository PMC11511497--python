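"""Linear-triangle FEM forward solver for the 2D conductivity equation.

Solves div(sigma grad u) = 0 with point-electrode (gap model) current
injection and one grounded reference node, and evaluates the differential
voltages of an adjacent measurement protocol.  Voltages are returned for
the configured RMS drive current, i.e. they are RMS carrier amplitudes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..protocol import ProtocolSpec
from .mesh import Mesh2D

__all__ = ["ForwardError", "DEFAULT_THICKNESS", "element_gradients", "assemble_stiffness", "ForwardModel", "forward_solve"]


class ForwardError(RuntimeError):
    pass


#: default slice thickness (m); sets the overall voltage scale so a 1 mA
#: drive lands the amplified carrier comfortably inside the 0-5 V ADC range
DEFAULT_THICKNESS = 0.02


def element_gradients(mesh: Mesh2D) -> tuple[np.ndarray, np.ndarray]:
    """Per-element shape-function gradient operators.

    Returns (G, areas): G has shape (M, 2, 3) with ``G[e] @ u[tri_e]`` the
    constant gradient of u on element e; areas are the (positive) element
    areas.
    """
    p = mesh.nodes[mesh.triangles]  # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    # b_i = y_j - y_k, c_i = x_k - x_j (cyclic)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    areas = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    if np.any(areas <= 0):
        raise ForwardError("mesh has non-positively-oriented elements")
    G = np.stack([b, c], axis=1) / (2 * areas)[:, None, None]
    return G, areas


def assemble_stiffness(
    mesh: Mesh2D, sigma: np.ndarray, thickness: float = 1.0
) -> sp.csc_matrix:
    """Global stiffness matrix for per-element conductivities (S/m)."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(mesh.n_elements, float(sigma))
    if np.any(sigma <= 0):
        raise ForwardError("conductivity must be strictly positive")
    G, areas = element_gradients(mesh)
    # element matrices: sigma * area * thickness * G^T G   (3x3 each)
    Ke = (sigma * areas * thickness)[:, None, None] * np.einsum(
        "eki,ekj->eij", G, G
    )
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsc()
    return K


class ForwardModel:
    """Factorized forward operator for one conductivity distribution.

    Grounds ``ref_node`` (default: the centre node 0) and solves for nodal
    potentials of arbitrary electrode current patterns with a single LU
    factorization.
    """

    def __init__(
        self,
        mesh: Mesh2D,
        sigma,
        thickness: float = DEFAULT_THICKNESS,
        ref_node: int = 0,
    ):
        self.mesh = mesh
        self.thickness = thickness
        self.ref_node = ref_node
        K = assemble_stiffness(mesh, sigma, thickness).tolil()
        K[ref_node, :] = 0.0
        K[:, ref_node] = 0.0
        K[ref_node, ref_node] = 1.0
        try:
            self._lu = spla.splu(K.tocsc())
        except RuntimeError as exc:  # singular factorization
            raise ForwardError(f"singular system: {exc}") from exc

    def solve_nodal(self, currents: np.ndarray) -> np.ndarray:
        """Nodal potentials for one or more nodal current vectors (A)."""
        rhs = np.asarray(currents, dtype=float)
        squeeze = rhs.ndim == 1
        if squeeze:
            rhs = rhs[:, None]
        rhs = rhs.copy()
        rhs[self.ref_node, :] = 0.0
        u = self._lu.solve(rhs)
        if not np.all(np.isfinite(u)):
            raise ForwardError("solver produced non-finite potentials")
        return u[:, 0] if squeeze else u

    def drive_currents(self, pattern: np.ndarray, current: float) -> np.ndarray:
        """Nodal current vector for a signed electrode drive column."""
        pattern = np.asarray(pattern, dtype=float)
        iv = np.zeros(self.mesh.n_nodes)
        iv[self.mesh.electrode_nodes] = current * pattern
        return iv

    def measure(self, u: np.ndarray, meas_pairs) -> np.ndarray:
        """Differential voltages u[even member] - u[odd member] per pair."""
        en = self.mesh.electrode_nodes
        first = np.array([p[0] for p in meas_pairs]) - 1
        second = np.array([p[1] for p in meas_pairs]) - 1
        # the second pair member is the even electrode, wired to v+
        return u[en[second]] - u[en[first]]

    def solve_protocol(
        self, spec: ProtocolSpec, current_rms: float = 1e-3
    ) -> np.ndarray:
        """All measurement voltages (RMS) as an (n_patterns, meas/pattern) array."""
        from ..protocol import stim_pattern_matrix

        S = stim_pattern_matrix(spec)
        rhs = np.zeros((self.mesh.n_nodes, spec.n_patterns))
        rhs[self.mesh.electrode_nodes, :] = current_rms * S
        U = self.solve_nodal(rhs)
        out = np.empty((spec.n_patterns, spec.meas_per_pattern))
        for k, pairs in enumerate(spec.meas_pairs):
            out[k] = self.measure(U[:, k], pairs)
        return out


def forward_solve(
    mesh: Mesh2D,
    sigma,
    pattern: np.ndarray,
    meas_pairs,
    current_rms: float = 1e-3,
    thickness: float = DEFAULT_THICKNESS,
) -> np.ndarray:
    """Differential voltages (RMS, V) for one signed stimulation column."""
    model = ForwardModel(mesh, sigma, thickness=thickness)
    u = model.solve_nodal(model.drive_currents(pattern, current_rms))
    return model.measure(u, meas_pairs)
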