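"""Structured-grid 2D plane-stress finite element core.

Every pixel of a masked density image becomes one 4-node bilinear
quadrilateral element (plane stress, unit thickness, 2x2 Gauss quadrature).
The grid convention follows the image convention used throughout the
package: pixel/element (0, 0) sits at the lower-left corner, row index
increases upward (+y, superior), column index increases rightward
(+x, medial).  Grid node (i, j) is the vertex at physical position
``origin + (j, i) * pixel_size``; each node carries DOFs ``(2*id, 2*id+1)``
for (ux, uy).

Forces are in newtons, moduli in pascals, displacements in metres
(thickness is 1 m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import tifffile

__all__ = [
    "DensityImage",
    "FEModel",
    "SingularModelError",
    "SolverError",
    "element_stiffness",
    "assemble",
    "solve",
    "reactions",
    "strain_energy",
]

# Direct sparse factorization below this many DOFs, PCG above.
_DIRECT_DOF_LIMIT = 500_000
_SOLVE_RTOL = 1e-8


def splu_spd(A: sp.spmatrix):
    """Sparse LU tuned for the SPD stiffness systems assembled here.

    Symmetric minimum-degree ordering with SuperLU's symmetric mode is
    several times faster than the default column ordering on these 2D
    grid problems.
    """
    return spla.splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A",
                     options=dict(SymmetricMode=True))


class SingularModelError(RuntimeError):
    """The model has a floating component with no displacement constraint."""


class SolverError(RuntimeError):
    """The linear solve failed to reach the requested residual tolerance."""


# ---------------------------------------------------------------------------
# density image container


@dataclass
class DensityImage:
    """Masked 2D grid of relative densities.

    ``values[r, c]`` is the relative density of the pixel whose lower-left
    corner is at ``origin_mm + (c, r) * pixel_size``; ``mask`` flags the
    pixels that belong to the bone domain.  Row 0 is the *bottom* row.
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_size_um: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        active = self.values[self.mask]
        if active.size and (active.min() < 0 or active.max() > 1):
            raise ValueError("densities outside [0, 1] on active pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "DensityImage":
        return DensityImage(
            self.values.copy(), self.mask.copy(), self.pixel_size_um, self.origin_mm
        )

    # -- I/O: 16-bit grayscale TIFF (density = value / 65535) + JSON sidecar
    def save(self, path: str | Path) -> None:
        path = Path(path)
        raw = np.round(np.where(self.mask, self.values, 0.0) * 65535).astype(np.uint16)
        tifffile.imwrite(path, raw[::-1])  # TIFF rows run top-down
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "origin_mm": list(self.origin_mm),
            "mask_encoding": "nonzero",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DensityImage":
        path = Path(path)
        raw = tifffile.imread(path)[::-1].astype(float) / 65535.0
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if meta.get("mask_encoding", "nonzero") != "nonzero":
            raise ValueError(f"unknown mask encoding {meta['mask_encoding']!r}")
        mask = raw > 0
        return cls(raw, mask, meta["pixel_size_um"], tuple(meta["origin_mm"]))


# ---------------------------------------------------------------------------
# element stiffness


def _ke_unit(nu: float) -> np.ndarray:
    """8x8 stiffness of a unit-modulus square bilinear quad, plane stress.

    Node order: lower-left, lower-right, upper-right, upper-left
    (counterclockwise); DOF order (ux0, uy0, ux1, uy1, ...).  For a square
    element with unit thickness the matrix is independent of edge length.
    """
    D = 1.0 / (1.0 - nu**2) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    # reference square [-1,1]^2, corners CCW from lower-left
    xn = np.array([-1.0, 1.0, 1.0, -1.0])
    yn = np.array([-1.0, -1.0, 1.0, 1.0])
    g = 1.0 / np.sqrt(3.0)
    ke = np.zeros((8, 8))
    for xi in (-g, g):
        for eta in (-g, g):
            dN_dxi = 0.25 * xn * (1.0 + eta * yn)
            dN_deta = 0.25 * yn * (1.0 + xi * xn)
            # physical element side a maps with Jacobian a/2; B ~ 2/a, detJ ~
            # a^2/4, so a cancels: evaluate at a = 2 (identity Jacobian).
            B = np.zeros((3, 8))
            B[0, 0::2] = dN_dxi
            B[1, 1::2] = dN_deta
            B[2, 0::2] = dN_deta
            B[2, 1::2] = dN_dxi
            ke += B.T @ D @ B
    return ke


def element_stiffness(modulus: float, nu: float, size_um: float = 1.0) -> np.ndarray:
    """Element stiffness matrix (N/m per unit thickness) of one square quad.

    ``size_um`` is accepted for interface completeness; for a square
    plane-stress bilinear element of unit thickness the stiffness does not
    depend on the edge length.
    """
    if not modulus > 0:
        raise ValueError("modulus must be positive")
    if not size_um > 0:
        raise ValueError("size_um must be positive")
    return modulus * _ke_unit(nu)


# ---------------------------------------------------------------------------
# model


@dataclass
class FEModel:
    """Structured quadrilateral mesh over the active pixels of a grid.

    ``element_id[r, c]`` is -1 for inactive pixels, otherwise the dense
    element index; ``node_id`` likewise maps grid vertices touched by at
    least one active element to dense node indices.  ``edof`` holds the
    8 DOF indices of each element in CCW node order.
    """

    element_id: np.ndarray
    node_id: np.ndarray
    edof: np.ndarray
    moduli: np.ndarray
    nu: float
    fixed_dofs: np.ndarray
    element_size_um: float
    origin_mm: tuple[float, float] = (0.0, 0.0)
    _ke1: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_elements(self) -> int:
        return int(self.moduli.size)

    @property
    def n_nodes(self) -> int:
        return int(self.node_id.max()) + 1

    @property
    def n_dofs(self) -> int:
        return 2 * self.n_nodes

    @property
    def ke_unit(self) -> np.ndarray:
        if self._ke1 is None:
            self._ke1 = _ke_unit(self.nu)
        return self._ke1

    def node_grid_positions(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) grid indices per node id."""
        out = np.empty((self.n_nodes, 2), dtype=int)
        rr, cc = np.nonzero(self.node_id >= 0)
        out[self.node_id[rr, cc]] = np.stack([rr, cc], axis=1)
        return out

    def node_coords_mm(self) -> np.ndarray:
        """(n_nodes, 2) array of (x, y) positions in mm."""
        pos = self.node_grid_positions()
        px_mm = self.element_size_um / 1000.0
        x = self.origin_mm[0] + pos[:, 1] * px_mm
        y = self.origin_mm[1] + pos[:, 0] * px_mm
        return np.stack([x, y], axis=1)

    def dofs_of_grid_nodes(self, rows, cols) -> np.ndarray:
        """(n, 2) DOF ids (ux, uy) for grid vertices; -1 rows for missing."""
        ids = self.node_id[np.asarray(rows), np.asarray(cols)]
        out = np.stack([2 * ids, 2 * ids + 1], axis=-1)
        out[ids < 0] = -1
        return out

    @classmethod
    def from_active_grid(
        cls,
        active: np.ndarray,
        moduli_grid: np.ndarray,
        nu: float,
        element_size_um: float,
        fixed_nodes: np.ndarray | None = None,
        origin_mm: tuple[float, float] = (0.0, 0.0),
    ) -> "FEModel":
        """Build a model from a boolean element grid and per-pixel moduli.

        ``fixed_nodes`` is an (n, 2) array of (row, col) grid-vertex indices
        whose DOFs (both ux and uy) are constrained to zero.
        """
        active = np.asarray(active, dtype=bool)
        nr, nc = active.shape
        element_id = np.full((nr, nc), -1, dtype=np.int64)
        element_id[active] = np.arange(int(active.sum()))

        node_touched = np.zeros((nr + 1, nc + 1), dtype=bool)
        node_touched[:-1, :-1] |= active
        node_touched[:-1, 1:] |= active
        node_touched[1:, 1:] |= active
        node_touched[1:, :-1] |= active
        node_id = np.full((nr + 1, nc + 1), -1, dtype=np.int64)
        node_id[node_touched] = np.arange(int(node_touched.sum()))

        er, ec = np.nonzero(active)
        # CCW: LL, LR, UR, UL
        n0 = node_id[er, ec]
        n1 = node_id[er, ec + 1]
        n2 = node_id[er + 1, ec + 1]
        n3 = node_id[er + 1, ec]
        nodes = np.stack([n0, n1, n2, n3], axis=1)
        edof = np.empty((nodes.shape[0], 8), dtype=np.int64)
        edof[:, 0::2] = 2 * nodes
        edof[:, 1::2] = 2 * nodes + 1

        moduli = np.asarray(moduli_grid, dtype=float)[active]
        if np.any(moduli <= 0):
            raise ValueError("all active-element moduli must be positive")

        if fixed_nodes is None:
            fixed = np.empty(0, dtype=np.int64)
        else:
            fixed_nodes = np.asarray(fixed_nodes, dtype=int)
            ids = node_id[fixed_nodes[:, 0], fixed_nodes[:, 1]]
            if np.any(ids < 0):
                raise ValueError("fixed node outside the active mesh")
            fixed = np.unique(np.concatenate([2 * ids, 2 * ids + 1]))

        return cls(element_id, node_id, edof, moduli, nu,
                   fixed, element_size_um, origin_mm)


# ---------------------------------------------------------------------------
# assembly and solves


def assemble(model: FEModel, moduli: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (CSR, symmetric)."""
    E = model.moduli if moduli is None else np.asarray(moduli, dtype=float)
    ke = model.ke_unit
    data = (E[:, None, None] * ke[None]).ravel()
    rows = np.repeat(model.edof, 8, axis=1).ravel()
    cols = np.tile(model.edof, (1, 8)).ravel()
    K = sp.coo_matrix((data, (rows, cols)), shape=(model.n_dofs, model.n_dofs))
    return K.tocsr()


def _check_constrained_components(model: FEModel, constrained_dofs: np.ndarray) -> None:
    """Raise SingularModelError if a node component carries no constraint."""
    n = model.n_nodes
    e0 = model.edof[:, 0::2] // 2  # element node ids
    pairs_i = np.concatenate([e0[:, k] for k in (0, 1, 2, 3)])
    pairs_j = np.concatenate([e0[:, k] for k in (1, 2, 3, 0)])
    adj = sp.coo_matrix(
        (np.ones(pairs_i.size), (pairs_i, pairs_j)), shape=(n, n)
    )
    ncomp, labels = sp.csgraph.connected_components(adj, directed=False)
    constrained_nodes = np.unique(np.asarray(constrained_dofs) // 2)
    ok = np.zeros(ncomp, dtype=bool)
    ok[np.unique(labels[constrained_nodes])] = True
    if not ok.all():
        bad = np.nonzero(~ok)[0]
        sizes = [int((labels == b).sum()) for b in bad]
        raise SingularModelError(
            f"{bad.size} floating component(s) without constraints "
            f"(node counts: {sizes})"
        )


def solve(
    model: FEModel,
    load: np.ndarray,
    prescribed: dict[int, float] | None = None,
    method: str = "auto",
    rtol: float = _SOLVE_RTOL,
    K: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Solve K u = f with homogeneous fixed DOFs plus optional prescribed
    (possibly nonzero) displacements.  Returns the full displacement vector.

    ``method`` is ``"auto"`` (direct below 5e5 DOFs, PCG above), ``"direct"``
    or ``"pcg"``.
    """
    load = np.asarray(load, dtype=float)
    if load.shape != (model.n_dofs,):
        raise ValueError("load vector length mismatch")
    if not np.all(np.isfinite(load)):
        raise ValueError("non-finite load entries")

    pres_dofs = np.asarray(sorted(prescribed), dtype=np.int64) if prescribed else np.empty(0, np.int64)
    pres_vals = np.array([prescribed[d] for d in pres_dofs]) if prescribed else np.empty(0)
    all_pres = np.unique(np.concatenate([model.fixed_dofs, pres_dofs]))
    if all_pres.size == 0:
        raise SingularModelError("no constrained DOFs: rigid-body modes present")
    _check_constrained_components(model, all_pres)

    if K is None:
        K = assemble(model)
    u = np.zeros(model.n_dofs)
    u[pres_dofs] = pres_vals

    free = np.setdiff1d(np.arange(model.n_dofs), all_pres, assume_unique=False)
    Kff = K[free][:, free]
    rhs = load[free] - K[free][:, all_pres] @ u[all_pres]

    if method == "auto":
        method = "direct" if free.size <= _DIRECT_DOF_LIMIT else "pcg"
    if method == "direct":
        lu = splu_spd(Kff)
        uf = lu.solve(rhs)
    elif method == "pcg":
        d = Kff.diagonal()
        M = sp.diags(1.0 / d)
        uf, info = spla.cg(Kff, rhs, rtol=rtol * 1e-2, atol=0.0, M=M, maxiter=20000)
        if info != 0:
            raise SolverError(f"PCG did not converge (info={info})")
    else:
        raise ValueError(f"unknown method {method!r}")

    scale = np.linalg.norm(rhs)
    if scale > 0:
        res = np.linalg.norm(Kff @ uf - rhs) / scale
        if res > rtol:
            raise SolverError(f"relative residual {res:.2e} exceeds {rtol:.0e}")
    u[free] = uf
    return u


def reactions(
    model: FEModel,
    prescribed: dict[int, float],
    load: np.ndarray | None = None,
    K: sp.csr_matrix | None = None,
    u: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nodal reaction forces at prescribed DOFs.

    Solves the model with the prescribed displacement map (on top of its
    homogeneous ``fixed_dofs``) and returns ``(r, u)`` where
    ``r = (K u)|_prescribed - load|_prescribed`` in the order of
    ``sorted(prescribed)``.  Pass ``u`` to skip the internal solve.
    """
    if not prescribed:
        raise ValueError("prescribed DOF map is empty")
    dofs = np.asarray(sorted(prescribed), dtype=np.int64)
    if dofs.min() < 0 or dofs.max() >= model.n_dofs:
        raise IndexError("prescribed DOF outside model")
    if load is None:
        load = np.zeros(model.n_dofs)
    if K is None:
        K = assemble(model)
    if u is None:
        u = solve(model, load, prescribed=prescribed, K=K)
    r = (K @ u)[dofs] - np.asarray(load, dtype=float)[dofs]
    return r, u


def strain_energy(
    model: FEModel, u: np.ndarray, moduli: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-element strain energies and the total 1/2 u^T K u (joules).

    The per-element energy is ``1/2 E_i ue^T k1 ue`` with ``k1`` the
    unit-modulus element matrix; the sum equals the quadratic form exactly
    up to round-off.
    """
    E = model.moduli if moduli is None else np.asarray(moduli, dtype=float)
    ue = np.asarray(u, dtype=float)[model.edof]  # (n_el, 8)
    per = 0.5 * E * np.einsum("ij,jk,ik->i", ue, model.ke_unit, ue)
    return per, float(per.sum())
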