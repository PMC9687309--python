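"""ROI extraction and physiological local-load estimation.

The localized reconstruction replaces the global FE model by a model of the
region of interest alone.  The price is that the ROI's mechanical
environment — the tractions the discarded bone exerts across the cut
boundary — must be supplied as external loads.  They are estimated by
static condensation: solve the low-resolution global model under the
physiological loads, read the displacements of the single layer of nodes on
the ROI perimeter (the cut boundary), prescribe them on a localized model
of the ROI, and take the reaction forces.  For linear elasticity this is
exact: re-applying the estimated loads to the same localized model
reproduces the global interior field up to a rigid-body motion, and each
estimated load set is self-equilibrated (zero resultant force and moment).

The loads are estimated once, at LR, and held fixed during the subsequent
optimization; they are mapped to the refined boundary by assigning each LR
nodal force to its coincident HR node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import DensityImage, FEModel, assemble, reactions, solve
from .refine import ROISpec

__all__ = [
    "LocalLoadSet",
    "extract_roi",
    "roi_ring_nodes",
    "build_local_model",
    "cut_boundary_displacements",
    "estimate_local_loads",
    "refine_local_loads",
    "pin_corner_dofs",
]


@dataclass
class LocalLoadSet:
    """Estimated external loads for the localized model, one per load case.

    ``forces`` has shape (n_cases, n_dofs_local) on the LR localized model;
    each row is self-equilibrated.  ``u_local`` holds the condensation
    solutions (displacements of the localized model under the prescribed cut
    boundary motion), kept for verification.
    """

    model: FEModel  # LR localized model the forces live on
    roi: ROISpec
    forces: np.ndarray  # (J, ndof)
    ring_dofs: np.ndarray
    u_local: np.ndarray  # (J, ndof)
    provenance: str = ""

    def resultants(self) -> np.ndarray:
        """(J, 3) array of (sum Fx, sum Fy, sum moment about origin)."""
        coords = self.model.node_coords_mm() / 1000.0  # m
        out = np.empty((self.forces.shape[0], 3))
        for j, f in enumerate(self.forces):
            fx, fy = f[0::2], f[1::2]
            out[j, 0] = fx.sum()
            out[j, 1] = fy.sum()
            out[j, 2] = (coords[:, 0] * fy - coords[:, 1] * fx).sum()
        return out


def extract_roi(image: DensityImage, roi: ROISpec) -> DensityImage:
    """Crop the ROI window out of a density image.

    The cropped image keeps the pixel size, gets its own origin at the ROI
    lower-left corner, and its densities are bit-identical to the global
    values in the window.  Extraction works anywhere inside the mask,
    including across the cortical shell.
    """
    roi.validate(image)
    px_mm = image.pixel_size_um / 1000.0
    sl = (slice(roi.row0, roi.row0 + roi.rows),
          slice(roi.col0, roi.col0 + roi.cols))
    return DensityImage(
        image.values[sl].copy(),
        image.mask[sl].copy(),
        image.pixel_size_um,
        (image.origin_mm[0] + roi.col0 * px_mm,
         image.origin_mm[1] + roi.row0 * px_mm),
    )


def roi_ring_nodes(roi: ROISpec) -> np.ndarray:
    """Grid nodes on the ROI perimeter, in ROI-local (row, col) coordinates.

    The cut boundary is the single layer of nodes on the rectangle
    perimeter: rows 0..rows, cols 0..cols, border only.
    """
    r, c = roi.rows, roi.cols
    nodes = [(0, j) for j in range(c + 1)]
    nodes += [(r, j) for j in range(c + 1)]
    nodes += [(i, 0) for i in range(1, r)]
    nodes += [(i, c) for i in range(1, r)]
    return np.array(sorted(nodes), dtype=int)


def build_local_model(global_model: FEModel, roi: ROISpec) -> FEModel:
    """Localized FE model of the ROI with moduli copied from the global model.

    All ROI elements must be active in the global model.  The localized
    model carries no fixed DOFs of its own; constraints come either from
    prescribed cut-boundary displacements or from corner pins.
    """
    win = global_model.element_id[roi.row0:roi.row0 + roi.rows,
                                  roi.col0:roi.col0 + roi.cols]
    if (win < 0).any():
        raise ValueError("ROI contains inactive elements in the global model")
    moduli_grid = global_model.moduli[win]
    active = np.ones((roi.rows, roi.cols), dtype=bool)
    px_mm = global_model.element_size_um / 1000.0
    origin = (global_model.origin_mm[0] + roi.col0 * px_mm,
              global_model.origin_mm[1] + roi.row0 * px_mm)
    model = FEModel.from_active_grid(
        active, moduli_grid, global_model.nu, global_model.element_size_um,
        fixed_nodes=None, origin_mm=origin,
    )
    return model


def _ring_dofs(model: FEModel, roi: ROISpec) -> np.ndarray:
    ring = roi_ring_nodes(ROISpec(0, 0, roi.rows, roi.cols))
    dofs = model.dofs_of_grid_nodes(ring[:, 0], ring[:, 1])
    return dofs.ravel()


def cut_boundary_displacements(
    global_model: FEModel,
    load: np.ndarray,
    roi: ROISpec,
    u_global: np.ndarray | None = None,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Displacements of the ROI perimeter nodes under one global load case.

    Returns a map from ROI-local grid node (row, col) to (ux, uy) in metres.
    Pass ``u_global`` to reuse an existing global solution.
    """
    if u_global is None:
        u_global = solve(global_model, load)
    ring_local = roi_ring_nodes(ROISpec(0, 0, roi.rows, roi.cols))
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for i, j in ring_local:
        gid = global_model.node_id[roi.row0 + i, roi.col0 + j]
        if gid < 0:
            raise ValueError(f"ROI perimeter node ({i}, {j}) not in global mesh")
        out[(int(i), int(j))] = (u_global[2 * gid], u_global[2 * gid + 1])
    return out


def estimate_local_loads(
    global_model: FEModel,
    loads: list[np.ndarray],
    roi: ROISpec,
    provenance: str = "",
) -> LocalLoadSet:
    """Estimate the physiological local loads of the ROI for each load case.

    Operational static condensation: for each case, solve the global model,
    prescribe the cut-boundary displacements on the localized model, solve,
    and take the perimeter reactions (plus any global loads applied to ROI
    interior nodes) as the local load vector.  Equivalent to forming
    ``Kcc' Dc - Kcl' Kll^-1 Klc' Dc`` explicitly, without building the
    condensed matrix.
    """
    local = build_local_model(global_model, roi)
    ring_local = roi_ring_nodes(ROISpec(0, 0, roi.rows, roi.cols))
    ring_dofs = _ring_dofs(local, roi)
    K_local = assemble(local)
    K_global = assemble(global_model)

    J = len(loads)
    forces = np.zeros((J, local.n_dofs))
    us = np.zeros((J, local.n_dofs))
    for j, load in enumerate(loads):
        u_g = solve(global_model, load, K=K_global)
        dc = cut_boundary_displacements(global_model, load, roi, u_global=u_g)
        prescribed = {}
        for (i, jj), (ux, uy) in dc.items():
            nid = local.node_id[i, jj]
            prescribed[2 * nid] = ux
            prescribed[2 * nid + 1] = uy

        # global applied loads that fall on ROI nodes belong to the
        # localized model (zero for interior ROIs)
        f_loc = np.zeros(local.n_dofs)
        rows = np.arange(roi.rows + 1)
        cols = np.arange(roi.cols + 1)
        for i in rows:
            for jj in cols:
                gid = global_model.node_id[roi.row0 + i, roi.col0 + jj]
                nid = local.node_id[i, jj]
                if gid >= 0 and nid >= 0:
                    f_loc[2 * nid] = load[2 * gid]
                    f_loc[2 * nid + 1] = load[2 * gid + 1]

        r, u_loc = reactions(local, prescribed, load=f_loc, K=K_local)
        f_total = f_loc.copy()
        pres_dofs = np.asarray(sorted(prescribed), dtype=np.int64)
        f_total[pres_dofs] += r
        forces[j] = f_total
        us[j] = u_loc

    lls = LocalLoadSet(local, roi, forces, ring_dofs, us, provenance)
    res = lls.resultants()
    scale = np.abs(forces).sum(axis=1) + 1e-300
    if np.any(np.abs(res[:, :2]).max(axis=1) > 1e-6 * scale):
        raise RuntimeError(
            "estimated local loads are not self-equilibrated: "
            f"resultants {res[:, :2]} vs scale {scale}")
    return lls


def _ring_chain(rows: int, cols: int) -> np.ndarray:
    """HR ring nodes of an (rows x cols)-element grid as an ordered closed
    chain of (row, col) pairs, counterclockwise from the lower-left corner."""
    top, right = rows, cols
    chain = [(0, j) for j in range(right)]
    chain += [(i, right) for i in range(top)]
    chain += [(top, j) for j in range(right, 0, -1)]
    chain += [(i, 0) for i in range(top, 0, -1)]
    return np.array(chain, dtype=int)


def refine_local_loads(lls: LocalLoadSet, n: int, hr_model: FEModel,
                       spread: str = "linear") -> np.ndarray:
    """Map LR local loads onto the refined localized model.

    The cut-boundary reactions at LR nodes represent a piecewise-linear
    traction along the ROI perimeter (the LR shape functions), so with
    ``spread="linear"`` each LR ring force is distributed with hat weights
    over the HR ring nodes of its tributary segment (total force preserved
    exactly) - the load stays at LR resolution, without the artificial
    stress singularities of single-node injection.  ``spread="point"``
    assigns each LR force to its geometrically coincident HR node instead.
    Non-ring LR forces always map to the coincident node.  Returns shape
    (J, ndof_hr).
    """
    if spread not in ("linear", "point"):
        raise ValueError(f"unknown spread {spread!r}")
    roi = lls.roi
    out = np.zeros((lls.forces.shape[0], hr_model.n_dofs))

    chain = _ring_chain(roi.rows * n, roi.cols * n)
    P = chain.shape[0]
    chain_ids = hr_model.node_id[chain[:, 0], chain[:, 1]]
    if (chain_ids < 0).any():
        raise ValueError("coincident HR ring node missing")
    ring_local = {(i * n, j * n) for i, j in
                  roi_ring_nodes(ROISpec(0, 0, roi.rows, roi.cols))}

    nr, nc = roi.rows + 1, roi.cols + 1
    for i in range(nr):
        for j in range(nc):
            lid = lls.model.node_id[i, j]
            if lid < 0:
                continue
            f = lls.forces[:, [2 * lid, 2 * lid + 1]]  # (J, 2)
            if not f.any():
                continue
            if spread == "linear" and (i * n, j * n) in ring_local:
                # chain position of the coincident HR node
                p0 = int(np.nonzero((chain[:, 0] == i * n)
                                    & (chain[:, 1] == j * n))[0][0])
                for d in range(-(n - 1), n):
                    w = (1.0 - abs(d) / n) / n
                    hid = chain_ids[(p0 + d) % P]
                    out[:, 2 * hid] += w * f[:, 0]
                    out[:, 2 * hid + 1] += w * f[:, 1]
            else:
                hid = hr_model.node_id[i * n, j * n]
                if hid < 0:
                    raise ValueError("coincident HR node missing")
                out[:, 2 * hid] += f[:, 0]
                out[:, 2 * hid + 1] += f[:, 1]
    return out


def pin_corner_dofs(model: FEModel) -> np.ndarray:
    """Minimal rigid-body pins for a self-equilibrated localized model.

    Both DOFs of the lower-left corner node plus the vertical DOF of the
    lower-right corner node.  With self-equilibrated loads the pin
    reactions stay at round-off level, which is checked in tests.
    """
    nr, nc = model.element_id.shape
    n_ll = model.node_id[0, 0]
    n_lr = model.node_id[0, nc]
    if n_ll < 0 or n_lr < 0:
        raise ValueError("corner nodes missing from localized model")
    return np.array([2 * n_ll, 2 * n_ll + 1, 2 * n_lr + 1], dtype=np.int64)
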