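"""Topology-optimization reconstruction of trabecular microstructure.

The reconstruction minimizes the weighted multi-load compliance

    f(rho) = sum_j c_j (1/2 u_j^T K u_j)

over the high-resolution design densities of the region of interest,
subject to the density-deviation constraint

    g(rho) = (1/N) sum_i (rho_i - rho0_i)^2 <= eps,

which preserves the patient-specific continuum density pattern while the
compliance term drives the intermediate densities toward a stiff, near
binary strut architecture (the mechanical reading of Wolff's law).  The
design update is the method of moving asymptotes on cone-filtered
densities.

The deviation constraint is enforced at the *continuum* resolution: the
deviation field rho - rho0 is smoothed with a Gaussian of half the parent
pixel width before the mean square is taken, so the bound compares local
bone mass at the scale of the input image.  Measured per sub-element
instead, the bound would forbid any binarization (a strut layout deviates
from a smooth parent field by ~0.4 RMS, far above sqrt(eps) = 0.1); a
hard per-parent-pixel block average would allow it but imprints the LR
pixel lattice on the microstructure.  The smoothed form pins the local
bone mass to the patient image, is free of grid artefacts, and still lets
the optimizer polarize densities within the pixel - which is what
reconstruction is for.

On top of the deviation bound, bone mass is conserved: a uniform dual
shift on the objective gradient is bisected so that every MMA update lands
on the parent mean density (the volume-constraint treatment of classic
compliance topology optimization).  Compliance minimization alone would
spend the whole deviation budget on uniform densification - stiffer, but
no longer the patient's bone; with the mass pinned, the compliance term
instead drives the formation of load-aligned struts at conserved bone
fraction, which is the remodeling behaviour the method models.  The
filtered field passes through a Heaviside projection with beta
continuation (three-field SIMP) so the final physical densities are
near-binary.

Two drivers share the loop:

* ``mode="global"`` (conventional): the design lives inside the refined
  *global* model and every iteration re-analyzes that model under the
  physiological surface loads.  Since only ROI elements change, the
  unchanging exterior is reduced once onto the ROI cut boundary by an exact
  Schur complement; the per-iteration solve then involves only ROI DOFs
  plus the condensed boundary operator, and reproduces the full-model
  solution to solver precision.
* ``mode="localized"``: the design lives in a stand-alone ROI model loaded
  with the statically condensed local loads estimated once at LR, with
  three pinned corner DOFs removing the rigid-body modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .fem import DensityImage, FEModel, assemble, splu_spd
from .localize import LocalLoadSet, extract_roi, pin_corner_dofs, refine_local_loads
from .materials import MaterialParams, simp_modulus
from .mma import MMAOptions, MMAState, mma_update
from .phantom import Landmarks, LoadCase, distribute_load
from .refine import ROISpec, build_refined_global_model, refine_image

__all__ = [
    "OptimizerParams",
    "OptimizationResult",
    "objective",
    "constraint_value",
    "sensitivities",
    "density_filter",
    "filter_backprop",
    "run_reconstruction",
]


@dataclass(frozen=True)
class OptimizerParams:
    """Optimization settings.

    ``epsilon`` is the density-deviation bound; ``filter_radius`` is the
    cone-filter radius in HR element widths; convergence is declared when
    the largest density change drops below ``change_tol``.
    """

    epsilon: float = 0.01
    filter_radius: float = 1.5
    filter_type: str = "density"  # "density" | "sensitivity"
    conserve_mass: bool = True
    projection: bool = True  # Heaviside projection of the filtered field
    proj_eta: float = 0.5
    proj_beta_max: float = 16.0
    proj_beta_iters: int = 40  # iterations between beta doublings
    move_limit: float = 0.2
    max_iters: int = 700
    change_tol: float = 0.01
    asyinit: float = 0.5
    asyincr: float = 1.2
    asydecr: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.filter_type not in ("sensitivity", "density"):
            raise ValueError(f"unknown filter_type {self.filter_type!r}")


@dataclass
class OptimizationResult:
    """Final design field and convergence record of one reconstruction."""

    rho: np.ndarray  # (rows, cols) HR physical densities
    rho_image: DensityImage  # same field as a ROI-local image
    f_history: np.ndarray
    g_history: np.ndarray
    change_history: np.ndarray
    g_final: float
    iterations: int
    converged: bool
    mode: str
    n_design: int
    mma_fallbacks: int = 0


# ---------------------------------------------------------------------------
# objective / constraint / sensitivities (reference implementations)


def objective(model: FEModel, loads, weights, us=None) -> float:
    """Weighted compliance sum_j c_j (1/2 u_j^T K u_j) over the load cases.

    Solves each case unless displacement fields ``us`` are supplied.
    """
    from .fem import solve as fem_solve

    weights = np.asarray(weights, dtype=float)
    K = assemble(model)
    total = 0.0
    for j, load in enumerate(loads):
        u = fem_solve(model, load, K=K) if us is None else us[j]
        total += weights[j] * 0.5 * float(u @ (K @ u))
    return total


def constraint_value(rho, rho0) -> float:
    """Mean squared density deviation g = (1/N) sum (rho - rho0)^2."""
    rho = np.asarray(rho, dtype=float).ravel()
    rho0 = np.asarray(rho0, dtype=float).ravel()
    if rho.shape != rho0.shape:
        raise ValueError("rho and rho0 lengths differ")
    return float(np.mean((rho - rho0) ** 2))


def sensitivities(
    rho,
    rho0,
    model: FEModel,
    us,
    weights,
    params: MaterialParams = MaterialParams(),
    design_eids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of compliance and constraint w.r.t. design rho.

    Self-adjoint compliance sensitivity for SIMP:
    ``dF/drho_i = -1/2 sum_j c_j gamma rho_i^(gamma-1) E0 ue_j^T k1 ue_j``
    (k1 the unit-modulus element matrix); always <= 0.  Constraint:
    ``dG/drho_i = 2 (rho_i - rho0_i) / N``.
    """
    rho = np.asarray(rho, dtype=float).ravel()
    rho0 = np.asarray(rho0, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float)
    eids = (np.arange(model.n_elements) if design_eids is None
            else np.asarray(design_eids))
    edof = model.edof[eids]
    q = np.zeros(eids.size)
    for j, u in enumerate(us):
        ue = np.asarray(u)[edof]
        q += weights[j] * np.einsum("ij,jk,ik->i", ue, model.ke_unit, ue)
    dF = -0.5 * params.gamma * rho ** (params.gamma - 1.0) * params.E0 * q
    dG = 2.0 * (rho - rho0) / rho.size
    return dF, dG


# ---------------------------------------------------------------------------
# density filter


def _cone_kernel(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    if r < 1:
        return np.ones((1, 1))
    off = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(off, off)
    w = np.maximum(0.0, radius - np.hypot(dx, dy))
    return w


def density_filter(field: np.ndarray, radius: float) -> np.ndarray:
    """Cone-weight (linear hat) density filter over a 2D design grid.

    Row-normalized: constants are preserved exactly; a spike's total mass is
    preserved away from the grid edge.  ``radius <= 1`` is the identity.
    """
    field = np.asarray(field, dtype=float)
    if radius < 0:
        raise ValueError("filter radius must be >= 0")
    kern = _cone_kernel(radius)
    if kern.size == 1:
        return field.copy()
    den = ndimage.convolve(np.ones_like(field), kern, mode="constant")
    num = ndimage.convolve(field, kern, mode="constant")
    return num / den


def filter_backprop(v: np.ndarray, radius: float) -> np.ndarray:
    """Chain-rule transpose of :func:`density_filter` applied to ``v``."""
    v = np.asarray(v, dtype=float)
    kern = _cone_kernel(radius)
    if kern.size == 1:
        return v.copy()
    den = ndimage.convolve(np.ones_like(v), kern, mode="constant")
    return ndimage.convolve(v / den, kern, mode="constant")


def heaviside_projection(xbar: np.ndarray, beta: float, eta: float = 0.5
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed Heaviside projection of a filtered density field.

    The classic three-field SIMP step: pushes intermediate filtered
    densities toward 0/1 with sharpness ``beta`` around threshold ``eta``;
    ``beta -> 0`` is the identity.  Returns the projected field and its
    derivative d(proj)/d(xbar) for the chain rule.
    """
    den = np.tanh(beta * eta) + np.tanh(beta * (1.0 - eta))
    phys = (np.tanh(beta * eta) + np.tanh(beta * (xbar - eta))) / den
    dphys = beta * (1.0 / np.cosh(beta * (xbar - eta))) ** 2 / den
    return phys, dphys


def project_mean(x: np.ndarray, target: float, lo: float, hi: float) -> np.ndarray:
    """Shift a bounded density field so its mean equals ``target``.

    Bisection on a uniform additive shift with clipping to the box — the
    same scalar search that enforces the volume constraint in classic
    compliance topology optimization.  Keeps the reconstructed bone mass
    equal to the parent image's mass, so the compliance term funds strut
    rearrangement rather than uniform densification.
    """
    if np.clip(x, lo, hi).mean() == target:
        return np.clip(x, lo, hi)
    a, b = lo - hi, hi - lo
    for _ in range(60):
        c = 0.5 * (a + b)
        if np.clip(x + c, lo, hi).mean() < target:
            a = c
        else:
            b = c
    return np.clip(x + 0.5 * (a + b), lo, hi)


def sensitivity_filter(dF2d: np.ndarray, rho2d: np.ndarray,
                       radius: float) -> np.ndarray:
    """Classic mesh-independency (sensitivity) filter for SIMP.

    Replaces each compliance sensitivity by the cone-weighted,
    density-weighted average of its neighbourhood,
    ``dF_i <- sum_j w_ij rho_j dF_j / (rho_i sum_j w_ij)``; suppresses
    checkerboards without graying the density field itself.
    """
    kern = _cone_kernel(radius)
    if kern.size == 1:
        return dF2d.copy()
    den = ndimage.convolve(np.ones_like(dF2d), kern, mode="constant")
    num = ndimage.convolve(rho2d * dF2d, kern, mode="constant")
    return num / (den * np.maximum(rho2d, 1e-3))


# ---------------------------------------------------------------------------
# analysis backends


class _FactorSolver:
    """Factor K on the free DOFs once, solve many load vectors."""

    def __init__(self, model: FEModel, K: sp.csr_matrix):
        self.ndof = model.n_dofs
        self.fixed = model.fixed_dofs
        self.free = np.setdiff1d(np.arange(self.ndof), self.fixed)
        self.lu = splu_spd(K[self.free][:, self.free])

    def solve(self, loads: np.ndarray) -> np.ndarray:
        loads = np.atleast_2d(loads)
        us = np.zeros((loads.shape[0], self.ndof))
        us[:, self.free] = self.lu.solve(loads[:, self.free].T).T
        return us


class _LocalizedProblem:
    """Per-iteration analysis of the stand-alone HR ROI model."""

    def __init__(self, model: FEModel, loads_hr: np.ndarray, weights):
        self.model = model
        self.loads = np.asarray(loads_hr, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self.edof = model.edof  # every element is a design element

    def analyze(self, moduli: np.ndarray):
        K = assemble(self.model, moduli)
        solver = _FactorSolver(self.model, K)
        us = solver.solve(self.loads)
        f = 0.0
        q = np.zeros(self.model.n_elements)
        ke = self.model.ke_unit
        for j in range(self.loads.shape[0]):
            f += self.weights[j] * 0.5 * float(self.loads[j] @ us[j])
            ue = us[j][self.edof]
            q += self.weights[j] * np.einsum("ij,jk,ik->i", ue, ke, ue)
        return f, q


class _GlobalProblem:
    """Refined-global analysis with the fixed exterior condensed out.

    The exterior (non-design) elements never change, so their stiffness is
    reduced once onto the ROI cut-boundary DOFs by an exact Schur
    complement; each iteration then factors only ROI DOFs plus the dense
    boundary block.  Compliance and ROI displacements equal the full-model
    values to solver precision (identity: with u_e eliminated,
    f = 1/2 rhs^T u_red + 1/2 F_e^T K_ee^-1 F_e).
    """

    _CHUNK = 64

    def __init__(self, rgm, loads_hr: np.ndarray, weights):
        model = rgm.model
        self.weights = np.asarray(weights, dtype=float)
        loads = np.asarray(loads_hr, dtype=float)

        d_edof = model.edof[rgm.design_eids]
        roi_nodes = np.unique(d_edof // 2)
        r = rgm.roi_hr
        ring_rows = np.concatenate([
            np.zeros(r.cols + 1, int), np.full(r.cols + 1, r.rows),
            np.arange(1, r.rows), np.arange(1, r.rows)])
        ring_cols = np.concatenate([
            np.arange(r.cols + 1), np.arange(r.cols + 1),
            np.zeros(r.rows - 1, int), np.full(r.rows - 1, r.cols)])
        ring_ids = model.node_id[r.row0 + ring_rows, r.col0 + ring_cols]
        assert (ring_ids >= 0).all()
        ring_ids = np.unique(ring_ids)
        interior_ids = np.setdiff1d(roi_nodes, ring_ids)

        i_dofs = np.sort(np.concatenate([2 * interior_ids, 2 * interior_ids + 1]))
        b_dofs = np.sort(np.concatenate([2 * ring_ids, 2 * ring_ids + 1]))
        fixed = model.fixed_dofs
        if np.intersect1d(fixed, np.concatenate([i_dofs, b_dofs])).size:
            raise ValueError("ROI touches the fixed distal cut; move the ROI")
        e_dofs = np.setdiff1d(
            np.arange(model.n_dofs),
            np.concatenate([i_dofs, b_dofs, fixed]))

        # exterior-only stiffness
        ext = np.ones(model.n_elements, dtype=bool)
        ext[rgm.design_eids] = False
        eed = model.edof[ext]
        ke = model.ke_unit
        data = (model.moduli[ext][:, None, None] * ke[None]).ravel()
        rows = np.repeat(eed, 8, axis=1).ravel()
        cols = np.tile(eed, (1, 8)).ravel()
        K_ext = sp.coo_matrix((data, (rows, cols)),
                              shape=(model.n_dofs, model.n_dofs)).tocsr()

        Kee = K_ext[e_dofs][:, e_dofs].tocsc()
        Keb = K_ext[e_dofs][:, b_dofs].tocsc()
        lu_e = splu_spd(Kee)
        nb = b_dofs.size
        S = K_ext[b_dofs][:, b_dofs].toarray()
        for c0 in range(0, nb, self._CHUNK):
            c1 = min(c0 + self._CHUNK, nb)
            X = lu_e.solve(Keb[:, c0:c1].toarray())
            S[:, c0:c1] -= Keb.T @ X

        ni = i_dofs.size
        self.nred = ni + nb
        red_of = np.full(model.n_dofs, -1, dtype=np.int64)
        red_of[i_dofs] = np.arange(ni)
        red_of[b_dofs] = ni + np.arange(nb)
        edof_red = red_of[d_edof]
        assert (edof_red >= 0).all()
        self.edof_red = edof_red
        self.rows = np.repeat(edof_red, 8, axis=1).ravel()
        self.cols = np.tile(edof_red, (1, 8)).ravel()
        self.ke = ke

        bi, bj = np.meshgrid(ni + np.arange(nb), ni + np.arange(nb),
                             indexing="ij")
        self.S_embed = sp.coo_matrix(
            (S.ravel(), (bi.ravel(), bj.ravel())),
            shape=(self.nred, self.nred)).tocsr()

        J = loads.shape[0]
        self.rhs = np.zeros((J, self.nred))
        self.c_const = np.zeros(J)
        for j in range(J):
            fe = loads[j][e_dofs]
            ye = lu_e.solve(fe)
            self.rhs[j, :ni] = loads[j][i_dofs]
            self.rhs[j, ni:] = loads[j][b_dofs] - Keb.T @ ye
            self.c_const[j] = 0.5 * float(fe @ ye)

    def analyze(self, moduli: np.ndarray):
        data = (moduli[:, None, None] * self.ke[None]).ravel()
        K = sp.coo_matrix((data, (self.rows, self.cols)),
                          shape=(self.nred, self.nred)).tocsr()
        K = K + self.S_embed
        lu = splu_spd(K)
        us = lu.solve(self.rhs.T).T
        f = 0.0
        q = np.zeros(self.edof_red.shape[0])
        for j in range(self.rhs.shape[0]):
            f += self.weights[j] * (
                0.5 * float(self.rhs[j] @ us[j]) + self.c_const[j])
            ue = us[j][self.edof_red]
            q += self.weights[j] * np.einsum("ij,jk,ik->i", ue, self.ke, ue)
        return f, q


# ---------------------------------------------------------------------------
# driver


def block_average(field2d: np.ndarray, n: int) -> np.ndarray:
    """Average an HR field over its n x n parent-pixel blocks."""
    R, C = field2d.shape[0] // n, field2d.shape[1] // n
    return field2d.reshape(R, n, C, n).mean(axis=(1, 3))


def continuum_deviation(
    phys2d: np.ndarray, rho0_2d: np.ndarray, n: int
) -> tuple[float, np.ndarray]:
    """Continuum-scale density-deviation constraint and its gradient.

    ``g = mean(S(rho - rho0)^2)`` where S is a Gaussian smoother with
    sigma of a quarter of the parent pixel width (n/4 sub-elements,
    reflected boundaries); the gradient is ``2 S^T S (rho - rho0) / N``.
    The sigma sets the mass-transport scale the bound tolerates: density
    rearrangement within ~2 sigma of a pixel is nearly free (that is what
    reconstruction needs to binarize), while moving bone across parent
    pixels is charged - which is what keeps the reconstruction on the
    patient's continuum pattern.
    """
    sigma = n / 4.0
    dev = phys2d - rho0_2d
    s = ndimage.gaussian_filter(dev, sigma, mode="reflect")
    g = float(np.mean(s * s))
    dG = ndimage.gaussian_filter(s, sigma, mode="reflect") * (2.0 / dev.size)
    return g, dG.ravel()


def _mass_balanced_update(x, dF, g, dG, eps, xmin, xmax, state, options,
                          target, phys_mean=None):
    """MMA step with the linear mass constraint handled by an outer dual.

    Bisects a uniform shift mu added to the objective gradient - the
    multiplier of the bone-mass equality - so that the MMA update itself
    lands on the conserved mass, measured on the physical (filtered and
    projected) field via ``phys_mean`` when given, else on the design
    field.  Saturated elements (bounds, move limit) drop out of the balance
    automatically, so concentrated boundary sensitivities cannot skew the
    interior competition the way a plain gradient-mean subtraction does.
    The updated mean is monotone nonincreasing in mu, so bisection is safe.
    """
    if phys_mean is None:
        phys_mean = np.mean

    def trial(mu):
        return float(phys_mean(mma_update(x, dF + mu, g, dG, eps, xmin, xmax,
                                          state, options,
                                          advance_state=False)))

    scale = max(float(np.abs(dF).max()), 1e-12)
    lo, hi = -scale, scale
    for _ in range(60):
        if trial(lo) >= target:
            break
        lo *= 2.0
    for _ in range(60):
        if trial(hi) <= target:
            break
        hi *= 2.0
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if trial(mid) > target:
            lo = mid
        else:
            hi = mid
    mu = 0.5 * (lo + hi)
    return mma_update(x, dF + mu, g, dG, eps, xmin, xmax, state, options)


def _build_localized(image, roi, lls: LocalLoadSet, n, material):
    roi_img = extract_roi(image, roi)
    hr = refine_image(roi_img, n)
    rho0 = np.clip(hr.values, material.rho_min, material.rho_max)
    model = FEModel.from_active_grid(
        np.ones(hr.shape, dtype=bool), simp_modulus(rho0, material),
        material.nu, hr.pixel_size_um, fixed_nodes=None, origin_mm=hr.origin_mm)
    model.fixed_dofs = pin_corner_dofs(model)
    loads_hr = refine_local_loads(lls, n, model)
    return model, loads_hr, rho0.ravel(), hr


def run_reconstruction(
    image: DensityImage,
    roi: ROISpec,
    loads,
    weights=None,
    mode: str = "localized",
    n: int = 12,
    opt: OptimizerParams = OptimizerParams(),
    material: MaterialParams = MaterialParams(),
    landmarks: Landmarks | None = None,
    log_fn=None,
) -> OptimizationResult:
    """Reconstruct the HR microstructure of one ROI.

    ``mode="global"``: ``loads`` is a list of activity :class:`LoadCase`
    objects distributed at HR over the landmark surfaces of the refined
    global model (``landmarks`` required); weights default to the case
    weights.  ``mode="localized"``: ``loads`` is a :class:`LocalLoadSet`
    estimated at LR; ``weights`` must be given.

    The design starts from the refined parent densities (a feasible start,
    g = 0), iterates filter -> FE analysis -> sensitivities -> MMA until the
    largest density change drops below ``opt.change_tol`` or ``max_iters``.
    """
    if mode == "global":
        if landmarks is None:
            raise ValueError("global mode needs phantom landmarks")
        cases: list[LoadCase] = list(loads)
        rgm = build_refined_global_model(image, roi, n, material)
        loads_hr = np.stack([distribute_load(c, landmarks, rgm.model)
                             for c in cases])
        if weights is None:
            weights = [c.weight for c in cases]
        problem = _GlobalProblem(rgm, loads_hr, weights)
        rho0 = rgm.rho0
        shape = rgm.design_shape
        px_um = rgm.hr_image.pixel_size_um
        origin = (image.origin_mm[0] + roi.col0 * image.pixel_size_um / 1000.0,
                  image.origin_mm[1] + roi.row0 * image.pixel_size_um / 1000.0)
    elif mode == "localized":
        if not isinstance(loads, LocalLoadSet):
            raise TypeError("localized mode needs a LocalLoadSet")
        if weights is None:
            raise ValueError("localized mode needs explicit weights")
        model, loads_hr, rho0, hr = _build_localized(image, roi, loads, n, material)
        problem = _LocalizedProblem(model, loads_hr, weights)
        shape = hr.shape
        px_um = hr.pixel_size_um
        origin = hr.origin_mm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    N = rho0.size
    xmin = np.full(N, material.rho_min)
    xmax = np.full(N, material.rho_max)
    x = rho0.copy()

    use_proj = opt.projection and opt.filter_type == "density"

    def phys_of(design: np.ndarray, beta: float):
        """Physical densities and the projection derivative (chain rule)."""
        if opt.filter_type != "density":
            return (np.clip(design, material.rho_min, material.rho_max),
                    np.ones(N))
        xbar = density_filter(design.reshape(shape), opt.filter_radius)
        if beta > 0:
            p, dp = heaviside_projection(xbar, beta, opt.proj_eta)
        else:
            p, dp = xbar, np.ones_like(xbar)
        return (np.clip(p.ravel(), material.rho_min, material.rho_max),
                dp.ravel())

    beta = 1.0 if use_proj else 0.0
    phys, dproj = phys_of(x, beta)

    state = MMAState()
    options = MMAOptions(opt.move_limit, opt.asyinit, opt.asyincr, opt.asydecr)
    f_hist, g_hist, ch_hist = [], [], []
    fscale = None
    converged = False

    for it in range(opt.max_iters):
        if use_proj:
            new_beta = min(opt.proj_beta_max,
                           2.0 ** (it // opt.proj_beta_iters))
            if new_beta != beta:
                beta = new_beta
                phys, dproj = phys_of(x, beta)
        moduli = simp_modulus(phys, material)
        f_raw, q = problem.analyze(moduli)
        if fscale is None:
            # design-region weighted strain energy at the start; same scale
            # for both modes
            fscale = max(0.5 * float(moduli @ q), 1e-300)
        g, dG_phys = continuum_deviation(phys.reshape(shape),
                                         rho0.reshape(shape), n)
        dF_phys = (-0.5 * material.gamma * phys ** (material.gamma - 1.0)
                   * material.E0 * q) / fscale
        if opt.filter_type == "density":
            dF = filter_backprop((dF_phys * dproj).reshape(shape),
                                 opt.filter_radius).ravel()
            dG = filter_backprop((dG_phys * dproj).reshape(shape),
                                 opt.filter_radius).ravel()
        else:
            dF = sensitivity_filter(dF_phys.reshape(shape), phys.reshape(shape),
                                    opt.filter_radius).ravel()
            dG = dG_phys

        if opt.conserve_mass:
            xn = _mass_balanced_update(
                x, dF, g, dG, opt.epsilon, xmin, xmax, state, options,
                rho0.mean(), phys_mean=lambda d: phys_of(d, beta)[0].mean())
        else:
            xn = mma_update(x, dF, g, dG, opt.epsilon, xmin, xmax, state,
                            options)
        change = float(np.max(np.abs(xn - x)))
        x = xn
        phys, dproj = phys_of(x, beta)

        f_hist.append(f_raw)
        g_hist.append(g)
        ch_hist.append(change)
        if log_fn is not None:
            log_fn(it, f_raw, g, change)
        if change < opt.change_tol and (not use_proj
                                        or beta >= opt.proj_beta_max):
            converged = True
            break

    g_final, _ = continuum_deviation(phys.reshape(shape), rho0.reshape(shape), n)
    rho2d = phys.reshape(shape)
    rho_image = DensityImage(rho2d, np.ones(shape, dtype=bool), px_um, origin)
    return OptimizationResult(
        rho=rho2d,
        rho_image=rho_image,
        f_history=np.array(f_hist),
        g_history=np.array(g_hist),
        change_history=np.array(ch_hist),
        g_final=g_final,
        iterations=len(f_hist),
        converged=converged,
        mode=mode,
        n_design=N,
        mma_fallbacks=state.fallback_count,
    )
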