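"""Synthetic proximal-femur phantom and physiological load cases.

No suitable public low-resolution density image of a proximal femur with
ground-truth loads exists for this pipeline, so the input is generated: a
masked 2D relative-density grid at continuum resolution (600 um/pixel by
default) with

* a closed cortical shell (thick along the diaphysis, thin over the head),
* a medullary canal in the shaft,
* smooth interior density gradients with densified bands along the
  principal compressive (head-calcar) and tensile (trochanteric arch)
  trabecular trajectories and a low-density Ward's-triangle region in the
  neck, and
* landmark surfaces (femoral head arc, greater trochanter arc, distal cut)
  for load application and boundary conditions.

Geometry is composed from signed-distance primitives (head disc, neck
capsule, trochanter lobe, shaft box) blended with a smooth union.  The
frontal-plane convention is x rightward = medial, y upward = superior;
load angles are measured from the vertical axis, a positive angle tilting
the force vector toward the lateral (-x) side and a negative angle toward
the medial side, as in the standard frontal-plane hip-loading diagrams.

The default load set models three daily activities (one-legged stance,
abduction, adduction), each a hip-contact force on the femoral head plus an
abductor muscle force on the greater trochanter, weighted by relative daily
cycle counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fem import DensityImage, FEModel

__all__ = [
    "DensityProfile",
    "FemurPhantomParams",
    "Landmarks",
    "LoadComponent",
    "LoadCase",
    "generate_femur",
    "default_load_cases",
    "distribute_load",
    "surface_nodes",
    "bottom_edge_nodes",
]


@dataclass(frozen=True)
class DensityProfile:
    """Interior relative-density field parameters (lengths in mm).

    The trabecular field is a smooth base level plus Gaussian bumps along
    the characteristic trajectories; values chosen to give a dense femoral
    head (~0.55), a sparse neck (~0.2) and an intermediate intertrochanteric
    region (~0.4) at continuum level, the typical relative-density ranges of
    those sites.
    """

    base: float = 0.20
    head_peak: float = 0.38
    head_sigma_mm: float = 11.0
    compressive_amp: float = 0.22
    compressive_radius_mm: float = 4.0
    compressive_path_mm: tuple = ((62.0, 90.0), (46.0, 54.0))
    tensile_amp: float = 0.12
    tensile_radius_mm: float = 5.0
    tensile_path_mm: tuple = ((22.0, 50.0), (30.0, 72.0), (55.0, 80.0))
    metaphysis_amp: float = 0.18
    metaphysis_center_mm: tuple = (33.0, 63.0)
    metaphysis_sigma_mm: float = 10.0
    ward_depth: float = 0.18
    ward_center_mm: tuple = (51.0, 75.0)
    ward_sigma_mm: float = 6.0
    marrow: float = 0.06
    canal_margin_mm: float = 6.0
    canal_top_mm: float = 40.0
    cortical_density: float = 0.92
    noise_amp: float = 0.04
    noise_sigma_px: float = 1.5


@dataclass(frozen=True)
class FemurPhantomParams:
    """Geometry of the phantom (lengths in mm, resolution in um/pixel).

    The default domain is 94.2 x 104.4 mm at 600 um/pixel (157 x 174
    pixels).  ``half_scale()`` returns a desk-scale variant with every
    length halved at the same pixel size, for fast paired reconstructions.
    ``seed`` fully determines the generated image.
    """

    width_mm: float = 94.2
    height_mm: float = 104.4
    pixel_size_um: float = 600.0
    head_center_mm: tuple = (64.0, 82.0)
    head_radius_mm: float = 19.0
    neck_axis_angle_deg: float = 47.0
    neck_length_mm: float = 32.0
    neck_radius_mm: float = 12.5
    troch_center_mm: tuple = (27.0, 80.0)
    troch_radius_mm: float = 12.0
    shaft_x_mm: tuple = (16.0, 50.0)
    shaft_top_mm: float = 72.0
    blend_mm: float = 5.0
    cortical_thickness_mm: float = 1.5
    shaft_cortical_mm: float = 4.0
    profile: DensityProfile = field(default_factory=DensityProfile)
    seed: int = 0

    def scaled(self, factor: float) -> "FemurPhantomParams":
        """Return a copy with every length (mm) multiplied by ``factor``."""
        s = factor
        p = self.profile
        prof = replace(
            p,
            head_sigma_mm=p.head_sigma_mm * s,
            compressive_radius_mm=p.compressive_radius_mm * s,
            compressive_path_mm=tuple((x * s, y * s) for x, y in p.compressive_path_mm),
            tensile_radius_mm=p.tensile_radius_mm * s,
            tensile_path_mm=tuple((x * s, y * s) for x, y in p.tensile_path_mm),
            metaphysis_center_mm=(p.metaphysis_center_mm[0] * s,
                                  p.metaphysis_center_mm[1] * s),
            metaphysis_sigma_mm=p.metaphysis_sigma_mm * s,
            ward_center_mm=(p.ward_center_mm[0] * s, p.ward_center_mm[1] * s),
            ward_sigma_mm=p.ward_sigma_mm * s,
            canal_margin_mm=p.canal_margin_mm * s,
            canal_top_mm=p.canal_top_mm * s,
        )
        return replace(
            self,
            width_mm=self.width_mm * s,
            height_mm=self.height_mm * s,
            head_center_mm=(self.head_center_mm[0] * s, self.head_center_mm[1] * s),
            head_radius_mm=self.head_radius_mm * s,
            neck_length_mm=self.neck_length_mm * s,
            neck_radius_mm=self.neck_radius_mm * s,
            troch_center_mm=(self.troch_center_mm[0] * s, self.troch_center_mm[1] * s),
            troch_radius_mm=self.troch_radius_mm * s,
            shaft_x_mm=(self.shaft_x_mm[0] * s, self.shaft_x_mm[1] * s),
            shaft_top_mm=self.shaft_top_mm * s,
            blend_mm=self.blend_mm * s,
            cortical_thickness_mm=self.cortical_thickness_mm * s,
            shaft_cortical_mm=self.shaft_cortical_mm * s,
            profile=prof,
        )

    def half_scale(self) -> "FemurPhantomParams":
        return self.scaled(0.5)


@dataclass
class Landmarks:
    """Load-application surfaces and anatomical anchor points (mm)."""

    head_center_mm: tuple
    head_radius_mm: float
    troch_center_mm: tuple
    troch_radius_mm: float
    distal_cut_nodes: np.ndarray  # (n, 2) grid node (row, col), row 0
    preset_centers_mm: dict  # name -> (x, y)


@dataclass(frozen=True)
class LoadComponent:
    """One distributed force: resultant magnitude at an angle from vertical,
    pressed toward the centre of the named landmark surface."""

    magnitude_N: float
    angle_deg: float
    surface: str  # "head" | "trochanter"


@dataclass(frozen=True)
class LoadCase:
    """One daily-activity load: hip contact + abductor muscle force, with a
    normalized weight c_j (relative daily cycle count)."""

    name: str
    hip: LoadComponent
    abductor: LoadComponent
    weight: float


def default_load_cases() -> list[LoadCase]:
    """The three daily-activity load cases.

    Hip contact forces of 2317, 1158 and 1548 N at 24, -15 and 56 degrees
    from vertical toward the femoral head centre; abductor forces of 703,
    351 and 468 N at 28, -8 and 35 degrees toward the greater trochanter
    centre; weights 0.6 / 0.2 / 0.2 (6000 / 2000 / 2000 daily cycles).
    """
    return [
        LoadCase("one_legged_stance",
                 LoadComponent(2317.0, 24.0, "head"),
                 LoadComponent(703.0, 28.0, "trochanter"), 0.6),
        LoadCase("abduction",
                 LoadComponent(1158.0, -15.0, "head"),
                 LoadComponent(351.0, -8.0, "trochanter"), 0.2),
        LoadCase("adduction",
                 LoadComponent(1548.0, 56.0, "head"),
                 LoadComponent(468.0, 35.0, "trochanter"), 0.2),
    ]


# ---------------------------------------------------------------------------
# signed-distance geometry


def _sd_disc(px, py, c, r):
    return np.hypot(px - c[0], py - c[1]) - r


def _sd_box(px, py, x0, x1, y0, y1):
    qx = np.maximum(x0 - px, px - x1)
    qy = np.maximum(y0 - py, py - y1)
    outside = np.hypot(np.maximum(qx, 0), np.maximum(qy, 0))
    inside = np.minimum(np.maximum(qx, qy), 0)
    return outside + inside


def _sd_segment(px, py, a, b, r):
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / (dx * dx + dy * dy), 0, 1)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy)) - r


def _smooth_union(a, b, k):
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0, 1)
    return b + (a - b) * h - k * h * (1 - h)


def _dist_polyline(px, py, pts):
    d = np.full_like(px, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        d = np.minimum(d, _sd_segment(px, py, a, b, 0.0))
    return d


def _smoothstep(t):
    t = np.clip(t, 0, 1)
    return t * t * (3 - 2 * t)


# ---------------------------------------------------------------------------
# phantom generation


def generate_femur(params: FemurPhantomParams = FemurPhantomParams()
                   ) -> tuple[DensityImage, Landmarks]:
    """Generate the phantom density image and its landmark map.

    The output is fully determined by ``params`` (including ``seed``).
    Raises ``ValueError`` if the domain cannot contain the geometry.
    """
    px_mm = params.pixel_size_um / 1000.0
    nc = int(np.floor(params.width_mm / px_mm + 0.5))
    nr = int(np.floor(params.height_mm / px_mm + 0.5))
    if (params.head_center_mm[0] + params.head_radius_mm >= params.width_mm
            or params.head_center_mm[1] + params.head_radius_mm >= params.height_mm):
        raise ValueError("domain too small to contain the femoral head")

    # pixel centres
    xs = (np.arange(nc) + 0.5) * px_mm
    ys = (np.arange(nr) + 0.5) * px_mm
    X, Y = np.meshgrid(xs, ys)  # shape (nr, nc), row 0 at bottom

    hc = params.head_center_mm
    neck_a = np.deg2rad(params.neck_axis_angle_deg)
    neck_p0 = (hc[0] - params.neck_length_mm * np.sin(neck_a),
               hc[1] - params.neck_length_mm * np.cos(neck_a))

    sdf = _sd_box(X, Y, params.shaft_x_mm[0], params.shaft_x_mm[1],
                  -10.0 * px_mm, params.shaft_top_mm)
    for other in (
        _sd_disc(X, Y, hc, params.head_radius_mm),
        _sd_segment(X, Y, neck_p0, hc, params.neck_radius_mm),
        _sd_disc(X, Y, params.troch_center_mm, params.troch_radius_mm),
    ):
        sdf = _smooth_union(sdf, other, params.blend_mm)
    mask = sdf < 0
    mask[:, 0] = mask[:, -1] = mask[-1, :] = False  # keep side/top margins

    prof = params.profile
    rho = np.full((nr, nc), prof.base)
    rho += prof.head_peak * np.exp(-(_sd_disc(X, Y, hc, 0.0) / prof.head_sigma_mm) ** 2)
    d_comp = _dist_polyline(X, Y, list(prof.compressive_path_mm))
    rho += prof.compressive_amp * np.exp(-(d_comp / prof.compressive_radius_mm) ** 2)
    d_ten = _dist_polyline(X, Y, list(prof.tensile_path_mm))
    rho += prof.tensile_amp * np.exp(-(d_ten / prof.tensile_radius_mm) ** 2)
    rho += prof.metaphysis_amp * np.exp(
        -(_sd_disc(X, Y, prof.metaphysis_center_mm, 0.0)
          / prof.metaphysis_sigma_mm) ** 2)
    rho -= prof.ward_depth * np.exp(
        -(_sd_disc(X, Y, prof.ward_center_mm, 0.0) / prof.ward_sigma_mm) ** 2)

    # medullary canal in the shaft
    canal = (_sd_box(X, Y, params.shaft_x_mm[0] + prof.canal_margin_mm,
                     params.shaft_x_mm[1] - prof.canal_margin_mm,
                     -10.0 * px_mm, prof.canal_top_mm) < 0)
    fade = _smoothstep((Y - (prof.canal_top_mm - 8.0)) / 8.0)
    rho = np.where(canal, prof.marrow + (rho - prof.marrow) * fade, rho)

    rng = np.random.default_rng(params.seed)
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)),
                                    prof.noise_sigma_px)
    if noise.std() > 0:
        rho += prof.noise_amp * noise / noise.std()
    rho = np.clip(rho, 0.01, 0.95)

    # cortical shell: distance (mm) to the exterior, thickness graded from
    # diaphyseal to metaphyseal values
    depth = ndimage.distance_transform_edt(mask) * px_mm
    t_cort = (params.shaft_cortical_mm
              + (params.cortical_thickness_mm - params.shaft_cortical_mm)
              * _smoothstep((Y - (params.shaft_top_mm - 14.0)) / 14.0))
    shell = mask & (depth <= t_cort)
    rho = np.where(shell, np.maximum(rho, prof.cortical_density), rho)

    rho = np.where(mask, np.clip(rho, 0.01, 1.0), 0.0)
    image = DensityImage(rho, mask, params.pixel_size_um, (0.0, 0.0))

    neck_mid = ((neck_p0[0] + hc[0]) / 2.0, (neck_p0[1] + hc[1]) / 2.0)
    # neck preset offset up-laterally toward Ward's area, off the
    # compressive band
    neck_preset = (neck_mid[0] - 0.06 * params.neck_length_mm,
                   neck_mid[1] + 0.12 * params.neck_length_mm)
    inter_preset = ((params.shaft_x_mm[0] + params.shaft_x_mm[1]) / 2.0,
                    params.shaft_top_mm - 8.0 * (params.shaft_top_mm / 72.0))
    landmarks = Landmarks(
        head_center_mm=hc,
        head_radius_mm=params.head_radius_mm,
        troch_center_mm=params.troch_center_mm,
        troch_radius_mm=params.troch_radius_mm,
        distal_cut_nodes=bottom_edge_nodes(mask),
        preset_centers_mm={
            "head": hc,
            "neck": neck_preset,
            "intertrochanter": inter_preset,
        },
    )
    return image, landmarks


def bottom_edge_nodes(active: np.ndarray) -> np.ndarray:
    """Grid nodes (row 0) under active bottom-row elements, as (row, col)."""
    cols = np.nonzero(active[0])[0]
    node_cols = np.unique(np.concatenate([cols, cols + 1]))
    return np.stack([np.zeros_like(node_cols), node_cols], axis=1)


def surface_nodes(model: FEModel) -> np.ndarray:
    """Grid (row, col) of mesh nodes on the boundary of the active region.

    A node is a surface node if it touches at least one active element but
    fewer than four.
    """
    active = model.element_id >= 0
    nr, nc = active.shape
    count = np.zeros((nr + 1, nc + 1), dtype=int)
    count[:-1, :-1] += active
    count[:-1, 1:] += active
    count[1:, 1:] += active
    count[1:, :-1] += active
    rr, cc = np.nonzero((count > 0) & (count < 4))
    return np.stack([rr, cc], axis=1)


def distribute_load(case: LoadCase, landmarks: Landmarks, model: FEModel
                    ) -> np.ndarray:
    """Nodal force vector (N) for one activity load case.

    Each component is spread cosine-weighted over a 60-degree surface arc
    centred on the point where the force line enters the landmark circle,
    each nodal force pointing toward the landmark centre.  The per-node
    forces are then mapped by a single rotation+scale so that the vector
    resultant equals the stated magnitude at the stated angle exactly.
    """
    f = np.zeros(model.n_dofs)
    surf = surface_nodes(model)
    coords = model.node_coords_mm()
    for comp in (case.hip, case.abductor):
        if comp.surface == "head":
            center, radius = landmarks.head_center_mm, landmarks.head_radius_mm
        elif comp.surface == "trochanter":
            center, radius = landmarks.troch_center_mm, landmarks.troch_radius_mm
        else:
            raise ValueError(f"unknown landmark surface {comp.surface!r}")
        f += _distribute_component(comp, center, radius, model, surf, coords)
    return f


def _distribute_component(comp, center, radius, model, surf, coords):
    th = np.deg2rad(comp.angle_deg)
    # Force direction, pressing toward the landmark centre.  A positive
    # printed angle tilts the force toward the lateral (-x) side, so the
    # stance hip force enters the superomedial head surface and presses
    # down-laterally, roughly along the neck axis - the standard
    # frontal-plane hip-loading geometry.
    d = np.array([-np.sin(th), -np.cos(th)])
    if comp.magnitude_N == 0:
        return np.zeros(model.n_dofs)

    ids = model.node_id[surf[:, 0], surf[:, 1]]
    p = coords[ids]
    rel = p - np.asarray(center)
    dist = np.hypot(rel[:, 0], rel[:, 1])
    elem_mm = model.element_size_um / 1000.0
    on_circle = np.abs(dist - radius) <= 1.5 * elem_mm
    # angular deviation from the entry point (at direction -d from centre)
    ang = np.arctan2(rel[:, 0], rel[:, 1])
    entry_ang = np.arctan2(-d[0], -d[1])
    dev = np.angle(np.exp(1j * (ang - entry_ang)))
    sel = on_circle & (np.abs(dev) <= np.deg2rad(30.0))
    if not sel.any():
        raise ValueError(
            f"no surface nodes on the {comp.surface} arc for load at "
            f"{comp.angle_deg} deg")

    w = np.cos(dev[sel] * 3.0)  # zero at the 30-degree arc edges
    toward = -rel[sel] / dist[sel, None]
    fn = w[:, None] * toward
    res = fn.sum(axis=0)
    target = comp.magnitude_N * d
    # rotation+scale mapping the raw resultant onto the target resultant
    den = res @ res
    a = (res @ target) / den
    b = (res[0] * target[1] - res[1] * target[0]) / den
    M = np.array([[a, -b], [b, a]])
    fn = fn @ M.T

    out = np.zeros(model.n_dofs)
    sel_ids = ids[sel]
    np.add.at(out, 2 * sel_ids, fn[:, 0])
    np.add.at(out, 2 * sel_ids + 1, fn[:, 1])
    return out
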