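"""Mesh refinement of low-resolution images to microstructure resolution.

Each low-resolution pixel is subdivided into n x n sub-elements that
inherit the parent density (block refinement, no interpolation).  With the
default continuum resolution of 600 um and a reconstruction resolution of
50 um, n = 12.  Inside the region of interest the sub-elements become
design variables with the SIMP micro-level material law; everywhere else
they keep the continuum density-modulus law and are never updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import DensityImage, FEModel
from .materials import MaterialParams, continuum_modulus, simp_modulus
from .phantom import bottom_edge_nodes

__all__ = ["ROISpec", "RefinedGlobalModel", "refine_image",
           "build_refined_global_model", "build_continuum_model"]

DEFAULT_REFINE_FACTOR = 12  # 600 um -> 50 um


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in LR pixel coordinates.

    ``row0``/``col0`` are 0-based inclusive lower-left pixel indices (row 0
    at the bottom); ``rows``/``cols`` are extents in pixels.
    """

    row0: int
    col0: int
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("ROI extents must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate(self, image: DensityImage) -> None:
        """Raise if the ROI is not fully inside the image mask."""
        nr, nc = image.shape
        if self.row0 + self.rows > nr or self.col0 + self.cols > nc:
            raise ValueError("ROI exceeds image bounds")
        win = image.mask[self.row0:self.row0 + self.rows,
                         self.col0:self.col0 + self.cols]
        if not win.all():
            raise ValueError("ROI contains pixels outside the bone mask")

    def scaled(self, n: int) -> "ROISpec":
        return ROISpec(self.row0 * n, self.col0 * n, self.rows * n, self.cols * n)


def refine_image(image: DensityImage, n: int) -> DensityImage:
    """Subdivide each pixel into an n x n block of identical sub-pixels."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"refinement factor must be a positive integer, got {n!r}")
    n = int(n)
    if n == 1:
        return image.copy()
    ones = np.ones((n, n))
    return DensityImage(
        np.kron(image.values, ones),
        np.kron(image.mask, ones).astype(bool),
        image.pixel_size_um / n,
        image.origin_mm,
    )


def build_continuum_model(
    image: DensityImage,
    params: MaterialParams = MaterialParams(),
    fixed_nodes: np.ndarray | None = None,
) -> FEModel:
    """Continuum-law FE model of a density image at its own resolution.

    Every active pixel becomes one element with the BMD-modulus law; this
    is the low-resolution global model used both for cut-boundary
    displacement extraction and as the pre-refinement starting point.
    ``fixed_nodes`` defaults to the distal-cut (bottom edge) nodes.
    """
    rho = np.clip(image.values, params.rho_min, params.rho_max)
    moduli = np.ones(image.shape)
    moduli[image.mask] = continuum_modulus(rho[image.mask], params)
    if fixed_nodes is None:
        fixed_nodes = bottom_edge_nodes(image.mask)
    return FEModel.from_active_grid(
        image.mask, moduli, params.nu, image.pixel_size_um,
        fixed_nodes, image.origin_mm)


@dataclass
class RefinedGlobalModel:
    """Refined global FE model with its design-variable bookkeeping.

    ``design_eids`` are the flat element ids (into ``model.moduli``) of the
    HR sub-elements inside the ROI, in row-major order over the HR ROI grid
    of shape ``design_shape``; ``rho0`` are their initial densities.
    """

    model: FEModel
    hr_image: DensityImage
    roi_lr: ROISpec
    roi_hr: ROISpec
    design_eids: np.ndarray
    design_shape: tuple[int, int]
    rho0: np.ndarray


def build_refined_global_model(
    image: DensityImage,
    roi: ROISpec,
    n: int = DEFAULT_REFINE_FACTOR,
    params: MaterialParams = MaterialParams(),
    fixed_nodes_lr: np.ndarray | None = None,
) -> RefinedGlobalModel:
    """Refine the whole LR image and route material laws by region.

    ROI sub-elements get the SIMP modulus of their (initial) density and are
    flagged as design variables; all other active sub-elements get the
    continuum BMD-modulus law and stay fixed.  ``fixed_nodes_lr`` are fully
    constrained grid nodes in LR coordinates (default: the distal cut, i.e.
    every bottom-edge node); they are mapped to HR by multiplication.
    """
    roi.validate(image)
    hr = refine_image(image, n)
    roi_hr = roi.scaled(n)

    in_roi = np.zeros(hr.shape, dtype=bool)
    in_roi[roi_hr.row0:roi_hr.row0 + roi_hr.rows,
           roi_hr.col0:roi_hr.col0 + roi_hr.cols] = True

    rho = np.clip(hr.values, params.rho_min, params.rho_max)
    moduli = np.ones(hr.shape)
    active = hr.mask
    roi_a = in_roi & active
    out_a = ~in_roi & active
    moduli[roi_a] = simp_modulus(rho[roi_a], params)
    moduli[out_a] = continuum_modulus(rho[out_a], params)

    if fixed_nodes_lr is None:
        fixed_hr = bottom_edge_nodes(hr.mask)
    else:
        fixed_hr = np.asarray(fixed_nodes_lr, dtype=int) * n

    model = FEModel.from_active_grid(
        active, moduli, params.nu, hr.pixel_size_um, fixed_hr, hr.origin_mm
    )
    win = model.element_id[roi_hr.row0:roi_hr.row0 + roi_hr.rows,
                           roi_hr.col0:roi_hr.col0 + roi_hr.cols]
    design_eids = win.ravel()
    assert (design_eids >= 0).all()
    rho0 = rho[roi_hr.row0:roi_hr.row0 + roi_hr.rows,
               roi_hr.col0:roi_hr.col0 + roi_hr.cols].ravel()
    return RefinedGlobalModel(model, hr, roi, roi_hr, design_eids,
                              (roi_hr.rows, roi_hr.cols), rho0)
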