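"""Run configuration, pipeline orchestration and fixture generation.

``run_pipeline`` drives the full validation workflow on the phantom:
generate the femur image, distribute the activity loads, then for every
configured ROI reconstruct with the conventional (global) and/or localized
method, compute the morphometric reports, and tabulate method-agreement
errors.  All outputs are plain formats: TIFF + JSON sidecars for images,
CSV for tables, JSON for configs and loads.

Two stock configurations are provided.  ``desk_config`` is the default
problem size used throughout the test-suite and the result-reproduction
script: a half-linear-scale phantom (47.1 x 52.2 mm at 600 um/pixel) with
refinement factor n = 6, i.e. 100 um design elements, dense-site ROIs of
16 x 16 LR pixels and a sparse neck ROI of 8 x 8, with the iteration cap at
300.  ``full_config`` reproduces the full-scale setting (94.2 x 104.4 mm,
n = 12, 50 um elements, ROI sizes 8/16/24) and is long-running; it is
shipped for completeness, not exercised by the tests.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import DensityImage
from .localize import estimate_local_loads
from .materials import MaterialParams
from .morphometry import ComparisonReport, MorphometryReport, compare, report
from .phantom import (FemurPhantomParams, Landmarks, default_load_cases,
                      distribute_load, generate_femur)
from .reconstruct import OptimizationResult, OptimizerParams, run_reconstruction
from .refine import ROISpec, build_continuum_model

__all__ = [
    "ROIConfig",
    "RunConfig",
    "PipelineError",
    "PipelineResult",
    "desk_config",
    "full_config",
    "roi_preset",
    "run_pipeline",
    "make_fixtures",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ROIConfig:
    name: str
    preset: str  # head | neck | intertrochanter
    size_px: int  # square extent in LR pixels


@dataclass
class RunConfig:
    """JSON-serializable description of one pipeline run."""

    seed: int = 0
    scale: float = 1.0  # phantom linear scale factor
    pixel_size_um: float = 600.0
    n: int = 12  # refinement factor (600 -> 50 um)
    rois: list = field(default_factory=list)  # list[ROIConfig]
    modes: tuple = ("global", "localized")
    material: MaterialParams = field(default_factory=MaterialParams)
    optimizer: OptimizerParams = field(default_factory=OptimizerParams)
    threshold: float = 0.5
    tensor_sigma: float = 2.0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scale": self.scale,
            "pixel_size_um": self.pixel_size_um,
            "n": self.n,
            "rois": [dataclasses.asdict(r) for r in self.rois],
            "modes": list(self.modes),
            "material": {
                "E0_Pa": self.material.E0,
                "gamma": self.material.gamma,
                "nu": self.material.nu,
                "rho_min": self.material.rho_min,
                "rho_max": self.material.rho_max,
            },
            "optimizer": dataclasses.asdict(self.optimizer),
            "threshold": self.threshold,
            "tensor_sigma": self.tensor_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            mat = d.get("material", {})
            material = MaterialParams(
                E0=mat.get("E0_Pa", 15e9),
                gamma=mat.get("gamma", 3.0),
                nu=mat.get("nu", 0.3),
                rho_min=mat.get("rho_min", 0.01),
                rho_max=mat.get("rho_max", 1.0),
            )
            optimizer = OptimizerParams(**d.get("optimizer", {}))
            rois = [ROIConfig(**r) for r in d.get("rois", [])]
            return cls(
                seed=int(d.get("seed", 0)),
                scale=float(d.get("scale", 1.0)),
                pixel_size_um=float(d.get("pixel_size_um", 600.0)),
                n=int(d.get("n", 12)),
                rois=rois,
                modes=tuple(d.get("modes", ("global", "localized"))),
                material=material,
                optimizer=optimizer,
                threshold=float(d.get("threshold", 0.5)),
                tensor_sigma=float(d.get("tensor_sigma", 2.0)),
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(f"invalid run configuration: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def desk_config(seed: int = 0) -> RunConfig:
    """Desk-scale paired-reconstruction configuration (see module docs)."""
    return RunConfig(
        seed=seed,
        scale=0.5,
        n=6,
        rois=[
            ROIConfig("head", "head", 16),
            ROIConfig("neck", "neck", 8),
            ROIConfig("intertrochanter", "intertrochanter", 16),
        ],
        optimizer=OptimizerParams(max_iters=300),
    )


def full_config(seed: int = 0) -> RunConfig:
    """Full-scale configuration (long-running; hours on one CPU)."""
    rois = [
        ROIConfig(f"{site}_{s}px", site, s)
        for site in ("head", "neck", "intertrochanter")
        for s in (8, 16, 24)
    ]
    return RunConfig(seed=seed, scale=1.0, n=12, rois=rois,
                     optimizer=OptimizerParams(max_iters=700))


def roi_preset(
    image: DensityImage,
    landmarks: Landmarks,
    name: str,
    size_px: int,
) -> ROISpec:
    """Square ROI of ``size_px`` LR pixels centred on a named landmark."""
    if name not in landmarks.preset_centers_mm:
        raise ValueError(f"unknown ROI preset {name!r}")
    cx, cy = landmarks.preset_centers_mm[name]
    px_mm = image.pixel_size_um / 1000.0
    row0 = int(np.floor(cy / px_mm - size_px / 2.0 + 0.5))
    col0 = int(np.floor(cx / px_mm - size_px / 2.0 + 0.5))
    roi = ROISpec(row0, col0, size_px, size_px)
    roi.validate(image)
    return roi


@dataclass
class PipelineResult:
    image: DensityImage
    landmarks: Landmarks
    config: RunConfig
    results: dict  # roi name -> mode -> OptimizationResult
    reports: dict  # roi name -> mode -> MorphometryReport
    comparisons: dict  # roi name -> ComparisonReport
    out_dir: Path | None


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 progress=None) -> PipelineResult:
    """Run the full phantom -> loads -> reconstruct -> morphometry pipeline.

    ``progress`` is an optional callable receiving log lines.  When
    ``out_dir`` is given, images, per-iteration histories, morphometry
    tables and the method-agreement error table are written there; partial
    outputs are kept if a later stage fails.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "run.json")
    lines: list[str] = []

    def log(msg: str) -> None:
        lines.append(msg)
        if progress is not None:
            progress(msg)
        if out is not None:
            (out / "run.log").write_text("\n".join(lines) + "\n")

    # -- phantom
    try:
        params = FemurPhantomParams(seed=config.seed,
                                    pixel_size_um=config.pixel_size_um)
        if config.scale != 1.0:
            params = params.scaled(config.scale)
        image, landmarks = generate_femur(params)
        cases = default_load_cases()
        weights = [c.weight for c in cases]
        log(f"phantom: {image.shape[0]}x{image.shape[1]} px at "
            f"{image.pixel_size_um:g} um, {int(image.mask.sum())} active")
        if out is not None:
            image.save(out / "femur.tiff")
            _write_loads_json(cases, out / "loads.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("phantom", exc) from exc

    # -- LR global model + loads (needed by the localized mode only)
    need_local = "localized" in config.modes
    lr_model = lr_loads = None
    if need_local:
        try:
            lr_model = build_continuum_model(image, config.material)
            lr_loads = [distribute_load(c, landmarks, lr_model) for c in cases]
            log(f"LR global model: {lr_model.n_elements} elements, "
                f"{lr_model.n_dofs} DOFs")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("localization", exc) from exc

    results: dict = {}
    reports: dict = {}
    comparisons: dict = {}
    for rc in config.rois:
        roi = roi_preset(image, landmarks, rc.preset, rc.size_px)
        results[rc.name] = {}
        reports[rc.name] = {}
        n_design = rc.size_px**2 * config.n**2
        for mode in config.modes:
            t0 = time.perf_counter()
            try:
                if mode == "global":
                    res = run_reconstruction(
                        image, roi, cases, mode="global", n=config.n,
                        opt=config.optimizer, material=config.material,
                        landmarks=landmarks)
                elif mode == "localized":
                    lls = estimate_local_loads(
                        lr_model, lr_loads, roi,
                        provenance=f"phantom seed {config.seed}, ROI {rc.name}")
                    log(f"{rc.name}/{mode}: localized model with {n_design} "
                        f"design elements (no refined global solve)")
                    res = run_reconstruction(
                        image, roi, lls, weights=weights, mode="localized",
                        n=config.n, opt=config.optimizer,
                        material=config.material)
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"reconstruct:{rc.name}:{mode}", exc) from exc
            dt = time.perf_counter() - t0
            log(f"{rc.name}/{mode}: {res.iterations} iterations, "
                f"f {res.f_history[-1]:.4e}, g {res.g_final:.5f}, "
                f"converged={res.converged}, {dt:.1f}s")
            results[rc.name][mode] = res
            try:
                rep = report(res.rho, res.rho_image.pixel_size_um,
                             config.threshold, label=rc.name,
                             tensor_sigma=config.tensor_sigma)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"morphometry:{rc.name}:{mode}", exc) from exc
            reports[rc.name][mode] = rep
            if out is not None:
                res.rho_image.save(out / f"{rc.name}_{mode}.tiff")
                pd.DataFrame({
                    "iteration": np.arange(res.iterations),
                    "f": res.f_history,
                    "g": res.g_history,
                    "max_change": res.change_history,
                }).to_csv(out / f"{rc.name}_{mode}_history.csv", index=False)
        if "global" in config.modes and "localized" in config.modes:
            comparisons[rc.name] = compare(reports[rc.name]["global"],
                                           reports[rc.name]["localized"])

    if out is not None:
        _write_tables(out, config, results, reports, comparisons)
    return PipelineResult(image, landmarks, config, results, reports,
                          comparisons, out)


def _write_loads_json(cases, path: Path) -> None:
    payload = [
        {
            "name": c.name,
            "weight": c.weight,
            "hip": {"magnitude_N": c.hip.magnitude_N,
                    "angle_deg": c.hip.angle_deg, "surface": c.hip.surface},
            "abductor": {"magnitude_N": c.abductor.magnitude_N,
                         "angle_deg": c.abductor.angle_deg,
                         "surface": c.abductor.surface},
        }
        for c in cases
    ]
    path.write_text(json.dumps(payload, indent=2))


def _write_tables(out, config, results, reports, comparisons) -> None:
    rows = []
    for name, modes in reports.items():
        for mode, rep in modes.items():
            rows.append({
                "roi": name, "mode": mode, "bv_tv_pct": rep.bv_tv,
                "tb_th_um": rep.tb_th_um, "tb_sp_um": rep.tb_sp_um,
                "tb_n_per_mm": rep.tb_n_mm,
                "alignment_deg": rep.alignment_angle_deg,
                "iterations": results[name][mode].iterations,
                "g_final": results[name][mode].g_final,
            })
    pd.DataFrame(rows).to_csv(out / "morphometry.csv", index=False)
    if comparisons:
        pd.DataFrame([
            {
                "roi": name,
                "bv_tv_error_pp": c.bv_tv_error_pp,
                "tb_th_error_pct": c.tb_th_error_pct,
                "tb_sp_error_pct": c.tb_sp_error_pct,
                "tb_n_error_pct": c.tb_n_error_pct,
                "angle_diff_deg": c.angle_diff_deg,
            }
            for name, c in comparisons.items()
        ]).to_csv(out / "errors.csv", index=False)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic test objects, generated rather than shipped.

    Returns a dict with a homogeneous plate image, a seeded heterogeneous
    plate, analytic stripe phantoms and a two-variable compliance toy.
    """
    rng = np.random.default_rng(seed)
    plate = DensityImage(np.full((12, 12), 0.5), np.ones((12, 12), bool), 600.0)
    hetero = DensityImage(
        np.round(0.2 + 0.7 * rng.random((12, 12)), 6),
        np.ones((12, 12), bool), 600.0)

    stripes_v = np.zeros((60, 60), dtype=bool)
    stripes_v[:, ::4] = True  # 1 px bone, 3 px gap
    yy, xx = np.mgrid[0:80, 0:80]
    # coordinate perpendicular to a line tilted 30 deg from vertical
    phase = xx * np.cos(np.deg2rad(30.0)) - yy * np.sin(np.deg2rad(30.0))
    stripes_30 = (phase % 8) < 3  # 3 px bone, 5 px gap, tilted 30 deg

    toy = {"c1": 1.0, "c2": 2.0, "rho0": (0.4, 0.4), "epsilon": 0.01}
    return {
        "plate": plate,
        "heterogeneous_plate": hetero,
        "stripes_vertical": stripes_v,
        "stripes_30deg": stripes_30,
        "two_bar_toy": toy,
    }
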