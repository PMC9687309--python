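"""Density-to-stiffness material laws.

Two interpolation laws are used side by side on the same density scale:

* a SIMP power law for the micro-level (design) elements inside the region
  of interest, which penalizes intermediate densities so that the optimizer
  is driven toward a binary bone/marrow layout, and
* an empirical bone-mineral-density regression for the continuum-level
  (non-design) elements, a two-branch power law on apparent density that
  represents homogenized trabecular/cortical stiffness.

Densities are relative (1 = fully mineralized bone, 0.01 = marrow) and both
laws return an elastic modulus in pascals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialParams", "simp_modulus", "continuum_modulus"]

# Continuum BMD-modulus regression coefficients.  The argument of the power
# law is 2*rho: the factor 2 maps relative density onto the apparent-density
# scale (g/cm^3) the regression was fitted on.  The branch point 0.84 and the
# rho=1 -> E0 consistency only hold with this literal form.
_C_LOW, _P_LOW = 0.3044, 1.49
_C_HIGH, _P_HIGH = 0.1908, 2.39
_BRANCH = 0.84


@dataclass(frozen=True)
class MaterialParams:
    """Elastic parameters shared by both material laws.

    Attributes
    ----------
    E0 : float
        Reference elastic modulus of fully dense bone tissue, Pa.
    gamma : float
        SIMP penalization exponent (>= 1).
    nu : float
        Poisson ratio, identical for every element.
    rho_min, rho_max : float
        Lower/upper relative-density bounds; the lower bound stands in for
        bone marrow and keeps the stiffness matrix nonsingular.
    """

    E0: float = 15e9
    gamma: float = 3.0
    nu: float = 0.3
    rho_min: float = 0.01
    rho_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.E0 > 0:
            raise ValueError(f"E0 must be positive, got {self.E0}")
        if not self.gamma >= 1:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if not (0 < self.rho_min < self.rho_max <= 1):
            raise ValueError(
                f"need 0 < rho_min < rho_max <= 1, got "
                f"({self.rho_min}, {self.rho_max})"
            )
        if not (0 < self.nu < 0.5):
            raise ValueError(f"nu must be in (0, 0.5), got {self.nu}")


def simp_modulus(rho, params: MaterialParams = MaterialParams()):
    """Micro-level (design element) modulus: ``rho**gamma * E0``.

    Accepts scalars or arrays; the result has the shape of ``rho``.
    Raises ``ValueError`` if any density lies outside [0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("relative density outside [0, 1]")
    out = rho**params.gamma * params.E0
    return float(out) if out.ndim == 0 else out


def continuum_modulus(rho, params: MaterialParams = MaterialParams()):
    """Continuum-level (non-design element) modulus.

    Piecewise power law on the apparent-density scale (argument ``2*rho``),
    with the low-density branch below rho = 0.84 and the high-density branch
    above.  The two branches are continuous at the threshold to within 0.1%
    and return E0 at rho = 1 to within 0.1%.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("relative density must be positive")
    low = _C_LOW * (2.0 * rho) ** _P_LOW
    high = _C_HIGH * (2.0 * rho) ** _P_HIGH
    out = np.where(rho <= _BRANCH, low, high) * params.E0
    return float(out) if out.ndim == 0 else out
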