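"""Method of moving asymptotes, specialized to a single constraint.

Standard sequential convex approximation for box-constrained problems

    minimize f(x)  subject to  g(x) <= b,  xmin <= x <= xmax,

where f and g are replaced at each design point by separable rational
approximations with moving lower/upper asymptotes L < x < U.  The convex
subproblem is solved exactly through its dual: with one constraint the dual
is one-dimensional in the multiplier lam >= 0, the inner minimizer x(lam)
has a closed form, and the dual derivative is monotone, so a bracketed
bisection suffices.

Asymptote bookkeeping follows the usual rules: initial half-range offsets,
then expansion (1.2) when the iterates move monotonically and contraction
(0.7) when they oscillate, with a move limit on top of the 0.1 feasibility
margin toward the asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MMAOptions", "MMAState", "mma_update"]

_ALBEFA = 0.1  # margin keeping x away from its asymptotes
_RAA0 = 1e-5  # curvature floor in the objective approximation


@dataclass(frozen=True)
class MMAOptions:
    move_limit: float = 0.2
    asyinit: float = 0.5
    asyincr: float = 1.2
    asydecr: float = 0.7


@dataclass
class MMAState:
    """Carries the previous iterates and asymptotes between updates."""

    xold1: np.ndarray | None = None
    xold2: np.ndarray | None = None
    low: np.ndarray | None = None
    upp: np.ndarray | None = None
    iteration: int = 0
    fallback_count: int = 0
    log: list = field(default_factory=list)


def _approx_terms(df, low, upp, x, span):
    """p, q coefficients of the rational approximation of one function."""
    dfp = np.maximum(df, 0.0)
    dfm = np.maximum(-df, 0.0)
    ux, xl = upp - x, x - low
    p = ux**2 * (1.001 * dfp + 0.001 * dfm + _RAA0 / span)
    q = xl**2 * (0.001 * dfp + 1.001 * dfm + _RAA0 / span)
    return p, q


def mma_update(
    x: np.ndarray,
    df: np.ndarray,
    g: float,
    dg: np.ndarray,
    bound: float,
    xmin: np.ndarray,
    xmax: np.ndarray,
    state: MMAState,
    options: MMAOptions = MMAOptions(),
    advance_state: bool = True,
) -> np.ndarray:
    """One MMA design update for min f s.t. g <= bound, xmin <= x <= xmax.

    ``df``/``dg`` are gradients at ``x``; ``g`` is the constraint value.
    Returns the new design and mutates ``state`` (unless
    ``advance_state=False``, for trial evaluations inside an outer dual
    search).  If even the largest multiplier cannot restore approximate
    feasibility the update falls back to the feasibility-restoring design
    (counted in ``state.fallback_count``).
    """
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    dg = np.asarray(dg, dtype=float)
    if not (np.all(np.isfinite(df)) and np.all(np.isfinite(dg))):
        raise ValueError("non-finite gradients passed to MMA")
    span = np.maximum(xmax - xmin, 1e-12)

    # --- asymptotes
    if state.xold1 is None or state.xold2 is None:
        low = x - options.asyinit * span
        upp = x + options.asyinit * span
    else:
        sign = (x - state.xold1) * (state.xold1 - state.xold2)
        factor = np.ones_like(x)
        factor[sign > 0] = options.asyincr
        factor[sign < 0] = options.asydecr
        low = x - factor * (state.xold1 - state.low)
        upp = x + factor * (state.upp - state.xold1)
        low = np.clip(low, x - 10.0 * span, x - 0.01 * span)
        upp = np.clip(upp, x + 0.01 * span, x + 10.0 * span)

    alfa = np.maximum.reduce([xmin, low + _ALBEFA * (x - low),
                              x - options.move_limit * span])
    beta = np.minimum.reduce([xmax, upp - _ALBEFA * (upp - x),
                              x + options.move_limit * span])

    p0, q0 = _approx_terms(df, low, upp, x, span)
    p1, q1 = _approx_terms(dg, low, upp, x, span)
    # residual so that the approximation matches g at the current point
    r1 = g - np.sum(p1 / (upp - x) + q1 / (x - low))

    def x_of_lam(lam: float) -> np.ndarray:
        pl = np.sqrt(p0 + lam * p1)
        ql = np.sqrt(q0 + lam * q1)
        xn = (low * pl + upp * ql) / (pl + ql)
        return np.clip(xn, alfa, beta)

    def g_approx(xn: np.ndarray) -> float:
        return r1 + float(np.sum(p1 / (upp - xn) + q1 / (xn - low)))

    # --- dual bisection on the single multiplier
    if g_approx(x_of_lam(0.0)) <= bound:
        lam = 0.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(80):
            if g_approx(x_of_lam(hi)) <= bound:
                break
            lo, hi = hi, hi * 10.0
        else:
            if advance_state:
                state.fallback_count += 1
                _advance(state, x, xn := x_of_lam(hi), low, upp)
                return xn
            return x_of_lam(hi)
        for _ in range(28):
            mid = 0.5 * (lo + hi)
            if g_approx(x_of_lam(mid)) <= bound:
                hi = mid
            else:
                lo = mid
        lam = hi
    xn = x_of_lam(lam)
    if advance_state:
        _advance(state, x, xn, low, upp)
    return xn


def _advance(state, x, xn, low, upp):
    state.xold2 = state.xold1
    state.xold1 = x.copy()
    state.low = low
    state.upp = upp
    state.iteration += 1
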