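"""Continuous two-segment ("broken-stick" / split-line) regression.

Milk yield responds to urea dose linearly up to a tolerance threshold and
declines beyond it; the model is a continuous piecewise-linear function with
an estimated breakpoint. For a fixed breakpoint c the model is ordinary
least squares on the hinge basis {1, x, max(x - c, 0)}; the breakpoint is
estimated by profiling the SSE over a candidate grid (deterministic, unlike
general nonlinear optimisation), followed by a +-grid-step refinement pass
at 1 g/d resolution. Ties in SSE go to the smallest candidate.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    ImplausibleValueWarning,
    InsufficientSupportError,
    InvalidArgumentError,
)
from .types import SplitLineFit


def _hinge_design(x: np.ndarray, c: float) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _valid_candidate(xs_unique: np.ndarray, c: float) -> bool:
    """A candidate needs at least 2 distinct x at or below it and 2 above."""
    return (xs_unique <= c).sum() >= 2 and (xs_unique > c).sum() >= 2


def default_candidates(x: Sequence[float], grid_step: float = 10.0) -> np.ndarray:
    """Breakpoint grid: every ``grid_step`` g/d across the interior of the
    dose range, excluding the outermost two distinct doses on each side."""
    xs = np.unique(np.asarray(x, dtype=float))
    if xs.size < 5:
        raise InsufficientSupportError(
            "need at least 5 distinct doses for a default grid"
        )
    lo, hi = xs[2], xs[-3]
    start = np.ceil(lo / grid_step) * grid_step
    grid = np.arange(start, hi + 1e-9, grid_step)
    if grid.size == 0:
        grid = np.array([(lo + hi) / 2.0])
    return grid


def fit_splitline(
    x: Sequence[float],
    y: Sequence[float],
    candidates: Optional[Sequence[float]] = None,
    grid_step: float = 10.0,
    refine: bool = True,
) -> SplitLineFit:
    """Fit the broken-stick model of ``y`` on ``x`` with a profiled breakpoint.

    Parameters
    ----------
    x, y : dose (g/d) and response (kg/d) per observation; observations are
        treated as independent cow-days.
    candidates : explicit breakpoint grid; defaults to
        :func:`default_candidates` over the interior of the dose range.
    refine : after grid selection, re-profile +-``grid_step`` around the
        winner at 1 g/d resolution.

    Returns
    -------
    SplitLineFit with the SSE-minimising breakpoint, segment slopes, R² and
    the F-test p-value of the slope change (the hinge term) at the selected
    breakpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-d and equal-length")
    n = x.size
    if n < 5:
        raise InvalidArgumentError(f"need n >= 5 observations, got {n}")
    xs_unique = np.unique(x)
    if xs_unique.size == 1:
        raise DegenerateInputError("all x identical; no dose-response to fit")

    if candidates is None:
        cand = default_candidates(x, grid_step)
    else:
        cand = np.asarray(candidates, dtype=float)
    cand = np.sort(cand)
    valid = [c for c in cand if _valid_candidate(xs_unique, c)]
    if not valid:
        raise InsufficientSupportError(
            "no candidate breakpoint has >= 2 distinct doses on each side"
        )

    def profile(cands: Sequence[float], best=None) -> tuple:
        # best = (sse, c, beta); ties in SSE go to the smallest breakpoint
        for c in cands:
            beta, sse = _ols_sse(_hinge_design(x, c), y)
            if best is None:
                best = (sse, c, beta)
                continue
            tie = np.isclose(sse, best[0], rtol=1e-12, atol=1e-12)
            if (tie and c < best[1]) or (not tie and sse < best[0]):
                best = (sse, c, beta)
        return best

    best = profile(valid)
    if refine:
        lo = best[1] - grid_step
        hi = best[1] + grid_step
        fine = [c for c in np.arange(lo, hi + 0.5) if _valid_candidate(xs_unique, c)]
        best = profile(fine, best)

    sse, c, beta = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)

    # F-test of the hinge (slope-change) term at the selected breakpoint
    _, sse_reduced = _ols_sse(np.column_stack([np.ones_like(x), x]), y)
    df_resid = n - 3
    if sse <= 0 or df_resid <= 0:
        p_change = 0.0 if sse_reduced > sse else 1.0
    else:
        f_stat = max(0.0, (sse_reduced - sse)) / (sse / df_resid)
        p_change = float(stats.f.sf(f_stat, 1, df_resid))

    return SplitLineFit(
        intercept=float(beta[0]),
        slope_below=float(beta[1]),
        slope_above=float(beta[1] + beta[2]),
        breakpoint=float(c),
        sse=sse,
        r2=r2,
        n=n,
        p_value_slope_change=p_change,
    )


def predict_splitline(fit: SplitLineFit, x) -> np.ndarray | float:
    """Evaluate a fitted split-line model at dose(s) ``x``."""
    xv = np.asarray(x, dtype=float)
    out = (
        fit.intercept
        + fit.slope_below * np.minimum(xv, fit.breakpoint)
        + fit.slope_above * np.maximum(xv - fit.breakpoint, 0.0)
    )
    return float(out) if np.isscalar(x) else out


def decline_per_100g(fit: SplitLineFit) -> Optional[float]:
    """Post-breakpoint decline rate, kg of milk per 100 g of urea.

    Returns None (with a warning) when the upper segment does not decline.
    """
    if fit.slope_above >= 0:
        warnings.warn(
            f"upper-segment slope {fit.slope_above:g} is not a decline",
            ImplausibleValueWarning,
            stacklevel=2,
        )
        return None
    return -fit.slope_above * 100.0
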