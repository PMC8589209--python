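"""Model-predicted indifference delays for bundled choices.

Given a participant's discount rate k — the reciprocal of the
indifference delay observed in the single-reward control condition —
the additive hyperbolic model predicts the first-installment delay D1*
at which the larger-later and smaller-sooner bundles are equal in
summed discounted value.  With the $1000 : $500 totals split equally
over n installments, the equality reduces (divide through by the
per-installment LLR amount) to

    sum_{i=1..n-1} 1/(1 + k i D1)  +  2/(1 + k n D1)  =  1

whose unique positive root scales as D1* = x*(n) / k.  The predicted
task outcome is the grid delay nearest D1*, and model accuracy is
scored as predicted minus observed log10 indifference delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy import optimize

from .task import DelayGrid, default_delay_grid
from .valuation import DiscountParams

__all__ = [
    "PredictionResult",
    "k_from_indifference",
    "solve_predicted_D1",
    "snap_to_grid",
    "difference_score",
    "predict_for_participant",
]


@dataclass(frozen=True)
class PredictionResult:
    """Predicted indifference delay for one participant at one bundle size."""

    k: float
    bundle_size: int
    D1_star: float  # continuous root, days
    snapped_days: float  # nearest grid delay
    predicted_log10: float  # log10(snapped_days)
    observed_log10: float | None = None
    diff_score: float | None = None  # predicted - observed, log10 days


def k_from_indifference(indifference_days: float) -> DiscountParams:
    """Discount rate from a single-reward indifference delay: k = 1/ID.

    At indifference, $1000/(1 + k*ID) = $500, so k = 1/ID exactly for
    the 2:1 amount ratio.
    """
    if not indifference_days > 0:
        raise ValueError(f"indifference delay must be > 0, got {indifference_days}")
    return DiscountParams(k=1.0 / indifference_days)


def _reduced_equation(x: float, n: int) -> float:
    # x = k * D1; equal-value equation for the 2:1 totals, minus 1
    return sum(1.0 / (1.0 + i * x) for i in range(1, n)) + 2.0 / (1.0 + n * x) - 1.0


def solve_predicted_D1(params: DiscountParams, n: int) -> float:
    """First-installment delay D1* (days) at which the bundles are equal.

    Solved on the reduced equation in x = k*D1 by bracketing root-finding
    to relative tolerance 1e-10, so the root is exact up to solver
    precision and scale-invariant in k (D1* = x*/k).  For n = 1 the
    closed form D1* = 1/k is returned directly.
    """
    if not params.k > 0:
        raise ValueError(f"prediction requires k > 0, got {params.k}")
    if n < 1:
        raise ValueError(f"bundle size must be >= 1, got {n}")
    if n == 1:
        return 1.0 / params.k
    # The left side is strictly decreasing in x, equals n at x=0+ and
    # tends to -1 as x -> inf, so exactly one sign change exists.
    lo, hi = 1e-12, 1.0
    while _reduced_equation(hi, n) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ArithmeticError(
                f"no sign change located for n={n}; f(lo)={_reduced_equation(lo, n):g}, "
                f"f(hi)={_reduced_equation(hi, n):g}"
            )
    x_star = optimize.brentq(_reduced_equation, lo, hi, args=(n,), rtol=1e-12, xtol=1e-15)
    return x_star / params.k


def snap_to_grid(D1_star: float, grid: DelayGrid | None = None, *, log_space: bool = False) -> float:
    """The grid delay nearest to a continuous predicted delay.

    Distance is measured in linear days by default; ``log_space=True``
    snaps by log-distance instead (the grid is log-spaced and the
    analysis scale is log10 days).  Exact midpoint ties break toward
    the shorter delay.  Values beyond the grid ends clamp to them.
    """
    if not D1_star > 0:
        raise ValueError(f"predicted delay must be > 0, got {D1_star}")
    if grid is None:
        grid = default_delay_grid()
    d = np.asarray(grid.delays)
    if log_space:
        dist = np.abs(np.log(d) - math.log(D1_star))
    else:
        dist = np.abs(d - D1_star)
    return float(d[int(np.argmin(dist))])  # argmin takes the first (shorter) on ties


def difference_score(predicted_days: float, observed_days: float) -> float:
    """Predicted minus observed indifference delay, in log10 days.

    Positive scores mean the additive model overestimated the bundling
    effect; negative scores mean it underestimated.
    """
    if not predicted_days > 0 or not observed_days > 0:
        raise ValueError(
            f"delays must be > 0, got predicted={predicted_days}, observed={observed_days}"
        )
    return math.log10(predicted_days) - math.log10(observed_days)


def predict_for_participant(
    control_indifference_days: float,
    bundle_size: int,
    observed_days: float | None = None,
    grid: DelayGrid | None = None,
    *,
    log_space_snap: bool = False,
) -> PredictionResult:
    """Full prediction pipeline for one participant and bundle size.

    Derives k from the control-condition indifference delay, solves for
    D1*, snaps it to the task grid, and (when the observed indifference
    delay for the bundled condition is supplied) attaches the
    log10 difference score.
    """
    params = k_from_indifference(control_indifference_days)
    d1_star = solve_predicted_D1(params, bundle_size)
    snapped = snap_to_grid(d1_star, grid, log_space=log_space_snap)
    observed_log10 = math.log10(observed_days) if observed_days is not None else None
    diff = difference_score(snapped, observed_days) if observed_days is not None else None
    return PredictionResult(
        k=params.k,
        bundle_size=bundle_size,
        D1_star=d1_star,
        snapped_days=snapped,
        predicted_log10=math.log10(snapped),
        observed_log10=observed_log10,
        diff_score=diff,
    )
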