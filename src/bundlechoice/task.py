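"""Five-trial adjusting-delay task, generalized to bundled options.

The task is a binary search over a fixed, approximately log-spaced grid
of 32 candidate indifference delays (1 hour to 25 years).  On every
trial the participant chooses between a larger-later bundle whose first
installment arrives after D1 and a smaller-sooner bundle whose first
installment is immediate.  Choosing the larger-later option moves the
search to longer delays; choosing the smaller-sooner option moves it to
shorter delays.  After five trials the search interval has collapsed to
a single grid value — the indifference delay.

A sixth, quality-control trial offers the two totals with all delays
removed ("$500 now" vs "$1000 now", framed as installments at larger
bundle sizes); choosing the smaller total flags inattention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .valuation import (
    DEFAULT_LLR_TOTAL,
    DEFAULT_SSR_TOTAL,
    HOUR,
    YEAR,
    BundleOption,
    MoneyAmount,
    Role,
    build_bundle_options,
    split_total,
)

__all__ = [
    "DelayGrid",
    "TaskRecord",
    "Chooser",
    "default_delay_grid",
    "run_adjusting_task",
    "enumerate_outcomes",
    "qc_choice_trial",
]

#: A chooser maps the (LLR, SSR) option pair for one trial to a Role.
Chooser = Callable[[BundleOption, BundleOption], Role]

GRID_SIZE = 32


@dataclass(frozen=True)
class DelayGrid:
    """The ordered candidate indifference delays the staircase searches.

    Invariants: exactly 32 strictly increasing delays (days); the first
    presented delay under the bisection rule is ``delays[start_index]``.
    """

    delays: tuple[float, ...]
    start_index: int = 16

    def __post_init__(self) -> None:
        if len(self.delays) != GRID_SIZE:
            raise ValueError(f"grid must have {GRID_SIZE} delays, got {len(self.delays)}")
        d = np.asarray(self.delays)
        if not np.all(np.diff(d) > 0):
            raise ValueError("grid delays must be strictly increasing")
        if not 0 <= self.start_index < GRID_SIZE:
            raise ValueError(f"start_index out of range: {self.start_index}")

    def __len__(self) -> int:
        return GRID_SIZE

    def __getitem__(self, i: int) -> float:
        return self.delays[i]


def default_delay_grid() -> DelayGrid:
    """The canonical 32-value delay grid.

    Anchored at the published constraints of the task: minimum 1 hour,
    maximum 25 years, second-largest 12 years, and 3 weeks as the first
    presented delay (the bisection midpoint of the full 0..31 interval,
    index 16).  The interior values are log-spaced between the anchors;
    the exact list is configurable — any strictly increasing 32-vector
    honouring the bisection start can be substituted via
    :class:`DelayGrid`.
    """
    lo = np.geomspace(HOUR, 3 * 7.0, 17)  # indices 0..16, 1 h .. 3 wk
    hi = np.geomspace(3 * 7.0, 12 * YEAR, 15)[1:]  # indices 17..30
    delays = np.concatenate([lo, hi, [25 * YEAR]])
    return DelayGrid(tuple(float(x) for x in delays), start_index=16)


@dataclass(frozen=True)
class TaskRecord:
    """One administration of the five-trial task at one bundle size."""

    bundle_size: int
    trials: tuple[tuple[float, Role], ...]  # (presented D1 in days, choice)
    final_index: int
    indifference_days: float
    qc_pass: bool | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != 5:
            raise ValueError(f"a task record holds exactly 5 trials, got {len(self.trials)}")


def _bisect_step(low: int, high: int) -> int:
    return (low + high + 1) // 2


def run_adjusting_task(
    chooser: Chooser,
    grid: DelayGrid | None = None,
    bundle_size: int = 1,
    total_llr: MoneyAmount | int = DEFAULT_LLR_TOTAL,
    total_ssr: MoneyAmount | int = DEFAULT_SSR_TOTAL,
) -> TaskRecord:
    """Run the five-trial staircase against a chooser function.

    The search maintains a closed index interval [low, high], initially
    [0, 31].  Each trial presents D1 = delays[(low+high+1)//2]; a
    larger-later choice sets low to the presented index (indifference
    lies at a longer delay), a smaller-sooner choice sets high to the
    presented index minus one.  Five halvings collapse 32 candidates to
    one: low == high == final_index.

    A chooser exception is re-raised with the trial context attached.
    """
    if grid is None:
        grid = default_delay_grid()
    low, high = 0, GRID_SIZE - 1
    trials: list[tuple[float, Role]] = []
    for trial in range(5):
        mid = _bisect_step(low, high)
        d1 = grid[mid]
        llr, ssr = build_bundle_options(d1, bundle_size, total_llr, total_ssr)
        try:
            choice = Role(chooser(llr, ssr))
        except Exception as exc:
            raise RuntimeError(
                f"chooser failed on trial {trial + 1} (bundle_size={bundle_size}, "
                f"D1={d1:g} d)"
            ) from exc
        trials.append((d1, choice))
        if choice is Role.LLR:
            low = mid
        else:
            high = mid - 1
    assert low == high
    return TaskRecord(
        bundle_size=bundle_size,
        trials=tuple(trials),
        final_index=low,
        indifference_days=grid[low],
    )


def enumerate_outcomes(grid: DelayGrid | None = None) -> dict[str, int]:
    """Map every 5-bit choice sequence to its final grid index.

    Sequences are strings over {'L', 'S'} ('L' = larger-later choice).
    The staircase is a perfect binary search, so the 2**5 = 32 sequences
    land on 32 distinct indices covering 0..31 exactly once.
    """
    if grid is None:
        grid = default_delay_grid()
    out: dict[str, int] = {}
    for bits in range(32):
        seq = "".join("L" if bits & (1 << (4 - t)) else "S" for t in range(5))
        choices = iter(seq)
        record = run_adjusting_task(
            lambda llr, ssr: Role.LLR if next(choices) == "L" else Role.SSR,
            grid=grid,
        )
        out[seq] = record.final_index
    return out


def qc_choice_trial(
    bundle_size: int,
    chooser: Chooser,
    total_large: MoneyAmount | int = DEFAULT_LLR_TOTAL,
    total_small: MoneyAmount | int = DEFAULT_SSR_TOTAL,
) -> bool:
    """The appended quality-control trial: both totals fully immediate.

    Presents the $1000-total option against the $500-total option with
    every delay removed; at bundle sizes above 1 the totals stay framed
    as installments ("$333.33 now, $333.34 now, and $333.33 now").
    Passing means choosing the larger total, which dominates for any
    value-maximizing chooser at any discount rate.
    """
    zeros = [0.0] * bundle_size
    large = BundleOption(Role.LLR, split_total(total_large, bundle_size), zeros)
    small = BundleOption(Role.SSR, split_total(total_small, bundle_size), zeros)
    return Role(chooser(large, small)) is Role.LLR
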