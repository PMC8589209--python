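"""Hyperbolic discounting of single and bundled rewards.

The single-reward model is the hyperbolic discount function

    V = A / (1 + k * D)

with amount ``A`` (USD), delay ``D`` (days) and discount rate ``k``
(1/day).  A *bundle* is a series of rewards delivered at successive
delays; under the additive extension of the model its value is the sum
of the discounted values of every installment:

    V_bundle = sum_i  A_i / (1 + k * D_i)

Money is held as integer cents at rest (exact arithmetic); floating
point enters only when a discount curve is evaluated.  Rounding to
cents is round-half-up, which reproduces the cent-adjusted installment
splits used when a fixed total is divided across a bundle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "HOUR",
    "WEEK",
    "MONTH",
    "YEAR",
    "Role",
    "DiscountParams",
    "MoneyAmount",
    "BundleOption",
    "round_to_cents",
    "discounted_value",
    "bundle_value",
    "split_total",
    "build_bundle_options",
    "DEFAULT_LLR_TOTAL",
    "DEFAULT_SSR_TOTAL",
]

# Time units, expressed in days.  A 365-day year keeps the task's
# printed schedule arithmetic exact (e.g. 715.30 d = 1.96 y and
# 715.30 * 9 / 365 = 17.64 y).
HOUR = 1.0 / 24.0
WEEK = 7.0
MONTH = 365.0 / 12.0
YEAR = 365.0

#: Default option totals, in cents: $1000 larger-later vs $500 smaller-sooner.
DEFAULT_LLR_TOTAL = 100_000
DEFAULT_SSR_TOTAL = 50_000


class Role(str, enum.Enum):
    """Which side of an intertemporal choice an option plays."""

    LLR = "LLR"  # larger, later reward
    SSR = "SSR"  # smaller, sooner reward


@dataclass(frozen=True)
class DiscountParams:
    """Hyperbolic discounting parameters.

    Parameters
    ----------
    k : float
        Discount rate in 1/day.  Must be non-negative; ``k == 0`` is the
        degenerate no-discounting case (useful in limits and tests).
    """

    k: float

    def __post_init__(self) -> None:
        if not (self.k >= 0.0) or math.isinf(self.k) or math.isnan(self.k):
            raise ValueError(f"discount rate k must be finite and >= 0, got {self.k!r}")


@dataclass(frozen=True)
class MoneyAmount:
    """An exact USD amount stored as integer cents."""

    cents: int

    def __post_init__(self) -> None:
        if not isinstance(self.cents, int) or isinstance(self.cents, bool):
            raise TypeError("cents must be an int")
        if self.cents < 0:
            raise ValueError(f"money amounts are non-negative, got {self.cents} cents")

    @classmethod
    def from_dollars(cls, dollars: float) -> "MoneyAmount":
        return cls(round_to_cents(dollars))

    @property
    def dollars(self) -> float:
        return self.cents / 100.0

    def __str__(self) -> str:  # "$333.34"
        return f"${self.cents // 100}.{self.cents % 100:02d}"


def round_to_cents(dollars: float) -> int:
    """Round a dollar amount to integer cents, half-up.

    ``round()`` is not used because banker's rounding would turn
    $238.665 into $238.66 or $238.68 depending on binary representation;
    half-up matches the cent-adjusted amounts shown to participants.
    """
    if dollars < 0:
        raise ValueError(f"negative amount: {dollars}")
    return int(math.floor(dollars * 100.0 + 0.5))


@dataclass(frozen=True)
class BundleOption:
    """One choice alternative: a bundle of installments.

    ``amounts`` and ``delays`` are parallel: installment ``i`` pays
    ``amounts[i]`` after ``delays[i]`` days.  Delays must be
    non-decreasing; in an adjusting-delay trial they are strictly
    increasing with spacing D1 (the quality-control trial, with every
    installment at delay 0, is the one sanctioned exception).
    """

    role: Role
    amounts: tuple[MoneyAmount, ...]
    delays: tuple[float, ...]

    def __init__(self, role: Role, amounts: Sequence[MoneyAmount], delays: Sequence[float]):
        object.__setattr__(self, "role", Role(role))
        object.__setattr__(self, "amounts", tuple(amounts))
        object.__setattr__(self, "delays", tuple(float(d) for d in delays))
        self._validate()

    def _validate(self) -> None:
        if len(self.amounts) == 0:
            raise ValueError("a bundle must contain at least one installment")
        if len(self.amounts) != len(self.delays):
            raise ValueError(
                f"{len(self.amounts)} amounts but {len(self.delays)} delays"
            )
        if any(d < 0 for d in self.delays):
            raise ValueError(f"negative delay in {self.delays}")
        if any(b < a for a, b in zip(self.delays, self.delays[1:])):
            raise ValueError(f"delays must be non-decreasing, got {self.delays}")

    @property
    def bundle_size(self) -> int:
        return len(self.amounts)

    @property
    def total(self) -> MoneyAmount:
        return MoneyAmount(sum(a.cents for a in self.amounts))


def discounted_value(amount: float, params: DiscountParams, delay: float) -> float:
    """Discounted value ``A / (1 + k * D)`` of a single reward, in USD.

    Full precision: rounding to cents happens only at presentation via
    :func:`round_to_cents`.

    Parameters
    ----------
    amount : float
        Objective amount A in dollars, >= 0.
    params : DiscountParams
        Discount rate k (1/day).
    delay : float
        Delay D in days, >= 0.
    """
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount}")
    if delay < 0:
        raise ValueError(f"delay must be >= 0, got {delay}")
    return amount / (1.0 + params.k * delay)


def bundle_value(
    option: BundleOption, params: DiscountParams, *, cent_rounded_terms: bool = False
) -> float:
    """Additive value of a bundle: the summed discounted values of its rewards.

    With ``cent_rounded_terms=True`` each installment's discounted value
    is rounded to cents before summing, reproducing presentation-style
    arithmetic such as $477.33 + $313.48 + $233.37 = $1024.18; the
    default keeps full floating-point precision for model work.
    """
    terms = (
        discounted_value(a.dollars, params, d)
        for a, d in zip(option.amounts, option.delays)
    )
    if cent_rounded_terms:
        return sum(round_to_cents(t) for t in terms) / 100.0
    return sum(terms)


def split_total(
    total: MoneyAmount | int, n: int, *, residual_order: str = "later-first"
) -> list[MoneyAmount]:
    """Split a total into ``n`` cent-exact installments.

    Every installment starts at round-half-up(total / n); the leftover
    cents (at most a few, one per installment) are applied starting at
    the middle installment (index ceil(n/2), 1-based) and spreading
    outward, so the installments always sum exactly to the total and no
    two differ by more than one cent.  E.g. $500 / 3 ->
    [$166.67, $166.66, $166.67] and $1000 / 3 -> [$333.33, $333.34, $333.33].

    ``residual_order`` controls which neighbour of the middle receives
    the second correction cent when more than one is needed
    ("later-first", the default, or "earlier-first"); both printed
    3-installment schedules need only a single correction cent and are
    identical under either order.
    """
    if isinstance(total, MoneyAmount):
        total_cents = total.cents
    else:
        total_cents = int(total)
    if n < 1:
        raise ValueError(f"bundle size must be >= 1, got {n}")
    if residual_order not in ("later-first", "earlier-first"):
        raise ValueError(f"unknown residual_order: {residual_order!r}")

    base = round_to_cents(total_cents / n / 100.0)
    residual = total_cents - base * n  # signed cents still owed
    cents = [base] * n

    # middle first, then alternate outward one cent at a time
    mid = math.ceil(n / 2) - 1  # 0-based
    order = [mid]
    for step in range(1, n):
        pair = [mid + step, mid - step]
        if residual_order == "earlier-first":
            pair.reverse()
        order.extend(i for i in pair if 0 <= i < n)
    sign = 1 if residual > 0 else -1
    for i in order[: abs(residual)]:
        cents[i] += sign
    assert sum(cents) == total_cents
    return [MoneyAmount(c) for c in cents]


def build_bundle_options(
    D1: float,
    n: int,
    total_llr: MoneyAmount | int = DEFAULT_LLR_TOTAL,
    total_ssr: MoneyAmount | int = DEFAULT_SSR_TOTAL,
) -> tuple[BundleOption, BundleOption]:
    """Construct the LLR/SSR bundle pair for one trial at first delay ``D1``.

    The larger-later option pays its installments at D1, 2*D1, ..., n*D1;
    the smaller-sooner option at 0, D1, ..., (n-1)*D1.  The spacing
    between consecutive rewards within either bundle is D1, and every
    smaller-sooner installment arrives exactly D1 days before its paired
    larger-later installment.
    """
    if not D1 > 0:
        raise ValueError(f"D1 must be > 0, got {D1}")
    llr_amounts = split_total(total_llr, n)
    ssr_amounts = split_total(total_ssr, n)
    llr = BundleOption(Role.LLR, llr_amounts, [i * D1 for i in range(1, n + 1)])
    ssr = BundleOption(Role.SSR, ssr_amounts, [i * D1 for i in range(0, n)])
    return llr, ssr
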