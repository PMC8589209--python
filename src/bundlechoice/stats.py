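"""Statistical analyses for the bundled intertemporal-choice study.

Indifference delays are positively skewed, so all inference runs on
log10 days.  The analysis battery:

* two-way mixed ANOVA — bundle size within subjects, presentation
  order between subjects, and their interaction; partial eta squared
  per effect and uncorrected degrees of freedom by default (a
  Greenhouse–Geisser flag is available);
* planned comparisons — paired t tests between bundle-size conditions
  and two-sample t tests between order groups at each bundle size,
  each family of three Bonferroni-corrected;
* one-sample t tests of predicted-minus-observed difference scores
  against zero;
* one-sample TOST equivalence tests with an equivalence interval of
  0 ± 0.1 standard deviations of the difference scores;
* a priori power for the within-between interaction in
  repeated-measures ANOVA via the noncentral F distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaTable",
    "ComparisonResult",
    "TTestResult",
    "EquivalenceResult",
    "PowerSpec",
    "log_transform",
    "mixed_anova",
    "planned_comparisons",
    "one_sample_t",
    "equivalence_test",
    "rm_anova_power",
]


def log_transform(indifference_days):
    """Base-10 log of indifference delay(s) in days.

    Base 10 is pinned by the published scale of the analysis: a mean
    log indifference delay of 2.85 corresponds to 715.30 raw days, and
    log10(715.30) = 2.854.
    """
    x = np.asarray(indifference_days, dtype=float)
    if np.any(x <= 0):
        raise ValueError("indifference delays must be > 0 for log transform")
    out = np.log10(x)
    return float(out) if np.isscalar(indifference_days) or out.ndim == 0 else out


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaTable:
    """Mixed-ANOVA results keyed by effect."""

    bundle_size: AnovaEffect  # within-subjects main effect
    order: AnovaEffect  # between-subjects main effect
    interaction: AnovaEffect
    n_analyzed: int
    n_excluded: int  # listwise exclusions for missing conditions

    def effects(self) -> dict[str, AnovaEffect]:
        return {
            "bundle_size": self.bundle_size,
            "order": self.order,
            "interaction": self.interaction,
        }


def _complete_cases(
    data: pd.DataFrame, dv: str, within: str, subject: str, between: str
) -> tuple[pd.DataFrame, int]:
    m = data[within].nunique()
    counts = data.groupby(subject)[within].nunique()
    complete = counts[counts == m].index
    excluded = int((counts != m).sum())
    if excluded:
        warnings.warn(
            f"{excluded} participant(s) lack at least one condition; "
            "excluded listwise from the ANOVA",
            stacklevel=3,
        )
    return data[data[subject].isin(complete)].copy(), excluded


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "log10_id",
    within: str = "bundle_size",
    between: str = "order_group",
    subject: str = "participant_id",
    *,
    sphericity_correction: bool = False,
) -> AnovaTable:
    """Two-way mixed ANOVA with partial eta squared.

    ``data`` is long-format: one row per participant x condition.
    Degrees of freedom are uncorrected by default — with N analyzed
    participants, g groups and m conditions the within effects carry
    ((m-1), (N-g)(m-1)) and the between effect (g-1, N-g).  Passing
    ``sphericity_correction=True`` applies Greenhouse–Geisser.
    """
    clean, excluded = _complete_cases(data, dv, within, subject, between)
    n = clean[subject].nunique()
    if n < 3:
        raise ValueError(f"too few complete participants for ANOVA: {n}")
    table = pg.mixed_anova(
        data=clean, dv=dv, within=within, subject=subject, between=between,
        correction=bool(sphericity_correction), effsize="np2",
    )
    table = table.set_index("Source")

    def _effect(source: str, name: str) -> AnovaEffect:
        row = table.loc[source]
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        if sphericity_correction and "p_GG_corr" in row.index and not pd.isna(row.get("p_GG_corr")):
            p = float(row["p_GG_corr"])
        return AnovaEffect(
            name=name, F=float(row["F"]), df1=df1, df2=df2, p=p,
            partial_eta_sq=float(row["np2"]),
        )

    return AnovaTable(
        bundle_size=_effect(within, "bundle_size"),
        order=_effect(between, "order"),
        interaction=_effect("Interaction", "interaction"),
        n_analyzed=n,
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """One planned comparison with its Bonferroni-corrected p value."""

    label: str
    kind: str  # "paired" or "independent"
    mean_diff: float  # log10 units
    t: float
    df: float
    p_uncorrected: float
    p_bonferroni: float
    family_size: int


def planned_comparisons(
    data: pd.DataFrame,
    dv: str = "log10_id",
    within: str = "bundle_size",
    between: str = "order_group",
    subject: str = "participant_id",
) -> list[ComparisonResult]:
    """Planned within- and between-subjects comparisons.

    Family 1 (paired, Bonferroni x3): each pair of bundle-size
    conditions, later minus earlier condition in ascending size order.
    Family 2 (independent, Bonferroni x3): descending minus ascending
    order group at each bundle size.  Mean differences are in log10
    days.
    """
    clean, _ = _complete_cases(data, dv, within, subject, between)
    wide = clean.pivot_table(index=subject, columns=within, values=dv)
    sizes = sorted(wide.columns)
    groups = clean.drop_duplicates(subject).set_index(subject)[between]
    if (wide.shape[0] < 2) or any(
        (groups == g).sum() < 2 for g in groups.unique()
    ):
        raise ValueError("planned comparisons need >= 2 participants per cell")

    results: list[ComparisonResult] = []
    pairs = [(b, a) for i, a in enumerate(sizes) for b in sizes[i + 1:]]
    fam = len(pairs)
    for hi, lo in pairs:
        t, p = sps.ttest_rel(wide[hi], wide[lo])
        results.append(ComparisonResult(
            label=f"BS{hi} - BS{lo}", kind="paired",
            mean_diff=float((wide[hi] - wide[lo]).mean()),
            t=float(t), df=float(wide.shape[0] - 1), p_uncorrected=float(p),
            p_bonferroni=min(1.0, float(p) * fam), family_size=fam,
        ))

    fam2 = len(sizes)
    for bs in sizes:
        desc = wide.loc[groups[groups == "descending"].index, bs]
        asc = wide.loc[groups[groups == "ascending"].index, bs]
        t, p = sps.ttest_ind(desc, asc)
        results.append(ComparisonResult(
            label=f"descending - ascending @ BS{bs}", kind="independent",
            mean_diff=float(desc.mean() - asc.mean()),
            t=float(t), df=float(len(desc) + len(asc) - 2), p_uncorrected=float(p),
            p_bonferroni=min(1.0, float(p) * fam2), family_size=fam2,
        ))
    return results


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean: float
    sd: float
    n: int


def one_sample_t(scores) -> TTestResult:
    """Two-sided one-sample t test of the scores against zero."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t needs n >= 2")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    t, p = sps.ttest_1samp(x, 0.0)
    return TTestResult(
        t=float(t), df=float(x.size - 1), p=float(p),
        mean=float(x.mean()), sd=sd, n=int(x.size),
    )


@dataclass(frozen=True)
class EquivalenceResult:
    """One-sample TOST against a +/- delta-factor * SD interval."""

    mean_diff: float
    sd: float
    n: int
    delta: float  # equivalence half-width (delta_factor * sd)
    t_lower: float
    p_lower: float
    t_upper: float
    p_upper: float
    ci95: tuple[float, float]
    equivalent: bool  # both one-sided p < alpha
    ci_within_interval: bool  # 95% CI entirely inside (-delta, +delta)


def equivalence_test(
    scores, delta_factor: float = 0.1, alpha: float = 0.05
) -> EquivalenceResult:
    """One-sample equivalence test (two one-sided t tests).

    The equivalence interval is zero plus or minus ``delta_factor``
    standard deviations of the scores — with the default 0.1 SD, a
    negligible effect size.  The lower test rejects when the mean is
    significantly above -delta, the upper when significantly below
    +delta; equivalence requires both at level ``alpha``.  The result
    also reports whether the 95% confidence interval of the mean lies
    entirely within the interval, the criterion under which a
    significant equivalence conclusion manifests.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("equivalence test needs n >= 2")
    n = int(x.size)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: equivalence bounds degenerate")
    delta = delta_factor * sd
    se = sd / math.sqrt(n)
    df = n - 1
    t_lower = (mean + delta) / se  # H0: mean <= -delta
    t_upper = (mean - delta) / se  # H0: mean >= +delta
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    tcrit = float(sps.t.ppf(0.975, df))
    ci95 = (mean - tcrit * se, mean + tcrit * se)
    return EquivalenceResult(
        mean_diff=mean, sd=sd, n=n, delta=delta,
        t_lower=float(t_lower), p_lower=p_lower,
        t_upper=float(t_upper), p_upper=p_upper,
        ci95=ci95,
        equivalent=bool(p_lower < alpha and p_upper < alpha),
        ci_within_interval=bool(-delta < ci95[0] and ci95[1] < delta),
    )


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for repeated-measures interaction power.

    f is Cohen's effect size; rho the correlation among repeated
    measures; epsilon the nonsphericity correction (1 = none).
    """

    f: float
    alpha: float = 0.05
    g: int = 2  # between-subjects groups
    m: int = 3  # repeated measures
    rho: float = 0.5
    N: int = 260  # total sample size
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("effect size f must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.g < 2 or self.m < 2 or self.N <= self.g:
            raise ValueError("need g >= 2, m >= 2, N > g")


def rm_anova_power(spec: PowerSpec) -> float:
    """Power for the within-between interaction in mixed repeated-measures ANOVA.

    Noncentral-F computation with noncentrality
    lambda = f^2 * N * m * epsilon / (1 - rho), numerator df
    (g-1)(m-1)*epsilon and denominator df (N-g)(m-1)*epsilon — the
    standard convention for repeated-measures power with correlated
    measures.  At f = 0 the distribution is central and power equals
    alpha.
    """
    lam = spec.f**2 * spec.N * spec.m * spec.epsilon / (1.0 - spec.rho)
    df1 = (spec.g - 1) * (spec.m - 1) * spec.epsilon
    df2 = (spec.N - spec.g) * (spec.m - 1) * spec.epsilon
    fcrit = sps.f.isf(spec.alpha, df1, df2)
    if lam == 0.0:
        return float(spec.alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))
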