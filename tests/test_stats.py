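"""Statistical pipeline: log transform, mixed ANOVA, planned comparisons,
one-sample t, TOST equivalence, and repeated-measures power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bundlechoice import (
    PowerSpec,
    equivalence_test,
    log_transform,
    mixed_anova,
    one_sample_t,
    planned_comparisons,
    rm_anova_power,
)
from conftest import null_log_id_table


class TestLogTransform:
    def test_published_scale_anchor(self):
        """log10(715.30 d) = 2.85 at two decimals pins the base."""
        assert round(log_transform(715.30), 2) == 2.85

    @pytest.mark.parametrize("days, expected", [(1.0, 0.0), (266.11, 2.4251)])
    def test_values(self, days, expected):
        assert log_transform(days) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_transform(0.0)


def manual_mixed_anova_ss(df):
    """From-scratch sum-of-squares decomposition for the balanced
    two-way mixed design (within: bundle_size; between: order_group)."""
    wide = df.pivot_table(index="participant_id", columns="bundle_size", values="log10_id")
    groups = df.drop_duplicates("participant_id").set_index("participant_id")["order_group"]
    y = wide.to_numpy()
    n, m = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    glabels = groups.loc[wide.index].to_numpy()
    out = {}
    # between-subjects decomposition
    ss_subj = m * ((subj_means - grand) ** 2).sum()
    ss_group = sum(
        m * (glabels == g).sum() * (subj_means[glabels == g].mean() - grand) ** 2
        for g in np.unique(glabels)
    )
    ss_subj_within_grp = ss_subj - ss_group
    # within-subjects decomposition
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_interaction = 0.0
    for g in np.unique(glabels):
        sub = y[glabels == g]
        gc = sub.mean(axis=0)
        ss_interaction += sub.shape[0] * ((gc - gc.mean() - cond_means + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_error_within = ss_total - ss_subj - ss_cond - ss_interaction
    g_count = len(np.unique(glabels))
    return {
        "group": (ss_group, g_count - 1, ss_subj_within_grp, n - g_count),
        "cond": (ss_cond, m - 1, ss_error_within, (n - g_count) * (m - 1)),
        "inter": (ss_interaction, (g_count - 1) * (m - 1), ss_error_within,
                  (n - g_count) * (m - 1)),
    }


class TestMixedAnova:
    def test_df_bookkeeping_at_study_scale(self):
        """222 analyzed participants, 2 groups, 3 conditions -> within df
        (2, 440) and between df (1, 220)."""
        table = mixed_anova(null_log_id_table(222, np.random.default_rng(0)))
        assert (table.bundle_size.df1, table.bundle_size.df2) == (2, 440)
        assert (table.interaction.df1, table.interaction.df2) == (2, 440)
        assert (table.order.df1, table.order.df2) == (1, 220)

    @given(n=st.sampled_from([8, 20, 54]), m=st.sampled_from([2, 3, 4]))
    @settings(max_examples=12, deadline=None)
    def test_df_closed_forms(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        rows = []
        for pid in range(n):
            for c in range(m):
                rows.append((pid, "ascending" if pid % 2 else "descending", c, rng.normal()))
        df = pd.DataFrame(rows, columns=["participant_id", "order_group", "bundle_size", "log10_id"])
        table = mixed_anova(df)
        assert (table.bundle_size.df1, table.bundle_size.df2) == (m - 1, (n - 2) * (m - 1))
        assert (table.order.df1, table.order.df2) == (1, n - 2)

    def test_matches_manual_ss_decomposition(self):
        """Six-participant dataset vs a from-scratch SS oracle."""
        rng = np.random.default_rng(13)
        df = null_log_id_table(6, rng)
        df["log10_id"] += 0.2 * df["bundle_size"]  # add a real condition effect
        table = mixed_anova(df)
        ss = manual_mixed_anova_ss(df)
        for effect, (sse, df1, ssr, df2) in zip(
            [table.order, table.bundle_size, table.interaction],
            [ss["group"], ss["cond"], ss["inter"]],
        ):
            f_expected = (sse / df1) / (ssr / df2)
            assert effect.F == pytest.approx(f_expected, rel=1e-8)
            assert effect.partial_eta_sq == pytest.approx(sse / (sse + ssr), rel=1e-8)

    def test_incomplete_participants_excluded_with_warning(self):
        df = null_log_id_table(10, np.random.default_rng(2))
        df = df.drop(df[(df["participant_id"] == 0) & (df["bundle_size"] == 9)].index)
        with pytest.warns(UserWarning, match="excluded listwise"):
            table = mixed_anova(df)
        assert table.n_analyzed == 9
        assert table.n_excluded == 1

    def test_null_type_one_error_rate(self):
        """Under a pure-noise generator each effect rejects at ~alpha."""
        rng = np.random.default_rng(101)
        reject = {"bundle_size": 0, "order": 0, "interaction": 0}
        reps = 300
        for _ in range(reps):
            table = mixed_anova(null_log_id_table(20, rng))
            for name, eff in table.effects().items():
                reject[name] += eff.p < 0.05
        for name, count in reject.items():
            rate = count / reps
            # binomial 3-sigma band around .05 for 300 reps
            assert 0.05 - 3 * 0.0126 < rate < 0.05 + 3 * 0.0126, (name, rate)


class TestPlannedComparisons:
    def test_identical_conditions_give_zero_diff_p_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=12)
        rows = []
        for pid in range(12):
            for bs in (1, 3, 9):
                rows.append((pid, "ascending" if pid % 2 else "descending", bs, base[pid]))
        df = pd.DataFrame(rows, columns=["participant_id", "order_group", "bundle_size", "log10_id"])
        results = planned_comparisons(df)
        paired = [r for r in results if r.kind == "paired"]
        assert all(r.mean_diff == pytest.approx(0.0) for r in paired)
        assert all(r.p_bonferroni == 1.0 for r in paired)

    def test_deterministic_cohort_shows_positive_bundling_effects(self, deterministic_cohort):
        from bundlechoice.pipeline import indifference_table

        ids = indifference_table(deterministic_cohort.trials)
        results = planned_comparisons(ids)
        paired = {r.label: r for r in results if r.kind == "paired"}
        assert paired["BS3 - BS1"].mean_diff > 0
        assert paired["BS9 - BS1"].mean_diff > 0
        assert paired["BS9 - BS3"].mean_diff > 0

    def test_family_wise_error_under_null(self):
        """Bonferroni x3 keeps the family-wise rejection rate at or
        below .05 in each family."""
        rng = np.random.default_rng(17)
        reps = 2000
        fw_paired = fw_between = 0
        for _ in range(reps):
            df = null_log_id_table(16, rng)
            results = planned_comparisons(df)
            fw_paired += any(
                r.p_bonferroni < 0.05 for r in results if r.kind == "paired")
            fw_between += any(
                r.p_bonferroni < 0.05 for r in results if r.kind == "independent")
        # <= .05 plus 3-sigma Monte-Carlo headroom
        assert fw_paired / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)
        assert fw_between / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_too_small_cells_rejected(self):
        df = null_log_id_table(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            planned_comparisons(df)


class TestOneSampleT:
    def test_against_scipy_free_oracle(self):
        """Direct t = mean/(sd/sqrt(n)) with survival-function p."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0.1, 1.0, size=rng.integers(5, 40))
            res = one_sample_t(x)
            t_manual = x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))
            p_manual = 2 * sps.t.sf(abs(t_manual), len(x) - 1)
            assert res.t == pytest.approx(t_manual, rel=1e-10)
            assert res.p == pytest.approx(p_manual, rel=1e-10)
            assert res.df == len(x) - 1

    def test_antisymmetric_data_gives_t_zero_p_one(self):
        res = one_sample_t([-0.4, 0.4, -1.1, 1.1])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_null_scores_rarely_reject(self):
        """n=222 draws from Normal(0, 0.85): the null is retained in the
        large majority of replications."""
        rng = np.random.default_rng(7)
        retained = sum(
            one_sample_t(rng.normal(0.0, 0.85, size=222)).p > 0.05 for _ in range(200)
        )
        assert retained >= 180  # ~95% expected

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.5] * 10)


class TestEquivalence:
    def test_large_tight_sample_is_equivalent(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 1.0, size=1000)
        res = equivalence_test(x)
        # SE ~ 0.032 << delta ~ 0.1 sd: both one-sided tests reject
        assert res.equivalent
        assert res.p_lower < 0.05 and res.p_upper < 0.05

    def test_shifted_mean_not_equivalent(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.0, 1.0, size=1000) + 2.0
        assert not equivalence_test(x).equivalent

    def test_small_noisy_sample_not_equivalent_despite_null_t(self):
        """Mirrors the study's outcome pattern: the t test retains the
        null while equivalence is not established."""
        rng = np.random.default_rng(10)
        x = rng.normal(0.0, 1.0, size=10)
        x -= x.mean()  # mean exactly 0
        res = equivalence_test(x)
        assert one_sample_t(x).p == pytest.approx(1.0)
        assert not res.equivalent

    def test_tost_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.02, 0.5, size=60)
        res = equivalence_test(x, delta_factor=0.1, alpha=0.05)
        n, mean, sd = len(x), x.mean(), x.std(ddof=1)
        se = sd / math.sqrt(n)
        delta = 0.1 * sd
        assert res.p_lower == pytest.approx(sps.t.sf((mean + delta) / se, n - 1), rel=1e-10)
        assert res.p_upper == pytest.approx(sps.t.cdf((mean - delta) / se, n - 1), rel=1e-10)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_conclusion_invariant_to_rescaling(self, scale):
        """delta scales with the SD, so scaling all scores cannot change
        the equivalence verdict."""
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 0.3, size=80)
        assert equivalence_test(x).equivalent == equivalence_test(x * scale).equivalent

    def test_ci_within_interval_flag(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0.0, 1.0, size=5000)
        res = equivalence_test(x)
        lo, hi = res.ci95
        assert res.ci_within_interval == (-res.delta < lo and hi < res.delta)


class TestPower:
    def test_study_sample_size_reaches_95_percent(self):
        spec = PowerSpec(f=0.10, alpha=0.05, g=2, m=3, rho=0.5, N=260)
        assert rm_anova_power(spec) >= 0.95

    def test_zero_effect_power_equals_alpha(self):
        assert rm_anova_power(PowerSpec(f=0.0, alpha=0.05)) == pytest.approx(0.05)

    def test_power_increases_with_sample_size(self):
        powers = [rm_anova_power(PowerSpec(f=0.10, N=n)) for n in range(50, 501, 50)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f=0.1, rho=1.0)
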