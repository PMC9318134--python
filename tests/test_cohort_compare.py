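"""Tests of the normality, rank-test and cohort-comparison machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ihcquant import (
    compare_cohort,
    dagostino_pearson,
    generate_cohort,
    mann_whitney,
    results_to_frame,
    wilcoxon_signed_rank,
)


# --- independent enumeration oracles --------------------------------------

def mw_enumeration_oracle(a, b):
    """Two-sided exact p over all C(n_a+n_b, n_a) group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_stat(aa, bb):
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    u_obs = u_stat(a, b)
    idx = range(len(pooled))
    us = []
    for comb in itertools.combinations(idx, na):
        rest = [i for i in idx if i not in comb]
        us.append(u_stat(pooled[list(comb)], pooled[rest]))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, p)


def wsr_enumeration_oracle(a, b):
    """Two-sided exact p over all 2^n sign assignments of the rank sums."""
    d = np.asarray(b, float) - np.asarray(a, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    tps = np.array(
        [sum(r for s, r in zip(signs, ranks) if s)
         for signs in itertools.product([0, 1], repeat=len(d))]
    )
    p = 2 * min((tps <= t_plus).mean(), (tps >= t_plus).mean())
    return min(t_plus, ranks.sum() - t_plus), min(1.0, p)


class TestDagostinoPearson:
    def test_type_one_error_is_calibrated(self, rng):
        """~5% rejections on truly normal data (500 simulations of n=10^4)."""
        rej = sum(
            dagostino_pearson(rng.normal(size=10_000)).p_value < 0.05 for _ in range(500)
        )
        assert 0.03 <= rej / 500 <= 0.07

    def test_detects_exponential_skew(self, rng):
        """>=90% power against an exponential sample at n=200."""
        rej = sum(
            dagostino_pearson(rng.exponential(size=200)).p_value < 0.05 for _ in range(500)
        )
        assert rej / 500 >= 0.90

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            dagostino_pearson(np.arange(7.0))
        with pytest.raises(ValueError, match="zero-variance"):
            dagostino_pearson(np.full(20, 2.0))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        out = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert out.statistic == 0.0
        assert out.p_value == pytest.approx(0.1)   # 2/20 arrangements as extreme
        assert out.method == "exact"

    def test_identical_groups_give_p_one(self):
        out = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.p_value == pytest.approx(1.0)

    def test_u_identity(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            u_ab = mann_whitney(a, b).statistic
            u_ba = mann_whitney(b, a).statistic
            assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            a = rng.normal(size=int(rng.integers(2, 6)))
            b = rng.normal(size=int(rng.integers(2, 6)))
            u_oracle, p_oracle = mw_enumeration_oracle(a, b)
            out = mann_whitney(a, b)
            assert out.method == "exact"
            assert out.statistic == pytest.approx(u_oracle)
            assert out.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_asymptotic_close_to_exact_for_small_samples(self, rng):
        """Normal approximation within 0.05 of enumeration for tie-free data."""
        for _ in range(15):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            _, p_exact = mw_enumeration_oracle(a, b)
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert abs(res.pvalue - p_exact) <= 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_null_calibration_at_study_size(self, rng):
        """Type-I error in [3%, 7%] at n = 11 per group over 2000 simulations."""
        rej = sum(
            mann_whitney(rng.normal(size=11), rng.normal(size=11)).p_value < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07


class TestWilcoxonSignedRank:
    def test_constant_shift_is_maximally_extreme(self):
        a = np.arange(6.0)
        out = wilcoxon_signed_rank(a, a + 3.0)
        assert out.statistic == 0.0
        assert out.p_value == pytest.approx(2 / 64)
        assert out.method == "exact"

    def test_all_zero_differences_rejected(self):
        a = np.arange(5.0)
        with pytest.raises(ValueError, match="all paired differences are zero"):
            wilcoxon_signed_rank(a, a.copy())

    def test_two_sided_p_symmetric_in_arguments(self, rng):
        for _ in range(10):
            a = rng.normal(size=8)
            b = a + rng.normal(0.3, 1.0, size=8)
            assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
                wilcoxon_signed_rank(b, a).p_value
            )

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 10))
            a = rng.normal(size=n)
            b = a + rng.normal(0.5, 1.0, size=n)
            w_oracle, p_oracle = wsr_enumeration_oracle(a, b)
            out = wilcoxon_signed_rank(a, b)
            assert out.method == "exact"
            assert out.statistic == pytest.approx(w_oracle)
            assert out.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_asymptotic_close_to_exact_for_small_samples(self, rng):
        for _ in range(15):
            a = rng.normal(size=9)
            b = a + rng.normal(0.2, 1.0, size=9)
            _, p_exact = wsr_enumeration_oracle(a, b)
            d = b - a
            res = stats.wilcoxon(d, alternative="two-sided", correction=True, method="approx")
            assert abs(res.pvalue - p_exact) <= 0.05

    def test_null_calibration_at_study_size(self, rng):
        """Type-I error in [3%, 7%] for n = 11 pairs over 2000 simulations."""
        rej = 0
        for _ in range(2000):
            a = rng.normal(size=11)
            b = a + rng.normal(0.0, 1.0, size=11)
            rej += wilcoxon_signed_rank(a, b).p_value < 0.05
        assert 0.03 <= rej / 2000 <= 0.07


class TestCompareCohort:
    def test_deterministic_result_table(self):
        c = generate_cohort(seed=6)
        t1 = results_to_frame(compare_cohort(c))
        t2 = results_to_frame(compare_cohort(c))
        assert t1.equals(t2)

    def test_effect_markers_flagged_null_markers_not(self):
        c = generate_cohort(seed=1)
        df = results_to_frame(compare_cohort(c))
        pi_pd = df[df.comparison == "PI_vs_PD"]
        flagged = set(pi_pd.loc[pi_pd.significant, "marker"])
        assert {"CD68", "CD138"} <= flagged

    def test_identical_methods_surface_degenerate_signed_rank(self):
        c = generate_cohort(seed=2)
        data = c.data.copy()
        # overwrite DC with MC values: every paired difference is zero
        wide = data.pivot_table(index=["patient_id", "group", "marker", "field_id"],
                                columns="method", values="value").reset_index()
        wide["DC"] = wide["MC"]
        long = wide.melt(id_vars=["patient_id", "group", "marker", "field_id"],
                         value_vars=["MC", "DC"], var_name="method", value_name="value")
        from ihcquant import CohortDataset
        df = results_to_frame(compare_cohort(CohortDataset(data=long, n_pi=11, n_pd=11)))
        mcdc = df[df.comparison == "MC_vs_DC"]
        assert (mcdc.significant.isna()).all()
        assert mcdc.note.str.contains("zero").all()

    def test_field_level_unit_runs(self):
        c = generate_cohort(seed=3)
        df = results_to_frame(compare_cohort(c, unit="field", include_normality=False))
        assert (df[df.comparison == "PI_vs_PD"].test_name == "mann_whitney_asymptotic").all()

    @pytest.mark.parametrize("how", ["bonferroni", "fdr_bh"])
    def test_multiplicity_correction_only_raises_pvalues(self, how):
        c = generate_cohort(seed=4)
        raw = results_to_frame(compare_cohort(c, include_normality=False))
        adj = results_to_frame(compare_cohort(c, include_normality=False, correction=how))
        raw_pi = raw[raw.comparison == "PI_vs_PD"].reset_index()
        adj_pi = adj[adj.comparison == "PI_vs_PD"].reset_index()
        assert (adj_pi.p_value >= raw_pi.p_value - 1e-12).all()
        # the injected large effects survive a 7-marker correction
        assert set(adj_pi.loc[adj_pi.significant, "marker"]) >= {"CD68", "CD138"}
        with pytest.raises(ValueError):
            compare_cohort(c, correction="holmes")

    def test_null_cohort_false_positive_rate(self):
        """With no injected effects, ~5% of marker tests reject per run."""
        flags = []
        for s in range(60):
            c = generate_cohort(marker_effects={}, seed=1000 + s)
            df = results_to_frame(compare_cohort(c, include_normality=False))
            pi_pd = df[(df.comparison == "PI_vs_PD") & (df.method == "MC")]
            flags.append(int(pi_pd.significant.sum()))
        rate = np.sum(flags) / (60 * 7)
        assert 0.01 <= rate <= 0.10
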