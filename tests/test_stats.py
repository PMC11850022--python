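"""Statistics suite cross-checked against hand formulas and independent
library implementations (scipy.stats, statsmodels, scikit-learn)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import catstep as cs
from catstep.simulate import INCOMPREHENSIBLE
from catstep.stats import (
    EXCLUDED,
    InsufficientDataError,
    UndefinedStatisticError,
    participant_metrics,
)


class TestAggregateRatings:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [(3, 4, 3.5), (5, 5, 5.0), (1, 2, 1.5), ("2", "4", 3.0)],
    )
    def test_mean_of_two_raters(self, r1, r2, expected):
        assert cs.aggregate_ratings(r1, r2) == expected

    def test_either_incomprehensible_excludes(self):
        assert cs.aggregate_ratings(2, INCOMPREHENSIBLE) == EXCLUDED
        assert cs.aggregate_ratings(INCOMPREHENSIBLE, 5) == EXCLUDED
        assert cs.aggregate_ratings(INCOMPREHENSIBLE, INCOMPREHENSIBLE) == EXCLUDED


class TestBinDimsUsed:
    @pytest.mark.parametrize(
        "x,expected",
        [(1.0, "LOW"), (1.5, "LOW"), (2.0, "MID"), (3.5, "MID"), (4.0, "HIGH"), (5.0, "HIGH")],
    )
    def test_bin_edges(self, x, expected):
        assert cs.bin_dims_used(x) == expected

    @pytest.mark.parametrize("x", [0.5, 5.5])
    def test_out_of_range(self, x):
        with pytest.raises(UndefinedStatisticError):
            cs.bin_dims_used(x)


class TestSpearman:
    def test_perfect_monotone(self):
        assert cs.spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert cs.spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks equal values; sum of squared rank differences = 4
        r = cs.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.rho == pytest.approx(0.6)
        assert r.df == 2

    def test_exhaustive_permutations_match_scipy(self):
        """All rank permutations for n = 3..5 agree with scipy.stats.spearmanr
        (rho exactly, t-approximation p-value closely)."""
        for n in (3, 4, 5):
            xs = list(range(1, n + 1))
            for perm in itertools.permutations(xs):
                try:
                    ours = cs.spearman(xs, perm)
                except UndefinedStatisticError:
                    continue
                ref_rho, ref_p = sps.spearmanr(xs, perm)
                assert ours.rho == pytest.approx(ref_rho, abs=1e-12)
                if abs(ours.rho) < 1:  # scipy's p at |rho|=1 is also 0/nan-free
                    assert ours.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_ties_use_midranks(self):
        ours = cs.spearman([1, 1, 2, 3], [4, 5, 6, 7])
        ref_rho, _ = sps.spearmanr([1, 1, 2, 3], [4, 5, 6, 7])
        assert ours.rho == pytest.approx(ref_rho, abs=1e-12)

    def test_monotone_invariance_and_reversal_antisymmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = cs.spearman(x, y).rho
        assert cs.spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert cs.spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)
        assert cs.spearman(-x, y).rho == pytest.approx(-base, abs=1e-12)

    def test_permutation_p_close_to_t_approx(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        t_p = cs.spearman(x, y).p_value
        perm = cs.spearman(x, y, p_method="permutation", n_perm=4000, seed=3)
        assert perm.p_value == pytest.approx(t_p, abs=0.02)

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            cs.spearman([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            cs.spearman([1, 2], [3, 4])


class TestOlsStandardized:
    def test_perfect_linear_relation(self):
        r = cs.ols_standardized([1, 2, 3, 4], [3, 5, 7, 9])
        assert r.beta == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_beta_equals_pearson_and_identities(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r = cs.ols_standardized(x, y)
        assert r.beta == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)
        assert r.beta**2 == pytest.approx(r.r_squared, abs=1e-12)
        assert r.t == pytest.approx(
            r.beta * math.sqrt((len(x) - 2) / (1 - r.r_squared)), abs=1e-9
        )

    def test_matches_statsmodels_on_zscored_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        y = -0.7 * x + rng.normal(size=30)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(zy, sm.add_constant(zx)).fit()
        ours = cs.ols_standardized(x, y)
        assert ours.beta == pytest.approx(fit.params[1], abs=1e-9)
        assert ours.r_squared == pytest.approx(fit.rsquared, abs=1e-9)
        assert ours.adj_r_squared == pytest.approx(fit.rsquared_adj, abs=1e-9)
        assert ours.p_value == pytest.approx(fit.pvalues[1], abs=1e-9)

    def test_near_zero_slope_for_independent_noise(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(cs.ols_standardized(x, y).beta) < 0.1

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            cs.ols_standardized([2, 2, 2, 2], [1, 2, 3, 4])


class TestAgreement:
    def test_identical_lists(self):
        r = cs.agreement([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.kappa == pytest.approx(1.0)
        assert r.percent_identical == 100.0
        assert r.mean_abs_diff == 0.0

    def test_perfect_disagreement(self):
        # p_o = 0, p_e = 0.5 by the hand formula
        r = cs.agreement(["A", "A", "B", "B"], ["B", "B", "A", "A"])
        assert r.kappa == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # p_o = 0.8, p_e = 0.36 -> kappa = 0.6875
        r = cs.agreement([1, 1, 2, 2, 3], [1, 2, 2, 2, 3])
        assert r.kappa == pytest.approx(0.6875)
        assert r.percent_identical == pytest.approx(80.0)
        assert r.mean_abs_diff == pytest.approx(0.2)

    def test_exhaustive_small_inputs_match_hand_formula(self):
        """All rating pairs of length <= 4 over {1, 2, ID}: kappa equals the
        direct confusion-matrix formula and sklearn's implementation."""
        from sklearn.metrics import cohen_kappa_score

        labels = ["1", "2", INCOMPREHENSIBLE]
        for n in (2, 3, 4):
            for r1 in itertools.product(labels, repeat=n):
                for r2 in itertools.product(labels, repeat=n):
                    p_o = sum(a == b for a, b in zip(r1, r2)) / n
                    cats = sorted(set(r1) | set(r2))
                    p_e = sum(
                        (r1.count(c) / n) * (r2.count(c) / n) for c in cats
                    )
                    if p_e >= 1 - 1e-12:
                        with pytest.raises(UndefinedStatisticError):
                            cs.agreement(list(r1), list(r2))
                        continue
                    ours = cs.agreement(list(r1), list(r2))
                    expected = (p_o - p_e) / (1 - p_e)
                    assert ours.kappa == pytest.approx(expected, abs=1e-12)
                    ref = cohen_kappa_score(list(r1), list(r2))
                    assert ours.kappa == pytest.approx(ref, abs=1e-9)

    def test_incomprehensible_in_kappa_not_in_mad(self):
        r = cs.agreement([1, INCOMPREHENSIBLE, 3], [1, INCOMPREHENSIBLE, 5])
        # the ID-ID pair counts as agreement for kappa...
        assert r.percent_identical == pytest.approx(200 / 3)
        # ...but only numeric pairs enter the mean absolute difference
        assert r.mean_abs_diff == pytest.approx(1.0)

    def test_no_numeric_pairs(self):
        r = cs.agreement([INCOMPREHENSIBLE, 1], [2, INCOMPREHENSIBLE])
        assert r.mean_abs_diff is None


class TestAnovaTukey:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(19)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        res = cs.anova_tukey([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, abs=1e-9)

    def test_equal_group_means_give_zero_eta_squared(self):
        a = [1.0, 2.0, 3.0]
        b = [0.0, 2.0, 4.0]  # same mean, nonzero within-variance
        res = cs.anova_tukey([a, b])
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.eta_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_f_oneway_and_tukey_hsd(self):
        rng = np.random.default_rng(23)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 8), (0.5, 10), (1.5, 9))]
        res = cs.anova_tukey(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f_ref, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)
        ref = sps.tukey_hsd(*groups)
        for pair in res.pairs:
            i = int(pair.group1[-1]) - 1
            j = int(pair.group2[-1]) - 1
            assert pair.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-7)

    def test_detects_separated_group_in_most_seeds(self):
        """Groups at means (0, 0, 2), SD 1, n=15: Tukey rejects exactly the
        pairs involving the shifted group in >=95 of 100 seeds (the
        studentized-range oracle gives this scenario ~99% power)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = [rng.normal(m, 1, 15) for m in (0, 0, 2)]
            res = cs.anova_tukey(g, alpha=0.05)
            by_pair = {(p.group1, p.group2): p.reject for p in res.pairs}
            ok = (
                by_pair[("group1", "group3")]
                and by_pair[("group2", "group3")]
                and not by_pair[("group1", "group2")]
            )
            hits += ok
        assert hits >= 95

    def test_tukey_p_at_least_unadjusted_t(self):
        """Multiplicity correction: adjusted p >= pooled-t p for every pair."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 6))
            groups = [
                rng.normal(rng.normal(0, 1), 1, int(rng.integers(4, 9)))
                for _ in range(k)
            ]
            res = cs.anova_tukey(groups)
            ns = [len(g) for g in groups]
            df2 = sum(ns) - k
            msw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / df2
            for pair in res.pairs:
                i = int(pair.group1[-1]) - 1
                j = int(pair.group2[-1]) - 1
                se = math.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
                t = abs(pair.mean_diff) / se
                p_unadj = 2 * sps.t.sf(t, df2)
                assert pair.p_adj >= p_unadj - 1e-12

    def test_cohen_d_pooled_sd(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        res = cs.anova_tukey([a, b])
        s_pool = math.sqrt((a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6)
        assert res.pairs[0].cohen_d == pytest.approx((b.mean() - a.mean()) / s_pool)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            cs.anova_tukey([[1.0, 2.0]])
        with pytest.raises(InsufficientDataError):
            cs.anova_tukey([[1.0, 2.0], [1.0]])
        with pytest.raises(UndefinedStatisticError):
            cs.anova_tukey([[1.0, 1.0], [1.0, 1.0]])


class TestGroupSummary:
    def test_single_participant_low_bin(self, design_ca5):
        from catstep.simulate import Dataset, simulate_participant
        from tests.test_simulate import make_params

        res = simulate_participant(make_params(), design_ca5, "EXP1")
        trials = pd.DataFrame(res.trials)
        ds = Dataset(
            trials=trials,
            ratings=pd.DataFrame(
                [("P001", 1, 1)], columns=["participant_id", "rater1", "rater2"]
            ),
            participants=pd.DataFrame(),
        )
        table = cs.group_summary(ds, {"P001": 1.0})
        assert table.loc["n_participants", "LOW"] == 1
        expected_rt = trials.loc[trials["phase"] == "transfer", "rt_seconds"].mean()
        assert table.loc["mean_transfer_rt", "LOW"] == pytest.approx(expected_rt)
        assert table.loc["n_participants", ["MID", "HIGH", "ID"]].sum() == 0

    def test_all_excluded_goes_to_id_bin(self, small_cohort):
        dims = {p: EXCLUDED for p in small_cohort.trials["participant_id"].unique()}
        table = cs.group_summary(small_cohort, dims)
        assert table.loc["n_participants", "ID"] == 10
        assert table.loc["n_participants", ["LOW", "MID", "HIGH"]].sum() == 0

    def test_matches_independent_aggregation(self, small_cohort):
        """Table cells equal a from-scratch pandas aggregation."""
        from catstep.pipeline import aggregate_all_ratings

        dims = aggregate_all_ratings(small_cohort)
        table = cs.group_summary(small_cohort, dims)
        # independent recomputation of the LOW-bin transfer RT mean
        trials = small_cohort.trials
        per_pid = (
            trials[trials["phase"] == "transfer"]
            .groupby("participant_id")["rt_seconds"]
            .mean()
        )
        low_pids = [
            p for p, v in dims.items() if v != EXCLUDED and float(v) < 2.0
        ]
        if low_pids:
            assert table.loc["mean_transfer_rt", "LOW"] == pytest.approx(
                per_pid.loc[low_pids].mean()
            )
        counts = table.loc["n_participants"]
        assert counts.sum() == trials["participant_id"].nunique()

    def test_bin_counts_partition_cohort(self, small_cohort):
        from catstep.pipeline import aggregate_all_ratings

        dims = aggregate_all_ratings(small_cohort)
        table = cs.group_summary(small_cohort, dims)
        n_excluded = sum(1 for v in dims.values() if v == EXCLUDED)
        assert table.loc["n_participants", "ID"] == n_excluded

    def test_participant_metrics_columns(self, small_cohort):
        m = participant_metrics(small_cohort)
        assert set(m.columns) == {
            "mean_transfer_rt",
            "dim_accuracy_pct",
            "dims_100",
            "mean_training_rt",
            "training_blocks",
        }
        assert (m["dims_100"] <= 5).all()
        assert (m["dim_accuracy_pct"] <= 100).all()
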