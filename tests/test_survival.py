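"""Survival curves, association tests and mutation/CNV summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpattern.survival import (
    cnv_frequencies,
    contingency_tests,
    cox_fit,
    km_estimate,
    logrank_test,
    mutation_summaries,
    rank_tests,
    spearman_corr,
    time_dependent_auc,
)


def km_bruteforce(times, events):
    """Direct product over risk sets."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in np.sort(np.unique(times[events == 1])):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_censoring_product(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        lookup = dict(zip(c.times, c.survival))
        assert lookup[1] == pytest.approx(2 / 3)
        assert lookup[2] == pytest.approx(1 / 3)
        assert lookup[3] == pytest.approx(0.0)

    def test_all_censored_flat(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert (c.survival == 1.0).all()

    def test_matches_bruteforce_on_random_toys(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 50))
            times = np.round(rng.exponential(5, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            c = km_estimate(times, events)
            lookup = dict(zip(c.times, c.survival))
            for t, s in km_bruteforce(times, events).items():
                assert lookup[t] == pytest.approx(s)

    def test_curve_monotone_with_ci(self):
        c = km_estimate([1, 1, 2, 3, 5, 8], [1, 0, 1, 1, 0, 1])
        assert (np.diff(c.survival) <= 1e-12).all()
        assert (c.ci_low <= c.survival + 1e-12).all()
        assert (c.survival <= c.ci_high + 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_hand_computed_toy(self):
        stat, df, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1],
                                   ["A", "A", "B", "B"])
        assert stat == pytest.approx(2.8824, abs=1e-3)
        assert df == 1

    def test_identical_groups_null(self):
        stat, _, p = logrank_test([1, 2, 1, 2], [1, 1, 1, 1],
                                  ["A", "A", "B", "B"])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        t = [1, 3, 2, 5, 4, 6.0]
        e = [1, 1, 0, 1, 1, 1]
        g1 = ["A", "A", "A", "B", "B", "B"]
        g2 = ["B", "B", "B", "A", "A", "A"]
        assert logrank_test(t, e, g1)[0] == pytest.approx(logrank_test(t, e, g2)[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestCoxFit:
    def test_binary_toy_matches_grid_oracle(self):
        from tests.test_diffexp import efron_loglik_grid

        x = np.array([1.0, 0.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        m = cox_fit(pd.DataFrame({"x": x}), t, e)
        oracle = efron_loglik_grid(x, t, e, np.arange(-2, 4, 0.001))
        assert m.beta["x"] == pytest.approx(oracle, abs=1e-3)

    def test_duplicated_covariate_rejected(self):
        x = np.random.default_rng(0).normal(0, 1, 30)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="rank-deficient"):
            cox_fit(df, np.arange(1, 31, dtype=float), np.ones(30))

    def test_recovers_two_group_hazard_ratio(self):
        hrs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 2, 600)
            t = rng.exponential(np.where(g == 1, 0.5, 1.0) * 20)
            c = rng.exponential(50, 600)
            m = cox_fit(pd.DataFrame({"g": g.astype(float)}),
                        np.minimum(t, c), (t <= c).astype(float))
            hrs.append(m.hr["g"])
        assert 1.8 < np.mean(hrs) < 2.2

    def test_ci_covers_hr(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 100)
        t = rng.exponential(np.exp(-0.5 * x) * 10)
        m = cox_fit(pd.DataFrame({"x": x}), t, np.ones(100))
        assert m.ci_low["x"] <= m.hr["x"] <= m.ci_high["x"]

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(pd.DataFrame({"x": [1.0, 2.0]}), [1.0, 2.0], [0, 0])


class TestTimeDependentAUC:
    def test_perfect_marker_no_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 100)
        auc = time_dependent_auc(-t, t, np.ones(100, bool), float(np.median(t)))
        assert auc == pytest.approx(1.0)

    def test_null_marker_near_half(self):
        inside = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 500
            marker = rng.normal(0, 1, n)
            t = rng.exponential(20, n)
            c = rng.exponential(40, n)
            auc = time_dependent_auc(marker, np.minimum(t, c), t <= c, 15.0)
            inside += 0.45 < auc < 0.55
        assert inside >= 36  # >= 90%

    def test_no_censoring_matches_rank_oracle(self):
        # cumulative/dynamic AUC without censoring is the case/control
        # Mann-Whitney statistic at the horizon
        rng = np.random.default_rng(3)
        n = 150
        marker = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(-0.7 * marker) * 10)
        horizon = float(np.quantile(t, 0.6))
        auc = time_dependent_auc(marker, t, np.ones(n, bool), horizon)
        cases = t <= horizon
        u = 0.0
        for mi in marker[cases]:
            u += (mi > marker[~cases]).sum() + 0.5 * (mi == marker[~cases]).sum()
        oracle = u / (cases.sum() * (~cases).sum())
        assert auc == pytest.approx(oracle, abs=1e-10)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1.0, 2.0], [10.0, 20.0], [True, True], 5.0)


class TestRankTests:
    def test_identical_groups_p_one(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        g = np.array([0, 0, 0, 1, 1, 1])
        _, p = rank_tests(v, g)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_enumeration(self):
        # 20 rank assignments; the observed extreme split has one-sided
        # probability 1/20 and two-sided 2/20
        v = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array([0, 0, 0, 1, 1, 1])
        _, p = rank_tests(v, g)
        assert p == pytest.approx(2 / 20)
        one_sided = stats.mannwhitneyu(v[g == 0], v[g == 1],
                                       alternative="less").pvalue
        assert one_sided == pytest.approx(1 / 20)

    def test_kruskal_three_identical_groups(self):
        v = np.tile([1.0, 2, 3], 3)
        g = np.repeat([0, 1, 2], 3)
        stat, _ = rank_tests(v, g)
        assert stat == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests(np.array([1.0, 2]), np.array([0, 0]))

    def test_sample_order_invariance(self, rng):
        v = rng.normal(0, 1, 30)
        g = rng.integers(0, 3, 30)
        perm = rng.permutation(30)
        assert rank_tests(v, g) == rank_tests(v[perm], g[perm])


class TestContingency:
    def test_hand_computed_chi2(self):
        out = contingency_tests([[10, 20], [20, 10]])
        assert out["chi2"] == pytest.approx(20 / 3)

    def test_fisher_exact_enumeration(self):
        out = contingency_tests([[5, 0], [0, 5]])
        assert out["fisher_p"] == pytest.approx(2 / 252)

    def test_independence_gives_zero(self):
        out = contingency_tests([[10, 10], [10, 10]])
        assert out["chi2"] == pytest.approx(0.0)

    def test_odds_ratio_haldane_on_zero_cell(self):
        out = contingency_tests([[5, 0], [2, 3]])
        assert np.isfinite(out["odds_ratio"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_tests([[1, -2], [3, 4]])


class TestSpearman:
    def test_hand_example(self):
        rho, _ = spearman_corr([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_monotone_transform_is_one(self, rng):
        x = rng.normal(0, 1, 40)
        rho, _ = spearman_corr(x, np.exp(2 * x))
        assert rho == pytest.approx(1.0)

    def test_rank_invariance(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        a, _ = spearman_corr(x, y)
        b, _ = spearman_corr(stats.rankdata(x), stats.rankdata(y))
        assert a == pytest.approx(b)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 1.0, 1.0], [1, 2, 3])


class TestMutationSummaries:
    @staticmethod
    def _maf(rows):
        return pd.DataFrame(
            rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                           "Variant_Classification"]
        )

    def test_empty_table(self):
        out = mutation_summaries(self._maf([]), [f"s{i}" for i in range(5)],
                                 ["TET1"])
        assert (out["frequency"] == 0).all()
        assert (out["tmb"] == 0).all()

    def test_frequency_counting(self):
        maf = self._maf([("TET1", "s0", "Missense_Mutation"),
                         ("TET1", "s0", "Nonsense_Mutation"),
                         ("TET1", "s1", "Missense_Mutation")])
        out = mutation_summaries(maf, [f"s{i}" for i in range(10)], ["TET1"])
        assert out["frequency"]["TET1"] == pytest.approx(0.2)

    def test_silent_calls_excluded_from_tmb(self):
        maf = self._maf([("TET1", "s0", "Silent"),
                         ("TET2", "s0", "Missense_Mutation")])
        out = mutation_summaries(maf, ["s0", "s1"], ["TET1", "TET2"])
        assert out["tmb"]["s0"] == 1
        assert out["frequency"]["TET1"] == 0.0

    def test_planted_cooccurrence_matches_hypergeometric_oracle(self):
        samples = [f"s{i}" for i in range(20)]
        rows = []
        for s in samples[:5]:  # always mutated together
            rows += [("A", s, "Missense_Mutation"), ("B", s, "Missense_Mutation")]
        out = mutation_summaries(self._maf(rows), samples, ["A", "B"])
        cooc = out["co_occurrence"].iloc[0]
        oracle = stats.fisher_exact([[5, 0], [0, 15]]).pvalue
        assert cooc["p_value"] == pytest.approx(oracle)
        assert bool(cooc["co_occurrent"])

    def test_unknown_class_warns(self):
        maf = self._maf([("A", "s0", "WeirdClass")])
        with pytest.warns(UserWarning, match="unknown variant class"):
            out = mutation_summaries(maf, ["s0"], ["A"])
        assert out["tmb"]["s0"] == 0

    def test_pattern_dependent_burden(self, small_cohort):
        c = small_cohort
        out = mutation_summaries(c.mutations, list(c.clinical.index), ["TET1"])
        tmb = out["tmb"]
        med = tmb.groupby(c.truth.pattern).median()
        rates = np.asarray(c.config.mut_rates)
        assert med.idxmax() == int(np.argmax(rates))


class TestCnvFrequencies:
    def test_all_zero(self):
        cnv = pd.DataFrame(np.zeros((4, 3), int), columns=list("abc"))
        out = cnv_frequencies(cnv)
        assert (out == 0).all().all()

    def test_gain_counting(self):
        cnv = pd.DataFrame({"g": [1, 1, 0, 0]})
        assert cnv_frequencies(cnv)["gain_frequency"]["g"] == pytest.approx(0.5)

    def test_partition_bound(self, rng):
        cnv = pd.DataFrame(rng.integers(-2, 3, (30, 8)))
        out = cnv_frequencies(cnv)
        assert ((out["gain_frequency"] + out["loss_frequency"]) <= 1 + 1e-12).all()

    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            cnv_frequencies(pd.DataFrame({"g": [0, 3]}))
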