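"""Moderated F-test, BH adjustment, univariate Cox screen, signature."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpattern.diffexp import (
    bh_adjust,
    derive_signature,
    moderated_f_test,
    trigamma_inverse,
    univariate_cox_screen,
)


def bh_bruteforce(p):
    """Independent step-up oracle: adj_p_(i) = min_{j>=i} min(1, p_(j)*m/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_identical_ps_collapse(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, bh_bruteforce([0.2] * 5))
        assert np.allclose(out, 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.7])[0] == 0.7

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestModeratedF:
    @staticmethod
    def _null(seed, n_genes=2000, per_group=20, k=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(0, 1, (n_genes, per_group * k)),
                         index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{i}" for i in range(per_group * k)])
        groups = pd.Series(np.repeat(range(k), per_group), index=X.columns)
        return X, groups

    def test_shrinkage_formula(self):
        # posterior variance combines prior and residual by df weights
        d0, s0_2, d_g, s_g2 = 4.0, 1.0, 4.0, 2.0
        assert (d0 * s0_2 + d_g * s_g2) / (d0 + d_g) == 1.5

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (1e-5, 0.01, 0.5, 2.0, 50.0):
            y = trigamma_inverse(x)
            assert abs(polygamma(1, y) - x) < 1e-6 * max(x, 1)

    def test_equal_variances_drive_d0_to_infinity(self):
        # all genes share one variance: the prior dominates and the
        # moderated F reduces to the pooled-variance statistic
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (400, 30))
        X = pd.DataFrame(base, index=[f"g{i}" for i in range(400)],
                         columns=[f"s{i}" for i in range(30)])
        groups = pd.Series(np.repeat([0, 1, 2], 10), index=X.columns)
        tab = moderated_f_test(X, groups)
        assert tab.attrs["d0"] > 27  # heavy moderation on homogeneous data

    def test_null_calibration(self):
        zero_seeds = 0
        for seed in range(5):
            X, groups = self._null(seed)
            tab = moderated_f_test(X, groups)
            ks = stats.kstest(tab["p_value"], "uniform")
            assert ks.pvalue > 0.01
            zero_seeds += (tab["adj_p"] < 0.05).sum() == 0
        assert zero_seeds >= 4

    def test_variance_moderation_shrinks_spread(self):
        X, groups = self._null(3, n_genes=500, per_group=4)
        tab = moderated_f_test(X, groups)
        s2_post = tab.attrs["s2_post"]
        # raw residual variances recomputed directly
        raw = X.T.groupby(groups).transform("mean")
        s2_raw = ((X - raw.T) ** 2).sum(axis=1) / (X.shape[1] - 3)
        assert s2_post.var() < s2_raw.var()

    def test_constant_gene_flagged(self):
        X, groups = self._null(0, n_genes=50, per_group=5)
        X.iloc[0] = 3.0
        tab = moderated_f_test(X, groups)
        assert bool(tab["flagged"].iloc[0])
        assert tab["p_value"].iloc[0] == 1.0

    def test_detects_planted_shift(self, small_cohort):
        c = small_cohort
        tab = moderated_f_test(c.expression, c.truth.pattern)
        planted = tab.loc[c.truth.deg_genes, "adj_p"]
        assert (planted < 0.01).mean() > 0.95

    def test_small_group_rejected(self):
        X, _ = self._null(0, n_genes=10, per_group=3)
        groups = pd.Series([0] * 8 + [1], index=X.columns)
        with pytest.raises(ValueError, match="< 2 samples"):
            moderated_f_test(X, groups)

    def test_matches_limma_reference(self, tmp_path):
        # independent oracle: limma's eBayes moderated F on the same data
        X, groups = self._null(7, n_genes=120, per_group=6)
        xp = tmp_path / "x.tsv"
        X.to_csv(xp, sep="\t")
        script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{xp}", row.names=1))
        g <- factor(rep(0:2, each=6))
        design <- model.matrix(~g)
        fit <- eBayes(lmFit(x, design))
        tt <- topTable(fit, coef=2:3, number=Inf, sort.by="none")
        out <- data.frame(F=tt$F, p=tt$P.Value, s2post=fit$s2.post)
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        tab = moderated_f_test(X, groups)
        assert np.allclose(tab["F_statistic"], ref["F"], rtol=1e-6)
        assert np.allclose(tab["p_value"], ref["p"], rtol=1e-5)
        assert np.allclose(tab.attrs["s2_post"], ref["s2post"], rtol=1e-6)


def efron_loglik_grid(x, time, event, grid):
    """Grid-search oracle for the single-covariate Efron partial likelihood."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    best_b, best_ll = None, -np.inf
    for b in grid:
        ll = 0.0
        for t in np.unique(time[event == 1]):
            D = (time == t) & (event == 1)
            R = time >= t
            d = D.sum()
            wR = np.exp(b * x[R]).sum()
            wD = np.exp(b * x[D]).sum()
            ll += b * x[D].sum()
            for el in range(d):
                ll -= np.log(wR - el / d * wD)
        if ll > best_ll:
            best_ll, best_b = ll, b
    return best_b


class TestCoxScreen:
    def _toy(self):
        # x alternates so the partial likelihood has an interior maximum
        # (a covariate separating early from late events entirely has a
        # monotone likelihood and no finite estimate)
        expr = pd.DataFrame([[1.0, 0.0, 1.0, 0.0]], index=["gX"],
                            columns=list("abcd"))
        clin = pd.DataFrame({"os_time": [1.0, 2.0, 3.0, 4.0],
                             "os_event": [1, 1, 1, 1]},
                            index=list("abcd"))
        return expr, clin

    def test_toy_matches_grid_search_oracle(self):
        expr, clin = self._toy()
        tab = univariate_cox_screen(expr, clin, ["gX"])
        beta = tab["beta"].iloc[0]
        grid = np.arange(-2.0, 4.0, 0.001)
        oracle = efron_loglik_grid(expr.iloc[0], clin["os_time"],
                                   clin["os_event"], grid)
        assert beta > 0
        assert abs(beta - oracle) < 1e-3

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        x = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(-0.6 * x))
        c = rng.exponential(2.0, n)
        time, ev = np.minimum(t, c), (t <= c).astype(int)
        # introduce ties to exercise the Efron correction
        time = np.round(time, 1) + 0.01
        expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(n)])
        clin = pd.DataFrame({"os_time": time, "os_event": ev}, index=expr.columns)
        tab = univariate_cox_screen(expr, clin, ["g"])
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": time, "e": ev}), "t", "e"
        )
        assert abs(tab["beta"].iloc[0] - cph.params_["x"]) < 1e-4
        assert abs(tab["se"].iloc[0] - cph.standard_errors_["x"]) < 1e-4

    def test_constant_gene_excluded(self):
        expr, clin = self._toy()
        expr.loc["gflat"] = 1.0
        tab = univariate_cox_screen(expr, clin, ["gX", "gflat"])
        assert "gflat" not in tab.index
        assert tab.attrs["n_flagged"] == 1

    def test_zero_events_rejected(self):
        expr, clin = self._toy()
        clin["os_event"] = 0
        with pytest.raises(ValueError, match="events"):
            univariate_cox_screen(expr, clin, ["gX"])

    def test_planted_beta_recovery(self):
        from methpattern.synthetic import SyntheticConfig, generate_cohort

        betas = []
        for seed in range(5):
            cfg = SyntheticConfig(n_samples=600, seed=seed,
                                  risk_gene_betas={"G001000": 0.5},
                                  surv_hazards=(0.03, 0.03, 0.03))
            c = generate_cohort(cfg)
            tab = univariate_cox_screen(c.expression, c.clinical, ["G001000"])
            betas.append(tab["beta"].iloc[0])
        assert abs(np.mean(betas) - 0.5) < 0.1

    def test_wald_agrees_with_score_zero(self, rng):
        # at the optimum the Efron score equations are satisfied
        from methpattern.diffexp import _cox_newton

        x = rng.normal(0, 1, (5, 80))
        t = rng.exponential(1, 80)
        e = rng.integers(0, 2, 80).astype(float)
        e[0] = 1
        beta, se, conv, _ = _cox_newton(x, t, e)
        from methpattern.diffexp import _cox_pass, _efron_terms

        prep = _efron_terms(t, e)
        _, score, _ = _cox_pass(x, beta, prep)
        assert np.abs(score[conv]).max() < 1e-6


class TestDeriveSignature:
    @staticmethod
    def _tables():
        deg = pd.DataFrame({"adj_p": [0.001, 0.001, 0.001]},
                           index=pd.Index(["A", "B", "C"], name="gene"))
        cox = pd.DataFrame({"p_value": [0.005, 0.5, 0.009],
                            "beta": [1.0, -0.2, -0.5]},
                           index=pd.Index(["A", "B", "C"], name="gene"))
        return deg, cox

    def test_intersection_filter(self):
        deg, cox = self._tables()
        sig = derive_signature(deg, cox)
        assert sig.genes == ["A", "C"]
        assert sig.directions == {"A": 1, "C": -1}

    def test_thresholds_one_keeps_all_fitted(self):
        deg, cox = self._tables()
        sig = derive_signature(deg, cox, deg_threshold=1.0, cox_threshold=1.0)
        assert set(sig.genes) == {"A", "B", "C"}

    def test_empty_signature_raises(self):
        deg, cox = self._tables()
        with pytest.raises(ValueError, match="empty signature"):
            derive_signature(deg, cox, deg_threshold=1e-9, cox_threshold=1e-9)

    def test_deterministic_order(self):
        deg = pd.DataFrame({"adj_p": [0.002, 0.001, 0.002]},
                           index=pd.Index(["Z", "M", "A"], name="gene"))
        cox = pd.DataFrame({"p_value": [0.001] * 3, "beta": [1.0] * 3},
                           index=deg.index)
        assert derive_signature(deg, cox).genes == ["M", "A", "Z"]
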