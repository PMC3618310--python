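import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import phregulon as pr
from phregulon.containers import ValidationError
from phregulon.de import VARIANCE_FLOOR, ModeratedModel

from conftest import full_design, make_matrix


def two_group_design(n=3):
    rows = [(f"wt_pH4_r{r}", "wt", 4, r) for r in range(1, n + 1)]
    rows += [(f"wt_pH8_r{r}", "wt", 8, r) for r in range(1, n + 1)]
    from conftest import make_meta

    return make_meta(rows)


class TestFitConditionMeans:
    def test_df_is_n_minus_conditions(self, small_experiment, small_model):
        # 12 samples, 4 conditions -> 8 residual df
        assert small_model.df_residual == 8

    def test_constant_gene_handled_by_floor(self):
        meta = two_group_design()
        m = make_matrix(np.ones((60, 6)), sample_ids=list(meta.sample_ids),
                        scale="normalized_concentration")
        model = pr.fit_condition_means(m, meta)
        assert (model.s2 == 0).all()
        d0, s02 = pr.estimate_prior(model.s2, model.df_residual)
        assert math.isinf(d0)
        assert s02 == pytest.approx(VARIANCE_FLOOR)

    def test_log10_delta_of_0p30103_is_twofold(self):
        meta = two_group_design()
        vals = np.tile([1.0, 1.0, 1.0, 1.30103, 1.30103, 1.30103], (1, 1))
        m = make_matrix(vals, sample_ids=list(meta.sample_ids),
                        scale="normalized_concentration")
        model = pr.with_prior(pr.fit_condition_means(m, meta), d0=0.0, s02=1.0)
        res = pr.call_de(pr.moderated_t(model, ("wt_pH8", "wt_pH4")))
        assert res["fc"].iloc[0] == pytest.approx(2.000, abs=1e-4)

    def test_single_replicate_condition_rejected(self):
        from conftest import make_meta

        meta = make_meta([("a", "wt", 4, 1), ("b", "wt", 8, 1), ("c", "wt", 8, 2)])
        m = make_matrix(np.ones((5, 3)), sample_ids=["a", "b", "c"])
        with pytest.raises(ValidationError, match="replicate"):
            pr.fit_condition_means(m, meta)


class TestEstimatePrior:
    def test_parameter_recovery_within_20_percent(self):
        rng = np.random.default_rng(12)
        d0_true, s02_true, dg = 4.0, 0.02, 8
        sigma2 = d0_true * s02_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(dg, size=5000) / dg
        d0, s02 = pr.estimate_prior(pd.Series(s2), dg)
        assert abs(d0 - d0_true) / d0_true < 0.2
        assert abs(s02 - s02_true) / s02_true < 0.2

    def test_identical_variances_degenerate_limit(self):
        s2 = pd.Series(np.full(100, 0.037))
        d0, s02 = pr.estimate_prior(s2, 8)
        assert math.isinf(d0)
        assert s02 == pytest.approx(0.037)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        s2 = pd.Series(0.05 * rng.chisquare(8, size=2000) / 8)
        d0_a, s02_a = pr.estimate_prior(s2, 8)
        d0_b, s02_b = pr.estimate_prior(s2 * 7.0, 8)
        assert d0_b == pytest.approx(d0_a, rel=1e-9)
        assert s02_b == pytest.approx(7.0 * s02_a, rel=1e-9)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError, match="50"):
            pr.estimate_prior(pd.Series(np.ones(10)), 8)


class TestModeratedT:
    def test_identical_groups_give_t0_p1(self):
        meta = two_group_design()
        vals = np.tile([2.0, 2.0, 2.0, 2.0, 2.0, 2.0], (60, 1)) + np.random.default_rng(0).normal(
            0, 0.1, (60, 6)
        )
        vals[0] = [2.0, 2.1, 1.9, 2.0, 2.1, 1.9]  # same values in both groups
        m = make_matrix(vals, sample_ids=list(meta.sample_ids), scale="normalized_concentration")
        model = pr.with_prior(pr.fit_condition_means(m, meta))
        res = pr.moderated_t(model, ("wt_pH8", "wt_pH4"))
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # groups (1,2,3) vs (4,5,6), d0=0: classical pooled t = -3.674
        meta = two_group_design()
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]] * 60)
        m = make_matrix(vals, sample_ids=list(meta.sample_ids), scale="normalized_concentration")
        model = pr.with_prior(pr.fit_condition_means(m, meta), d0=0.0, s02=1.0)
        res = pr.moderated_t(model, ("wt_pH4", "wt_pH8"))
        assert res["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        t_ref, p_ref = stats.ttest_ind([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res["t"].iloc[0] == pytest.approx(t_ref, abs=1e-10)
        assert res["pvalue"].iloc[0] == pytest.approx(p_ref, abs=1e-10)

    def test_d0_infinity_limit(self):
        meta = two_group_design()
        rng = np.random.default_rng(1)
        vals = rng.normal(2, 0.3, (80, 6))
        m = make_matrix(vals, sample_ids=list(meta.sample_ids), scale="normalized_concentration")
        model = pr.with_prior(pr.fit_condition_means(m, meta), d0=math.inf, s02=0.09)
        res = pr.moderated_t(model, ("wt_pH8", "wt_pH4"))
        delta = (model.means["wt_pH8"] - model.means["wt_pH4"]).to_numpy()
        expected = delta / np.sqrt(0.09 * (2.0 / 3.0))
        np.testing.assert_allclose(res["t"].to_numpy(), expected, atol=1e-12)

    def test_classical_oracle_over_random_genes(self):
        """d0 = 0 reduces the moderated pipeline to the classical pooled
        two-sample t on every gene, matching scipy to 1e-10."""
        rng = np.random.default_rng(42)
        meta = two_group_design()
        vals = rng.normal(2, 0.5, size=(1000, 6))
        m = make_matrix(vals, sample_ids=list(meta.sample_ids), scale="normalized_concentration")
        model = pr.with_prior(pr.fit_condition_means(m, meta), d0=0.0, s02=1.0)
        res = pr.moderated_t(model, ("wt_pH8", "wt_pH4"))
        t_ref, p_ref = stats.ttest_ind(vals[:, 3:], vals[:, :3], axis=1)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(res["pvalue"].to_numpy(), p_ref, atol=1e-10)

    def test_unknown_condition_rejected(self, small_model):
        with pytest.raises(ValidationError, match="unknown condition"):
            pr.moderated_t(small_model, ("wt_pH8", "nope"))


class TestLimmaCrossCheck:
    def test_prior_and_t_match_limma(self, tmp_path):
        """Independent oracle: the R limma package on the same matrix must
        agree on the empirical-Bayes prior and the moderated t statistics."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; the cross-check oracle cannot run")
        rng = np.random.default_rng(5)
        meta = full_design()
        sigma2 = 4 * 0.02 / rng.chisquare(4, size=300)
        vals = rng.normal(2, 0.5, size=(300, 1)) + rng.standard_normal((300, 12)) * np.sqrt(
            sigma2
        )[:, None]
        m = make_matrix(vals, sample_ids=list(meta.sample_ids), scale="normalized_concentration")
        m.values.to_csv(tmp_path / "x.tsv", sep="\t")
        meta.conditions().to_csv(tmp_path / "cond.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            cond <- read.delim(args[2], row.names=1)[colnames(x), 1]
            design <- model.matrix(~0 + factor(cond))
            colnames(design) <- levels(factor(cond))
            fit <- lmFit(x, design)
            cm <- makeContrasts(c1 = wt_pH8 - wt_pH4, levels = design)
            fit2 <- eBayes(contrasts.fit(fit, cm))
            out <- data.frame(t = fit2$t[, 1], p = fit2$p.value[, 1])
            cat(fit2$df.prior, fit2$s2.prior, "\\n")
            write.table(out, args[3], sep = "\\t", quote = FALSE)
            """
        )
        proc = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "x.tsv"), str(tmp_path / "cond.tsv"),
             str(tmp_path / "out.tsv")],
            capture_output=True, text=True, check=True,
        )
        d0_ref, s02_ref = map(float, proc.stdout.split())
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        model = pr.with_prior(pr.fit_condition_means(m, meta))
        assert model.d0 == pytest.approx(d0_ref, rel=1e-4)
        assert model.s02 == pytest.approx(s02_ref, rel=1e-4)
        res = pr.moderated_t(model, ("wt_pH8", "wt_pH4"))
        np.testing.assert_allclose(res["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(res["pvalue"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6)


class TestBenjaminiHochberg:
    def test_singleton_identity(self):
        np.testing.assert_allclose(pr.adjust_bh([0.05]), [0.05])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            pr.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pr.adjust_bh([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    def test_monotone_in_ranks_and_bounded(self, pvals):
        adj = pr.adjust_bh(pvals)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCalls:
    def test_cutoffs(self):
        base = pd.DataFrame({"log10_fc": [np.log10(2.5), np.log10(2.5), -np.log10(3)],
                             "pvalue": [0.001, 0.9, 0.001]},
                            index=["a", "b", "c"])
        res = pr.call_de(base.assign(adj_pvalue=[0.01, 0.2, 0.01]))
        assert list(res["call"]) == ["up", "ns", "down"]

    def test_call_invariant(self, small_model):
        res = pr.run_contrast(small_model, pr.DEFAULT_CONTRASTS["wt8_vs_wt4"])
        up = res["call"] == "up"
        assert ((res.loc[up, "fc"] >= 2) & (res.loc[up, "adj_pvalue"] < 0.05)).all()
        down = res["call"] == "down"
        assert ((res.loc[down, "fc"] <= 0.5) & (res.loc[down, "adj_pvalue"] < 0.05)).all()
        assert (res["adj_pvalue"] >= res["pvalue"] - 1e-15).all()

    def test_scoring_against_truth(self, small_experiment, small_model):
        """Planted pH-responsive genes are recovered far above chance with
        controlled false discoveries; the noise-free limit is exact."""
        _, _, _, truth = small_experiment
        res = pr.run_contrast(small_model, pr.DEFAULT_CONTRASTS["wt8_vs_wt4"])
        called_up = set(res.index[res["call"] == "up"])
        true_up = {g for g in res.index
                   if truth.true_log10_fc.loc[g, "wt8_vs_wt4"] > 0}
        sens = len(called_up & true_up) / len(true_up)
        fdr = len(called_up - true_up) / max(len(called_up), 1)
        assert sens > 0.4
        # nominal FDR 0.05 plus binomial fluctuation at ~20 discoveries
        assert fdr <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / max(len(called_up), 1))


class TestTrendline:
    def test_exact_line_no_outliers(self):
        x = pd.Series(np.arange(10.0))
        fit = pr.trendline_outliers(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.n_outliers == 0

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(0)
        x = pd.Series(np.linspace(0, 10, 101))
        y = x.copy() + rng.normal(0, 0.01, 101)
        y.iloc[50] += 1.0  # far beyond 2 SD of the tight residuals
        fit = pr.trendline_outliers(x, y)
        assert fit.outliers.iloc[50]
        assert fit.n_outliers == 1

    def test_null_flag_fraction_near_two_sided_normal_tail(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.normal(size=20000))
        y = pd.Series(0.8 * x.to_numpy() + rng.normal(size=20000))
        fit = pr.trendline_outliers(x, y)
        frac = fit.outliers.mean()
        assert frac == pytest.approx(0.0455, abs=0.006)

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pr.trendline_outliers(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))
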