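"""Binomial GLMM, LRT, per-variant GLMs and BH adjustment."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mosaicbench.batch import (
    batch_effect_test,
    bh_adjust,
    fit_glmm,
    fit_variant_glm,
    glmm_loglik_at,
    lrt,
    per_variant_tests,
)


def simulate_counts(n_variants=85, depth=100, beta_rm=0.5, sigma=0.4, seed=0,
                    platforms=("E",), platform_effect=0.0):
    """Paired RM/non-RM binomial counts with per-variant baseline logits."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_variants):
        b0 = np.log(0.15 / 0.85) + rng.normal(0.0, sigma)
        for src, shift in (("RM", beta_rm), ("NONRM", 0.0)):
            for j, plat in enumerate(platforms):
                eta = b0 + shift + (platform_effect if j else 0.0)
                p = 1.0 / (1.0 + np.exp(-eta))
                n = max(1, rng.poisson(depth))
                alt = rng.binomial(n, p)
                rows.append(dict(variant_id=f"v{i:03d}", dna_source=src, platform=plat,
                                 alt_count=alt, ref_count=n - alt))
    return pd.DataFrame(rows)


class TestGlmm:
    def test_null_simulation_estimate_near_zero(self):
        df = simulate_counts(beta_rm=0.0, sigma=0.0, seed=42)
        fit = fit_glmm(df)
        se = fit.coef_se("dna_source_RM")
        assert abs(fit.coef("dna_source_RM")) < 3 * se

    def test_effect_recovered_single_run(self):
        df = simulate_counts(beta_rm=0.5, seed=7)
        fit = fit_glmm(df, compute_se=False)
        assert 0.3 <= fit.coef("dna_source_RM") <= 0.7

    def test_quadrature_refinement_stable(self):
        df = simulate_counts(seed=3, n_variants=40)
        fit = fit_glmm(df, nodes=25, compute_se=False)
        ll_101 = glmm_loglik_at(df, fit.beta, fit.sigma_u, nodes=101)
        assert abs(fit.loglik - ll_101) < 1e-4

    def test_sigma_zero_reproduces_pooled_glm_loglik(self):
        df = simulate_counts(sigma=0.0, seed=5, n_variants=40)
        exog = pd.DataFrame({
            "const": 1.0, "rm": (df["dna_source"] == "RM").astype(float)
        })
        glm = sm.GLM(df[["alt_count", "ref_count"]].to_numpy(float), exog,
                     family=sm.families.Binomial()).fit()
        ll = glmm_loglik_at(df, glm.params.to_numpy(), 0.0)
        assert abs(ll - glm.llf) < 1e-6

    def test_rank_deficient_design_rejected(self):
        df = simulate_counts(seed=1, n_variants=5)
        df["dna_source"] = "RM"  # source column constant -> collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            fit_glmm(df)

    def test_matches_glmmtmb_oracle(self, tmp_path):
        """Independent cross-check of the marginal-likelihood fit against the
        standard R mixed-model implementation on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: cannot run the independent GLMM oracle")
        df = simulate_counts(n_variants=40, depth=80, beta_rm=0.5, seed=123,
                             platforms=("E", "R"), platform_effect=0.2)
        counts = tmp_path / "counts.tsv"
        df.to_csv(counts, sep="\t", index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""\
            suppressMessages(library(glmmTMB))
            d <- read.delim("{counts}")
            d$dna_source <- relevel(factor(d$dna_source), ref="NONRM")
            m <- glmmTMB(cbind(alt_count, ref_count) ~ dna_source + platform
                         + (1|variant_id), family=binomial, data=d)
            cat(fixef(m)$cond, sqrt(VarCorr(m)$cond$variant_id[1,1]), logLik(m), "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        b0, b_rm, b_plat, sigma, ll = map(float, out.stdout.split())
        fit = fit_glmm(df, compute_se=False)
        assert fit.coef("intercept") == pytest.approx(b0, abs=0.01)
        assert fit.coef("dna_source_RM") == pytest.approx(b_rm, abs=0.01)
        assert fit.coef("platform_R") == pytest.approx(b_plat, abs=0.01)
        assert fit.sigma_u == pytest.approx(sigma, abs=0.01)
        assert fit.loglik == pytest.approx(ll, abs=0.5)  # Laplace vs 25-node AGQ


class TestLrt:
    def test_identical_fits_give_zero_statistic(self):
        df = simulate_counts(seed=2, n_variants=20)
        fit = fit_glmm(df, compute_se=False)
        stat, dof, p = lrt(fit, fit)
        assert stat == 0.0 and dof == 1 and p == 1.0

    def test_negative_statistic_rejected(self):
        df = simulate_counts(seed=2, n_variants=20)
        full = fit_glmm(df, compute_se=False)
        reduced = fit_glmm(df, include_source=False, compute_se=False)
        with pytest.raises(ValueError, match="nested"):
            lrt(reduced, full)  # swapped: reduced cannot beat full

    def test_strong_effect_detected(self):
        detected = 0
        for s in range(20):
            df = simulate_counts(beta_rm=0.5, seed=100 + s)
            full = fit_glmm(df, compute_se=False)
            reduced = fit_glmm(df, include_source=False, compute_se=False)
            _, _, p = lrt(full, reduced)
            detected += p < 1e-4
        assert detected >= 19


class TestVariantGlm:
    def test_two_by_two_equals_closed_form_log_odds_ratio(self):
        df = pd.DataFrame([
            dict(variant_id="v", dna_source="RM", platform="E", alt_count=20, ref_count=80),
            dict(variant_id="v", dna_source="NONRM", platform="E", alt_count=10, ref_count=90),
        ])
        r = fit_variant_glm(df)
        expected = np.log((20 / 80) / (10 / 90))  # log(2.25)
        assert r.log_odds_rm == pytest.approx(expected, abs=1e-8)
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        assert r.ci95_high - r.ci95_low == pytest.approx(2 * 1.96 * se, rel=1e-3)

    def test_equal_proportions_give_zero_estimate(self):
        df = pd.DataFrame([
            dict(variant_id="v", dna_source="RM", platform="E", alt_count=15, ref_count=85),
            dict(variant_id="v", dna_source="NONRM", platform="E", alt_count=15, ref_count=85),
        ])
        assert fit_variant_glm(df).log_odds_rm == pytest.approx(0.0, abs=1e-10)

    def test_zero_cell_uses_haldane_and_flags_separation(self):
        df = pd.DataFrame([
            dict(variant_id="v", dna_source="RM", platform="E", alt_count=30, ref_count=70),
            dict(variant_id="v", dna_source="NONRM", platform="E", alt_count=0, ref_count=100),
        ])
        r = fit_variant_glm(df)
        assert r.separation
        expected = np.log((30.5 * 100.5) / (70.5 * 0.5))
        assert r.log_odds_rm == pytest.approx(expected)

    def test_missing_source_rejected(self):
        df = pd.DataFrame([
            dict(variant_id="v", dna_source="RM", platform="E", alt_count=5, ref_count=95),
        ])
        with pytest.raises(ValueError, match="both RM and NONRM"):
            fit_variant_glm(df)


class TestBH:
    def test_step_up_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariance(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.03])
        perm = np.array([3, 1, 4, 0, 2])
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFullAnalysis:
    def test_per_variant_table_has_q_values_monotone_in_p(self):
        df = simulate_counts(n_variants=30, beta_rm=0.4, seed=6)
        table = per_variant_tests(df)
        assert len(table) == 30
        srt = table.sort_values("p")
        assert (np.diff(srt["q_bh"].to_numpy()) >= -1e-12).all()

    def test_batch_effect_test_end_to_end(self):
        df = simulate_counts(n_variants=40, beta_rm=0.5, seed=9)
        fit = batch_effect_test(df, compute_se=False)
        assert fit.lrt_p < 1e-6
        assert fit.sigma_u > 0.1
        assert len(fit.per_variant) == 40
        assert "q_bh" in fit.per_variant.columns
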