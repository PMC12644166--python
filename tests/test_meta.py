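"""Effect computation, REML random-effects fit, correlations, CV decomposition."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

from umbrellas import (
    RatingScale,
    SampleSummary,
    StudyArms,
    compare_meta,
    compute_effects,
    correlations,
    cv_decomposition,
    reml_re,
)
from umbrellas.scales import ScaleDomainError


def make_arms(study_id, mean_c, sd_c, mean_t, sd_t, n=5000, scale=None):
    scale = scale or RatingScale(0, 6)
    return StudyArms(
        study_id,
        SampleSummary(mean_c, sd_c, n, "unbiased"),
        SampleSummary(mean_t, sd_t, n, "unbiased"),
        scale,
    )


class TestEffects:
    def test_worked_standardized_effects(self):
        """Equal-SD, limit-SD and mixed-SD replications: d = 1.33, 1.89, 1.57."""
        studies = [
            make_arms("A", 2.0, 1.5, 4.0, 1.5),
            make_arms("B", 4.0, 1.5, 6.0, 0.0),
            make_arms("C", 2.0, 1.5, 4.0, 1.0),
        ]
        recs = compute_effects(studies, correction=False)
        assert [round(r.d, 2) for r in recs] == [1.33, 1.89, 1.57]
        assert recs[1].s_pooled == pytest.approx(math.sqrt(1.125))
        assert recs[1].d == pytest.approx(2 / math.sqrt(1.125))

    def test_d_times_pooled_sd_recovers_md(self):
        recs = compute_effects(
            [make_arms("x", 1.2, 0.9, 3.4, 1.4, n=40)], correction=False
        )
        assert recs[0].d * recs[0].s_pooled == pytest.approx(recs[0].MD)

    def test_hedges_factor_applied_when_correction_on(self):
        raw = compute_effects([make_arms("x", 2, 1.5, 4, 1.5, n=10)], False)[0]
        corrected = compute_effects([make_arms("x", 2, 1.5, 4, 1.5, n=10)], True)[0]
        j = 1 - 3 / (4 * 20 - 9)
        assert corrected.d == pytest.approx(raw.d * j)
        assert corrected.small_sample_corrected

    def test_population_sds_converted_before_pooling(self):
        sc = RatingScale(0, 6)
        n = 12
        pop = StudyArms(
            "p",
            SampleSummary(2.0, 1.0, n, "population"),
            SampleSummary(4.0, 1.0, n, "population"),
            sc,
        )
        unb = StudyArms(
            "u",
            SampleSummary(2.0, 1.0 * math.sqrt(n / (n - 1)), n, "unbiased"),
            SampleSummary(4.0, 1.0 * math.sqrt(n / (n - 1)), n, "unbiased"),
            sc,
        )
        rp, ru = compute_effects([pop, unb], correction=False)
        assert rp.d == pytest.approx(ru.d)
        assert rp.var_MD == pytest.approx(ru.var_MD)

    def test_zero_pooled_sd_flagged_not_fatal(self):
        studies = [
            make_arms("ok", 2, 1.5, 4, 1.5),
            make_arms("flat", 1.0, 0.0, 3.0, 0.0),
        ]
        recs = compute_effects(studies)
        assert recs[1].d is None and recs[1].var_d is None
        assert recs[1].MD == pytest.approx(2.0)


def _restricted_ll_oracle(tau2, y, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


class TestREML:
    def test_homogeneous_inputs_give_zero_heterogeneity(self):
        res = reml_re([0.4] * 6, [0.05, 0.02, 0.09, 0.04, 0.03, 0.06])
        assert res.tau == 0.0
        assert res.I2 == 0.0
        assert res.H2 == 1.0
        assert res.QEp == pytest.approx(1.0)
        assert res.mu == pytest.approx(0.4)

    @given(
        st.lists(st.floats(-1.5, 1.5), min_size=3, max_size=12),
        st.floats(0.01, 0.5),
    )
    def test_equal_variance_closed_form(self, y, v):
        """Homoscedastic REML: tau2 = max(0, unbiased variance of y minus v)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # mu ~ 0 makes CV NaN
            res = reml_re(y, [v] * len(y))
        expected = max(0.0, float(np.var(y, ddof=1)) - v)
        assert res.tau2 == pytest.approx(expected, abs=1e-6)

    def test_matches_grid_and_golden_section_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            K = int(rng.integers(3, 11))
            y = rng.normal(0.5, 0.5, K)
            v = rng.uniform(0.01, 0.2, K)
            res = reml_re(y, v)
            grid = np.linspace(0, 5 * np.var(y, ddof=1) + 0.5, 4001)
            lls = [_restricted_ll_oracle(t, y, v) for t in grid]
            t0 = grid[int(np.argmax(lls))]
            bracket = (max(t0 - 0.01, 0.0), t0 + 0.01)
            refined = optimize.minimize_scalar(
                lambda t: -_restricted_ll_oracle(t, y, v),
                bounds=bracket,
                method="bounded",
                options={"xatol": 1e-12},
            ).x
            best = refined if _restricted_ll_oracle(refined, y, v) >= _restricted_ll_oracle(0.0, y, v) else 0.0
            assert res.tau2 == pytest.approx(best, abs=1e-6)

    def test_matches_metafor_reference(self):
        """Independent cross-check against the R reference REML implementation."""
        rng = np.random.default_rng(42)
        y = rng.normal(0.6, 0.4, 8)
        v = rng.uniform(0.02, 0.1, 8)
        res = reml_re(y, v)
        r_code = (
            "suppressMessages(library(metafor));"
            f"y <- c({','.join(f'{x:.12g}' for x in y)});"
            f"v <- c({','.join(f'{x:.12g}' for x in v)});"
            "fit <- rma(yi=y, vi=v, method='REML', control=list(threshold=1e-10));"
            "cat(sprintf('%.8f %.8f %.8f %.8f', fit$tau2, fit$beta, fit$se, fit$QE))"
        )
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        tau2_r, mu_r, se_r, q_r = map(float, out.stdout.split())
        assert res.tau2 == pytest.approx(tau2_r, abs=1e-4)
        assert res.mu == pytest.approx(mu_r, abs=1e-6)
        assert res.se_mu == pytest.approx(se_r, abs=1e-5)
        assert res.Q == pytest.approx(q_r, abs=1e-6)

    def test_internal_identities(self):
        rng = np.random.default_rng(9)
        res = reml_re(rng.normal(0.8, 0.4, 10), rng.uniform(0.02, 0.1, 10))
        assert res.I2 == pytest.approx(100 * (res.H2 - 1) / res.H2)
        assert res.CV == pytest.approx(res.tau / abs(res.mu))
        assert res.tau == pytest.approx(math.sqrt(res.tau2))

    def test_single_study_rejected(self):
        with pytest.raises(ScaleDomainError):
            reml_re([0.5], [0.1])

    def test_zero_mean_cv_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="CV"):
            res = reml_re([-0.5, 0.5], [0.1, 0.1])
        assert math.isnan(res.CV)
        assert res.tau2 >= 0


class TestCorrelations:
    def test_monotone_pair_has_perfect_spearman(self):
        res = correlations([0.1, 0.5, 0.7, 1.4, 2.0], [1.0, 1.2, 1.5, 1.9, 2.8])
        assert res.r_spearman == pytest.approx(1.0)

    def test_exact_negative_linear_pair(self):
        md = [0.2, 0.6, 1.0, 1.4, 1.8]
        res = correlations(md, [3.0 - m for m in md])
        assert res.r_pearson == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # direct product-moment arithmetic on a 6-point vector pair
        x = np.array([0.5, 0.8, 1.1, 0.9, 1.6, 1.3])
        y = np.array([1.2, 1.0, 1.5, 1.1, 1.9, 1.4])
        r_hand = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        res = correlations(x, y)
        assert res.r_pearson == pytest.approx(r_hand, abs=1e-12)
        assert res.pearson_CI[0] <= res.r_pearson <= res.pearson_CI[1]
        assert res.spearman_CI[0] <= res.r_spearman <= res.spearman_CI[1]

    def test_fisher_ci_equivariant_under_sign_flip(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(scale=0.5, size=12)
        res = correlations(x, y)
        flipped = correlations(x, -y)
        assert flipped.r_pearson == pytest.approx(-res.r_pearson)
        assert flipped.pearson_CI[0] == pytest.approx(-res.pearson_CI[1])
        assert flipped.pearson_CI[1] == pytest.approx(-res.pearson_CI[0])

    def test_degenerate_vectors_rejected(self):
        with pytest.raises(ScaleDomainError):
            correlations([1, 1, 1, 1], [0.5, 0.7, 0.9, 1.1])
        with pytest.raises(ScaleDomainError):
            correlations([1, 2, 3], [1, 2, 3])  # K < 4


class TestCvDecomposition:
    def test_homogeneous_md_reduces_to_sigma_cv(self):
        assert cv_decomposition(0.0, 0.37, -0.5) == pytest.approx(0.37)

    def test_perfect_positive_coupling_cancels(self):
        assert cv_decomposition(0.25, 0.25, 1.0) == pytest.approx(0.0)

    def test_bounds_of_the_quadratic_form(self):
        cv = cv_decomposition(0.3, 0.2, -0.8)
        assert abs(0.3 - 0.2) <= cv <= 0.3 + 0.2

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ScaleDomainError):
            cv_decomposition(0.3, 0.2, 1.5)


class TestCompareMeta:
    def test_homogeneous_md_heterogeneity_lives_in_d(self):
        """Identical MDs with varying pooled SDs: CV_MD = 0, CV_d tracks CV(sigma)."""
        sds = [1.35, 1.4, 1.45, 1.5, 1.55, 1.6, 1.65, 1.7]
        studies = [
            make_arms(f"s{i}", 2.0, sd, 3.5, sd, n=10000)
            for i, sd in enumerate(sds)
        ]
        rep = compare_meta(studies, correction=False)
        assert rep.meta_MD.CV == pytest.approx(0.0, abs=1e-8)
        sp = np.array([e.s_pooled for e in rep.effects])
        cv_sigma = sp.std(ddof=1) / sp.mean()
        assert rep.meta_d.CV == pytest.approx(cv_sigma, abs=0.02)

    def test_identical_studies_are_homogeneous(self):
        studies = [make_arms(f"s{i}", 2.0, 1.5, 3.0, 1.4, n=200) for i in range(6)]
        rep = compare_meta(studies)
        assert rep.meta_MD.tau == 0.0
        assert rep.meta_d.tau == 0.0
        assert rep.meta_MD.QEp == pytest.approx(1.0)

    def test_opposed_pattern_negative_correlation_inflates_cv_d(self):
        from umbrellas import SimConfig, generate_multilab

        cfg = SimConfig(
            K=24, n_c=50, n_t=50, scenario="opposed", mu_MD=1.5, tau_MD=0.5, seed=77
        )
        _, arms = generate_multilab(cfg)
        rep = compare_meta(arms)
        assert rep.correlation.r_pearson < 0
        assert rep.meta_d.CV > rep.meta_MD.CV
        assert rep.decomposition.CV_d_predicted > rep.decomposition.CV_MD

    def test_zero_pooled_sd_studies_counted_not_fatal(self):
        studies = [make_arms(f"s{i}", 2.0, 1.5, 3.0, 1.4, n=100) for i in range(4)]
        studies.append(make_arms("flat", 1.0, 0.0, 2.0, 0.0, n=100))
        rep = compare_meta(studies)
        assert rep.n_excluded_d == 1
        assert rep.meta_MD.K == 4  # zero sampling variance excludes both sides
        assert rep.meta_d.K == 4

    def test_tables_have_expected_shape(self):
        studies = [
            make_arms(f"s{i}", 2.0 + 0.05 * i, 1.5, 3.0 + 0.1 * i, 1.4 - 0.03 * i,
                      n=150)
            for i in range(6)
        ]
        rep = compare_meta(studies)
        het = rep.heterogeneity_table()
        assert list(het["measure"]) == ["MD", "d"]
        assert {"mu", "tau", "CV", "H2", "I2", "QEp", "df"} <= set(het.columns)
        assert set(rep.umbrella_points["condition"]) == {"control", "treatment"}
        assert len(rep.umbrella_points) == 12
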