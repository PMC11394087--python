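"""Bootstrap goodness-of-fit, residual flags, RII filter, logistic fits."""

import numpy as np
import pandas as pd
import pytest

from crocdiet import (
    bootstrap_gof,
    bootstrap_gof_stomach,
    fit_logistic_presence,
    logistic_screen,
    presence_curve,
    residual_flags,
    rii_filter,
)
from crocdiet.errors import DegenerateTestError, ValidationError


class TestBootstrapGof:
    def test_uniform_counts_fit_perfectly(self):
        res = bootstrap_gof([10, 10, 10, 10], iterations=200, seed=0)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_total_concentration_gives_minimal_p(self):
        # chi2_obs is the maximum attainable statistic for T=40, S=4, so no
        # replicate can exceed it and essentially none can match it
        res = bootstrap_gof([40, 0, 0, 0], iterations=1000, seed=123)
        assert res.p == pytest.approx(1 / 1001)

    def test_p_never_zero_and_seed_reproducible(self):
        counts = [30, 10, 5, 5, 1]
        r1 = bootstrap_gof(counts, iterations=500, seed=9)
        r2 = bootstrap_gof(counts, iterations=500, seed=9)
        assert r1.p > 0
        assert r1.p == r2.p and r1.chi2 == r2.chi2

    def test_relabeling_invariance(self):
        a = bootstrap_gof([8, 2, 5, 9], iterations=200, seed=4)
        b = bootstrap_gof([9, 8, 5, 2], iterations=200, seed=4)
        assert a.chi2 == pytest.approx(b.chi2)

    def test_single_category_degenerate(self):
        with pytest.raises(DegenerateTestError):
            bootstrap_gof([12], iterations=200, seed=0)

    def test_custom_expected_proportions(self):
        res = bootstrap_gof(
            [30, 10], iterations=200, expected_proportions=[0.75, 0.25], seed=1
        )
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_stomach_level_variant_runs(self, fixture_dataset, fixture_diet):
        from crocdiet import stomach_category_matrix

        mat = stomach_category_matrix(
            list(fixture_dataset.stomachs), list(fixture_dataset.prey)
        )
        res = bootstrap_gof_stomach(mat, iterations=300, seed=5)
        assert res.chi2 > 0
        assert 0 < res.p <= 1

    def test_type_one_error_calibrated(self):
        """Rejection rate under a uniform multinomial null, T=100, S=11."""
        s, t = 11, 100
        rng = np.random.default_rng(777)
        n_datasets = 500
        rejections = 0
        for i in range(n_datasets):
            counts = rng.multinomial(t, np.full(s, 1 / s))
            res = bootstrap_gof(counts, iterations=1000, seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        assert 0.03 <= rejections / n_datasets <= 0.07


class TestResidualFlags:
    def test_fixture_overconsumed_items(self, fixture_diet):
        res = bootstrap_gof(fixture_diet.pooled_counts(), iterations=1000, seed=2)
        flags = residual_flags(res)
        over = {c for c, f in flags.items() if f == "over"}
        assert over == {"Coleoptera", "Hemiptera", "Araneae"}

    def test_uniform_counts_unflagged(self):
        res = bootstrap_gof([10, 10, 10], iterations=200, seed=0)
        assert set(residual_flags(res).values()) == {"none"}

    def test_zero_threshold_flags_everything_nonzero(self):
        res = bootstrap_gof([12, 8, 10], iterations=200, seed=0)
        flags = residual_flags(res, threshold=0.0)
        assert flags == {"cat1": "over", "cat2": "under", "cat3": "none"}

    def test_residuals_account_for_observed_minus_expected(self, fixture_diet):
        res = bootstrap_gof(fixture_diet.pooled_counts(), iterations=200, seed=2)
        recon = res.residuals * np.sqrt(res.expected) + res.expected
        assert recon == pytest.approx(res.observed)


class TestRiiFilter:
    def test_fixture_retained_categories(self, fixture_metrics):
        kept = rii_filter(fixture_metrics, threshold=1.0)
        assert set(kept) == {
            "Coleoptera",
            "Hemiptera",
            "Araneae",
            "Blattodea",
            "Hymenoptera",
            "Odonata",
            "Fish",
        }

    def test_threshold_inclusive(self, fixture_metrics):
        # Odonata peaks at exactly RII = 1.0 in the medium class
        kept = rii_filter(fixture_metrics, threshold=1.0)
        assert "Odonata" in kept

    def test_zero_threshold_keeps_all(self, fixture_metrics):
        assert len(rii_filter(fixture_metrics, threshold=0.0)) == 11

    def test_unreachable_threshold(self, fixture_metrics):
        assert rii_filter(fixture_metrics, threshold=100.0) == []


def _simulate_logistic(rng, n, beta0, beta1, tl_range=(300.0, 509.0)):
    tl = rng.uniform(*tl_range, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * tl)))
    return (rng.random(n) < p).astype(float), tl


class TestLogisticPresence:
    def test_matches_statsmodels(self):
        """IRLS agrees with an independent ML fit on coefficients and LR test."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        y, tl = _simulate_logistic(rng, 120, -8.0, 0.02)
        fit = fit_logistic_presence(y, tl)
        ref = sm.Logit(y, sm.add_constant(tl)).fit(disp=0)
        assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-5)
        assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-8)
        assert fit.se_beta1 == pytest.approx(ref.bse[1], rel=1e-4)
        assert fit.chi2 == pytest.approx(ref.llr, abs=1e-6)

    def test_matches_brute_force_grid_on_small_samples(self):
        """MLE equals a refined likelihood-grid maximum to 3 decimals, n <= 30."""

        def grid_mle(y, x):
            xc = x - x.mean()

            def ll(b0, b1):
                eta = b0 + np.multiply.outer(b1, xc) if np.ndim(b1) else b0 + b1 * xc
                return np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)

            b0_lo, b0_hi = -6.0, 6.0
            b1_lo, b1_hi = -0.6, 0.6
            for _ in range(6):
                b0s = np.linspace(b0_lo, b0_hi, 41)
                b1s = np.linspace(b1_lo, b1_hi, 41)
                vals = np.array([[ll(b0, b1) for b1 in b1s] for b0 in b0s])
                i, j = np.unravel_index(np.argmax(vals), vals.shape)
                s0 = b0s[1] - b0s[0]
                s1 = b1s[1] - b1s[0]
                b0_lo, b0_hi = b0s[i] - 1.5 * s0, b0s[i] + 1.5 * s0
                b1_lo, b1_hi = b1s[j] - 1.5 * s1, b1s[j] + 1.5 * s1
            b0c, b1 = b0s[i], b1s[j]
            return b0c - b1 * x.mean(), b1

        for seed, n in [(0, 20), (1, 25), (2, 30)]:
            rng = np.random.default_rng(seed)
            y, tl = _simulate_logistic(rng, n, -6.0, 0.015)
            fit = fit_logistic_presence(y, tl)
            if not fit.estimable:
                continue
            g0, g1 = grid_mle(y, tl)
            # compare on the centred scale where both parameters are O(1)
            assert fit.beta0 + fit.beta1 * tl.mean() == pytest.approx(
                g0 + g1 * tl.mean(), abs=1e-3
            )
            assert fit.beta1 == pytest.approx(g1, abs=1e-3)

    def test_null_slope_recovery_and_uniform_p(self):
        """With no TL effect the slope stays near 0 and p is not anti-conservative."""
        rng = np.random.default_rng(99)
        small_p = 0
        n_fits = 0
        for _ in range(200):
            tl = rng.uniform(300, 509, size=200)
            y = (rng.random(200) < 0.4).astype(float)
            fit = fit_logistic_presence(y, tl)
            if not fit.estimable:
                continue
            n_fits += 1
            assert abs(fit.beta1) < 3.5 * fit.se_beta1 + 1e-12 or fit.p < 0.01
            small_p += fit.p < 0.05
        assert n_fits > 190
        assert small_p / n_fits < 0.09

    def test_slope_recovery(self):
        """Median recovered slope within 20% of the generating 0.03 per mm."""
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y, tl = _simulate_logistic(rng, 500, -12.0, 0.03)
            fit = fit_logistic_presence(y, tl)
            assert fit.estimable
            estimates.append(fit.beta1)
        median = float(np.median(estimates))
        assert abs(median - 0.03) <= 0.2 * 0.03

    def test_one_level_outcome_flagged(self):
        fit = fit_logistic_presence(np.ones(20), np.linspace(300, 500, 20))
        assert not fit.estimable
        assert fit.reason == "one-level outcome"

    def test_complete_separation_flagged(self):
        tl = np.linspace(300, 500, 20)
        y = (tl > 400).astype(float)
        fit = fit_logistic_presence(y, tl)
        assert not fit.estimable
        assert fit.reason == "separation"

    def test_deviance_monotone_and_converged(self):
        rng = np.random.default_rng(5)
        y, tl = _simulate_logistic(rng, 80, -10.0, 0.025)
        fit = fit_logistic_presence(y, tl)
        assert fit.converged
        assert fit.ll_full >= fit.ll_null - 1e-12
        assert fit.chi2 >= 0

    def test_presence_curve_monotone_and_banded(self):
        rng = np.random.default_rng(8)
        y, tl = _simulate_logistic(rng, 150, -9.0, 0.022)
        fit = fit_logistic_presence(y, tl)
        grid = np.linspace(300, 509, 50)
        curve = presence_curve(fit, grid)
        prob = curve["probability"].to_numpy()
        assert ((prob > 0) & (prob < 1)).all()
        diffs = np.diff(prob)
        assert (diffs >= 0).all() or (diffs <= 0).all()
        assert (curve["lower"] <= curve["probability"]).all()
        assert (curve["probability"] <= curve["upper"]).all()

    def test_screen_over_fixture_categories(self, fixture_dataset, fixture_metrics):
        from crocdiet import stomach_category_matrix

        kept = rii_filter(fixture_metrics)
        mat = stomach_category_matrix(
            list(fixture_dataset.stomachs), list(fixture_dataset.prey)
        )
        tl = [s.tl_mm for s in fixture_dataset.stomachs]
        table, fits = logistic_screen(mat, tl, categories=kept)
        assert list(table["category"]) == kept
        assert set(table.loc[table["estimable"], "category"]) <= set(kept)
        for _, row in table[table["estimable"]].iterrows():
            assert 0 <= row["p"] <= 1

    def test_non_binary_presence_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic_presence([0, 2, 1], [300, 400, 500])
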