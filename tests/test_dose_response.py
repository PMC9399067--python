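import numpy as np
import pytest

from radiocell import dose_response as dr
from radiocell import synthetic_data as sd


def _noiseless_points(alpha, doses, pe=0.5, plated=450):
    counts = [
        np.full(3, plated * pe * np.exp(-alpha * d)) for d in doses
    ]
    return dr.survival_fractions(
        np.asarray(doses), counts, np.full(3, plated * pe)
    )


class TestSurvivalFractions:
    def test_identical_counts_give_unity(self):
        pts = dr.survival_fractions(
            np.array([1.0]), [np.array([220, 220, 220])],
            np.array([220, 220, 220]),
        )
        assert pts[0].survival_fraction == pytest.approx(1.0)

    def test_poisson_ratio_propagation_example(self):
        pts = dr.survival_fractions(
            np.array([1.0]), [np.array([110, 110, 110])],
            np.array([220, 220, 220]),
        )
        assert pts[0].survival_fraction == pytest.approx(0.5)
        assert pts[0].sd == pytest.approx(
            0.5 * np.sqrt(1 / 110 + 1 / 220), rel=1e-9
        )

    def test_complete_kill_reports_upper_bound(self):
        pts = dr.survival_fractions(
            np.array([5.0]), [np.zeros(3)], np.array([220, 220, 220])
        )
        assert pts[0].survival_fraction == 0.0
        assert pts[0].sd > 0.0

    def test_zero_untreated_rejected(self):
        with pytest.raises(ValueError):
            dr.survival_fractions(
                np.array([1.0]), [np.array([10, 10, 10])], np.zeros(3)
            )


class TestFitAlpha:
    def test_noiseless_fit_recovers_generating_slope_exactly(self):
        doses = (0.74, 1.48, 2.22, 2.96, 3.70)
        fit = dr.fit_alpha(_noiseless_points(0.16, doses))
        assert fit.alpha_gy_inv == pytest.approx(0.16, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_dose_scaling_equivariance(self):
        doses = np.array([0.5, 1.0, 2.0, 3.0])
        f1 = dr.fit_alpha(_noiseless_points(0.3, doses))
        f2 = dr.fit_alpha(_noiseless_points(0.3 / 2.0, 2.0 * doses))
        assert f2.alpha_gy_inv == pytest.approx(f1.alpha_gy_inv / 2.0, rel=1e-9)

    def test_zero_sf_points_dropped_with_warning(self):
        doses = np.array([1.0, 2.0, 3.0, 8.0])
        counts = [np.full(3, 100.0), np.full(3, 50.0), np.full(3, 25.0),
                  np.zeros(3)]
        pts = dr.survival_fractions(doses, counts, np.full(3, 200.0))
        with pytest.warns(UserWarning):
            fit = dr.fit_alpha(pts)
        assert fit.n_points == 3

    def test_excluded_points_skipped(self):
        doses = (1.0, 2.0, 3.0, 4.0)
        pts = _noiseless_points(0.2, doses)
        tweaked = [
            dr.SurvivalPoint(
                p.dose_gy, p.mean_colonies, p.survival_fraction, p.sd,
                excluded=(p.dose_gy == 4.0),
            )
            for p in pts
        ]
        fit = dr.fit_alpha(tweaked, exclude_flagged=True)
        assert fit.n_points == 3

    def test_too_few_points_rejected(self):
        pts = _noiseless_points(0.2, (1.0, 2.0))
        with pytest.raises(ValueError):
            dr.fit_alpha(pts)

    def test_r_squared_high_at_assay_noise_scale(self):
        col, _ = sd.gen_clonogenic(
            sd.DEFAULT_DOSES_GY["Lu-177"], 0.16, seed=1
        )
        fit = dr.fit_alpha(dr.survival_points_from_table(col))
        assert fit.r_squared >= 0.96

    def test_median_recovery_within_5pct_over_seeds(self):
        """Across 200 seeded simulations at assay noise, the median fitted
        slope stays within 5% of the generating value for both nuclides."""
        for nuclide, alpha in (("Lu-177", 0.16), ("Ac-225", 0.67)):
            fitted = []
            for seed in range(200):
                col, _ = sd.gen_clonogenic(
                    sd.DEFAULT_DOSES_GY[nuclide], alpha, seed=3000 + seed
                )
                fitted.append(
                    dr.fit_alpha(
                        dr.survival_points_from_table(col)
                    ).alpha_gy_inv
                )
            assert np.median(fitted) == pytest.approx(alpha, rel=0.05)

    def test_optional_quadratic_term(self):
        doses = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        sf = np.exp(-0.2 * doses - 0.05 * doses**2)
        counts = [np.full(3, 225.0 * s) for s in sf]
        pts = dr.survival_fractions(doses, counts, np.full(3, 225.0))
        fit = dr.fit_alpha(pts, include_beta=True)
        assert fit.alpha_gy_inv == pytest.approx(0.2, abs=1e-6)
        assert fit.beta_gy2_inv == pytest.approx(0.05, abs=1e-6)


class TestPlotExport:
    def test_plot_file_written(self, tmp_path):
        pts = _noiseless_points(0.16, (0.74, 1.48, 2.22, 2.96, 3.70))
        fit = dr.fit_alpha(pts)
        out = tmp_path / "dose_response.png"
        dr.plot_dose_response(pts, fit, out, label="beta emitter")
        assert out.exists() and out.stat().st_size > 0


class TestRBE:
    def test_equal_slopes_give_unity(self):
        f = dr.DoseResponseFit(0.5, 0.01, 1.0, 5)
        assert dr.rbe(f, f).rbe == pytest.approx(1.0)

    def test_printed_value_propagation(self):
        test = dr.DoseResponseFit(0.67, 0.06, 1.0, 7)
        ref = dr.DoseResponseFit(0.16, 0.01, 1.0, 5)
        result = dr.rbe(test, ref)
        assert result.rbe == pytest.approx(4.19, abs=0.01)
        assert result.rbe_se == pytest.approx(0.457, abs=0.005)

    def test_scale_invariance(self):
        t = dr.DoseResponseFit(0.6, 0.05, 1.0, 5)
        r = dr.DoseResponseFit(0.2, 0.02, 1.0, 5)
        t2 = dr.DoseResponseFit(1.2, 0.10, 1.0, 5)
        r2 = dr.DoseResponseFit(0.4, 0.04, 1.0, 5)
        assert dr.rbe(t, r).rbe == pytest.approx(dr.rbe(t2, r2).rbe)
        assert dr.rbe(t, r).rbe_se == pytest.approx(dr.rbe(t2, r2).rbe_se)

    def test_zero_reference_rejected(self):
        t = dr.DoseResponseFit(0.6, 0.05, 1.0, 5)
        bad = dr.DoseResponseFit(0.0, 0.01, 1.0, 5)
        with pytest.raises(ValueError):
            dr.rbe(t, bad)

    def test_se_formula_matches_monte_carlo_ratio_oracle(self):
        """First-order ratio propagation vs the SD of an explicit ratio
        distribution (1e5 draws), within 5%."""
        rng = np.random.default_rng(42)
        a_t = rng.normal(0.67, 0.06, 100_000)
        a_r = rng.normal(0.16, 0.01, 100_000)
        oracle_sd = np.std(a_t / a_r)
        result = dr.rbe(
            dr.DoseResponseFit(0.67, 0.06, 1.0, 7),
            dr.DoseResponseFit(0.16, 0.01, 1.0, 5),
        )
        assert result.rbe_se == pytest.approx(oracle_sd, rel=0.05)
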