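"""Probabilistic and one-way sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from bariatric_cea import (
    ParameterDistributions,
    beta_from_moments,
    ceac,
    default_wtp_grid,
    gamma_from_moments,
    one_way,
    percentile_interval,
    run_psa,
)
from bariatric_cea.psa import ONE_WAY_PARAMETERS, PSAResult


class TestMomentMatching:
    @pytest.mark.parametrize(
        "mean, sd, shape",
        [
            (25_854, 2_044, 159.99),
            (157, 47, 11.157),
            (5.0, 5.0, 1.0),  # mean = sd is exponential-shaped
        ],
    )
    def test_gamma_shape(self, mean, sd, shape):
        got_shape, got_scale = gamma_from_moments(mean, sd)
        assert got_shape == pytest.approx(shape, rel=1e-3)
        assert got_shape * got_scale == pytest.approx(mean, rel=1e-12)

    def test_gamma_sampled_moments(self):
        """10^6 draws from the fitted gamma match the requested moments."""
        shape, scale = gamma_from_moments(25_854, 2_044)
        draws = np.random.default_rng(0).gamma(shape, scale, size=1_000_000)
        assert draws.mean() == pytest.approx(25_854, rel=5e-3)
        assert draws.std() == pytest.approx(2_044, rel=5e-3)

    def test_gamma_invalid(self):
        for mean, sd in [(0, 1), (1, 0), (-1, 1)]:
            with pytest.raises(ValueError, match="positive"):
                gamma_from_moments(mean, sd)

    def test_beta_hrql_parameters(self):
        alpha, beta_param = beta_from_moments(0.0042, 0.0011)
        assert alpha == pytest.approx(14.5, rel=0.01)
        assert beta_param == pytest.approx(3_441, rel=0.01)
        draws = np.random.default_rng(1).beta(alpha, beta_param, size=1_000_000)
        assert draws.mean() == pytest.approx(0.0042, rel=5e-3)
        assert draws.std() == pytest.approx(0.0011, rel=5e-3)

    def test_beta_symmetric(self):
        alpha, beta_param = beta_from_moments(0.5, 0.1)
        assert alpha == pytest.approx(beta_param)

    def test_beta_infeasible_variance(self):
        with pytest.raises(ValueError, match="sd"):
            beta_from_moments(0.0042, 0.07)
        with pytest.raises(ValueError, match="mean"):
            beta_from_moments(1.2, 0.1)


@pytest.fixture(scope="module")
def psa_result(calibrated):
    return run_psa(calibrated, n=400, seed=7)


class TestRunPsa:
    def test_fixed_seed_is_bit_reproducible(self, calibrated):
        a = run_psa(calibrated, n=50, seed=42)
        b = run_psa(calibrated, n=50, seed=42)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.incremental_cost, b.incremental_cost)
        np.testing.assert_array_equal(a.added_qalys, b.added_qalys)

    def test_replicate_count_and_shapes(self, psa_result):
        assert psa_result.n_replicates == 400
        assert psa_result.incremental_cost.shape == (400, 7)

    def test_degenerate_distributions_collapse_to_base_case(self, calibrated):
        """With vanishing spreads every replicate equals the deterministic

        base case, and the CEAC is exactly 0 or 1."""
        from bariatric_cea import base_case_results, icer

        tight = ParameterDistributions(
            intervention_cost=(25_854, 1e-6),
            savings_per_bmi=(157, 1e-9),
            bmi_reduction=(13.2, 1e-9),
            hrql_gain_per_bmi=(0.0042, 1e-9),
        )
        result = run_psa(calibrated, tight, n=60, seed=3)
        base = base_case_results(calibrated, range(1, 8))
        for j, inc in enumerate(base):
            np.testing.assert_allclose(
                result.incremental_cost[:, j], inc.incremental_cost, rtol=1e-4
            )
            np.testing.assert_allclose(result.added_qalys[:, j], inc.added_qalys, rtol=1e-4)
        probs = ceac(result, 4, [1e5])["probability"].to_numpy()
        assert probs[0] in (0.0, 1.0)
        lo, hi = percentile_interval(result, 4)
        assert lo == pytest.approx(icer(base[3]), rel=1e-3)
        assert hi == pytest.approx(icer(base[3]), rel=1e-3)

    def test_infeasible_draws_rejected_and_counted(self, calibrated):
        risky = ParameterDistributions(
            intervention_cost=(25_854, 2_044),
            savings_per_bmi=(157, 47),
            bmi_reduction=(45.0, 15.0),  # frequently >= bmi_pre = 48.7
            hrql_gain_per_bmi=(0.0042, 0.0011),
        )
        result = run_psa(calibrated, risky, n=50, seed=5)
        assert result.n_rejected > 0
        assert np.all(result.draws["bmi_reduction"] < calibrated.bmi_pre)

    def test_invalid_n(self, calibrated):
        with pytest.raises(ValueError, match="n must be"):
            run_psa(calibrated, n=0, seed=1)


class TestCeac:
    def test_monotone_in_wtp(self, psa_result):
        curve = ceac(psa_result, 4, default_wtp_grid())
        assert np.all(np.diff(curve["probability"]) >= 0)

    def test_limits(self, psa_result):
        at_zero = ceac(psa_result, 2, [0.0])["probability"].iloc[0]
        frac_saving = (psa_result.incremental_cost[:, 1] <= 0).mean()
        assert at_zero == pytest.approx(frac_saving)
        huge = ceac(psa_result, 2, [1e12])["probability"].iloc[0]
        assert huge == pytest.approx((psa_result.added_qalys[:, 1] > 0).mean())

    def test_monotone_in_horizon_at_threshold(self, psa_result):
        probs = [
            ceac(psa_result, h, [1e5])["probability"].iloc[0] for h in range(1, 8)
        ]
        assert np.all(np.diff(probs) >= 0)

    def test_empty_grid_rejected(self, psa_result):
        with pytest.raises(ValueError, match="wtp_grid"):
            ceac(psa_result, 4, [])


class TestPercentileInterval:
    def test_hand_enumerated_two_point_mixture(self):
        """A symmetric two-point replicate set has percentiles equal to the

        two support points (brute-force enumeration)."""
        n = 100
        costs = np.where(np.arange(n) < n // 2, 10_000.0, 20_000.0)
        qalys = np.full(n, 0.5)
        result = PSAResult(
            seed=0,
            horizons=(1,),
            draws=pd.DataFrame(index=range(n)),
            incremental_cost=costs[:, None],
            added_qalys=qalys[:, None],
            n_rejected=0,
        )
        icers = np.sort(costs / 0.5)
        lo, hi = percentile_interval(result, 1)
        assert lo == pytest.approx(np.percentile(icers, 2.5))
        assert hi == pytest.approx(np.percentile(icers, 97.5))
        assert lo == pytest.approx(20_000.0)
        assert hi == pytest.approx(40_000.0)

    def test_too_few_valid_replicates(self):
        result = PSAResult(
            seed=0,
            horizons=(1,),
            draws=pd.DataFrame(index=range(30)),
            incremental_cost=np.full((30, 1), 1000.0),
            added_qalys=np.full((30, 1), 0.1),
            n_rejected=0,
        )
        with pytest.raises(ValueError, match="40"):
            percentile_interval(result, 1)

    def test_nonpositive_qaly_replicates_excluded(self, psa_result):
        icers = psa_result.icers(4)
        q = psa_result.added_qalys[:, 3]
        assert np.isnan(icers[q <= 0]).all() if (q <= 0).any() else True
        assert np.isfinite(icers[q > 0]).all()


class TestOneWay:
    def test_unknown_parameter_lists_valid_names(self, calibrated):
        with pytest.raises(ValueError) as err:
            one_way(calibrated, "savings", [0, 157], horizon=4)
        for name in ONE_WAY_PARAMETERS:
            assert name in str(err.value)

    def test_empty_values_rejected(self, calibrated):
        with pytest.raises(ValueError, match="values"):
            one_way(calibrated, "discount_rate", [], horizon=4)

    def test_discount_sweep_monotone(self, calibrated):
        table = one_way(calibrated, "discount_rate", [0.0, 0.03, 0.06], horizon=4)
        assert np.all(np.diff(table["icer"]) > 0)

    def test_savings_sweep_monotone_and_finite(self, calibrated):
        table = one_way(calibrated, "savings_per_bmi", [0.0, 157.0, 314.0], horizon=4)
        assert np.all(np.diff(table["icer"]) < 0)
        assert np.isfinite(table["icer"]).all()
        base = table["icer"].iloc[1]
        assert table["icer"].iloc[0] > base > table["icer"].iloc[2]

    def test_zero_hrql_slope_raises_icer_and_delays_crossing(self, calibrated):
        table = one_way(calibrated, "hrql_gain_per_bmi", [0.0, 0.0042], horizon=7)
        assert table["icer"].iloc[0] > table["icer"].iloc[1]
        assert table["crossing_year"].iloc[0] > table["crossing_year"].iloc[1]
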