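"""Closed-form chain solution, stochastic simulator and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scfkin import (
    RateSet,
    TimeCourse,
    ValidationError,
    closed_form_fractions,
    distribution_summary,
    stochastic_encounter,
)

rate_lists = st.lists(
    st.floats(min_value=0.0, max_value=50.0, allow_nan=False), min_size=1,
    max_size=5,
)


class TestRateSet:
    @pytest.mark.parametrize("bad", [[-0.1], [np.nan], [np.inf], []])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValidationError):
            RateSet(bad)

    def test_negative_dissociation_rejected(self):
        with pytest.raises(ValidationError):
            RateSet([1.0], dissociation_rate=-1.0)

    def test_near_equal_and_all_zero_rates_flagged_degenerate(self):
        assert RateSet([0.3, 0.3]).is_degenerate()
        assert RateSet([0.0, 0.0]).is_degenerate()
        assert not RateSet([0.5, 0.2, 0.08]).is_degenerate()


class TestClosedForm:
    def test_no_flux_identity(self):
        tc = closed_form_fractions(RateSet([0.0]), [0.0, 1.0, 100.0])
        assert np.allclose(tc.fractions[:, 0], 1.0)
        assert np.allclose(tc.fractions[:, 1], 0.0)

    def test_single_exponential_half_life(self):
        t_half = np.log(2) / 0.5
        tc = closed_form_fractions(RateSet([0.5]), [t_half])
        assert tc.fractions[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_three_step_chain_matches_ode_oracle(self, ode_oracle):
        # saturating-enzyme initiation/elongation rates for the
        # RBR-E3-driven Cyclin E chain
        rates = [0.5, 0.2, 0.08]
        times = np.array([0.1, 1.0, 10.0])
        tc = closed_form_fractions(RateSet(rates), times)
        expected = ode_oracle(rates, times)
        assert np.max(np.abs(tc.fractions - expected)) <= 1e-8
        assert tc.fractions[-1, 0] == pytest.approx(np.exp(-5.0), rel=1e-9)
        assert tc.fractions[-1, 1] == pytest.approx(0.21432889, abs=1e-6)

    @pytest.mark.parametrize("rates", [
        [0.3, 0.3],                      # exactly repeated
        [1.0, 1.0 + 1e-12, 0.5],         # nearly repeated
        [0.0, 0.0],                      # all-zero
        [2.0, 2.0, 2.0, 2.0],            # fully degenerate
    ])
    def test_degenerate_rates_match_ode_oracle(self, rates, ode_oracle):
        times = np.array([0.01, 0.5, 2.0, 10.0])
        tc = closed_form_fractions(RateSet(rates), times)
        assert np.max(np.abs(tc.fractions - ode_oracle(rates, times))) <= 1e-8

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            closed_form_fractions(RateSet([0.5]), [1.0, 0.5])  # non-increasing
        with pytest.raises(ValidationError):
            closed_form_fractions(RateSet([0.5]), [-1.0])
        with pytest.raises(ValidationError):
            closed_form_fractions(RateSet([0.5]), [1.0], n_tracked=2)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(rates=rate_lists, t_max=st.floats(0.1, 50.0))
    def test_conservation_and_monotonicity(self, rates, t_max):
        """Rows sum to one; S0 non-increasing; terminal non-decreasing."""
        times = np.linspace(0.0, t_max, 12)
        tc = closed_form_fractions(RateSet(rates), times)
        assert np.allclose(tc.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(tc.fractions[:, 0]) <= 1e-12)
        assert np.all(np.diff(tc.fractions[:, -1]) >= -1e-12)
        assert np.all(tc.fractions >= -1e-12)

    def test_dissociation_freezes_released_substrate(self, ode_oracle):
        """With release, observed species keep mass that left the ligase;
        the terminal aggregate is smaller than without release."""
        times = np.array([1.0, 5.0, 20.0])
        with_d = closed_form_fractions(
            RateSet([0.5, 0.2], dissociation_rate=0.3), times
        )
        without = closed_form_fractions(RateSet([0.5, 0.2]), times)
        assert np.allclose(with_d.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(with_d.fractions[:, -1] < without.fractions[:, -1])
        # S0 decay still governed by k1 + d
        assert with_d.fractions[0, 0] > np.exp(-(0.5 + 0.3) * 1.0) - 1e-9


class TestStochastic:
    def test_no_flux_keeps_all_molecules_unmodified(self):
        tc = stochastic_encounter(RateSet([0.0, 0.0]), 500, [1.0, 10.0], seed=3)
        assert np.allclose(tc.fractions[:, 0], 1.0)

    def test_same_seed_bit_identical(self):
        a = stochastic_encounter(RateSet([0.5, 0.2]), 2000, [1.0, 5.0], seed=11)
        b = stochastic_encounter(RateSet([0.5, 0.2]), 2000, [1.0, 5.0], seed=11)
        assert np.array_equal(a.fractions, b.fractions)

    def test_converges_to_closed_form_within_binomial_bounds(self):
        rates = RateSet([0.5, 0.2, 0.08])
        n = 10_000
        times = [10.0]
        emp = stochastic_encounter(rates, n, times, seed=1).fractions[0]
        exact = closed_form_fractions(rates, times).fractions[0]
        bound = 3.0 * np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(emp - exact) <= np.maximum(bound, 1e-12))

    def test_dissociation_agrees_with_matrix_exponential_path(self):
        rs = RateSet([0.5, 0.2], dissociation_rate=0.3)
        times = [1.0, 5.0]
        emp = stochastic_encounter(rs, 40_000, times, seed=5).fractions
        exact = closed_form_fractions(rs, times).fractions
        assert np.max(np.abs(emp - exact)) < 0.01

    def test_invalid_molecule_count(self):
        with pytest.raises(ValidationError):
            stochastic_encounter(RateSet([0.5]), 0, [1.0], seed=1)


class TestDistributionSummary:
    def test_all_unmodified_has_zero_mean_length(self):
        tc = closed_form_fractions(RateSet([0.0] * 4), [1.0])
        s = distribution_summary(tc, 1.0, threshold_length=4)
        assert s.mean_chain_length == 0.0
        assert s.fraction_at_least == 0.0

    def test_weighted_average_of_known_distribution(self):
        tc = TimeCourse(times=[0.0], fractions=[[0.0, 0.5, 0.0, 0.5, 0.0]])
        s = distribution_summary(tc, 0.0, threshold_length=3)
        assert s.mean_chain_length == pytest.approx(2.0)
        assert s.fraction_at_least == pytest.approx(0.5)

    def test_matches_hand_computed_sums_on_closed_form(self):
        tc = closed_form_fractions(RateSet([0.5, 0.2, 0.08]), [10.0])
        s = distribution_summary(tc, 10.0, threshold_length=2)
        f = tc.fractions[0]
        assert s.mean_chain_length == pytest.approx(
            f[1] + 2 * f[2] + 3 * f[3])
        assert s.fraction_at_least == pytest.approx(f[2] + f[3])

    def test_off_grid_time_requires_interpolation(self):
        tc = closed_form_fractions(RateSet([0.5]), [1.0, 2.0])
        with pytest.raises(ValidationError):
            distribution_summary(tc, 1.5)
        s = distribution_summary(tc, 1.5, threshold_length=1,
                                 interpolate=True)
        assert 0.0 < s.fraction_at_least < 1.0

    def test_threshold_beyond_resolved_lengths_rejected(self):
        tc = closed_form_fractions(RateSet([0.5, 0.2]), [1.0])
        with pytest.raises(ValidationError):
            distribution_summary(tc, 1.0, threshold_length=3)
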