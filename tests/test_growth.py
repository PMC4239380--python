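"""Gompertz growth law, start-size inversion and the dormancy extensions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect, brentq

from metasim.growth import (
    DormancyConfig,
    GompertzGrowth,
    LateDormancyConfig,
    MetastasisState,
    gompertz_size,
    invert_growth_time,
    make_metastasis,
    metastasis_size,
    offset_from_start_size,
    size_with_dormancy,
    size_with_late_dormancy,
)

B = 4.5e9
X0 = 1e4


class TestGompertzSize:
    @pytest.mark.parametrize(
        "a, t, expected_cells, rtol",
        [
            # printed growth constants reproduce the printed mean tumour masses
            (0.0462, 49.9, 1.23e9, 2e-3),
            (0.0326, 69.4, 1.16e9, 2e-3),
        ],
    )
    def test_printed_constants_reproduce_mean_masses(self, a, t, expected_cells, rtol):
        g = GompertzGrowth.from_start_size(a, B, X0)
        assert gompertz_size(g, t) == pytest.approx(expected_cells, rel=rtol)

    def test_start_size_is_exact_at_t0_offset(self):
        g = GompertzGrowth.from_start_size(0.0462, B, X0)
        assert gompertz_size(g, 0.0) == pytest.approx(X0, rel=1e-9)
        assert gompertz_size(g, 0.0) == pytest.approx(
            math.exp(math.log(B) * (1 - math.exp(-g.a * g.t0))), rel=1e-12
        )

    def test_saturates_at_b(self):
        g = GompertzGrowth.from_start_size(0.0462, B, X0)
        assert gompertz_size(g, 1e4) == pytest.approx(B, rel=1e-6)

    def test_negative_time_rejected(self):
        g = GompertzGrowth(a=0.05, b=1e9)
        with pytest.raises(ValueError):
            gompertz_size(g, -0.1)

    def test_strictly_increasing_and_bounded_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = rng.uniform(1e-3, 0.5)
            b = 10 ** rng.uniform(1, 10)
            t0 = rng.uniform(0, 50)
            g = GompertzGrowth(a=a, b=b, t0=t0)
            t = np.sort(rng.uniform(0, 200, size=5))
            sizes = gompertz_size(g, t)
            assert np.all(np.diff(sizes) >= 0)
            # strict increase wherever the curve is not yet numerically saturated
            below = sizes[:-1] < b * (1 - 1e-9)
            assert np.all(np.diff(sizes)[below] > 0)
            assert np.all(sizes <= b * (1 + 1e-12))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GompertzGrowth(a=-0.1, b=1e9)
        with pytest.raises(ValueError):
            GompertzGrowth(a=0.1, b=0.5)
        with pytest.raises(ValueError):
            GompertzGrowth(a=0.1, b=1e9, t0=-1.0)


class TestStartSizeOffset:
    # expected offsets frozen from an independent bisection oracle on
    # gompertz_size(·, 0) = x0 (cross-checked below)
    @pytest.mark.parametrize(
        "a, x0, expected_t0",
        [(0.0462, 1e4, 11.5815), (0.0326, 1e4, 16.4131)],
    )
    def test_matches_bisection_oracle(self, a, x0, expected_t0):
        t0 = offset_from_start_size(a, B, x0)
        assert t0 == pytest.approx(expected_t0, abs=5e-4)
        oracle = bisect(
            lambda tau: gompertz_size(GompertzGrowth(a=a, b=B, t0=tau), 0.0) - x0,
            0.0,
            200.0,
            xtol=1e-12,
        )
        assert t0 == pytest.approx(oracle, rel=1e-9)

    def test_single_cell_start_has_zero_offset(self):
        assert offset_from_start_size(0.05, B, 1.0) == 0.0

    def test_round_trip_start_size(self):
        g = GompertzGrowth.from_start_size(0.0462, B, X0)
        assert gompertz_size(g, 0.0) == pytest.approx(X0, rel=1e-9)

    @pytest.mark.parametrize("bad_x0", [0.5, 4.5e9, 1e10])
    def test_out_of_range_start_size_rejected(self, bad_x0):
        with pytest.raises(ValueError):
            offset_from_start_size(0.05, B, bad_x0)


class TestInvertGrowthTime:
    def test_round_trip_through_forward_curve(self):
        g = GompertzGrowth.from_start_size(0.0462, B, X0)
        assert invert_growth_time(g, gompertz_size(g, 17.0)) == pytest.approx(
            17.0, rel=1e-6
        )

    def test_fitted_curve_reaches_mean_mass_at_mean_duration(self, pfp_growth):
        assert invert_growth_time(pfp_growth, 1.23e9) == pytest.approx(49.9, rel=1e-6)

    def test_start_size_maps_to_zero(self, pfp_growth):
        assert invert_growth_time(pfp_growth, gompertz_size(pfp_growth, 0.0)) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_saturation_size_never_reached(self, pfp_growth):
        with pytest.raises(ValueError):
            invert_growth_time(pfp_growth, B)

    @given(
        a=st.floats(1e-3, 0.5),
        logb=st.floats(2, 10),
        t=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverse_composition_property(self, a, logb, t):
        g = GompertzGrowth(a=a, b=10**logb, t0=0.0)
        x = gompertz_size(g, t)
        # skip the numerically saturated tail where the inverse is ill-posed
        if x < g.b * (1 - 1e-6):
            assert invert_growth_time(g, x) == pytest.approx(t, rel=1e-6, abs=1e-6)


def test_functional_form_anchored_to_printed_constants():
    """Solving x(49.9) = 1.23e9 for a under this parameterization recovers the
    printed 0.0462 day^-1, tying the functional form to the study inputs."""
    a = brentq(
        lambda a_: gompertz_size(GompertzGrowth.from_start_size(a_, B, X0), 49.9)
        - 1.23e9,
        1e-3,
        0.5,
        xtol=1e-12,
    )
    assert round(a, 4) == 0.0462


class TestDormancy:
    def test_size_is_one_while_dormant(self):
        g = GompertzGrowth(a=0.0462, b=B)
        state = MetastasisState(
            founded_at=5.0, growth=g, status="dormant", dormancy_end=35.0
        )
        assert size_with_dormancy(state, 20.0) == 1.0

    def test_zero_offset_reduces_to_plain_curve(self):
        g = GompertzGrowth(a=0.0462, b=B)
        state = MetastasisState(founded_at=5.0, growth=g, dormancy_end=5.0)
        for t in [5.0, 10.0, 40.0]:
            assert size_with_dormancy(state, t) == pytest.approx(
                gompertz_size(g, t - 5.0), rel=1e-12
            )

    def test_dormancy_is_a_pure_time_shift(self):
        g = GompertzGrowth(a=0.0462, b=B)
        state = MetastasisState(
            founded_at=0.0, growth=g, status="dormant", dormancy_end=30.0
        )
        assert size_with_dormancy(state, 40.0) == pytest.approx(
            gompertz_size(g, 10.0), rel=1e-12
        )

    def test_never_exceeds_plain_curve_and_non_decreasing(self):
        g = GompertzGrowth(a=0.1, b=1e6)
        state = MetastasisState(
            founded_at=0.0, growth=g, status="dormant", dormancy_end=12.0
        )
        ts = np.linspace(0, 60, 241)
        sizes = [size_with_dormancy(state, t) for t in ts]
        plain = [gompertz_size(g, t) for t in ts]
        assert np.all(np.diff(sizes) >= 0)
        assert np.all(np.asarray(sizes) <= np.asarray(plain) + 1e-9)

    def test_query_before_founding_rejected(self):
        g = GompertzGrowth(a=0.1, b=1e6)
        state = MetastasisState(founded_at=10.0, growth=g)
        with pytest.raises(ValueError):
            metastasis_size(state, 5.0)


class TestLateDormancy:
    @staticmethod
    def make_state(frozen_size=55.0, t_ld=30.0, a=0.0462):
        g = GompertzGrowth(a=a, b=B)
        trigger = invert_growth_time(g, frozen_size)
        return MetastasisState(
            founded_at=0.0,
            growth=g,
            frozen_size=frozen_size,
            trigger_time=trigger,
            late_dormancy_end=trigger + t_ld,
        )

    def test_frozen_exactly_at_trigger_size_during_arrest(self):
        state = self.make_state(frozen_size=55.0, t_ld=30.0)
        t_mid = (state.trigger_time + state.late_dormancy_end) / 2
        assert size_with_late_dormancy(state, t_mid) == 55.0
        assert 10 <= state.frozen_size <= 100

    def test_zero_duration_reduces_to_plain_curve(self):
        state = self.make_state(t_ld=0.0)
        g = state.growth
        for t in [0.0, state.trigger_time, state.trigger_time + 20.0]:
            assert size_with_late_dormancy(state, t) == pytest.approx(
                gompertz_size(g, t), rel=1e-9
            )

    def test_resumes_on_time_shifted_curve(self):
        state = self.make_state(frozen_size=40.0, t_ld=25.0)
        t = state.late_dormancy_end + 7.5
        assert size_with_late_dormancy(state, t) == pytest.approx(
            gompertz_size(state.growth, t - 25.0), rel=1e-9
        )

    def test_status_machine_transitions(self):
        state = self.make_state(frozen_size=40.0, t_ld=25.0)
        assert state.status_at(state.trigger_time - 1.0) == "growing"
        assert state.status_at(state.trigger_time + 1.0) == "late_dormant"
        assert state.status_at(state.late_dormancy_end + 1.0) == "resumed"


class TestMakeMetastasis:
    def test_sampled_trigger_sizes_respect_bounds(self, rng):
        cfg = LateDormancyConfig()
        g = GompertzGrowth(a=0.0462, b=B)
        for _ in range(200):
            state = make_metastasis(3.0, g, cfg, rng)
            assert cfg.size_min <= state.frozen_size <= cfg.size_max
            assert state.late_dormancy_end >= state.trigger_time

    def test_sampled_dormancy_durations_truncated_at_zero(self, rng):
        cfg = DormancyConfig(mean_duration=2.0, sd_duration=10.0)
        g = GompertzGrowth(a=0.0462, b=B)
        ends = [make_metastasis(1.0, g, cfg, rng).dormancy_end for _ in range(300)]
        assert min(ends) >= 1.0  # duration never negative

    def test_no_regime_starts_growing(self, rng):
        g = GompertzGrowth(a=0.0462, b=B)
        state = make_metastasis(2.0, g, None, rng)
        assert state.status == "growing"
        assert metastasis_size(state, 2.0) == pytest.approx(1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DormancyConfig(mean_duration=-1.0)
        with pytest.raises(ValueError):
            LateDormancyConfig(size_min=1.0)
        with pytest.raises(ValueError):
            LateDormancyConfig(size_min=50.0, size_max=10.0)
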