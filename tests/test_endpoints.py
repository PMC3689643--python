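"""Endpoint formulas: tumor volume, TGI, ILS, TGD, BWC, proliferation inhibition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import precombi as pc
from precombi.endpoints import EndpointError, proliferation_inhibition, round_half_away


class TestTumorVolume:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10, 20, 1000.0),
            (0, 5, 0.0),
            (12.6, 15.1, 12.6**2 * 15.1 / 2),  # = 1198.638
        ],
    )
    def test_formula(self, a, b, expected):
        assert pc.tumor_volume(a, b) == pytest.approx(expected)

    def test_rejects_a_greater_than_b(self):
        with pytest.raises(EndpointError):
            pc.tumor_volume(20, 10)


class TestTgi:
    def test_identity_is_zero(self):
        assert pc.tgi(5.0, 5.0) == 0.0

    def test_tumor_weight_example(self):
        # treated mean weight 0.28 g vs control 1.4 g
        assert pc.tgi(0.28, 1.4) == pytest.approx(80.0)

    def test_negative_when_treated_larger(self):
        assert pc.tgi(1.35, 1.0) == pytest.approx(-35.0)

    def test_zero_control_undefined(self):
        with pytest.raises(EndpointError):
            pc.tgi(1.0, 0.0)

    @given(
        w_t=st.floats(0, 1e4),
        w_c=st.floats(0.01, 1e4),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, w_t, w_c, c):
        assert pc.tgi(c * w_t, c * w_c) == pytest.approx(
            pc.tgi(w_t, w_c), rel=1e-9, abs=1e-8
        )


class TestIls:
    def test_identity_and_doubling(self):
        assert pc.ils(20.0, 20.0) == 0.0
        assert pc.ils(40.0, 20.0) == pytest.approx(100.0)

    def test_positive_for_life_extension(self):
        # medians 43.6 vs 20.0 days -> +118%
        assert round_half_away(pc.ils(43.6, 20.0)) == 118

    @given(
        m=st.floats(1, 200),
        ratio=st.floats(0.1, 10),
        c=st.floats(0.1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_homogeneous_degree_zero(self, m, ratio, c):
        assert pc.ils(c * m * ratio, c * m) == pytest.approx(pc.ils(m * ratio, m), rel=1e-9)


class TestTgd:
    def test_already_at_threshold_first_day(self):
        assert pc.tgd([10, 14], [1200, 2400], 1000) == 10.0

    def test_log_linear_interpolation(self):
        # 500 * 4^((t-10)/4) reaches 1000 at t = 12 exactly
        assert pc.tgd([10, 14], [500, 2000], 1000) == 12.0

    def test_never_crossing_reports_not_reached(self):
        assert pc.tgd([10, 14, 18], [300, 600, 900], 1000) is None

    def test_exponential_curve_matches_closed_form(self):
        v0, r, thr = 80.0, 0.21, 1000.0
        days = list(range(5, 30, 4))
        vols = [v0 * math.exp(r * (d - days[0])) for d in days]
        t_exact = days[0] + math.log(thr / v0) / r
        assert pc.tgd(days, vols, thr) == pytest.approx(t_exact, abs=0.05)

    def test_antitone_in_uniform_scaling(self):
        days = [7, 10, 14, 17, 21]
        vols = [100 * math.exp(0.2 * d) for d in days]
        t1 = pc.tgd(days, vols, 1000)
        t2 = pc.tgd(days, [2 * v for v in vols], 1000)
        assert t2 <= t1

    def test_delta_tgd(self):
        assert pc.delta_tgd(47, 24) == 23
        assert pc.delta_tgd(56, 47) == 9
        assert pc.delta_tgd(30, 30) == 0


class TestBwc:
    def test_constant_weights_zero(self):
        series, dec = pc.bwc([1, 5, 9], [20, 20, 20], 1)
        assert series == [0, 0, 0] and dec == 0

    def test_loss_and_gain(self):
        series, dec = pc.bwc([1, 5], [20, 18], 1)
        assert series[1] == pytest.approx(-10.0) and dec == pytest.approx(10.0)
        series, dec = pc.bwc([1, 5], [20, 22], 1)
        assert series[1] == pytest.approx(10.0) and dec == 0.0

    def test_missing_baseline_is_error(self):
        with pytest.raises(EndpointError):
            pc.bwc([5, 9], [20, 19], 1)


class TestProliferationInhibition:
    @pytest.mark.parametrize(
        "at,ac,am,expected",
        [
            (1.0, 1.0, 0.1, 0.0),  # untreated level -> no inhibition
            (0.1, 1.0, 0.1, 100.0),  # down to blank -> full inhibition
            (0.55, 1.0, 0.1, 50.0),
            (1.45, 1.0, 0.1, -50.0),  # growth stimulation is negative
        ],
    )
    def test_formula(self, at, ac, am, expected):
        assert proliferation_inhibition(at, ac, am) == pytest.approx(expected)

    def test_invalid_plate(self):
        with pytest.raises(EndpointError):
            proliferation_inhibition(0.5, 0.1, 0.2)


class TestGroupAggregation:
    def test_endpoint_table_end_to_end(self, four_group_design):
        animals, truth = pc.simulate_study(
            four_group_design,
            pc.InteractionSpec(f1=0.5, f2=0.8, gamma=1.0, noise_sd=0.0, seed=3),
            n_per_group=4,
        )
        table = pc.build_endpoint_table(animals, four_group_design)
        day = four_group_design.evaluation_days[0]
        assert table.tgi_at("agent-1", day) == pytest.approx(50.0, abs=1e-6)
        assert table.tgi_at("agent-2", day) == pytest.approx(20.0, abs=1e-6)
        # control reaches 1 cm³ near the growth model's closed-form day
        ctrl = table.groups["control"]
        assert ctrl.tgd_days == pytest.approx(math.log(100) / 0.19, abs=0.5)
        # n_alive never increases along a group curve
        curve = pc.group_curve(animals, "agent-1 + agent-2")
        assert all(b <= a for a, b in zip(curve.n_alive, curve.n_alive[1:]))

    def test_median_survival_uncensored_is_sample_median(self):
        t = np.array([10.0, 12.0, 14.0, 30.0])
        e = np.array([True] * 4)
        assert pc.median_survival(t, e) == 13.0

    def test_tsv_rendering_has_one_row_per_group(self, four_group_design):
        animals, _ = pc.simulate_study(four_group_design, n_per_group=3, seed=4)
        table = pc.build_endpoint_table(animals, four_group_design)
        text = table.to_tsv()
        assert len(text.strip().splitlines()) == 1 + len(four_group_design.groups)


def test_round_half_away_from_zero():
    assert round_half_away(51.12) == 51
    assert round_half_away(90.25) == 90
    assert round_half_away(16.5) == 17
    assert round_half_away(-16.5) == -17
    assert round_half_away(-35.4) == -35
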