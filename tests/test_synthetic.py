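"""Synthetic-study generator: determinism, closed forms, pipeline recovery."""

import math

import numpy as np
import pytest

import precombi as pc
from precombi.endpoints import plate_inhibition
from precombi.synthetic_data import (
    GROUP_COMBO,
    SACRIFICE_THRESHOLD,
    GrowthModel,
    InteractionSpec,
    simulate_animal,
    simulate_plate,
)


class TestGrowthModel:
    def test_exponential_crossing_closed_form(self):
        m = GrowthModel(kind="exponential", v0=100, rate=0.2)
        assert m.crossing_time(1000) == pytest.approx(math.log(10) / 0.2)

    def test_gompertz_saturates_below_capacity(self):
        m = GrowthModel(kind="gompertz", v0=50, rate=0.1, gompertz_capacity=1500)
        assert m.crossing_time(2000) is None
        t = m.crossing_time(1000)
        assert m.volume(t) == pytest.approx(1000, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GrowthModel(v0=-1)
        with pytest.raises(ValueError):
            GrowthModel(kind="gompertz", v0=100, rate=0.1, gompertz_capacity=50)


class TestSimulateAnimal:
    def test_effect_one_reproduces_control_curve(self):
        m = GrowthModel()
        days = [7, 10, 14]
        an = simulate_animal(m, 1.0, 0.0, days, seed=0)
        for meas in an.tumor_measurements:
            v = pc.tumor_volume(meas.a, meas.b)
            assert v == pytest.approx(float(m.volume(meas.day)), rel=1e-9)

    def test_latent_death_day_closed_form(self):
        m = GrowthModel(v0=100, rate=0.2)
        days = list(range(1, 40))
        an = simulate_animal(m, 1.0, 0.0, days, sacrifice_threshold=1000, seed=0)
        # ln(10)/0.2 = 11.51 -> sacrificed on day 12
        assert an.survival.last_day == 12
        assert an.survival.event.value == "death_or_sacrifice_sick"

    def test_same_seed_identical_series(self):
        m = GrowthModel()
        a1 = simulate_animal(m, 0.5, 0.1, [7, 10, 14], seed=42)
        a2 = simulate_animal(m, 0.5, 0.1, [7, 10, 14], seed=42)
        assert a1 == a2

    def test_effect_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_animal(GrowthModel(), 1.5, 0.0, [7])


class TestSimulateStudy:
    def test_small_groups_refused(self):
        with pytest.raises(ValueError, match="n_per_group"):
            pc.simulate_study(n_per_group=2)

    def test_deterministic_given_seed(self):
        a1, t1 = pc.simulate_study(seed=9, n_per_group=3)
        a2, t2 = pc.simulate_study(seed=9, n_per_group=3)
        assert a1 == a2 and t1 == t2

    def test_bliss_null_zero_noise_recovers_additive(self, four_group_design):
        spec = InteractionSpec(f1=0.52, f2=0.94, gamma=1.0, noise_sd=0.0, seed=1)
        animals, truth = pc.simulate_study(four_group_design, spec, n_per_group=4)
        report = pc.analyze_study(animals, four_group_design)
        tgi_v = [v for v in report.combinations if v.endpoint.startswith("TGI")][0]
        assert tgi_v.e_cytostatic == pytest.approx(48.0, abs=1e-6)
        assert tgi_v.e_modulator == pytest.approx(6.0, abs=1e-6)
        assert tgi_v.h_expected == pytest.approx(51.12, abs=1e-6)
        assert tgi_v.e_observed == pytest.approx(51.12, abs=1e-6)
        assert tgi_v.verdict is pc.Verdict.ADDITIVE
        assert truth.true_verdict is pc.Verdict.ADDITIVE

    def test_super_additive_gamma_recovers_synergism(self, four_group_design):
        spec = InteractionSpec(gamma=0.5, noise_sd=0.0, seed=1)
        animals, truth = pc.simulate_study(four_group_design, spec, n_per_group=4)
        report = pc.analyze_study(animals, four_group_design)
        tgi_v = [v for v in report.combinations if v.endpoint.startswith("TGI")][0]
        assert tgi_v.e_observed > tgi_v.h_expected
        assert tgi_v.verdict is pc.Verdict.SYNERGISM
        assert truth.true_verdict is pc.Verdict.SYNERGISM

    def test_combination_worse_than_cytostatic_is_antagonism(self, four_group_design):
        # gamma large enough that the combined volume exceeds cytostatic-alone
        spec = InteractionSpec(f1=0.5, f2=0.8, gamma=1.6, noise_sd=0.0, seed=1)
        animals, truth = pc.simulate_study(four_group_design, spec, n_per_group=4)
        report = pc.analyze_study(animals, four_group_design)
        tgi_v = [v for v in report.combinations if v.endpoint.startswith("TGI")][0]
        assert tgi_v.e_observed < tgi_v.e_cytostatic
        assert tgi_v.verdict is pc.Verdict.ANTAGONISM
        assert truth.true_verdict is pc.Verdict.ANTAGONISM

    def test_survival_consistency_in_gamma(self):
        """More combined inhibition (smaller γ) never shortens latent survival."""
        prev = -np.inf
        for gamma in (1.5, 1.0, 0.6, 0.3):
            _, truth = pc.simulate_study(
                interaction=InteractionSpec(gamma=gamma, noise_sd=0.0, seed=0),
                n_per_group=3,
            )
            assert truth.latent_death_day[GROUP_COMBO] >= prev
            prev = truth.latent_death_day[GROUP_COMBO]

    def test_sacrifice_threshold_distinct_from_tgd_threshold(self):
        assert SACRIFICE_THRESHOLD > 1000.0


class TestSimulatePlate:
    @pytest.mark.parametrize("inh,expected_at", [(0.0, 1.0), (100.0, 0.1), (50.0, 0.55)])
    def test_noiseless_inversion(self, inh, expected_at):
        plate = simulate_plate([inh], ac=1.0, am=0.1, noise_sd=0.0, replicates=3)
        ats = plate.replicates("cond-1")
        assert all(at == pytest.approx(expected_at) for at in ats)
        mean, sd = plate_inhibition(plate, "cond-1")
        assert mean == pytest.approx(inh)
        assert sd == pytest.approx(0.0)

    def test_noise_round_trip_near_truth(self):
        plate = simulate_plate([30.0], ac=1.2, am=0.08, noise_sd=0.01, replicates=8, seed=5)
        mean, sd = plate_inhibition(plate, "cond-1")
        assert mean == pytest.approx(30.0, abs=3.0)
        assert sd > 0

    def test_invalid_plate_parameters(self):
        with pytest.raises(ValueError):
            simulate_plate([10.0], ac=0.1, am=0.2)
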