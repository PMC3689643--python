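"""Synthetic preclinical combination studies with known ground truth.

The generator emulates a four-group subcutaneous mouse tumor study (control,
cytostatic alone, modulator alone, combination): near-exponential latent
tumor growth, treatment expressed as a volume fraction at an evaluation day,
lognormal caliper measurement noise distributed onto two diameters with a
fixed shape ratio, tumor-burden-triggered sacrifice, and SRB-style plate
absorbances inverted from target inhibition values.

Interaction between the two agents is controlled by a single multiplier γ on
the combined volume fraction, f_combo = f1·f2·γ: γ = 1 reproduces the
fractional-product (Bliss) null exactly, γ < 1 makes the combination
super-additive, γ > 1 sub-additive. The implied classification under a given
tolerance is recorded as ground truth so that end-to-end pipeline recovery
can be asserted.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .combination import DEFAULT_TOLERANCE, Verdict, classify, fractional_product
from .study_model import (
    AnimalSeries,
    BodyWeight,
    GroupRole,
    GroupSpec,
    StudyDesign,
    SurvivalEvent,
    SurvivalRecord,
    TumorMeasurement,
    PlateAssay,
    PlateWell,
)

#: b = SHAPE_RATIO * a when back-solving diameters from a volume
SHAPE_RATIO = 1.5

#: latent-volume sacrifice threshold, mm³ (distinct from the 1 cm³ TGD threshold)
SACRIFICE_THRESHOLD = 2000.0


class GrowthModel(BaseModel):
    """Latent tumor-growth law for one animal.

    Defaults describe a briskly growing s.c. murine colon tumor: ~10 mm³ at
    randomization and a doubling time of ~3.6 days, which carries the control
    curve to 1 cm³ about 24 days after randomization.
    """

    kind: Literal["exponential", "gompertz"] = "exponential"
    v0: float = 10.0  # mm³ at day 0
    rate: float = 0.19  # per day
    gompertz_capacity: Optional[float] = None  # mm³, gompertz only

    @model_validator(mode="after")
    def _check(self) -> "GrowthModel":
        if self.v0 <= 0 or self.rate <= 0:
            raise ValueError("v0 and rate must be > 0")
        if self.kind == "gompertz":
            if self.gompertz_capacity is None or self.gompertz_capacity <= self.v0:
                raise ValueError("gompertz needs capacity K > v0")
        return self

    def volume(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            return self.v0 * np.exp(self.rate * t)
        k = self.gompertz_capacity
        return k * np.exp(np.log(self.v0 / k) * np.exp(-self.rate * t))

    def crossing_time(self, threshold: float) -> Optional[float]:
        """Closed-form time at which the noiseless curve reaches *threshold*."""
        if threshold <= self.v0:
            return 0.0
        if self.kind == "exponential":
            return math.log(threshold / self.v0) / self.rate
        k = self.gompertz_capacity
        if threshold >= k:
            return None
        return -math.log(math.log(threshold / k) / math.log(self.v0 / k)) / self.rate


class InteractionSpec(BaseModel):
    """Treatment effects and interaction mode of a simulated study.

    ``f1`` and ``f2`` are the two agents' volume fractions at the evaluation
    day (treated central volume / control central volume); the defaults give
    single-agent growth inhibitions of 50% and 20%, in the range typical for
    a moderately active cytostatic paired with a weak modulator. ``gamma``
    multiplies the Bliss-null combined fraction f1·f2. ``noise_sd`` is the
    lognormal SD applied to observed volumes (0.08 ~ 8% caliper noise).
    """

    f1: float = 0.5
    f2: float = 0.8
    gamma: float = 1.0
    noise_sd: float = 0.08
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "InteractionSpec":
        for name, f in (("f1", self.f1), ("f2", self.f2)):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return self

    @property
    def f_combo(self) -> float:
        return min(1.0, self.f1 * self.f2 * self.gamma)


class SimulationTruth(BaseModel):
    """Generator parameters plus the interaction verdict they imply."""

    interaction: InteractionSpec
    model: GrowthModel
    n_per_group: int
    evaluation_day: int
    tolerance: float
    expected_tgi: dict[str, float]
    h_expected: float
    true_verdict: Verdict
    latent_death_day: dict[str, float]  # group -> latent sacrifice day (per-group)


GROUP_CONTROL = "control"
GROUP_AGENT1 = "agent-1"
GROUP_AGENT2 = "agent-2"
GROUP_COMBO = "agent-1 + agent-2"

#: twice-weekly caliper schedule from first dosing to study end
DEFAULT_MEASUREMENT_DAYS = [
    7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42, 45, 49, 52, 56, 60, 63,
]
DEFAULT_EVALUATION_DAY = 21


def default_design(
    evaluation_day: int = DEFAULT_EVALUATION_DAY,
    tgd_threshold_mm3: float = 1000.0,
) -> StudyDesign:
    """Four-group design (control, two singles, their combination)."""
    from .study_model import Arm, Route

    dosing = [7, 10, 13, 16, 19]
    arm1 = Arm(agent="agent-1", dose="100 mg/kg", route=Route.IV, days=dosing)
    arm2 = Arm(agent="agent-2", dose="1 ug/kg", route=Route.SC, days=dosing)
    return StudyDesign(
        study_id="synthetic-study",
        groups=[
            GroupSpec(name=GROUP_CONTROL, role=GroupRole.CONTROL),
            GroupSpec(name=GROUP_AGENT1, role=GroupRole.SINGLE_AGENT, arms=[arm1]),
            GroupSpec(name=GROUP_AGENT2, role=GroupRole.SINGLE_AGENT, arms=[arm2]),
            GroupSpec(
                name=GROUP_COMBO,
                role=GroupRole.COMBINATION,
                arms=[arm1, arm2],
                paired_singles=(GROUP_AGENT1, GROUP_AGENT2),
            ),
        ],
        evaluation_days=[evaluation_day],
        tgd_threshold_mm3=tgd_threshold_mm3,
    )


def _diameters_from_volume(v: float) -> tuple[float, float]:
    """Back-solve (a, b) from V = a²·b/2 with b = SHAPE_RATIO·a."""
    a = (2.0 * v / SHAPE_RATIO) ** (1.0 / 3.0)
    return a, SHAPE_RATIO * a


def _effect_curve(model: GrowthModel, effect: float, eval_day: int, t: np.ndarray):
    """Latent treated volume: control curve times effect^(t/eval_day).

    The multiplicative effect deepens smoothly from 1 at day 0 to *effect* at
    the evaluation day (a constant growth-rate reduction under continuous
    dosing), so treated/control central volume equals *effect* exactly on the
    evaluation day in the noiseless case.
    """
    return np.asarray(model.volume(t)) * effect ** (np.asarray(t, dtype=float) / eval_day)


def _latent_crossing(model: GrowthModel, effect: float, eval_day: int, threshold: float,
                     horizon: float = 365.0) -> Optional[float]:
    """First latent crossing of *threshold* for the effect-scaled curve."""
    if model.kind == "exponential":
        r_eff = model.rate + math.log(effect) / eval_day
        if r_eff <= 0:
            return None
        t = math.log(threshold / model.v0) / r_eff
        return max(0.0, t)
    # gompertz: bisection on the monotone latent curve
    lo, hi = 0.0, horizon
    if _effect_curve(model, effect, eval_day, np.array([hi]))[0] < threshold:
        return None
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if _effect_curve(model, effect, eval_day, np.array([mid]))[0] >= threshold:
            hi = mid
        else:
            lo = mid
    return hi


def simulate_animal(
    model: GrowthModel,
    effect: float,
    noise_sd: float,
    measurement_days: Sequence[int],
    sacrifice_threshold: float = SACRIFICE_THRESHOLD,
    seed: int = 0,
    animal_id: str = "a1",
    group: str = GROUP_CONTROL,
    evaluation_day: int = DEFAULT_EVALUATION_DAY,
    baseline_weight_g: float = 22.0,
) -> AnimalSeries:
    """Simulate one animal's measurement series.

    The latent volume follows the growth model scaled by *effect* (treated /
    control volume fraction at *evaluation_day*); observed volumes get
    multiplicative lognormal noise and are re-expressed as two caliper
    diameters with a fixed shape ratio. The animal is sacrificed on the first
    whole day its latent volume is at or beyond *sacrifice_threshold*, else
    censored at the last measurement day.
    """
    if not measurement_days:
        raise ValueError("measurement days must be nonempty")
    if sacrifice_threshold <= 0:
        raise ValueError("sacrifice threshold must be > 0")
    if not (0.0 < effect <= 1.0):
        raise ValueError("effect must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    cross = _latent_crossing(model, effect, evaluation_day, sacrifice_threshold)
    last = int(max(measurement_days))
    if cross is not None and cross <= last:
        death_day = max(int(math.ceil(cross)), int(min(measurement_days)))
        event = SurvivalEvent.DEATH
    else:
        death_day = last
        event = SurvivalEvent.CENSORED

    days = [d for d in measurement_days if d <= death_day]
    latent = _effect_curve(model, effect, evaluation_day, np.asarray(days, dtype=float))
    noise = rng.normal(0.0, noise_sd, size=len(days)) if noise_sd > 0 else np.zeros(len(days))
    observed = latent * np.exp(noise)
    tumors = []
    for d, v in zip(days, observed):
        a, b = _diameters_from_volume(float(v))
        tumors.append(TumorMeasurement(day=int(d), a=a, b=b))
    weights = [
        BodyWeight(day=int(d), grams=baseline_weight_g * float(np.exp(rng.normal(0.0, 0.01))))
        for d in days
    ]
    return AnimalSeries(
        animal_id=animal_id,
        group=group,
        tumor_measurements=tumors,
        body_weights=weights,
        survival=SurvivalRecord(last_day=death_day, event=event),
    )


def simulate_study(
    design: Optional[StudyDesign] = None,
    interaction: Optional[InteractionSpec] = None,
    n_per_group: int = 8,
    seed: Optional[int] = None,
    model: Optional[GrowthModel] = None,
    measurement_days: Optional[Sequence[int]] = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[list[AnimalSeries], SimulationTruth]:
    """Simulate a full four-group study and its ground truth.

    Per-animal randomness flows deterministically from a single seed through
    spawned substreams keyed by (group index, animal index).
    """
    design = design or default_design()
    interaction = interaction or InteractionSpec()
    if seed is not None:
        interaction = interaction.model_copy(update={"seed": int(seed)})
    model = model or GrowthModel()
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3 (group medians degenerate below that)")
    days = list(measurement_days or DEFAULT_MEASUREMENT_DAYS)
    eval_day = design.evaluation_days[0] if design.evaluation_days else DEFAULT_EVALUATION_DAY

    if len(design.group_names) != 4:
        raise ValueError("simulate_study expects a 4-group design (control, 2 singles, combo)")
    # map design groups onto the canonical roles in declaration order
    control = design.control_group.name
    singles = [g.name for g in design.groups if g.role is GroupRole.SINGLE_AGENT]
    combo = design.combination_groups[0].name
    effect_by_group = {
        control: 1.0,
        singles[0]: interaction.f1,
        singles[1]: interaction.f2,
        combo: interaction.f_combo,
    }

    ss = np.random.SeedSequence(interaction.seed)
    child_seeds = ss.spawn(4 * n_per_group)
    animals: list[AnimalSeries] = []
    latent_death: dict[str, float] = {}
    for gi, gname in enumerate([control, singles[0], singles[1], combo]):
        eff = effect_by_group[gname]
        cross = _latent_crossing(model, eff, eval_day, SACRIFICE_THRESHOLD)
        latent_death[gname] = float(cross) if cross is not None else float("inf")
        for ai in range(n_per_group):
            sub = child_seeds[gi * n_per_group + ai]
            animals.append(
                simulate_animal(
                    model,
                    eff,
                    interaction.noise_sd,
                    days,
                    seed=int(sub.generate_state(1)[0] % (2**31)),
                    animal_id=f"{gname}-{ai + 1:02d}",
                    group=gname,
                    evaluation_day=eval_day,
                )
            )

    e1 = 100.0 * (1.0 - interaction.f1)
    e2 = 100.0 * (1.0 - interaction.f2)
    e_obs = 100.0 * (1.0 - interaction.f_combo)
    h = fractional_product(e1, e2)
    truth = SimulationTruth(
        interaction=interaction,
        model=model,
        n_per_group=n_per_group,
        evaluation_day=eval_day,
        tolerance=tolerance,
        expected_tgi={control: 0.0, singles[0]: e1, singles[1]: e2, combo: e_obs},
        h_expected=h,
        true_verdict=classify(e_obs, h, e1, tolerance),
        latent_death_day=latent_death,
    )
    return animals, truth


def simulate_plate(
    true_inhibitions: Sequence[float],
    ac: float = 1.0,
    am: float = 0.1,
    noise_sd: float = 0.0,
    replicates: int = 4,
    seed: int = 0,
    plate_id: str = "plate-1",
) -> PlateAssay:
    """Simulate SRB-style absorbances from target inhibition percentages.

    At is drawn around Am + (Ac − Am)(1 − I/100) with Gaussian noise, so
    that with zero noise the inhibition formula round-trips exactly.
    """
    if not ac > am:
        raise ValueError("need control absorbance Ac > blank Am")
    rng = np.random.default_rng(seed)
    wells = []
    for ci, inh in enumerate(true_inhibitions):
        center = am + (ac - am) * (1.0 - inh / 100.0)
        for _ in range(replicates):
            at = center + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            wells.append(PlateWell(condition=f"cond-{ci + 1}", absorbance=at))
    return PlateAssay(
        plate_id=plate_id, wells=wells, control_absorbance=ac, medium_blank=am
    )
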