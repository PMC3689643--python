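"""Per-group efficacy and toxicity endpoints for in-vivo tumor studies.

Implements the classical subcutaneous-xenograft readouts:

* tumor volume from two caliper diameters, V = a²·b/2 (a <= b, mm -> mm³);
* tumor growth inhibition, TGI% = 100 − (W_T / W_C) × 100, on a central
  (median by default) tumor size of treated vs control;
* increase in life span, ILS% = (MST_T / MST_C) × 100 − 100, on Kaplan–Meier
  median survival times, so that longer survival is positive;
* tumor growth delay, TGD = time for the group's central volume curve to
  reach a threshold (default 1 cm³), log-linearly interpolated between
  bracketing measurement days, and its differences ΔTGD vs control or vs the
  cytostatic-alone group;
* body weight change, BWC% = (ABW_n / ABW_1) × 100 − 100, with the maximal
  decrease as the toxicity surrogate;
* percent proliferation inhibition from plate absorbances,
  100 − (At − Am)/(Ac − Am) × 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .study_model import AnimalSeries, PlateAssay, StudyDesign, SurvivalEvent

NOT_REACHED = "not reached"

CentralStat = Literal["median", "mean"]


class EndpointError(ValueError):
    """Raised when an endpoint is undefined for the given inputs."""


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention of printed report tables)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


# ---------------------------------------------------------------------------
# Scalar endpoint formulas
# ---------------------------------------------------------------------------


def tumor_volume(a: float, b: float) -> float:
    """Ellipsoid-approximation tumor volume a²·b/2 (a = shorter diameter, mm)."""
    if not (0 <= a <= b):
        raise EndpointError(f"require 0 <= a <= b, got a={a}, b={b}")
    return a * a * b / 2.0


def tgi(w_t: float, w_c: float) -> float:
    """Tumor growth inhibition percent; negative when treated exceeds control."""
    if w_c <= 0:
        raise EndpointError("control central tumor size must be > 0 for TGI")
    return 100.0 - (w_t / w_c) * 100.0


def ils(mst_t: float, mst_c: float) -> float:
    """Increase in life span percent; positive when treated outlive control."""
    if mst_c <= 0:
        raise EndpointError("control median survival must be > 0 for ILS")
    if not (math.isfinite(mst_t) and math.isfinite(mst_c)):
        raise EndpointError("median survival not reached; ILS undefined")
    return (mst_t / mst_c) * 100.0 - 100.0


def tgd(
    days: Sequence[float],
    volumes: Sequence[float],
    threshold: float = 1000.0,
) -> Optional[float]:
    """Day on which a central volume curve first reaches *threshold* (mm³).

    A crossing between measurement days is located by linear interpolation of
    log(volume) against day (tumor growth is near-exponential) and reported to
    one decimal. Returns None when the curve never reaches the threshold.
    """
    days = list(days)
    volumes = list(volumes)
    if len(days) < 2:
        raise EndpointError("TGD needs a curve with at least 2 days")
    if threshold <= 0:
        raise EndpointError("TGD threshold must be > 0")
    for i, v in enumerate(volumes):
        if v >= threshold:
            if i == 0:
                return round(float(days[0]), 1)
            v0, v1 = volumes[i - 1], volumes[i]
            d0, d1 = days[i - 1], days[i]
            if v0 <= 0:
                return round(float(d1), 1)
            t = d0 + (d1 - d0) * (math.log(threshold) - math.log(v0)) / (
                math.log(v1) - math.log(v0)
            )
            return round(float(t), 1)
    return None


def delta_tgd(tgd_treated: float, tgd_reference: float) -> float:
    """Difference in days between two tumor-growth-delay values."""
    return tgd_treated - tgd_reference


def bwc(
    days: Sequence[int],
    weights: Sequence[float],
    baseline_day: int,
) -> tuple[list[float], float]:
    """Per-day body-weight change percent vs the first treatment day.

    Returns (per-day BWC series aligned with *days*, maximal decrease percent).
    The maximal decrease is max(0, −min(BWC)) over days >= baseline_day.
    """
    days = list(days)
    weights = list(weights)
    if baseline_day not in days:
        raise EndpointError(f"no body weight recorded on baseline day {baseline_day}")
    abw1 = weights[days.index(baseline_day)]
    if abw1 <= 0:
        raise EndpointError("baseline body weight must be > 0")
    series = [(w / abw1) * 100.0 - 100.0 for w in weights]
    post = [s for d, s in zip(days, series) if d >= baseline_day]
    max_decrease = max(0.0, -min(post))
    return series, max_decrease


def proliferation_inhibition(at: float, ac: float, am: float) -> float:
    """Percent proliferation inhibition from treated/control/blank absorbances.

    Positive values mean inhibition; stimulation of growth gives negative
    values (no clipping).
    """
    if ac <= am:
        raise EndpointError("invalid plate: control absorbance Ac must exceed blank Am")
    return 100.0 - (at - am) / (ac - am) * 100.0


def plate_inhibition(plate: PlateAssay, condition: str) -> tuple[float, float]:
    """Mean and SD of percent inhibition over a condition's replicate wells."""
    reps = plate.replicates(condition)
    if not reps:
        raise EndpointError(f"no replicates for condition {condition!r}")
    vals = [
        proliferation_inhibition(at, plate.control_absorbance, plate.medium_blank)
        for at in reps
    ]
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


# ---------------------------------------------------------------------------
# Group-level aggregation
# ---------------------------------------------------------------------------


@dataclass
class GroupCurve:
    """Central tumor-volume curve of one group over the common day grid."""

    group: str
    days: list[int]
    central_volume: list[float]
    n_alive: list[int]


def _central(values: np.ndarray, stat: CentralStat) -> float:
    return float(np.median(values) if stat == "median" else np.mean(values))


def group_curve(
    animals: Sequence[AnimalSeries],
    group: str,
    stat: CentralStat = "median",
) -> GroupCurve:
    """Aggregate per-animal volumes into the group's central curve.

    Each day with at least one measured animal contributes a point; the
    central statistic runs over the animals measured that day.
    """
    members = [a for a in animals if a.group == group]
    if not members:
        raise EndpointError(f"no animals in group {group!r}")
    per_day: dict[int, list[float]] = {}
    for an in members:
        for m in an.tumor_measurements:
            per_day.setdefault(m.day, []).append(tumor_volume(m.a, m.b))
    days = sorted(per_day)
    return GroupCurve(
        group=group,
        days=days,
        central_volume=[_central(np.asarray(per_day[d]), stat) for d in days],
        n_alive=[len(per_day[d]) for d in days],
    )


def survival_arrays(
    animals: Sequence[AnimalSeries], group: str
) -> tuple[np.ndarray, np.ndarray]:
    """(durations, event flags) for a group, on the study-day scale."""
    members = [a for a in animals if a.group == group]
    if not members:
        raise EndpointError(f"no animals in group {group!r}")
    t = np.array([a.survival.last_day for a in members], dtype=float)
    e = np.array(
        [a.survival.event is SurvivalEvent.DEATH for a in members], dtype=bool
    )
    return t, e


def median_survival(durations: np.ndarray, events: np.ndarray) -> float:
    """Kaplan–Meier median survival time; the sample median when uncensored."""
    if len(durations) == 0:
        raise EndpointError("empty group has no median survival")
    if events.all():
        return float(np.median(durations))
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    return float(kmf.median_survival_time_)


# ---------------------------------------------------------------------------
# Endpoint table
# ---------------------------------------------------------------------------


@dataclass
class GroupEndpoints:
    group: str
    n: int
    tgi_percent: dict[int, float] = field(default_factory=dict)  # day -> TGI%
    ils_percent: Optional[float] = None
    median_survival: Optional[float] = None
    tgd_days: Optional[float] = None  # None = group absent; inf-like sentinel below
    tgd_reached: bool = True
    delta_tgd_control: Optional[float] = None
    delta_tgd_cytostatic: Optional[float] = None
    max_bw_decrease: Optional[float] = None


@dataclass
class EndpointTable:
    """Per-group endpoint values for one study."""

    groups: dict[str, GroupEndpoints]
    evaluation_days: list[int]
    central_stat: CentralStat

    def tgi_at(self, group: str, day: int) -> float:
        try:
            return self.groups[group].tgi_percent[day]
        except KeyError as exc:
            raise EndpointError(f"no TGI for group {group!r} on day {day}") from exc

    def to_tsv(self) -> str:
        header = [
            "group",
            "n",
            *(f"TGI%_d{d}" for d in self.evaluation_days),
            "MST_days",
            "ILS%",
            "TGD_days",
            "dTGD_control",
            "dTGD_cytostatic",
            "max_BW_decrease%",
        ]
        lines = ["\t".join(header)]

        def cell(x, nd=1):
            if x is None:
                return "NA"
            return f"{x:.{nd}f}"

        for name, ge in self.groups.items():
            row = [name, str(ge.n)]
            for d in self.evaluation_days:
                row.append(cell(ge.tgi_percent.get(d)))
            row += [
                cell(ge.median_survival),
                cell(ge.ils_percent),
                cell(ge.tgd_days) if ge.tgd_reached else NOT_REACHED,
                cell(ge.delta_tgd_control),
                cell(ge.delta_tgd_cytostatic),
                cell(ge.max_bw_decrease),
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def build_endpoint_table(
    animals: Sequence[AnimalSeries],
    design: StudyDesign,
    stat: CentralStat = "median",
    baseline_day: Optional[int] = None,
) -> EndpointTable:
    """Compute every group's endpoints against the design's control group.

    TGI is evaluated on each of the design's evaluation days (falling back to
    the last common measurement day when none are declared). TGD runs on the
    group central curve; ΔTGD is taken vs control and — for combination
    groups — vs their cytostatic (first paired single-agent) group. BWC uses
    the earliest administration day in the design as baseline unless
    *baseline_day* is given.
    """
    control = design.control_group.name
    curves = {g.name: group_curve(animals, g.name, stat) for g in design.groups}
    ctrl_curve = curves[control]
    ctrl_by_day = dict(zip(ctrl_curve.days, ctrl_curve.central_volume))

    eval_days = list(design.evaluation_days)
    if not eval_days:
        common = set(ctrl_curve.days)
        for c in curves.values():
            common &= set(c.days)
        if common:
            eval_days = [max(common)]

    if baseline_day is None:
        admin_days = [d for g in design.groups for a in g.arms for d in a.days]
        baseline_day = min(admin_days) if admin_days else 0

    surv = {g.name: survival_arrays(animals, g.name) for g in design.groups}
    mst = {name: median_survival(t, e) for name, (t, e) in surv.items()}
    mst_c = mst[control]

    table: dict[str, GroupEndpoints] = {}
    for g in design.groups:
        curve = curves[g.name]
        ge = GroupEndpoints(group=g.name, n=len(surv[g.name][0]))
        for d in eval_days:
            by_day = dict(zip(curve.days, curve.central_volume))
            if d in by_day and d in ctrl_by_day and ctrl_by_day[d] > 0:
                ge.tgi_percent[d] = tgi(by_day[d], ctrl_by_day[d])
        ge.median_survival = mst[g.name]
        if math.isfinite(mst_c) and mst_c > 0 and math.isfinite(mst[g.name]):
            ge.ils_percent = ils(mst[g.name], mst_c)
        if len(curve.days) >= 2:
            t_cross = tgd(curve.days, curve.central_volume, design.tgd_threshold_mm3)
            ge.tgd_days = t_cross
            ge.tgd_reached = t_cross is not None

        # body weight: group mean per day, then BWC vs baseline
        per_day: dict[int, list[float]] = {}
        for an in animals:
            if an.group != g.name:
                continue
            for w in an.body_weights:
                per_day.setdefault(w.day, []).append(w.grams)
        if per_day and baseline_day in per_day:
            days_sorted = sorted(per_day)
            means = [float(np.mean(per_day[d])) for d in days_sorted]
            _, ge.max_bw_decrease = bwc(days_sorted, means, baseline_day)
        table[g.name] = ge

    # ΔTGD against control and against the paired cytostatic
    ctrl_tgd = table[control].tgd_days
    for g in design.groups:
        ge = table[g.name]
        if ge.tgd_days is not None and ctrl_tgd is not None and g.name != control:
            ge.delta_tgd_control = delta_tgd(ge.tgd_days, ctrl_tgd)
        if g.paired_singles and ge.tgd_days is not None:
            cyt = table.get(g.paired_singles[0])
            if cyt is not None and cyt.tgd_days is not None:
                ge.delta_tgd_cytostatic = delta_tgd(ge.tgd_days, cyt.tgd_days)
    return EndpointTable(groups=table, evaluation_days=eval_days, central_stat=stat)
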