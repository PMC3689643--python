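"""Domain types and I/O for preclinical tumor-efficacy studies.

The data model mirrors how subcutaneous-tumor mouse studies are recorded in
practice: each animal carries a longitudinal series of caliper measurements
(two perpendicular diameters), body weights, and a survival record; the study
design declares treatment groups, their dosing arms, and — for combination
groups — which two single-agent groups they pair.

Measurements travel as a tidy CSV with the fixed header
``animal_id,group,day,diam_short_mm,diam_long_mm,body_weight_g,status``;
designs travel as YAML.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "animal_id",
    "group",
    "day",
    "diam_short_mm",
    "diam_long_mm",
    "body_weight_g",
    "status",
]


class StudyValidationError(ValueError):
    """Raised when study inputs violate a declared invariant."""


class Route(str, Enum):
    SC = "s.c."
    IV = "i.v."
    IP = "i.p."
    PO = "p.o."


class GroupRole(str, Enum):
    CONTROL = "control"
    SINGLE_AGENT = "single_agent"
    COMBINATION = "combination"


class SurvivalEvent(str, Enum):
    #: death, or sacrifice of an obviously sick animal — both count as events
    DEATH = "death_or_sacrifice_sick"
    CENSORED = "censored_end_of_study"


class Arm(BaseModel):
    """One agent's dosing schedule within a group."""

    agent: str
    dose: str
    route: Route
    days: list[int]

    @field_validator("days")
    @classmethod
    def _days_valid(cls, v: list[int]) -> list[int]:
        if any(d < 0 for d in v):
            raise ValueError("administration days must be >= 0 (day 0 = randomization)")
        if sorted(v) != v:
            raise ValueError("administration days must be sorted")
        return v


class GroupSpec(BaseModel):
    name: str
    role: GroupRole
    arms: list[Arm] = Field(default_factory=list)
    paired_singles: Optional[tuple[str, str]] = None

    @model_validator(mode="after")
    def _check_role(self) -> "GroupSpec":
        if self.role is GroupRole.CONTROL and self.arms:
            raise ValueError(f"control group {self.name!r} must have zero arms")
        if self.role is GroupRole.COMBINATION and self.paired_singles is None:
            raise ValueError(
                f"combination group {self.name!r} must name its two paired single-agent groups"
            )
        if self.role is not GroupRole.COMBINATION and self.paired_singles is not None:
            raise ValueError(f"group {self.name!r}: paired_singles only valid for combinations")
        return self


class StudyDesign(BaseModel):
    study_id: str
    groups: list[GroupSpec]
    evaluation_days: list[int] = Field(default_factory=list)
    tgd_threshold_mm3: float = 1000.0
    day0_definition: str = "randomization day"

    @field_validator("tgd_threshold_mm3")
    @classmethod
    def _threshold_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("tgd_threshold_mm3 must be > 0")
        return v

    @model_validator(mode="after")
    def _check_groups(self) -> "StudyDesign":
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        singles = {g.name for g in self.groups if g.role is GroupRole.SINGLE_AGENT}
        for g in self.groups:
            if g.role is GroupRole.COMBINATION:
                for ref in g.paired_singles:  # type: ignore[union-attr]
                    if ref not in singles:
                        raise ValueError(
                            f"combination group {g.name!r} references missing "
                            f"single-agent group {ref!r}"
                        )
        return self

    # -- convenience lookups -------------------------------------------------
    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def control_group(self) -> GroupSpec:
        controls = [g for g in self.groups if g.role is GroupRole.CONTROL]
        if not controls:
            raise StudyValidationError("no control group in design")
        return controls[0]

    @property
    def combination_groups(self) -> list[GroupSpec]:
        return [g for g in self.groups if g.role is GroupRole.COMBINATION]


class TumorMeasurement(BaseModel):
    day: int
    a: float  # shorter diameter, mm
    b: float  # longer diameter, mm

    @model_validator(mode="after")
    def _check(self) -> "TumorMeasurement":
        if self.a < 0 or self.b < 0:
            raise ValueError("diameters must be >= 0")
        if self.a > self.b:
            raise ValueError("shorter diameter a must not exceed b (normalize upstream)")
        return self


class BodyWeight(BaseModel):
    day: int
    grams: float

    @field_validator("grams")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("body weight must be > 0")
        return v


class SurvivalRecord(BaseModel):
    last_day: int
    event: SurvivalEvent


class AnimalSeries(BaseModel):
    """One animal's longitudinal record."""

    animal_id: str
    group: str
    tumor_measurements: list[TumorMeasurement] = Field(default_factory=list)
    body_weights: list[BodyWeight] = Field(default_factory=list)
    survival: SurvivalRecord

    @model_validator(mode="after")
    def _check(self) -> "AnimalSeries":
        for label, days in (
            ("tumor", [m.day for m in self.tumor_measurements]),
            ("body-weight", [w.day for w in self.body_weights]),
        ):
            if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
                raise ValueError(
                    f"animal {self.animal_id!r}: duplicate measurement day "
                    f"or unsorted {label} series"
                )
            if days and days[-1] > self.survival.last_day:
                raise ValueError(
                    f"animal {self.animal_id!r}: {label} record after last survival day"
                )
        return self


class PlateWell(BaseModel):
    condition: str
    absorbance: float


class PlateAssay(BaseModel):
    """One colorimetric proliferation plate (e.g. SRB assay).

    ``control_absorbance`` (Ac) and ``medium_blank`` (Am) are the per-plate
    reference absorbances; wells carry treated absorbances At per condition.
    """

    plate_id: str
    wells: list[PlateWell]
    control_absorbance: float  # Ac
    medium_blank: float  # Am

    @model_validator(mode="after")
    def _check(self) -> "PlateAssay":
        if not self.medium_blank < self.control_absorbance:
            raise ValueError(
                f"plate {self.plate_id!r}: blank absorbance Am must lie below control Ac"
            )
        if not self.wells:
            raise ValueError(f"plate {self.plate_id!r}: needs at least one well")
        return self

    def replicates(self, condition: str) -> list[float]:
        return [w.absorbance for w in self.wells if w.condition == condition]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_measurements(
    path: Union[str, Path],
    design: Optional[StudyDesign] = None,
) -> list[AnimalSeries]:
    """Read a tidy measurements CSV into per-animal series.

    Rows whose caliper diameters violate the a <= b convention are swapped
    with a logged warning (caliper entry order is arbitrary). Rows with a
    missing diameter contribute no tumor point but keep their body weight.
    Duplicate (animal, day) tumor rows and group names absent from *design*
    are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str, "status": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise StudyValidationError(f"measurements file missing columns: {missing}")

    if design is not None:
        known = set(design.group_names)
        unknown = sorted(set(df["group"]) - known)
        if unknown:
            raise StudyValidationError(f"unknown group name(s) in measurements: {unknown}")

    animals: list[AnimalSeries] = []
    for (animal_id, group), sub in df.groupby(["animal_id", "group"], sort=False):
        sub = sub.sort_values("day", kind="stable")
        tumor: list[TumorMeasurement] = []
        weights: list[BodyWeight] = []
        last_day = int(sub["day"].max())
        event = SurvivalEvent.CENSORED
        seen_tumor_days: set[int] = set()
        for row in sub.itertuples(index=False):
            day = int(row.day)
            a, b = row.diam_short_mm, row.diam_long_mm
            if pd.notna(a) and pd.notna(b):
                if day in seen_tumor_days:
                    raise StudyValidationError(
                        f"duplicate measurement day {day} for animal {animal_id!r}"
                    )
                seen_tumor_days.add(day)
                a, b = float(a), float(b)
                if a > b:
                    logger.warning(
                        "animal %s day %d: diameters swapped to satisfy a <= b", animal_id, day
                    )
                    a, b = b, a
                tumor.append(TumorMeasurement(day=day, a=a, b=b))
            if pd.notna(row.body_weight_g):
                weights.append(BodyWeight(day=day, grams=float(row.body_weight_g)))
            status = row.status if isinstance(row.status, str) else ""
            if status == "dead":
                event = SurvivalEvent.DEATH
                last_day = day
            elif status == "censored":
                event = SurvivalEvent.CENSORED
                last_day = day
        animals.append(
            AnimalSeries(
                animal_id=str(animal_id),
                group=str(group),
                tumor_measurements=tumor,
                body_weights=weights,
                survival=SurvivalRecord(last_day=last_day, event=event),
            )
        )
    return animals


def _fmt(x: float) -> str:
    return f"{x:g}"


def write_measurements(animals: Sequence[AnimalSeries], path: Union[str, Path]) -> None:
    """Write per-animal series back to the tidy CSV dialect (canonical formatting)."""
    rows: list[dict] = []
    for an in animals:
        by_day: dict[int, dict] = {}
        for m in an.tumor_measurements:
            by_day.setdefault(m.day, {})["tumor"] = (m.a, m.b)
        for w in an.body_weights:
            by_day.setdefault(w.day, {})["weight"] = w.grams
        for day in sorted(by_day):
            rec = by_day[day]
            status = ""
            if day == an.survival.last_day:
                status = "dead" if an.survival.event is SurvivalEvent.DEATH else "censored"
            rows.append(
                {
                    "animal_id": an.animal_id,
                    "group": an.group,
                    "day": day,
                    "diam_short_mm": _fmt(rec["tumor"][0]) if "tumor" in rec else "",
                    "diam_long_mm": _fmt(rec["tumor"][1]) if "tumor" in rec else "",
                    "body_weight_g": _fmt(rec["weight"]) if "weight" in rec else "",
                    "status": status,
                }
            )
    out = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    out.to_csv(path, index=False)


def read_design(path: Union[str, Path]) -> StudyDesign:
    """Read a YAML study design and validate it (groups, arms, pairing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        groups = []
        for g in raw.get("groups", []):
            arms = [
                Arm(
                    agent=a["agent"],
                    dose=str(a.get("dose", "")),
                    route=Route(a["route"]),
                    days=[int(d) for d in a.get("days", [])],
                )
                for a in g.get("arms", [])
            ]
            paired = g.get("paired_singles")
            groups.append(
                GroupSpec(
                    name=g["name"],
                    role=GroupRole(g["role"]),
                    arms=arms,
                    paired_singles=tuple(paired) if paired else None,
                )
            )
        return StudyDesign(
            study_id=str(raw.get("study_id", path.stem)),
            groups=groups,
            evaluation_days=[int(d) for d in raw.get("evaluation_days", [])],
            tgd_threshold_mm3=float(raw.get("tgd_threshold_mm3", 1000.0)),
            day0_definition=str(raw.get("day0_definition", "randomization day")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise StudyValidationError(f"invalid study design {path}: {exc}") from exc


def write_design(design: StudyDesign, path: Union[str, Path]) -> None:
    raw = {
        "study_id": design.study_id,
        "tgd_threshold_mm3": design.tgd_threshold_mm3,
        "evaluation_days": design.evaluation_days,
        "day0_definition": design.day0_definition,
        "groups": [
            {
                "name": g.name,
                "role": g.role.value,
                **(
                    {"paired_singles": list(g.paired_singles)}
                    if g.paired_singles
                    else {}
                ),
                **(
                    {
                        "arms": [
                            {
                                "agent": a.agent,
                                "dose": a.dose,
                                "route": a.route.value,
                                "days": a.days,
                            }
                            for a in g.arms
                        ]
                    }
                    if g.arms
                    else {}
                ),
            }
            for g in design.groups
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
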