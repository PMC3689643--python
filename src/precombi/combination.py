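"""Fractional-product (Bliss-independence-style) combination scoring.

For two inhibitory agents with single-agent effects E1 and E2 (percent), the
multiplicative null model says the unaffected fractions multiply, giving the
hypothetical combined effect

    %H = 100 − (100 − E1)(100 − E2) / 100.

Comparing the observed combination effect E_obs against %H and against the
cytostatic's own effect yields a four-way interaction call:

1. antagonism   — E_obs below the cytostatic alone (checked first);
2. additive     — |E_obs − %H| within a tolerance band (default 3 points);
3. synergism    — E_obs above %H beyond the band;
4. subadditive  — E_obs below %H but not below the cytostatic alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .endpoints import EndpointTable, round_half_away
from .study_model import StudyDesign

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 3.0  # percentage points for "comparable" (additive) calls


class Verdict(str, Enum):
    SYNERGISM = "synergism"
    ADDITIVE = "additive"
    SUBADDITIVE = "subadditive"
    ANTAGONISM = "antagonism"


def fractional_product(e1: float, e2: float) -> float:
    """Hypothetical combined effect %H = 100 − (100−E1)(100−E2)/100.

    Symmetric in its arguments; effects above 100% are rejected (an agent
    cannot leave less than nothing of the measured quantity), negative
    effects (treated worse than control) are allowed.
    """
    if e1 > 100 or e2 > 100:
        raise ValueError("single-agent effects must be <= 100%")
    return 100.0 - (100.0 - e1) * (100.0 - e2) / 100.0


def classify(
    e_observed: float,
    h_expected: float,
    e_cytostatic: float,
    tol: float = DEFAULT_TOLERANCE,
) -> Verdict:
    """Four-way interaction call; exhaustive and deterministic.

    The antagonism rule (observed below cytostatic alone) takes precedence
    over the additive tolerance band.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if e_observed < e_cytostatic:
        return Verdict.ANTAGONISM
    if abs(e_observed - h_expected) <= tol:
        return Verdict.ADDITIVE
    if e_observed > h_expected:
        return Verdict.SYNERGISM
    return Verdict.SUBADDITIVE


@dataclass
class CombinationVerdict:
    """Scored interaction for one combination group on one endpoint."""

    combination: str
    endpoint: str  # e.g. "TGI_d21", "ILS", "proliferation_inhibition"
    e_cytostatic: float
    e_modulator: float
    e_observed: float
    h_expected: float
    verdict: Verdict
    tolerance_used: float = DEFAULT_TOLERANCE

    @property
    def h_rounded(self) -> int:
        return round_half_away(self.h_expected)

    def row(self) -> list[str]:
        return [
            self.combination,
            self.endpoint,
            f"{self.e_cytostatic:.1f}",
            f"{self.e_modulator:.1f}",
            f"{self.e_observed:.1f}",
            f"{self.h_expected:.2f}",
            str(self.h_rounded),
            self.verdict.value,
        ]


REPORT_HEADER = [
    "combination",
    "endpoint",
    "E_cytostatic",
    "E_modulator",
    "E_observed",
    "H_expected",
    "H_rounded",
    "verdict",
]


def score_combination(
    endpoint: str,
    e_cytostatic: float,
    e_modulator: float,
    e_observed: float,
    combination: str = "combination",
    tol: float = DEFAULT_TOLERANCE,
) -> CombinationVerdict:
    """Score one (cytostatic, modulator, combination) effect triple."""
    h = fractional_product(e_cytostatic, e_modulator)
    return CombinationVerdict(
        combination=combination,
        endpoint=endpoint,
        e_cytostatic=e_cytostatic,
        e_modulator=e_modulator,
        e_observed=e_observed,
        h_expected=h,
        verdict=classify(e_observed, h, e_cytostatic, tol),
        tolerance_used=tol,
    )


def combination_report(
    endpoints: EndpointTable,
    design: StudyDesign,
    tol: float = DEFAULT_TOLERANCE,
) -> list[CombinationVerdict]:
    """Score every (combination group × endpoint) pair in a study.

    Uses raw (unrounded) single-agent effects. Endpoints a paired group lacks
    (e.g. ILS when median survival is not reached) are skipped with a logged
    reason rather than failing the whole report.
    """
    verdicts: list[CombinationVerdict] = []
    for combo in design.combination_groups:
        cyt_name, mod_name = combo.paired_singles  # type: ignore[misc]
        trio = [endpoints.groups.get(n) for n in (cyt_name, mod_name, combo.name)]
        if any(g is None for g in trio):
            logger.warning("combination %r: missing group endpoints; skipped", combo.name)
            continue
        cyt, mod, obs = trio  # type: ignore[misc]
        for day in endpoints.evaluation_days:
            vals = (cyt.tgi_percent.get(day), mod.tgi_percent.get(day), obs.tgi_percent.get(day))
            if any(v is None for v in vals):
                logger.warning(
                    "combination %r: TGI on day %d unavailable for all three groups; skipped",
                    combo.name,
                    day,
                )
                continue
            verdicts.append(
                score_combination(f"TGI_d{day}", *vals, combination=combo.name, tol=tol)
            )
        ils_vals = (cyt.ils_percent, mod.ils_percent, obs.ils_percent)
        if any(v is None for v in ils_vals):
            logger.warning("combination %r: ILS unavailable; skipped", combo.name)
        else:
            verdicts.append(
                score_combination("ILS", *ils_vals, combination=combo.name, tol=tol)
            )
    return verdicts


def report_tsv(verdicts: Sequence[CombinationVerdict]) -> str:
    lines = ["\t".join(REPORT_HEADER)]
    lines += ["\t".join(v.row()) for v in verdicts]
    return "\n".join(lines) + "\n"
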