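"""End-to-end study analysis and plain-text report rendering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .combination import (
    DEFAULT_TOLERANCE,
    CombinationVerdict,
    combination_report,
    report_tsv,
)
from .endpoints import CentralStat, EndpointTable, build_endpoint_table, survival_arrays
from .inference import TestResult, gehan_wilcoxon_peto
from .study_model import AnimalSeries, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class StudyReport:
    endpoints: EndpointTable
    combinations: list[CombinationVerdict]
    survival_tests: dict[str, TestResult]  # treated group -> test vs control

    def survival_tsv(self) -> str:
        lines = ["\t".join(["comparison", "test", "statistic", "p_value", "method"])]
        for group, res in self.survival_tests.items():
            lines.append(
                "\t".join(
                    [
                        f"{group} vs control",
                        res.test_name,
                        f"{res.statistic:.4f}",
                        f"{res.p_value:.4g}",
                        res.method,
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def analyze_study(
    animals: Sequence[AnimalSeries],
    design: StudyDesign,
    tol: float = DEFAULT_TOLERANCE,
    stat: CentralStat = "median",
) -> StudyReport:
    """Run the full endpoint + combination + survival analysis of a study."""
    endpoints = build_endpoint_table(animals, design, stat=stat)
    combos = combination_report(endpoints, design, tol=tol)
    control = design.control_group.name
    tc, ec = survival_arrays(animals, control)
    surv: dict[str, TestResult] = {}
    for g in design.groups:
        if g.name == control:
            continue
        tg, eg = survival_arrays(animals, g.name)
        if not (ec.any() or eg.any()):
            logger.warning("no events for %s vs control; survival test skipped", g.name)
            continue
        surv[g.name] = gehan_wilcoxon_peto(tg, eg, tc, ec)
    return StudyReport(endpoints=endpoints, combinations=combos, survival_tests=surv)


def write_report(report: StudyReport, out_dir: Union[str, Path]) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "endpoints": out / "endpoints.tsv",
        "combinations": out / "combinations.tsv",
        "survival_tests": out / "survival_tests.tsv",
    }
    paths["endpoints"].write_text(report.endpoints.to_tsv())
    paths["combinations"].write_text(report_tsv(report.combinations))
    paths["survival_tests"].write_text(report.survival_tsv())
    return paths
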