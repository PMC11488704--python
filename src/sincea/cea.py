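"""Incremental cost-effectiveness analysis and subgroup evaluation.

Each comparator strategy is compared with the reference arm by its
incremental cost divided by incremental QALYs (the ICER).  Strategies that
are cheaper and more effective than the reference are *dominant*; costlier
and less effective ones are *dominated*; near-zero incremental QALYs make
the ratio indeterminate.  Verdicts classify defined ICERs against the
willingness-to-pay bounds (<= convention: an ICER exactly at a bound is
cost-effective at that bound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import ArmResult, accumulate
from .markov_engine import ModelClock, build_trace
from .survival_models import ArmSurvival, ParametricFit
from .synthetic_data import ArmDefinition, ParameterWorkbook, SubgroupHR

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSurvival",
    "CEAResult",
    "evaluate_arm",
    "evaluate_workbook",
    "compute_icer",
    "run_cea",
    "run_subgroups",
    "cea_table",
]

_EPS_QALY = 1e-12


@dataclass(frozen=True)
class ReferenceSurvival:
    """Selected parametric fits for the reference arm's two endpoints."""

    pfs: ParametricFit
    os: ParametricFit

    def arm_survival(self, hr_pfs: float = 1.0, hr_os: float = 1.0) -> ArmSurvival:
        return ArmSurvival(pfs=self.pfs.survival, os=self.os.survival,
                           hr_pfs=hr_pfs, hr_os=hr_os)


@dataclass(frozen=True)
class CEAResult:
    """One comparison row: comparator vs reference."""

    strategy: str
    inc_cost: float
    inc_ly: float
    inc_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    label: str  # 'icer' | 'dominant' | 'dominated' | 'indeterminate'
    verdict: str


def evaluate_arm(
    arm_def: ArmDefinition,
    ref: ReferenceSurvival,
    wb: ParameterWorkbook,
    hr_pfs: float | None = None,
    hr_os: float | None = None,
) -> ArmResult:
    """Trace and accumulate one strategy; HR overrides support subgroups."""
    clock = ModelClock(cycle_days=wb.cycle_days, horizon_years=wb.horizon_years)
    surv = ref.arm_survival(
        hr_pfs if hr_pfs is not None else arm_def.hr_pfs,
        hr_os if hr_os is not None else arm_def.hr_os,
    )
    trace = build_trace(surv, clock)
    return accumulate(
        trace, wb.econ, arm_def.schedule, arm_def.ae_profile, clock,
        wb.anthropometry, arm_def.u_sd,
    )


def evaluate_workbook(wb: ParameterWorkbook, ref: ReferenceSurvival) -> dict[str, ArmResult]:
    """Per-arm totals for every strategy in the workbook."""
    return {a.name: evaluate_arm(a, ref, wb) for a in wb.arms}


def _verdict(label: str, icer: float | None, wtp_low: float, wtp_high: float) -> str:
    if label == "dominant":
        return "cost-effective at lower bound"
    if label in ("dominated", "indeterminate"):
        return "not cost-effective" if label == "dominated" else "indeterminate"
    assert icer is not None
    if icer <= wtp_low:
        return "cost-effective at lower bound"
    if icer <= wtp_high:
        return "cost-effective at upper bound only"
    return "not cost-effective"


def compute_icer(
    reference: ArmResult,
    comparator: ArmResult,
    wtp_low: float,
    wtp_high: float,
    strategy: str = "",
) -> CEAResult:
    """Incremental comparison of a comparator arm against the reference.

    Incremental fields are comparator minus reference; the ICER is
    inc_cost / inc_QALY when incremental QALYs are meaningfully positive,
    otherwise a dominance label replaces it.
    """
    inc_cost = comparator.cost - reference.cost
    inc_ly = comparator.ly - reference.ly
    inc_qaly = comparator.qaly - reference.qaly

    icer_qaly: float | None = None
    icer_ly: float | None = None
    if abs(inc_qaly) <= _EPS_QALY:
        label = "indeterminate" if abs(inc_cost) <= 1e-9 else (
            "dominant" if inc_cost < 0 else "dominated"
        )
    elif inc_qaly > 0 and inc_cost <= 0:
        label = "dominant"
    elif inc_qaly < 0 and inc_cost >= 0:
        label = "dominated"
    else:
        label = "icer"
        icer_qaly = inc_cost / inc_qaly
        if abs(inc_ly) > _EPS_QALY:
            icer_ly = inc_cost / inc_ly
    return CEAResult(
        strategy=strategy,
        inc_cost=inc_cost,
        inc_ly=inc_ly,
        inc_qaly=inc_qaly,
        icer_per_qaly=icer_qaly,
        icer_per_ly=icer_ly,
        label=label,
        verdict=_verdict(label, icer_qaly, wtp_low, wtp_high),
    )


def run_cea(wb: ParameterWorkbook, ref: ReferenceSurvival) -> tuple[dict[str, ArmResult], list[CEAResult]]:
    """Base-case analysis: per-arm totals plus each-vs-reference rows."""
    results = evaluate_workbook(wb, ref)
    ref_res = results[wb.reference.name]
    rows = [
        compute_icer(ref_res, results[a.name], wb.wtp_low, wb.wtp_high, strategy=a.name)
        for a in wb.arms[1:]
    ]
    return results, rows


def run_subgroups(wb: ParameterWorkbook, ref: ReferenceSurvival) -> pd.DataFrame:
    """Recompute each-vs-reference ICERs with subgroup hazard ratios.

    The reference arm is unchanged; a comparator arm missing a subgroup
    PFS HR is skipped with a warning.  A subgroup without an OS entry uses
    the arm's overall OS HR.
    """
    ref_res = evaluate_arm(wb.reference, ref, wb)
    rows = []
    for g in wb.subgroups:
        for arm_def in wb.arms[1:]:
            if arm_def.name not in g.pfs:
                logger.warning("subgroup %r: no PFS HR for arm %r, skipped", g.label, arm_def.name)
                continue
            hr_pfs = g.pfs[arm_def.name][0]
            hr_os = g.os[arm_def.name][0] if arm_def.name in g.os else arm_def.hr_os
            res = evaluate_arm(arm_def, ref, wb, hr_pfs=hr_pfs, hr_os=hr_os)
            row = compute_icer(ref_res, res, wb.wtp_low, wb.wtp_high, strategy=arm_def.name)
            rows.append(
                {
                    "subgroup": g.label,
                    "strategy": arm_def.name,
                    "hr_pfs": hr_pfs,
                    "hr_os": hr_os,
                    "inc_cost": row.inc_cost,
                    "inc_qaly": row.inc_qaly,
                    "icer_per_qaly": row.icer_per_qaly,
                    "label": row.label,
                    "verdict": row.verdict,
                }
            )
    return pd.DataFrame(rows)


def cea_table(results: dict[str, ArmResult], rows: list[CEAResult], reference_name: str) -> pd.DataFrame:
    """Base-case table (one column block per strategy, reference first)."""
    recs = []
    for name, r in results.items():
        row = next((x for x in rows if x.strategy == name), None)
        recs.append(
            {
                "strategy": name,
                "cost": r.cost,
                "ly": r.ly,
                "qaly": r.qaly,
                "inc_cost": row.inc_cost if row else np.nan,
                "inc_ly": row.inc_ly if row else np.nan,
                "inc_qaly": row.inc_qaly if row else np.nan,
                "icer_per_qaly": row.icer_per_qaly if row and row.icer_per_qaly is not None else np.nan,
                "icer_per_ly": row.icer_per_ly if row and row.icer_per_ly is not None else np.nan,
                "label": row.label if row else ("reference" if name == reference_name else ""),
                "verdict": row.verdict if row else "",
            }
        )
    return pd.DataFrame(recs)
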