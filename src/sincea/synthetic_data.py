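"""Synthetic trial data and parameter workbook generation.

The downstream pipeline expects two kinds of input that are normally
extracted from a publication: digitized Kaplan-Meier coordinates with a
numbers-at-risk table for the reference (chemotherapy) arm, and a parameter
workbook holding hazard ratios, drug schedules, adverse-event profiles,
utilities, lump costs and decision settings.  This module generates both
from a transparent data-generating process so every stage is testable
end to end.

The simulator emulates a second-line NSCLC trial of the ORIENT-31 type:
log-logistic PFS and OS in the chemotherapy arm (median OS about 20
months), proportional-hazards comparator arms (survival = reference
survival raised to the hazard ratio), uniform accrual with a fixed
follow-up cutoff producing administrative right-censoring, and comonotone
PFS/OS coupling (a shared patient-level uniform, with OS floored at PFS so
progression never postdates death).

The default workbook mirrors the structural layout of a published
cost-effectiveness parameter table: three strategies (chemotherapy,
sintilimab + chemotherapy, sintilimab + IBI305 + chemotherapy), per-agent
dose rules and 2022-USD unit prices, grade >=3 AE rows, arm-specific
stable-disease utilities, the Chinese progressed-disease utility 0.70300,
5% annual discounting, a 21-day cycle over 10 years, and willingness-to-pay
bounds of $15,289.34 and $38,223.34 per QALY (1.2x and 3.0x China's 2022
per-capita GDP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter

from .economics import AdverseEvent, DrugScheduleRow, EconParams, PatientAnthropometry
from .km_reconstruction import DigitizedCurve

__all__ = [
    "TrialSpec",
    "ArmDefinition",
    "SubgroupHR",
    "ParameterWorkbook",
    "simulate_trial",
    "digitize_km",
    "default_trial_spec",
    "default_workbook",
    "write_workbook",
    "read_workbook",
]

REFERENCE_ARM = "chemotherapy"
DOUBLET_ARM = "sintilimab+chemotherapy"
TRIPLET_ARM = "sintilimab+IBI305+chemotherapy"


@dataclass(frozen=True)
class TrialSpec:
    """Ground truth of the synthetic trial.

    ``theta``/``kappa`` parameterize the reference-arm log-logistic
    survival S(t) = 1/(1 + e^theta t^kappa) (t in months; median at
    exp(-theta/kappa)); ``arms`` maps comparator names to (hr_pfs, hr_os).
    Censoring is administrative: uniform accrual over ``accrual_months``
    with data cutoff at ``accrual_months + followup_months``.
    """

    n_per_arm: int = 150
    theta_pfs: float = -1.896
    kappa_pfs: float = 1.3
    theta_os: float = -4.793
    kappa_os: float = 1.6
    arms: dict = field(
        default_factory=lambda: {DOUBLET_ARM: (0.72, 0.79), TRIPLET_ARM: (0.51, 0.82)}
    )
    accrual_months: float = 12.0
    followup_months: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.kappa_pfs <= 0 or self.kappa_os <= 0:
            raise ValueError("kappa parameters must be positive")
        for name, (hp, ho) in self.arms.items():
            if hp <= 0 or ho <= 0:
                raise ValueError(f"arm {name!r}: hazard ratios must be positive")
        if self.accrual_months < 0 or self.followup_months <= 0:
            raise ValueError("accrual must be nonnegative and follow-up positive")


def _loglogistic_inverse(theta: float, kappa: float, s: np.ndarray) -> np.ndarray:
    """Time at which S(t) = s for the log-logistic: ((1-s)/s)^(1/kappa) e^(-theta/kappa)."""
    s = np.asarray(s, dtype=float)
    return ((1.0 - s) / s) ** (1.0 / kappa) * math.exp(-theta / kappa)


def simulate_trial(spec: TrialSpec) -> dict[str, dict[str, pd.DataFrame]]:
    """Draw per-arm pseudo-IPD for PFS and OS.

    Returns ``{arm: {"pfs": df, "os": df}}`` with columns ``time_months``
    and ``event``; the reference arm is included under
    :data:`REFERENCE_ARM`.  A single uniform per patient drives both
    endpoints (comonotone coupling) and OS is floored at PFS.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    arm_hrs = {REFERENCE_ARM: (1.0, 1.0), **spec.arms}
    for arm, (hr_pfs, hr_os) in arm_hrs.items():
        u = rng.uniform(size=spec.n_per_arm)
        # comparator survival S_ref^hr = u  <=>  S_ref = u^(1/hr)
        t_pfs = _loglogistic_inverse(spec.theta_pfs, spec.kappa_pfs, u ** (1.0 / hr_pfs))
        t_os = _loglogistic_inverse(spec.theta_os, spec.kappa_os, u ** (1.0 / hr_os))
        t_os = np.maximum(t_os, t_pfs)
        entry = rng.uniform(0.0, spec.accrual_months, size=spec.n_per_arm) if spec.accrual_months > 0 else np.zeros(spec.n_per_arm)
        cutoff = spec.accrual_months + spec.followup_months - entry
        out[arm] = {}
        for endpoint, t in (("pfs", t_pfs), ("os", t_os)):
            observed = np.minimum(t, cutoff)
            event = (t <= cutoff).astype(int)
            out[arm][endpoint] = pd.DataFrame(
                {"time_months": np.maximum(observed, 1e-9), "event": event}
            )
    return out


def digitize_km(
    ipd: pd.DataFrame, grid_step: float = 1.0, risk_interval: float = 3.0
) -> DigitizedCurve:
    """Evaluate the KM estimate of ``ipd`` on a regular grid.

    Emulates figure digitization: the step-function value of the KM curve
    is read at every multiple of ``grid_step`` months and the at-risk count
    (patients with time >= t) at every multiple of ``risk_interval``.
    """
    if grid_step <= 0 or risk_interval <= 0:
        raise ValueError("grid_step and risk_interval must be positive")
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    time = ipd["time_months"].to_numpy(dtype=float)
    event = ipd["event"].to_numpy(dtype=int)

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    t_max = float(time.max())
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)

    risk_times = np.arange(0.0, t_max + 1e-9, risk_interval)
    n_at_risk = np.array([(time >= rt).sum() for rt in risk_times], dtype=int)
    return DigitizedCurve(times=grid, survival=surv, risk_times=risk_times, n_at_risk=n_at_risk)


# --- parameter workbook ------------------------------------------------------


@dataclass
class SubgroupHR:
    """Subgroup hazard ratios per comparator arm: {arm: (hr_pfs, lo, hi)}
    with an optional OS triple; a missing OS entry falls back to the
    overall OS HR."""

    label: str
    pfs: dict
    os: dict = field(default_factory=dict)


@dataclass
class ArmDefinition:
    """One treatment strategy: efficacy (HRs vs the reference arm with 95%
    CIs), drug schedule, AE profile and SD-state utility."""

    name: str
    hr_pfs: float = 1.0
    hr_os: float = 1.0
    hr_pfs_ci: tuple | None = None
    hr_os_ci: tuple | None = None
    schedule: list = field(default_factory=list)
    ae_profile: list = field(default_factory=list)
    u_sd: float = 0.76

    def __post_init__(self):
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError(f"arm {self.name!r}: hazard ratios must be positive")
        if not 0 <= self.u_sd <= 1:
            raise ValueError(f"arm {self.name!r}: u_sd must lie in [0, 1]")


@dataclass
class ParameterWorkbook:
    """Complete model-input workbook: arms (first entry is the reference),
    shared economics, anthropometry, clock settings and WTP bounds."""

    arms: list
    econ: EconParams
    anthropometry: PatientAnthropometry = field(default_factory=PatientAnthropometry)
    cycle_days: float = 21.0
    horizon_years: float = 10.0
    wtp_low: float = 15289.34
    wtp_high: float = 38223.34
    subgroups: list = field(default_factory=list)

    def __post_init__(self):
        if not self.arms:
            raise ValueError("workbook needs at least one arm")
        if self.wtp_low >= self.wtp_high:
            raise ValueError("wtp_low must be below wtp_high")

    @property
    def reference(self) -> ArmDefinition:
        return self.arms[0]

    def arm(self, name: str) -> ArmDefinition:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)


def default_trial_spec(seed: int = 0, n_per_arm: int = 150) -> TrialSpec:
    return TrialSpec(seed=seed, n_per_arm=n_per_arm)


def default_workbook() -> ParameterWorkbook:
    """Synthetic stand-in workbook with the structural layout the analysis
    assumes (actual published supplementary values are not reproduced).

    Prices are 2022-USD magnitudes typical of Chinese bid-winning prices;
    chemotherapy is pemetrexed (500 mg/m2) + cisplatin (75 mg/m2) for four
    cycles followed by pemetrexed maintenance, sintilimab is 200 mg flat
    and IBI305 15 mg/kg, both capped at 35 cycles (~24 months).
    """
    chemo_schedule = [
        DrugScheduleRow("pemetrexed", "per-m2", 500.0, 0.09, max_cycles=35),
        DrugScheduleRow("cisplatin", "per-m2", 75.0, 0.11, max_cycles=4),
    ]
    sintilimab = DrugScheduleRow("sintilimab", "flat", 200.0, 1.57, max_cycles=35)
    ibi305 = DrugScheduleRow("IBI305", "per-kg", 15.0, 0.55, max_cycles=35)

    chemo_aes = [
        AdverseEvent("neutropenia", 0.30, 450.0, 0.20, 15.0),
        AdverseEvent("anaemia", 0.18, 380.0, 0.12, 20.0),
        AdverseEvent("thrombocytopenia", 0.12, 620.0, 0.11, 14.0),
    ]
    doublet_aes = chemo_aes + [
        AdverseEvent("immune-related pneumonitis", 0.03, 1800.0, 0.20, 30.0),
    ]
    triplet_aes = doublet_aes + [
        AdverseEvent("hypertension", 0.08, 260.0, 0.07, 25.0),
        AdverseEvent("proteinuria", 0.04, 300.0, 0.05, 25.0),
    ]

    arms = [
        ArmDefinition(
            REFERENCE_ARM,
            schedule=list(chemo_schedule),
            ae_profile=chemo_aes,
            u_sd=0.76,
        ),
        ArmDefinition(
            DOUBLET_ARM,
            hr_pfs=0.72,
            hr_os=0.79,
            hr_pfs_ci=(0.60, 0.87),
            hr_os_ci=(0.62, 1.00),
            schedule=[sintilimab] + list(chemo_schedule),
            ae_profile=doublet_aes,
            u_sd=0.78,
        ),
        ArmDefinition(
            TRIPLET_ARM,
            hr_pfs=0.51,
            hr_os=0.82,
            hr_pfs_ci=(0.42, 0.62),
            hr_os_ci=(0.67, 1.00),
            schedule=[sintilimab, ibi305] + list(chemo_schedule),
            ae_profile=triplet_aes,
            u_sd=0.78,
        ),
    ]

    econ = EconParams(
        u_pd=0.70300,
        cost_pd_therapy_cycle=600.0,
        cost_followup_cycle=60.0,
        cost_bsc_cycle=120.0,
        cost_terminal=1800.0,
        discount_rate=0.05,
    )

    subgroups = [
        SubgroupHR("age < 65", {DOUBLET_ARM: (0.68, 0.52, 0.88), TRIPLET_ARM: (0.48, 0.36, 0.64)}),
        SubgroupHR("age >= 65", {DOUBLET_ARM: (0.80, 0.58, 1.10), TRIPLET_ARM: (0.58, 0.41, 0.82)}),
        SubgroupHR("male", {DOUBLET_ARM: (0.74, 0.57, 0.96), TRIPLET_ARM: (0.53, 0.40, 0.70)}),
        SubgroupHR("female", {DOUBLET_ARM: (0.69, 0.50, 0.95), TRIPLET_ARM: (0.47, 0.33, 0.67)}),
        SubgroupHR("ECOG 1", {DOUBLET_ARM: (0.75, 0.58, 0.97), TRIPLET_ARM: (0.54, 0.41, 0.71)}),
        SubgroupHR("T790M negative", {DOUBLET_ARM: (0.66, 0.49, 0.89), TRIPLET_ARM: (0.45, 0.33, 0.62)}),
    ]

    return ParameterWorkbook(arms=arms, econ=econ, subgroups=subgroups)


# --- workbook I/O (YAML structured text) ------------------------------------


def write_workbook(wb: ParameterWorkbook, path) -> None:
    """Serialize the workbook to a YAML config file."""
    doc = {
        "cycle_days": wb.cycle_days,
        "horizon_years": wb.horizon_years,
        "wtp_low": wb.wtp_low,
        "wtp_high": wb.wtp_high,
        "anthropometry": asdict(wb.anthropometry),
        "econ": asdict(wb.econ),
        "arms": [
            {
                "name": a.name,
                "hr_pfs": a.hr_pfs,
                "hr_os": a.hr_os,
                "hr_pfs_ci": list(a.hr_pfs_ci) if a.hr_pfs_ci else None,
                "hr_os_ci": list(a.hr_os_ci) if a.hr_os_ci else None,
                "u_sd": a.u_sd,
                "schedule": [asdict(r) for r in a.schedule],
                "ae_profile": [asdict(r) for r in a.ae_profile],
            }
            for a in wb.arms
        ],
        "subgroups": [
            {"label": g.label, "pfs": {k: list(v) for k, v in g.pfs.items()},
             "os": {k: list(v) for k, v in g.os.items()}}
            for g in wb.subgroups
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_workbook(path) -> ParameterWorkbook:
    doc = yaml.safe_load(Path(path).read_text())
    arms = [
        ArmDefinition(
            name=a["name"],
            hr_pfs=a["hr_pfs"],
            hr_os=a["hr_os"],
            hr_pfs_ci=tuple(a["hr_pfs_ci"]) if a.get("hr_pfs_ci") else None,
            hr_os_ci=tuple(a["hr_os_ci"]) if a.get("hr_os_ci") else None,
            u_sd=a["u_sd"],
            schedule=[DrugScheduleRow(**r) for r in a["schedule"]],
            ae_profile=[AdverseEvent(**r) for r in a["ae_profile"]],
        )
        for a in doc["arms"]
    ]
    subgroups = [
        SubgroupHR(
            label=g["label"],
            pfs={k: tuple(v) for k, v in g.get("pfs", {}).items()},
            os={k: tuple(v) for k, v in g.get("os", {}).items()},
        )
        for g in doc.get("subgroups", [])
    ]
    return ParameterWorkbook(
        arms=arms,
        econ=EconParams(**doc["econ"]),
        anthropometry=PatientAnthropometry(**doc["anthropometry"]),
        cycle_days=doc["cycle_days"],
        horizon_years=doc["horizon_years"],
        wtp_low=doc["wtp_low"],
        wtp_high=doc["wtp_high"],
        subgroups=subgroups,
    )
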