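"""Deterministic and probabilistic sensitivity analysis.

The one-way DSA varies each model input over its plausible range (95%
confidence intervals for hazard ratios, 0-8% for the annual discount rate,
+/-25% around base for everything else) and reports the resulting ICER
spread as a tornado table.  The PSA samples all inputs jointly and
independently from assigned distributions — beta for probabilities and
utilities, gamma for costs, lognormal for hazard ratios (parameterized from
the 95% CI when available) — re-evaluates the model per draw, and
summarizes decision uncertainty as cost-effectiveness acceptability curves:
the fraction of draws in which each strategy maximizes net monetary benefit
``QALY * WTP - cost`` over a willingness-to-pay grid.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .cea import ReferenceSurvival, compute_icer, evaluate_workbook
from .synthetic_data import ParameterWorkbook

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "build_parameter_registry",
    "moment_match",
    "run_dsa",
    "run_psa",
    "PSAResult",
]

_Z95 = 1.959964  # two-sided 95% normal quantile


class PointMass:
    """Degenerate distribution used when a requested dispersion is zero."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        return self.value if size is None else np.full(size, self.value)

    def mean(self):
        return self.value


def moment_match(base_value: float, dispersion_fraction: float, family: str, ci=None):
    """Parameterize a PSA distribution around a base value.

    beta and gamma are moment-matched to mean = base and
    sd = dispersion_fraction * base; the lognormal is inverted from a 95%
    CI when one is given (mu = ln sqrt(lo*hi), sigma = (ln hi - ln lo) /
    (2 * 1.959964)), otherwise sigma = dispersion_fraction on the log
    scale.  Zero dispersion collapses to a point mass.
    """
    if family == "beta":
        if not 0 <= base_value <= 1:
            raise ValueError(f"beta requires a base value in [0, 1], got {base_value}")
        sd = dispersion_fraction * base_value
        if sd == 0 or base_value in (0.0, 1.0):
            return PointMass(base_value)
        nu = base_value * (1 - base_value) / sd**2 - 1
        if nu <= 0:  # dispersion too large for the support; cap just inside
            nu = 1e-6
        return stats.beta(a=base_value * nu, b=(1 - base_value) * nu)
    if family == "gamma":
        if base_value < 0:
            raise ValueError("gamma requires a nonnegative base value")
        sd = dispersion_fraction * base_value
        if sd == 0:
            return PointMass(base_value)
        shape = (base_value / sd) ** 2
        scale = sd**2 / base_value
        return stats.gamma(a=shape, scale=scale)
    if family == "lognormal":
        if base_value <= 0:
            raise ValueError("lognormal requires a positive base value")
        if ci is not None:
            lo, hi = ci
            mu = math.log(math.sqrt(lo * hi))
            sigma = (math.log(hi) - math.log(lo)) / (2 * _Z95)
        else:
            mu, sigma = math.log(base_value), dispersion_fraction
        if sigma == 0:
            return PointMass(math.exp(mu))
        return stats.lognorm(s=sigma, scale=math.exp(mu))
    raise ValueError(f"unknown distribution family {family!r}")


@dataclass
class Parameter:
    """One entry of the model-input registry.

    ``setter(wb, value)`` mutates a (deep-copied) workbook; ``low``/``high``
    are the DSA bounds; ``dist`` is the PSA sampling distribution (None =
    held fixed in the PSA, e.g. the discount rate).
    """

    name: str
    category: str
    base: float
    low: float
    high: float
    setter: Callable[[ParameterWorkbook, float], None]
    dist: object | None = None


def build_parameter_registry(
    wb: ParameterWorkbook, dispersion: float = 0.25
) -> list[Parameter]:
    """Enumerate every varied model input with DSA bounds and PSA
    distributions.

    Hazard ratios use their 95% CIs (DSA bounds and lognormal PSA); the
    discount rate spans 0-8% and is fixed in the PSA; utilities,
    frequencies, costs and prices use +/-25% DSA bounds with beta (bounded)
    or gamma (nonnegative) PSA distributions.  Adverse-event cost and
    disutility burdens are varied per arm through a common multiplier.
    """
    params: list[Parameter] = []

    def pm25(v):
        return 0.75 * v, 1.25 * v

    def add(name, category, base, low, high, setter, dist):
        params.append(Parameter(name, category, base, low, high, setter, dist))

    # discount rate: 0 - 8 %, fixed in the PSA
    add(
        "discount rate", "discount", wb.econ.discount_rate, 0.0, 0.08,
        lambda w, v: setattr(w.econ, "discount_rate", v), None,
    )

    # utilities
    add(
        "utility PD state", "pd_utility", wb.econ.u_pd,
        0.75 * wb.econ.u_pd, min(1.25 * wb.econ.u_pd, 1.0),
        lambda w, v: setattr(w.econ, "u_pd", v),
        moment_match(wb.econ.u_pd, dispersion, "beta"),
    )
    for i, arm in enumerate(wb.arms):
        add(
            f"utility SD state [{arm.name}]", "sd_utility", arm.u_sd,
            0.75 * arm.u_sd, min(1.25 * arm.u_sd, 1.0),
            (lambda i: lambda w, v: setattr(w.arms[i], "u_sd", v))(i),
            moment_match(arm.u_sd, dispersion, "beta"),
        )

    # lump costs
    for attr, label in [
        ("cost_pd_therapy_cycle", "subsequent therapy cost (PD, per cycle)"),
        ("cost_followup_cycle", "routine follow-up cost (per cycle)"),
        ("cost_bsc_cycle", "BSC cost (per cycle)"),
        ("cost_terminal", "terminal care cost (one-time)"),
    ]:
        base = getattr(wb.econ, attr)
        lo, hi = pm25(base)
        add(
            label, "lump_cost", base, lo, hi,
            (lambda a: lambda w, v: setattr(w.econ, a, v))(attr),
            moment_match(base, dispersion, "gamma"),
        )

    # drug unit prices, shared across arms by agent name
    seen: dict[str, float] = {}
    for arm in wb.arms:
        for row in arm.schedule:
            if row.agent not in seen:
                seen[row.agent] = row.unit_price_usd
    for agent, price in seen.items():
        lo, hi = pm25(price)

        def set_price(w, v, agent=agent):
            for a in w.arms:
                for r in a.schedule:
                    if r.agent == agent:
                        r.unit_price_usd = v

        add(f"unit price [{agent}]", "drug_price", price, lo, hi, set_price,
            moment_match(price, dispersion, "gamma"))

    # per-arm AE burden multipliers (cost and disutility)
    for i, arm in enumerate(wb.arms):
        if not arm.ae_profile:
            continue

        def set_ae_cost(w, v, i=i, base=[r.cost_usd for r in arm.ae_profile]):
            for r, b in zip(w.arms[i].ae_profile, base):
                r.cost_usd = b * v

        def set_ae_disu(w, v, i=i, base=[r.disutility for r in arm.ae_profile]):
            for r, b in zip(w.arms[i].ae_profile, base):
                r.disutility = min(b * v, 1.0)

        add(f"AE management cost [{arm.name}]", "ae_cost", 1.0, 0.75, 1.25,
            set_ae_cost, moment_match(1.0, dispersion, "gamma"))
        add(f"AE disutility [{arm.name}]", "ae_disutility", 1.0, 0.75, 1.25,
            set_ae_disu, moment_match(1.0, dispersion, "gamma"))

    # hazard ratios (comparator arms): CI bounds, lognormal PSA
    for i, arm in enumerate(wb.arms[1:], start=1):
        for endpoint, hr, ci in [("PFS", arm.hr_pfs, arm.hr_pfs_ci),
                                 ("OS", arm.hr_os, arm.hr_os_ci)]:
            lo, hi = ci if ci is not None else pm25(hr)
            attr = "hr_pfs" if endpoint == "PFS" else "hr_os"
            add(
                f"{endpoint} HR [{arm.name}]",
                "pfs_hr" if endpoint == "PFS" else "os_hr",
                hr, lo, hi,
                (lambda i, a: lambda w, v: setattr(w.arms[i], a, v))(i, attr),
                moment_match(hr, dispersion, "lognormal", ci=ci),
            )
    return params


def _icer_for(wb: ParameterWorkbook, ref: ReferenceSurvival, comparator: str):
    results = evaluate_workbook(wb, ref)
    row = compute_icer(
        results[wb.reference.name], results[comparator], wb.wtp_low, wb.wtp_high,
        strategy=comparator,
    )
    return row


def run_dsa(
    wb: ParameterWorkbook,
    ref: ReferenceSurvival,
    comparator: str,
    registry: list[Parameter] | None = None,
) -> pd.DataFrame:
    """One-way DSA tornado for one comparison.

    Every registry entry is varied to its low and high bound with all other
    inputs at base; rows are sorted by descending ICER spread.  A variation
    that flips the sign of the incremental QALYs is flagged as a dominance
    switch and its ICER replaced by the dominance label.
    """
    registry = registry if registry is not None else build_parameter_registry(wb)
    base_row = _icer_for(wb, ref, comparator)
    if base_row.label != "icer":
        raise ValueError(f"base case for {comparator!r} has no defined ICER ({base_row.label})")
    base_icer = base_row.icer_per_qaly

    recs = []
    for p in registry:
        vals = {}
        switch = False
        for side, v in (("low", p.low), ("high", p.high)):
            wb2 = copy.deepcopy(wb)
            p.setter(wb2, v)
            row = _icer_for(wb2, ref, comparator)
            if row.label != "icer":
                vals[side] = row.label
                switch = True
            else:
                vals[side] = row.icer_per_qaly
        spread = (
            abs(vals["high"] - vals["low"])
            if not switch
            else np.nan
        )
        recs.append(
            {
                "parameter": p.name,
                "category": p.category,
                "base_icer": base_icer,
                "icer_low": vals["low"],
                "icer_high": vals["high"],
                "spread": spread,
                "dominance_switch": switch,
            }
        )
    df = pd.DataFrame(recs)
    return df.sort_values("spread", ascending=False, na_position="last").reset_index(drop=True)


@dataclass(frozen=True)
class PSAResult:
    """Draws table (draw, arm, cost, qaly) and CEAC (wtp, strategy, probability)."""

    draws: pd.DataFrame
    ceac: pd.DataFrame


def run_psa(
    wb: ParameterWorkbook,
    ref: ReferenceSurvival,
    n_draws: int = 10_000,
    seed: int = 0,
    wtp_max: float = 200_000.0,
    wtp_step: float = 1_000.0,
    registry: list[Parameter] | None = None,
) -> PSAResult:
    """Monte-Carlo PSA with cost-effectiveness acceptability curves.

    Per draw, every registry parameter with a distribution is sampled
    independently, the workbook re-evaluated, and per-strategy cost and
    QALYs recorded.  The CEAC reports, at each WTP grid point, the fraction
    of draws in which each strategy attains the maximal net monetary
    benefit; exact ties split their draw equally.
    """
    registry = registry if registry is not None else build_parameter_registry(wb)
    sampled = [p for p in registry if p.dist is not None]
    rng = np.random.default_rng(seed)
    arm_names = [a.name for a in wb.arms]

    costs = np.empty((n_draws, len(arm_names)))
    qalys = np.empty((n_draws, len(arm_names)))
    rejected = 0
    # small PFS/OS crossings are expected and clamped on many draws; silence
    # the per-trace warning and summarize once below
    trace_logger = logging.getLogger("sincea.markov_engine")
    prior_level = trace_logger.level
    trace_logger.setLevel(logging.ERROR)
    for d in range(n_draws):
        while True:
            wb2 = copy.deepcopy(wb)
            for p in sampled:
                p.setter(wb2, float(p.dist.rvs(random_state=rng)))
            try:
                results = evaluate_workbook(wb2, ref)
            except ValueError:
                # e.g. sampled HR pair makes PFS cross above OS beyond the
                # model-consistency tolerance; reject and resample
                rejected += 1
                if rejected > 100 * n_draws:
                    raise
                continue
            break
        for j, name in enumerate(arm_names):
            costs[d, j] = results[name].cost
            qalys[d, j] = results[name].qaly
    trace_logger.setLevel(prior_level)
    if rejected:
        logger.warning("PSA rejected and resampled %d inconsistent draw(s)", rejected)

    draws = pd.DataFrame(
        {
            "draw": np.repeat(np.arange(n_draws), len(arm_names)),
            "arm": np.tile(arm_names, n_draws),
            "cost": costs.ravel(),
            "qaly": qalys.ravel(),
        }
    )

    wtp_grid = np.arange(0.0, wtp_max + wtp_step / 2, wtp_step)
    # nmb[d, w, j] = qaly[d, j] * wtp[w] - cost[d, j]
    nmb = qalys[:, None, :] * wtp_grid[None, :, None] - costs[:, None, :]
    best = nmb.max(axis=2, keepdims=True)
    winners = nmb >= best - 1e-9
    weights = winners / winners.sum(axis=2, keepdims=True)
    prob = weights.mean(axis=0)  # (n_wtp, n_arms)

    ceac = pd.DataFrame(
        {
            "wtp": np.repeat(wtp_grid, len(arm_names)),
            "strategy": np.tile(arm_names, len(wtp_grid)),
            "probability": prob.ravel(),
        }
    )
    return PSAResult(draws=draws, ceac=ceac)
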