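"""Three-state cohort trace built by survival-curve partition.

The Markov model has three mutually exclusive states — stable disease (SD),
progressed disease (PD) and death — evaluated on a 21-day cycle over a
10-year horizon.  Occupancy is obtained by partitioning the two endpoint
curves (partitioned-survival construction):

    occ_SD(t)   = S_PFS(t)          (HR-adjusted for comparator arms)
    occ_dead(t) = 1 - S_OS(t)
    occ_PD(t)   = S_OS(t) - S_PFS(t), clamped at 0

which reproduces both endpoint curves exactly while identifying state
occupancy; the per-cycle transition probabilities implied by the trace are
exposed separately for reporting.  Independent HR adjustment of PFS and OS
can make the curves cross slightly; small crossings (PFS above OS by less
than 0.05) are clamped with the deficit absorbed by SD, larger persistent
crossings raise a model-consistency error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival_models import ArmSurvival

logger = logging.getLogger(__name__)

__all__ = ["ModelClock", "CohortTrace", "build_trace", "implied_transition_probabilities"]

DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class ModelClock:
    """Cycle length and horizon of the cohort model.

    Defaults: 21-day cycles (treatment administration interval) over a
    10-year horizon, giving ceil(10 * 365.25 / 21) = 174 cycles.
    """

    cycle_days: float = 21.0
    horizon_years: float = 10.0

    def __post_init__(self):
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle_days and horizon_years must be positive")

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_days)

    @property
    def cycle_times_years(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.cycle_days / DAYS_PER_YEAR

    @property
    def cycle_times_months(self) -> np.ndarray:
        return self.cycle_times_years * MONTHS_PER_YEAR


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle (arrays of length n_cycles + 1).

    Invariants: occupancies sum to 1 at every cycle, occ_dead is
    nondecreasing, occ_sd nonincreasing; new_deaths[k] is the death mass
    added between cycles k-1 and k (0 at cycle 0).
    """

    occ_sd: np.ndarray
    occ_pd: np.ndarray
    occ_dead: np.ndarray
    new_deaths: np.ndarray

    def to_frame(self, clock: ModelClock | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": np.arange(len(self.occ_sd)),
                "occ_SD": self.occ_sd,
                "occ_PD": self.occ_pd,
                "occ_dead": self.occ_dead,
                "new_deaths": self.new_deaths,
            }
        )
        if clock is not None:
            df.insert(1, "t_years", clock.cycle_times_years)
        return df


def build_trace(
    arm: ArmSurvival,
    clock: ModelClock,
    crossing_tolerance: float = 1e-9,
    crossing_error: float = 0.05,
) -> CohortTrace:
    """Evaluate the partitioned-survival occupancy at every cycle time.

    Curve evaluation is in months; cycle 0 is (SD=1, PD=0, dead=0) by
    construction since S(0) = 1 for both endpoints.
    """
    t_months = clock.cycle_times_months
    s_pfs = np.asarray(arm.pfs_adjusted(t_months), dtype=float)
    s_os = np.asarray(arm.os_adjusted(t_months), dtype=float)
    if not (np.isclose(s_pfs[0], 1.0) and np.isclose(s_os[0], 1.0)):
        raise ValueError("survival handles must satisfy S(0) = 1")

    violation = s_pfs - s_os
    worst = float(violation.max(initial=0.0))
    if worst > crossing_error:
        raise ValueError(
            f"adjusted PFS exceeds adjusted OS by {worst:.3g} (> {crossing_error}); "
            "inconsistent survival inputs"
        )
    if worst > crossing_tolerance:
        logger.warning(
            "adjusted PFS exceeds adjusted OS by up to %.3g; clamping PD occupancy to 0",
            worst,
        )

    occ_dead = 1.0 - s_os
    occ_pd = np.maximum(s_os - s_pfs, 0.0)
    occ_sd = 1.0 - occ_dead - occ_pd  # absorbs any clamped deficit
    new_deaths = np.diff(occ_dead, prepend=occ_dead[0])
    return CohortTrace(occ_sd=occ_sd, occ_pd=occ_pd, occ_dead=occ_dead, new_deaths=new_deaths)


def implied_transition_probabilities(trace: CohortTrace) -> pd.DataFrame:
    """Per-cycle probabilities implied by the trace.

    ``p_leave_sd(k) = 1 - occ_SD(k)/occ_SD(k-1)`` and
    ``p_die_overall(k) = new_deaths(k) / (1 - occ_dead(k-1))``; cycles where
    the denominator vanishes report 0 with ``undefined`` flagged.
    """
    sd_prev = trace.occ_sd[:-1]
    dead_prev = trace.occ_dead[:-1]
    alive_prev = 1.0 - dead_prev

    with np.errstate(divide="ignore", invalid="ignore"):
        p_leave = np.where(sd_prev > 0, 1.0 - trace.occ_sd[1:] / np.where(sd_prev > 0, sd_prev, 1.0), 0.0)
        p_die = np.where(alive_prev > 0, trace.new_deaths[1:] / np.where(alive_prev > 0, alive_prev, 1.0), 0.0)

    p_leave = np.clip(p_leave, 0.0, 1.0)
    p_die = np.clip(p_die, 0.0, 1.0)
    return pd.DataFrame(
        {
            "cycle": np.arange(1, len(trace.occ_sd)),
            "p_leave_sd": p_leave,
            "p_die_overall": p_die,
            "undefined_sd": sd_prev <= 0,
            "undefined_death": alive_prev <= 0,
        }
    )
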