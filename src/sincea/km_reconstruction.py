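"""Pseudo-individual-patient-data reconstruction from digitized KM curves.

Published Kaplan-Meier figures only show the survival step function and
(usually) a numbers-at-risk table.  The interval-allocation algorithm of
Guyot et al. (BMC Med Res Methodol 2012) inverts the KM construction: within
each risk-table interval it guesses the number of censorings, spreads them
uniformly, allocates events at the digitized drop points so the running KM
product tracks the digitized curve, and adjusts the censoring count until
the implied number at risk matches the next risk-table entry.  The output is
per-patient ``(time, event)`` records whose KM estimate reproduces the input
curve to digitization accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DigitizedCurve",
    "ReconstructionError",
    "monotonize",
    "reconstruct_ipd",
    "read_curve_csv",
    "write_curve_csv",
    "read_ipd_csv",
    "write_ipd_csv",
]


class ReconstructionError(RuntimeError):
    """Raised when the risk table cannot be reconciled with the curve."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized KM coordinates plus a numbers-at-risk table.

    ``times`` are months (nondecreasing), ``survival`` in [0, 1];
    ``risk_times``/``n_at_risk`` give the at-risk counts printed under the
    figure.  The at-risk convention is "time >= risk_time", i.e. patients
    with an event exactly at the risk time are still counted.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        object.__setattr__(self, "risk_times", np.asarray(self.risk_times, dtype=float))
        object.__setattr__(self, "n_at_risk", np.asarray(self.n_at_risk, dtype=int))
        if self.times.size == 0:
            raise ValueError("empty digitized curve")
        if self.times.size != self.survival.size:
            raise ValueError("times and survival must have equal length")


def monotonize(curve: DigitizedCurve) -> DigitizedCurve:
    """Repair digitization noise: sort, collapse duplicate times, clip, and
    enforce a nonincreasing survival via a running minimum.

    A missing t=0 anchor is prepended with survival 1.0.  Duplicate times
    keep the minimum survival value.
    """
    order = np.argsort(curve.times, kind="stable")
    t = curve.times[order]
    s = np.clip(curve.survival[order], 0.0, 1.0)
    # collapse duplicates keeping the minimum survival at each time
    ut, inv = np.unique(t, return_inverse=True)
    us = np.full(ut.shape, np.inf)
    np.minimum.at(us, inv, s)
    if ut[0] > 0:
        ut = np.concatenate([[0.0], ut])
        us = np.concatenate([[1.0], us])
    us = np.minimum.accumulate(np.clip(us, 0.0, 1.0))
    return replace(curve, times=ut, survival=us)


def _risk_interval_bounds(times: np.ndarray, risk_times: np.ndarray) -> np.ndarray:
    """First grid index at or after each risk time."""
    return np.searchsorted(times, risk_times, side="left")


def reconstruct_ipd(
    curve: DigitizedCurve,
    n_total: int | None = None,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Reconstruct per-patient records from a monotonized digitized curve.

    Parameters
    ----------
    curve : DigitizedCurve
        Monotonized curve.  The risk table must contain an entry at (or
        before) the first coordinate; if the table is empty an
        events-only reconstruction is done from ``n_total`` with a warning.
    n_total : int, optional
        Initial cohort size; required only when the risk table is absent.

    Returns
    -------
    DataFrame with columns ``time_months`` (float) and ``event`` (1 = event,
    0 = censored); number of rows equals the initial number at risk.

    Raises
    ------
    ReconstructionError
        If a KM drop demands more events than patients remain at risk, with
        the offending interval named.
    """
    curve = monotonize(curve)
    t, s = curve.times, curve.survival

    if curve.risk_times.size == 0:
        if n_total is None:
            raise ReconstructionError("no risk table and no n_total supplied")
        logger.warning(
            "risk table absent: events-only reconstruction assuming no "
            "censoring before the last coordinate"
        )
        risk_times = np.array([t[0]])
        n_at_risk = np.array([n_total])
    else:
        keep = curve.risk_times <= t[-1]
        risk_times = curve.risk_times[keep]
        n_at_risk = curve.n_at_risk[keep]
        if risk_times.size == 0:
            raise ReconstructionError("risk table lies entirely beyond the curve")

    lower = _risk_interval_bounds(t, risk_times)
    if lower[0] != 0:
        raise ReconstructionError("risk table must start at or before the first coordinate")
    n_grid = len(t)
    K = len(risk_times)

    event_times: list[float] = []
    censor_times: list[float] = []
    km_last = 1.0  # running KM product at the last allocated event
    n_cur = int(n_at_risk[0])

    for k in range(K):
        # a drop recorded at a grid time equal to the next risk time reflects
        # events just before it, so it belongs to THIS interval: allocate over
        # grid indices (lower[k], lower[k+1]]
        first = int(lower[k]) + 1
        last = int(lower[k + 1]) if k < K - 1 else n_grid - 1
        t_start = t[lower[k]]
        if last < first:
            continue
        target = int(n_at_risk[k + 1]) if k < K - 1 else None

        if target is not None:
            guess = int(round(n_cur * (s[last] / km_last if km_last > 0 else 0.0))) - target
            guess = max(guess, 0)
        else:
            guess = 0  # final interval: administrative censoring handled afterwards

        best = None  # (abs mismatch, signed mismatch, guess, events, censors, km_end, n_end)
        for _ in range(max_iter):
            ev, cen, km_end, n_end = _allocate_interval(
                t, s, first, last, t_start, n_cur, km_last, guess
            )
            if target is None:
                best = (0, 0, guess, ev, cen, km_end, n_end)
                break
            mismatch = n_end - target
            if best is None or abs(mismatch) < best[0]:
                best = (abs(mismatch), mismatch, guess, ev, cen, km_end, n_end)
            if mismatch == 0:
                break
            new_guess = max(guess + mismatch, 0)
            if new_guess == guess:
                break
            guess = new_guess
        assert best is not None
        if best[0] != 0 and best[1] < 0 and best[2] == 0:
            # even with zero censorings too few patients remain: the KM drop
            # is larger than the risk table permits
            raise ReconstructionError(
                f"risk table inconsistent with curve in interval "
                f"({t_start:g}, {t[last]:g}]: KM drop implies "
                f"{target - best[6]} more departure(s) than the at-risk "
                f"counts allow"
            )
        _, _, _, ev, cen, km_last, n_cur = best
        event_times.extend(ev)
        censor_times.extend(cen)

    # patients still at risk past the last coordinate: administrative censoring
    censor_times.extend([float(t[-1])] * n_cur)

    times = np.array(event_times + censor_times, dtype=float)
    events = np.array([1] * len(event_times) + [0] * len(censor_times), dtype=int)
    # KM needs strictly positive times; nudge any t=0 records
    times[times <= 0] = 1e-9
    order = np.argsort(times, kind="stable")
    return pd.DataFrame({"time_months": times[order], "event": events[order]})


def _allocate_interval(t, s, first, last, t_start, n_start, km_start, n_censor):
    """Allocate events at the grid drops of indices ``first..last`` and
    ``n_censor`` censorings spread uniformly over ``(t_start, t[last])``.

    Censorings falling strictly before a grid time leave the risk set
    before that time's events; a censoring tied with an event time is
    placed after the event (standard KM convention).  Returns
    (event_times, censor_times, km_end, n_end).
    """
    width = t[last] - t_start
    if n_censor > 0 and width > 0:
        cens = t_start + (np.arange(1, n_censor + 1) / (n_censor + 1)) * width
    else:
        cens = np.full(n_censor, t_start, dtype=float)

    event_times: list[float] = []
    censor_times: list[float] = []
    n = n_start
    km = km_start
    for i in range(first, last + 1):
        # censorings during (t[i-1], t[i]) exit before the events at t[i]
        in_step = (cens >= t[i - 1]) & (cens < t[i]) if len(cens) else np.array([], bool)
        c = min(int(in_step.sum()), n)
        if c > 0:
            censor_times.extend(float(x) for x in cens[in_step][:c])
            n -= c
        if km > 0 and n > 0:
            d = min(int(round(n * (1.0 - s[i] / km))), n)
            if d > 0:
                km *= 1.0 - d / n
                event_times.extend([float(t[i])] * d)
                n -= d
    return event_times, censor_times, km, n


# --- CSV I/O -----------------------------------------------------------------


def write_curve_csv(curve: DigitizedCurve, curve_path, risk_path) -> None:
    """Write curve coordinates and risk table (schemas: time_months,survival
    and time_months,n_at_risk)."""
    pd.DataFrame({"time_months": curve.times, "survival": curve.survival}).to_csv(
        curve_path, index=False
    )
    pd.DataFrame({"time_months": curve.risk_times, "n_at_risk": curve.n_at_risk}).to_csv(
        risk_path, index=False
    )


def read_curve_csv(curve_path, risk_path=None) -> DigitizedCurve:
    cdf = pd.read_csv(curve_path)
    _require(cdf, ["time_months", "survival"], curve_path)
    if risk_path is not None:
        rdf = pd.read_csv(risk_path)
        _require(rdf, ["time_months", "n_at_risk"], risk_path)
        rt, nr = rdf["time_months"].to_numpy(), rdf["n_at_risk"].to_numpy()
    else:
        rt, nr = np.array([]), np.array([], dtype=int)
    return DigitizedCurve(cdf["time_months"].to_numpy(), cdf["survival"].to_numpy(), rt, nr)


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd[["time_months", "event"]].to_csv(path, index=False)


def read_ipd_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["time_months", "event"], path)
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
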