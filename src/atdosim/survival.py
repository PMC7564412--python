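"""Kaplan-Meier estimation and the Mantel-Cox log-rank test.

The therapy study follows groups of engrafted mice after a single injected
activity; animals are sacrificed on humane endpoints (event) or survive to
administrative censoring at study end. The product-limit estimator and the
two-sample Mantel-Cox test are implemented directly from their defining
formulas (no continuity correction); tied deaths and censorings at the same
time are resolved deaths-first, the standard convention.

For two groups, at each distinct event time j with n_j at risk, d_j total
deaths and n_1j at risk in group 1:

    E_1j = d_j * n_1j / n_j
    V_1j = d_j * (n_1j/n_j) * (1 - n_1j/n_j) * (n_j - d_j) / (n_j - 1)

    chi2 = (sum_j (d_1j - E_1j))^2 / sum_j V_1j,  1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "read_survival",
    "km_curve",
    "median_survival",
    "logrank",
    "survival_percent",
]

log = logging.getLogger(__name__)

CAUSES = {
    "acute_toxicity",
    "paraplegia",
    "extramedullary",
    "high_igg",
    "undetermined",
    "censored",
}


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal's follow-up: time in days and event (1) or censored (0)."""

    animal_id: str
    group: str
    time: float  # days from engraftment
    event: bool
    cause: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError(f"survival time must be positive, got {self.time}")
        if self.cause is not None:
            if self.cause not in CAUSES:
                raise ValidationError(f"unknown cause {self.cause!r}")
            if (self.cause == "censored") == self.event:
                raise ValidationError(
                    f"cause {self.cause!r} inconsistent with event={self.event}"
                )


@dataclass(frozen=True, eq=False)
class KMCurve:
    """Product-limit curve: step times, survival, at-risk counts."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each step
    at_risk: np.ndarray  # n at risk just before each step
    n_total: int

    def s(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df
    df: int
    p_value: float
    defined: bool = True


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read an events CSV with header ``animal,group,time_days,event,cause``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty survival file: {path}") from exc
    missing = [c for c in ("animal", "group", "time_days", "event") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        cause = row.get("cause")
        cause = None if pd.isna(cause) else str(cause)
        records.append(
            SurvivalRecord(
                animal_id=str(row["animal"]),
                group=str(row["group"]),
                time=float(row["time_days"]),
                event=bool(int(row["event"])),
                cause=cause,
            )
        )
    return records


def _times_events(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    if not recs:
        raise ValidationError("no survival records")
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=bool)
    return t, e


def km_curve(records: Iterable[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j / n_j).

    Censored observations reduce the risk set without stepping S down; at
    tied times deaths are processed before censorings.
    """
    t, e = _times_events(records)
    n = len(t)
    event_times = np.unique(t[e])
    surv, at_risk_out = [], []
    s = 1.0
    for tj in event_times:
        n_j = int(np.sum(t >= tj))  # deaths precede censorings at tj
        d_j = int(np.sum((t == tj) & e))
        s *= 1.0 - d_j / n_j
        surv.append(s)
        at_risk_out.append(n_j)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk_out, dtype=int),
        n_total=n,
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest t with S(t) <= 0.5; None (undefined) if S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.times[below[0]])


def logrank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-sample Mantel-Cox log-rank test.

    Sums observed-minus-expected deaths in group A over all distinct event
    times with the hypergeometric variance at each; chi-square with 1 df.
    Symmetric in the group labels. With zero events the statistic is
    undefined and flagged rather than raised.
    """
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones_like(ta, bool), np.zeros_like(tb, bool)])
    event_times = np.unique(t[e])
    if len(event_times) == 0:
        log.warning("log-rank undefined: no events in either group")
        return LogRankResult(float("nan"), 1, float("nan"), defined=False)
    o_minus_e = 0.0
    var = 0.0
    for tj in event_times:
        at_risk = t >= tj
        n_j = int(at_risk.sum())
        n_aj = int((at_risk & in_a).sum())
        dead = (t == tj) & e
        d_j = int(dead.sum())
        d_aj = int((dead & in_a).sum())
        o_minus_e += d_aj - d_j * n_aj / n_j
        if n_j > 1:
            var += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0.0:
        # all deaths in risk sets fully contained in one group: no information
        return LogRankResult(0.0, 1, 1.0, defined=False)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(float(chi2), 1, max(min(p, 1.0), np.nextafter(0, 1)))


def survival_percent(alive: int, total: int, *, decimals: int | None = None) -> float:
    """Overall survival, 100*alive/total, optionally report-rounded."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= alive <= total:
        raise ValidationError(f"alive={alive} outside [0, {total}]")
    pct = 100.0 * alive / total
    return round(pct, decimals) if decimals is not None else pct
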