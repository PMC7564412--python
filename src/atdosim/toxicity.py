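"""Hematologic and enzyme toxicity summaries.

Hematologic toxicity is quantified as the nadir percent decrease from the
pre-treatment baseline: leukopenia is deepest ~3 days after injection and
thrombocytopenia ~10 days after, both recovering by ~day 25, so each
analyte has a default nadir search window. Liver/kidney enzyme panels
(ASAT, ALAT, creatinine) are classified against configured normal-range
limits; no limits are hard-coded — they come from the run config with a
citation field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError

__all__ = [
    "HematologySeries",
    "EnzymePanel",
    "DEFAULT_WINDOWS",
    "read_hematology",
    "nadir_percent_decrease",
    "group_decrease_summary",
    "range_flag",
]

log = logging.getLogger(__name__)

ANALYTES = {"wbc", "rbc", "platelets"}
ENZYMES = {"asat", "alat", "creatinine"}

#: default nadir search windows in days post-treatment, per analyte
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "wbc": (1.0, 7.0),
    "platelets": (5.0, 15.0),
    "rbc": (1.0, 30.0),
}


@dataclass(frozen=True, eq=False)
class HematologySeries:
    """One animal's blood-count time series (counts per mm^3 by day)."""

    animal_id: str
    group: str
    analyte: str
    days: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if len(self.days) != len(self.counts) or len(self.days) == 0:
            raise ValidationError("days and counts must be equal-length, non-empty")
        if np.any(np.diff(self.days) < 0):
            raise ValidationError("days must be non-decreasing")
        if np.any(np.asarray(self.counts) < 0):
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class EnzymePanel:
    """A single enzyme measurement (IU/L; creatinine in its kit units)."""

    animal_id: str
    group: str
    analyte: str
    value: float
    day: float

    def __post_init__(self) -> None:
        if self.analyte not in ENZYMES:
            raise ValidationError(f"unknown enzyme analyte {self.analyte!r}")
        if self.value < 0:
            raise ValidationError(f"enzyme value must be non-negative, got {self.value}")


def read_hematology(path: str | Path) -> list[HematologySeries]:
    """Read a counts CSV with header ``animal,group,analyte,day,value``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty hematology file: {path}") from exc
    missing = [c for c in ("animal", "group", "analyte", "day", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = []
    for (animal, group, analyte), sub in df.groupby(["animal", "group", "analyte"]):
        sub = sub.sort_values("day")
        out.append(
            HematologySeries(
                animal_id=str(animal),
                group=str(group),
                analyte=str(analyte),
                days=sub["day"].to_numpy(float),
                counts=sub["value"].to_numpy(float),
            )
        )
    return out


def nadir_percent_decrease(
    series: HematologySeries, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Percent decrease from baseline at the nadir, and the nadir day.

    Baseline is the last sample at day <= 0 (pre-treatment). The nadir is
    the minimum count inside the search window (defaults per analyte).
    The decrease is floored at 0 if counts only rise; it is scale-invariant.
    """
    window = DEFAULT_WINDOWS[series.analyte] if window is None else window
    base_mask = series.days <= 0
    if not base_mask.any():
        raise ValidationError(f"no baseline (day <= 0) sample for {series.animal_id}")
    baseline = float(series.counts[base_mask][-1])
    if baseline <= 0:
        raise ValidationError(f"baseline count is zero for {series.animal_id}")
    lo, hi = window
    in_win = (series.days >= lo) & (series.days <= hi)
    if not in_win.any():
        raise ValidationError(
            f"no samples in window [{lo}, {hi}] days for {series.animal_id}"
        )
    idx = int(np.argmin(np.where(in_win, series.counts, np.inf)))
    nadir = float(series.counts[idx])
    decrease = max(100.0 * (baseline - nadir) / baseline, 0.0)
    return decrease, float(series.days[idx])


def group_decrease_summary(
    cohort: Iterable[HematologySeries],
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Mean +/- sample SD of per-animal nadir decreases, per group/analyte.

    Decreases are computed per animal and then averaged (not on group mean
    curves). Groups with a single animal report the mean with SD absent.
    """
    rows = []
    for s in cohort:
        window = None if windows is None else windows.get(s.analyte)
        dec, day = nadir_percent_decrease(s, window)
        rows.append({"group": s.group, "analyte": s.analyte, "decrease": dec, "nadir_day": day})
    if not rows:
        raise ValidationError("empty cohort")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "analyte"])["decrease"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out


def range_flag(panel: EnzymePanel, limits: Mapping[str, tuple[float, float]]) -> str:
    """Classify an enzyme value against configured normal limits.

    ``limits`` maps analyte -> (lower, upper); both bounds inclusive, so a
    value exactly at the upper limit is ``normal``. Missing limits raise
    :class:`ConfigError` naming the analyte.
    """
    if panel.analyte not in limits:
        raise ConfigError(f"no normal-range limits configured for {panel.analyte!r}")
    lo, hi = limits[panel.analyte]
    if panel.value < lo:
        return "below"
    if panel.value > hi:
        return "above"
    return "normal"
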