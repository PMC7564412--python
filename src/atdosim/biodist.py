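"""Organ biodistribution tables (%ID/g) and decay-correction handling.

A biodistribution study sacrifices small groups of animals at fixed times
post-injection and gamma-counts each organ; activity is expressed as percent
of injected dose per gram of tissue (%ID/g), except for the neck/thyroid
which is reported whole-organ as %ID. Tables are long (tidy): one row per
animal x organ x timepoint.

Gamma-counter output is conventionally decay-corrected back to injection
time; the dosimetry stage needs the physically decaying (uncorrected) curve,
so every table carries an explicit ``decay_corrected`` flag and
:func:`set_decay_correction` converts between the two scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "BiodistTable",
    "REQUIRED_COLUMNS",
    "WHOLE_ORGAN_LABELS",
    "read_biodistribution",
    "write_biodistribution",
    "summarize",
    "set_decay_correction",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("animal", "organ", "time_h", "value", "unit", "decay_corrected")

#: organs measured whole-organ (%ID) rather than per-gram
WHOLE_ORGAN_LABELS = frozenset({"neck", "thyroid"})

_UNITS = {"percent_id_per_gram", "percent_id"}


@dataclass(frozen=True, eq=False)
class BiodistTable:
    """Validated long-format biodistribution data plus study metadata."""

    records: pd.DataFrame
    injected_activity_mbq: float | None = None
    nuclide: str = "At-211"
    study: str = ""

    def __post_init__(self) -> None:
        _validate_records(self.records)

    @property
    def organs(self) -> list[str]:
        return sorted(self.records["organ"].unique())

    @property
    def uniform_decay_flag(self) -> bool | None:
        """The shared decay_corrected state, or None if mixed."""
        flags = self.records["decay_corrected"].unique()
        return bool(flags[0]) if len(flags) == 1 else None

    def organ_points(self, organ: str) -> pd.DataFrame:
        """Per-animal (time_h, value) rows for one organ."""
        sub = self.records[self.records["organ"] == organ]
        if sub.empty:
            raise ValidationError(f"no records for organ {organ!r}")
        return sub[["time_h", "value"]].reset_index(drop=True)


def _validate_records(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if df.empty:
        raise SchemaError("biodistribution table has no rows")
    bad_unit = ~df["unit"].isin(_UNITS)
    if bad_unit.any():
        raise ValidationError(
            f"unknown unit at rows {df.index[bad_unit].tolist()[:5]}"
        )
    for col in ("time_h", "value"):
        neg = df[col] < 0
        if neg.any():
            raise ValidationError(
                f"negative {col} at rows {df.index[neg].tolist()[:5]}"
            )
        nonfinite = ~np.isfinite(df[col])
        if nonfinite.any():
            raise ValidationError(
                f"non-finite {col} at rows {df.index[nonfinite].tolist()[:5]}"
            )
    per_gram_whole = df["unit"].eq("percent_id") & ~df["organ"].str.lower().isin(
        WHOLE_ORGAN_LABELS
    )
    if per_gram_whole.any():
        raise ValidationError(
            "unit percent_id only allowed for whole-organ labels "
            f"{sorted(WHOLE_ORGAN_LABELS)}; offending rows "
            f"{df.index[per_gram_whole].tolist()[:5]}"
        )


def read_biodistribution(
    path: str | Path,
    *,
    injected_activity_mbq: float | None = None,
    nuclide: str = "At-211",
    study: str = "",
) -> BiodistTable:
    """Read a long-format biodistribution CSV into a validated table.

    Expects header ``animal,organ,time_h,value,unit,decay_corrected``.
    Unknown organ labels are retained (and logged); schema problems raise
    :class:`SchemaError`, bad values :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty biodistribution file: {path}") from exc
    if "decay_corrected" in df.columns:
        df["decay_corrected"] = df["decay_corrected"].map(_parse_bool)
    table = BiodistTable(
        records=df,
        injected_activity_mbq=injected_activity_mbq,
        nuclide=nuclide,
        study=study,
    )
    log.info("read %d biodistribution records from %s", len(df), path)
    return table


def write_biodistribution(table: BiodistTable, path: str | Path) -> None:
    out = table.records.loc[:, list(REQUIRED_COLUMNS)]
    out.to_csv(path, index=False)
    log.info("wrote %d biodistribution records to %s", len(out), path)


def _parse_bool(x: object) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValidationError(f"cannot parse decay_corrected value {x!r}")


def summarize(table: BiodistTable) -> pd.DataFrame:
    """Per (organ, time) mean, sample SD (ddof=1) and n over animals."""
    g = table.records.groupby(["organ", "time_h"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out


def set_decay_correction(
    table: BiodistTable, lam: float, target_corrected: bool
) -> BiodistTable:
    """Convert the whole table to the requested decay-correction state.

    Correcting multiplies by e^(lambda*t) (rescaling counts to injection
    time); uncorrecting multiplies by e^(-lambda*t). A table whose rows do
    not share one flag is rejected. The round trip is the identity up to
    floating-point error.
    """
    if lam <= 0:
        raise ValidationError(f"decay constant must be positive, got {lam}")
    current = table.uniform_decay_flag
    if current is None:
        raise ValidationError("table mixes decay-corrected and uncorrected rows")
    if current == target_corrected:
        return table
    df = table.records.copy()
    factor = np.exp(lam * df["time_h"] * (1.0 if target_corrected else -1.0))
    df["value"] = df["value"] * factor
    df["decay_corrected"] = target_corrected
    return replace(table, records=df)
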