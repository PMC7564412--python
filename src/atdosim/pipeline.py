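"""End-to-end orchestration: simulate / analyse / report in one run.

`run_all` composes the stages — dosimetry from a biodistribution table,
Kaplan-Meier + log-rank from an events table, hematology nadir summaries —
and writes a report bundle with a manifest (config hash, seeds, constants)
so any output can be reproduced exactly. Stage failures are recorded in the
manifest instead of aborting the other stages.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biodist import BiodistTable, read_biodistribution, write_biodistribution
from .config import RunConfig
from .dosimetry import apply_rbe, build_dose_table
from .errors import AtdosimError
from .nuclide import load_chain, mean_alpha_energy_per_decay
from .survival import (
    SurvivalRecord,
    km_curve,
    logrank,
    median_survival,
    read_survival,
    survival_percent,
)
from .synthetic import gen_biodistribution, gen_hematology, gen_survival
from .tac import load_organ_models
from .toxicity import HematologySeries, group_decrease_summary, read_hematology

__all__ = ["subseed", "simulate_all", "run_all"]

log = logging.getLogger(__name__)


def subseed(seed: int, stream: int) -> int:
    """Deterministic per-stage substream seed fanned out from one global seed."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def simulate_all(out_dir: str | Path, seed: int) -> dict[str, Path]:
    """Generate the three synthetic datasets as the CSVs the stages read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "biodist": out / "biodistribution.csv",
        "survival": out / "survival.csv",
        "hematology": out / "hematology.csv",
    }
    table = gen_biodistribution(seed=subseed(seed, 0))
    write_biodistribution(table, paths["biodist"])

    records = gen_survival(seed=subseed(seed, 1))
    pd.DataFrame(
        {
            "animal": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "time_days": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "cause": [r.cause for r in records],
        }
    ).to_csv(paths["survival"], index=False)

    series = gen_hematology(seed=subseed(seed, 2))
    rows = []
    for s in series:
        for d, c in zip(s.days, s.counts):
            rows.append(
                {"animal": s.animal_id, "group": s.group, "analyte": s.analyte, "day": d, "value": c}
            )
    pd.DataFrame(rows).to_csv(paths["hematology"], index=False)
    return paths


def _dose_stage(config: RunConfig, biodist: BiodistTable, out: Path) -> dict:
    chain = load_chain(config.nuclide_file)
    mapping = load_organ_models(config.organ_model_file)
    dose_table = build_dose_table(biodist, chain, mapping, seed=subseed(config.seed, 10))
    dose_table.to_frame().to_csv(out / "dose_table.csv", index=False)
    at = dose_table.dose_at(config.injected_activity_mbq, decimals=config.rounding_decimals)
    at["dose_gy_rbe"] = [apply_rbe(d, config.rbe) for d in at["dose_gy"]]
    at.to_csv(out / "dose_at_activity.csv", index=False)
    return {
        "energy_per_decay_mev": dose_table.energy_per_decay,
        "half_life_h": chain.half_life,
        "organs": len(dose_table.entries),
        "all_converged": all(e.converged for e in dose_table.entries),
    }


def _survival_stage(config: RunConfig, records: list[SurvivalRecord], out: Path) -> dict:
    if config.undetermined_is_event is False:
        records = [
            SurvivalRecord(r.animal_id, r.group, r.time, False, "censored")
            if r.cause == "undetermined"
            else r
            for r in records
        ]
    groups = sorted({r.group for r in records})
    medians, km_rows = [], []
    for g in groups:
        grp = [r for r in records if r.group == g]
        curve = km_curve(grp)
        frame = curve.to_frame()
        frame.insert(0, "group", g)
        km_rows.append(frame)
        alive = sum(1 for r in grp if not r.event)
        medians.append(
            {
                "group": g,
                "n": len(grp),
                "median_days": median_survival(curve),
                "survival_percent": survival_percent(alive, len(grp), decimals=0),
            }
        )
    pd.concat(km_rows).to_csv(out / "km_curves.csv", index=False)
    pd.DataFrame(medians).to_csv(out / "survival_summary.csv", index=False)

    lr_rows = []
    for ga, gb in itertools.combinations(groups, 2):
        res = logrank(
            [r for r in records if r.group == ga], [r for r in records if r.group == gb]
        )
        lr_rows.append(
            {"group_a": ga, "group_b": gb, "chi2": res.statistic, "df": res.df, "p": res.p_value}
        )
    pd.DataFrame(lr_rows).to_csv(out / "logrank.csv", index=False)
    return {"groups": groups, "n_records": len(records)}


def _toxicity_stage(config: RunConfig, series: list[HematologySeries], out: Path) -> dict:
    summary = group_decrease_summary(series)
    summary.to_csv(out / "toxicity_summary.csv", index=False)
    return {"series": len(series), "groups": sorted(summary["group"].unique())}


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    *,
    biodist_csv: str | Path | None = None,
    survival_csv: str | Path | None = None,
    hematology_csv: str | Path | None = None,
) -> dict:
    """Run every stage whose input is present; write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``). A stage
    whose input is missing or that fails is recorded in the manifest; the
    other stages still run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.model_dump(mode="json"),
        "config_hash": config.manifest_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stages = [
        ("dose", biodist_csv, lambda p: _dose_stage(config, read_biodistribution(p), out)),
        ("survival", survival_csv, lambda p: _survival_stage(config, read_survival(p), out)),
        ("toxicity", hematology_csv, lambda p: _toxicity_stage(config, read_hematology(p), out)),
    ]
    for name, path, fn in stages:
        if path is None:
            manifest["stages"][name] = {"status": "skipped", "reason": "no input"}
            continue
        try:
            info = fn(path)
            manifest["stages"][name] = {"status": "ok", **info}
        except AtdosimError as exc:
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
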