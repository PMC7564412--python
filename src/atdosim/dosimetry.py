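"""Absorbed dose per unit injected activity from time-integrated activity.

The dose model is local energy deposition: the ~70 um range of the alpha
particles is small against organ dimensions, so every alpha emitted in a
tissue deposits its full energy there. For an organ whose decay-uncorrected
TAC integrates to ``auc`` %ID*h/g, the absorbed dose per MBq injected is

    D [Gy/MBq] = (auc / 100) [h/g]
                 * 3.6e9 [decays / (MBq h)]
                 * E_alpha [MeV] * 1.602176634e-13 [J/MeV]
                 * 1e3 [g/kg]

with E_alpha the branching-ratio-weighted alpha energy per decay of the
chain (6.79 MeV for 211At). The %ID/g input is already per unit tissue
mass, so no organ mass table is needed; an explicit whole-organ
(%ID + mass) route is provided and is algebraically identical.

Dose uncertainty propagates the fit's parameter covariance through the
analytic AUC gradient (delta method), with a seeded residual bootstrap as
a cross-check; the choice of method is an implementation decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .biodist import WHOLE_ORGAN_LABELS, BiodistTable, set_decay_correction, summarize
from .errors import ValidationError
from .nuclide import NuclideChain, decay_constant, mean_alpha_energy_per_decay
from .tac import ModelId, TACFit, auc_gradient, choose_model, eval_model, fit_tac

__all__ = [
    "GY_PER_MBQ_PER_AUC_PER_MEV",
    "DoseEntry",
    "DoseTable",
    "dose_per_unit_activity",
    "dose_from_whole_organ",
    "dose_at_activity",
    "dose_uncertainty",
    "apply_rbe",
    "build_dose_table",
]

log = logging.getLogger(__name__)

_DECAYS_PER_MBQ_H = 3.6e9  # 1 MBq = 1e6 decays/s
_J_PER_MEV = 1.602176634e-13
_G_PER_KG = 1e3

#: Gy/MBq contributed by 1 %ID*h/g of TIA per MeV of alpha energy
GY_PER_MBQ_PER_AUC_PER_MEV = _DECAYS_PER_MBQ_H * _J_PER_MEV * _G_PER_KG / 100.0


def dose_per_unit_activity(auc: float, energy: float) -> float:
    """Absorbed dose in Gy per MBq injected from an AUC in %ID*h/g.

    ``auc`` must come from a decay-UNcorrected TAC (physical decay is part
    of the effective clearance); linear in both arguments.
    """
    if auc < 0:
        raise ValidationError(f"AUC must be non-negative, got {auc}")
    if energy <= 0:
        raise ValidationError(f"energy per decay must be positive, got {energy}")
    return auc * energy * GY_PER_MBQ_PER_AUC_PER_MEV


def dose_from_whole_organ(auc_percent_id_h: float, mass_g: float, energy: float) -> float:
    """Dose from a whole-organ TIA (%ID*h) and the organ mass in grams.

    Equivalent to :func:`dose_per_unit_activity` on the per-gram AUC
    ``auc_percent_id_h / mass_g``: weighting the TIA by tissue mass and
    dividing the deposited energy by the same mass cancels exactly.
    """
    if mass_g <= 0:
        raise ValidationError(f"organ mass must be positive, got {mass_g}")
    return dose_per_unit_activity(auc_percent_id_h / mass_g, energy)


def dose_at_activity(
    dose_per_mbq: float, injected_mbq: float, *, decimals: int | None = None
) -> float:
    """Dose in Gy at a given injected activity, optionally report-rounded."""
    if injected_mbq < 0:
        raise ValidationError(f"injected activity must be non-negative, got {injected_mbq}")
    dose = dose_per_mbq * injected_mbq
    return round(dose, decimals) if decimals is not None else dose


def apply_rbe(dose_gy: float, rbe: float) -> float:
    """Weight an absorbed dose by a relative biological effectiveness factor."""
    if rbe <= 0:
        raise ValidationError(f"RBE must be positive, got {rbe}")
    return dose_gy * rbe


def dose_uncertainty(
    fit: TACFit,
    energy: float,
    method: Literal["delta", "bootstrap"] = "delta",
    *,
    points: Sequence[tuple[float, float]] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> float:
    """Standard error of the Gy/MBq dose implied by a TAC fit.

    delta: parameter covariance propagated through the analytic AUC gradient
    then the linear dose map. bootstrap: residuals are resampled with
    replacement (seeded), added back onto the fitted curve, and the model is
    refitted; the SE is the SD of the bootstrap doses. A singular covariance
    triggers a bootstrap fallback (requires ``points``).
    """
    if not fit.converged:
        log.warning("dose uncertainty requested for a non-converged fit")
    scale = energy * GY_PER_MBQ_PER_AUC_PER_MEV
    if method == "delta":
        g = auc_gradient(fit.model_id, fit.estimates)
        var = float(g @ fit.covariance @ g)
        if not np.isfinite(var) or var < 0:
            log.warning("singular covariance; falling back to residual bootstrap")
            return dose_uncertainty(
                fit, energy, "bootstrap", points=points, n_boot=n_boot, seed=seed
            )
        return float(np.sqrt(var)) * scale
    if method != "bootstrap":
        raise ValidationError(f"unknown SE method {method!r}")
    if points is None:
        raise ValidationError("bootstrap SE needs the fitted (t, value) points")
    pts = np.asarray(points, dtype=float)
    t, y = pts[:, 0], pts[:, 1]
    fitted = np.asarray(eval_model(fit.model_id, fit.estimates, t))
    resid = y - fitted
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_boot):
        y_star = np.clip(fitted + rng.choice(resid, size=len(resid), replace=True), 0.0, None)
        try:
            refit = fit_tac(np.column_stack([t, y_star]), fit.model_id, init=fit.estimates)
        except ValidationError:
            continue
        if refit.converged:
            aucs.append(refit.auc)
    if len(aucs) < 2:
        raise ValidationError("bootstrap produced fewer than 2 successful refits")
    return float(np.std(aucs, ddof=1)) * scale


@dataclass(frozen=True)
class DoseEntry:
    """Per-organ dose line: the building block of the dose table."""

    organ: str
    model_id: ModelId
    auc: float  # %ID*h/g, decay-uncorrected scale
    dose_per_mbq: float  # Gy/MBq
    se: float  # Gy/MBq
    converged: bool
    n_points: int


@dataclass(frozen=True, eq=False)
class DoseTable:
    """Organ absorbed doses per unit injected activity, with provenance."""

    entries: tuple[DoseEntry, ...]
    nuclide: str
    energy_per_decay: float  # MeV
    provenance: dict = field(default_factory=dict)

    def to_frame(self, *, decimals: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "organ": [e.organ for e in self.entries],
                "model": [e.model_id for e in self.entries],
                "auc_pct_id_h_per_g": [e.auc for e in self.entries],
                "dose_gy_per_mbq": [e.dose_per_mbq for e in self.entries],
                "se_gy_per_mbq": [e.se for e in self.entries],
                "converged": [e.converged for e in self.entries],
            }
        )
        if decimals is not None:
            for col in ("dose_gy_per_mbq", "se_gy_per_mbq"):
                df[col] = df[col].round(decimals)
        return df

    def dose_at(self, injected_mbq: float, *, decimals: int | None = None) -> pd.DataFrame:
        """Per-organ dose in Gy at a given injected activity."""
        df = self.to_frame()[["organ", "dose_gy_per_mbq"]].copy()
        df["dose_gy"] = [
            dose_at_activity(d, injected_mbq, decimals=decimals)
            for d in df["dose_gy_per_mbq"]
        ]
        return df


def build_dose_table(
    table: BiodistTable,
    chain: NuclideChain,
    mapping: dict[str, ModelId] | None = None,
    *,
    fit_means: bool = True,
    se_method: Literal["delta", "bootstrap"] = "delta",
    seed: int | None = None,
    energy_override: float | None = None,
) -> DoseTable:
    """End-to-end organ dosimetry from a biodistribution table.

    Converts the table to the decay-uncorrected scale, fits each organ's
    assigned model (to per-timepoint means by default, or to all animal
    points), integrates analytically and maps AUC to Gy/MBq with the
    chain's branching-weighted alpha energy. Whole-organ (%ID) records —
    neck/thyroid — are excluded from per-gram dosimetry. Organ fit failures
    are flagged in their entry; the table is still produced. Deterministic
    for fixed inputs and seed.
    """
    lam_phys = decay_constant(chain.half_life)
    if table.uniform_decay_flag is None:
        raise ValidationError("table mixes decay-correction states")
    uncorr = set_decay_correction(table, lam_phys, target_corrected=False)
    energy = energy_override if energy_override is not None else mean_alpha_energy_per_decay(chain)

    df = uncorr.records
    dose_organs = [
        o for o in sorted(df["organ"].unique()) if o.lower() not in WHOLE_ORGAN_LABELS
    ]
    entries: list[DoseEntry] = []
    for organ in dose_organs:
        if fit_means:
            means = summarize(
                BiodistTable(records=df[df["organ"] == organ].reset_index(drop=True))
            )
            pts = means[["time_h", "mean"]].to_numpy()
        else:
            pts = uncorr.organ_points(organ).to_numpy()
        model_id = choose_model(organ, mapping)
        try:
            fit = fit_tac(pts, model_id)
            auc = fit.auc
            dose = dose_per_unit_activity(auc, energy)
            se = dose_uncertainty(fit, energy, se_method, points=pts, seed=seed)
            entries.append(
                DoseEntry(organ, model_id, auc, dose, se, fit.converged, fit.n_points)
            )
        except ValidationError as exc:
            log.warning("dose fit failed for %s: %s", organ, exc)
            entries.append(
                DoseEntry(organ, model_id, float("nan"), float("nan"), float("nan"), False, len(pts))
            )
    return DoseTable(
        entries=tuple(entries),
        nuclide=chain.nuclide,
        energy_per_decay=energy,
        provenance={
            "half_life_h": chain.half_life,
            "lambda_phys_per_h": lam_phys,
            "fit_means": fit_means,
            "se_method": se_method,
            "seed": seed,
        },
    )
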