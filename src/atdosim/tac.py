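"""Time-activity curve (TAC) models, least-squares fitting and analytic AUC.

Two fixed model forms describe organ kinetics on the decay-uncorrected
scale:

* monoexponential   f(t) = A0 * exp(-lam * t)           (washout organs)
* biexponential     f(t) = A1 * [exp(-lam1*t) - exp(-lam2*t)], lam2 > lam1
                    (organs with uptake then washout, e.g. from
                    dehalogenation: gut, skin, stomach)

The constraint lam2 > lam1 keeps the biexponential non-negative with a
single peak at t* = ln(lam2/lam1)/(lam2 - lam1). Time-integrated activity
is the closed-form integral over [0, inf):

* monoexp  AUC = A0 / lam
* biexp    AUC = A1 * (1/lam1 - 1/lam2)

in %ID*h/g. Models are assigned to organs a priori by a shipped mapping,
not selected by information criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .errors import ConfigError, ValidationError

__all__ = [
    "ModelId",
    "TACFit",
    "eval_model",
    "analytic_auc",
    "auc_gradient",
    "fit_tac",
    "choose_model",
    "load_organ_models",
    "biexp_peak_time",
]

log = logging.getLogger(__name__)

ModelId = Literal["monoexp", "biexp"]

_N_PARAMS = {"monoexp": 2, "biexp": 3}
PARAM_NAMES = {"monoexp": ("A0", "lam"), "biexp": ("A1", "lam1", "lam2")}

#: box bounds applied to every fitted parameter
_LO, _HI = 1e-6, 1e4


def _check_params(model_id: ModelId, params: Sequence[float]) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if p.shape != (_N_PARAMS[model_id],):
        raise ValidationError(
            f"{model_id} takes {_N_PARAMS[model_id]} parameters, got {p.shape}"
        )
    if not np.all(p > 0):
        raise ValidationError(f"{model_id} parameters must all be positive: {p}")
    if model_id == "biexp" and p[2] <= p[1]:
        raise ValidationError(f"biexp requires lam2 > lam1, got lam1={p[1]}, lam2={p[2]}")
    return p


def eval_model(model_id: ModelId, params: Sequence[float], t) -> np.ndarray | float:
    """Evaluate the model at time(s) ``t`` (hours), returning %ID/g."""
    p = _check_params(model_id, params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("model evaluation requires t >= 0")
    if model_id == "monoexp":
        out = p[0] * np.exp(-p[1] * t_arr)
    else:
        out = p[0] * (np.exp(-p[1] * t_arr) - np.exp(-p[2] * t_arr))
    return out if out.ndim else float(out)


def analytic_auc(model_id: ModelId, params: Sequence[float]) -> float:
    """Closed-form area under the model curve over t in [0, inf), %ID*h/g."""
    p = _check_params(model_id, params)
    if model_id == "monoexp":
        return p[0] / p[1]
    return p[0] * (1.0 / p[1] - 1.0 / p[2])


def auc_gradient(model_id: ModelId, params: Sequence[float]) -> np.ndarray:
    """Gradient of :func:`analytic_auc` w.r.t. the parameter vector."""
    p = _check_params(model_id, params)
    if model_id == "monoexp":
        a0, lam = p
        return np.array([1.0 / lam, -a0 / lam**2])
    a1, l1, l2 = p
    return np.array([1.0 / l1 - 1.0 / l2, -a1 / l1**2, a1 / l2**2])


def biexp_peak_time(lam1: float, lam2: float) -> float:
    """Peak time of the biexponential, ln(lam2/lam1)/(lam2 - lam1)."""
    if lam2 <= lam1:
        raise ValidationError("biexp requires lam2 > lam1")
    return float(np.log(lam2 / lam1) / (lam2 - lam1))


@dataclass(frozen=True)
class TACFit:
    """Result of fitting a TAC model to (t, value) points.

    ``covariance`` is the Gauss-Newton parameter covariance
    sigma^2 (J'J)^-1 with sigma^2 = RSS/(n - p); it is the basis of the
    delta-method dose uncertainty.
    """

    model_id: ModelId
    estimates: np.ndarray
    covariance: np.ndarray
    rmse: float
    n_points: int
    converged: bool
    message: str = ""

    @property
    def auc(self) -> float:
        return analytic_auc(self.model_id, self.estimates)

    @property
    def auc_se(self) -> float:
        g = auc_gradient(self.model_id, self.estimates)
        var = float(g @ self.covariance @ g)
        return float(np.sqrt(max(var, 0.0)))

    @property
    def param_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def _init_monoexp(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Log-linear regression start for the monoexponential."""
    pos = y > 0
    if pos.sum() >= 2 and len(np.unique(t[pos])) >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        a0 = float(np.exp(intercept))
        lam = float(max(-slope, 1e-4))
    else:
        a0 = float(max(y.max(), 1e-3))
        lam = 0.1
    return np.clip([a0, lam], _LO, _HI)


def _init_biexp(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coarse grid over (lam1, lam2/lam1), A1 matched to the observed peak."""
    y_peak = float(max(y.max(), 1e-6))
    best, best_sse = None, np.inf
    for lam1 in (0.02, 0.05, 0.1, 0.3):
        for ratio in (5.0, 10.0, 50.0):
            lam2 = lam1 * ratio
            peak_val = eval_model("biexp", [1.0, lam1, lam2], biexp_peak_time(lam1, lam2))
            a1 = y_peak / float(peak_val)
            pred = eval_model("biexp", [a1, lam1, lam2], t)
            sse = float(np.sum((y - pred) ** 2))
            if sse < best_sse:
                best, best_sse = np.array([a1, lam1, lam2]), sse
    return np.clip(best, _LO, _HI)


def fit_tac(
    points: Sequence[tuple[float, float]] | np.ndarray,
    model_id: ModelId,
    *,
    init: Sequence[float] | None = None,
    bounds: tuple[float, float] = (_LO, _HI),
    weights: Sequence[float] | None = None,
) -> TACFit:
    """Weighted least-squares fit of a TAC model.

    The biexponential is fitted in the reparameterisation
    (A1, lam1, delta = lam2 - lam1) with delta > 0, which enforces the
    lam2 > lam1 ordering as a simple box bound. Non-convergence is reported
    through the ``converged`` flag, not an exception; too few distinct
    timepoints raise :class:`ValidationError`. Deterministic given identical
    inputs and start.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be a sequence of (t, value) pairs")
    order = np.argsort(pts[:, 0], kind="stable")
    t, y = pts[order, 0], pts[order, 1]
    n_par = _N_PARAMS[model_id]
    if len(np.unique(t)) < n_par:
        raise ValidationError(
            f"{model_id} needs >= {n_par} distinct timepoints, got {len(np.unique(t))}"
        )
    if np.any(y < 0):
        raise ValidationError("TAC values must be non-negative")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float)[order])

    if init is None:
        x0 = _init_monoexp(t, y) if model_id == "monoexp" else _init_biexp(t, y)
    else:
        x0 = _check_params(model_id, init)
    lo, hi = bounds

    if model_id == "biexp":  # internal coords: (A1, lam1, delta)
        x0_int = np.array([x0[0], x0[1], x0[2] - x0[1]])

        def to_model(x: np.ndarray) -> np.ndarray:
            return np.array([x[0], x[1], x[1] + x[2]])

    else:
        x0_int = x0

        def to_model(x: np.ndarray) -> np.ndarray:
            return x

    x0_int = np.clip(x0_int, lo * (1 + 1e-9), hi * (1 - 1e-9))

    def residuals(x: np.ndarray) -> np.ndarray:
        return w * (eval_model(model_id, to_model(x), t) - y)

    res = least_squares(residuals, x0_int, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    est = to_model(res.x)

    dof = max(len(y) - n_par, 1)
    sigma2 = float(np.sum(res.fun**2)) / dof
    jtj = res.jac.T @ res.jac
    try:
        cov_int = sigma2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov_int = sigma2 * np.linalg.pinv(jtj)
    if model_id == "biexp":
        tmat = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        cov = tmat @ cov_int @ tmat.T
    else:
        cov = cov_int
    cov = (cov + cov.T) / 2.0

    rmse = float(np.sqrt(np.mean((eval_model(model_id, est, t) - y) ** 2)))
    if not res.success:
        log.warning("TAC fit (%s) did not converge: %s", model_id, res.message)
    return TACFit(
        model_id=model_id,
        estimates=est,
        covariance=cov,
        rmse=rmse,
        n_points=len(y),
        converged=bool(res.success),
        message=res.message,
    )


def load_organ_models(path: str | Path | None = None) -> dict[str, ModelId]:
    """Load the organ -> model assignment (defaults to the shipped map)."""
    if path is None:
        text = resources.files("atdosim.data").joinpath("organ_models.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    mapping: dict[str, ModelId] = {}
    for model_id, organs in raw.items():
        if model_id not in _N_PARAMS:
            raise ConfigError(f"unknown model id {model_id!r} in organ map")
        for organ in organs:
            mapping[str(organ).strip().lower()] = model_id  # type: ignore[assignment]
    return mapping


def choose_model(
    organ: str,
    mapping: dict[str, ModelId] | None = None,
    *,
    default: ModelId | None = None,
) -> ModelId:
    """Model assignment for an organ; strict (error) unless a default is given."""
    mapping = load_organ_models() if mapping is None else mapping
    key = organ.strip().lower()
    if key in mapping:
        return mapping[key]
    if default is not None:
        return default
    raise ConfigError(f"no TAC model assigned for organ {organ!r}")
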