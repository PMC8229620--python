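"""Goodness-of-fit metrics and the held-out-temperature validation protocol.

All metrics are computed from residuals (observed − predicted):

* R² = 1 − SSE/SST, SST about the observed mean (pooled over all pairs);
* adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) for p model parameters;
* RMSE = sqrt(SSE/n), in SH percent units;
* CV% = 100 · RMSE / mean(observed).

External validation evaluates fitted per-treatment predictors on a dataset at
a temperature withheld from fitting (12 °C in the study design) and pools the
residuals across treatments into one report per model family, with
per-treatment sub-reports attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_io import KineticDataset
from .tempmodels import ArrheniusModel, LogLogisticModel, predict_sh


class ValidationError(Exception):
    pass


class InputError(ValidationError):
    """Observed/predicted sequences unusable (length mismatch, too short)."""


class UndefinedMetricError(ValidationError):
    """A metric is undefined for this input (zero variance or zero mean)."""


class MissingModelError(ValidationError):
    """A treatment in the holdout has no fitted model."""


@dataclass(frozen=True)
class ValidationReport:
    """Pooled observed-vs-predicted metrics for one model family."""

    model_name: str
    n: int
    r2: float
    adj_r2: float
    rmse: float
    cv_percent: float
    residuals: np.ndarray
    per_treatment: Mapping[str, "ValidationReport"] | None = None

    def to_dict(self) -> dict:
        out = {
            "model_name": self.model_name,
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "cv_percent": self.cv_percent,
        }
        if self.per_treatment:
            out["per_treatment"] = {t: r.to_dict() for t, r in self.per_treatment.items()}
        return out


def score(
    observed: Sequence[float],
    predicted: Sequence[float],
    n_params: int = 0,
    model_name: str = "",
) -> ValidationReport:
    """Score a predicted series against observations.

    Requires equal lengths >= 2 and n_params < n.  Raises
    :class:`UndefinedMetricError` when the observed series has zero variance
    (R² undefined) or zero mean (CV undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InputError("observed and predicted must be 1-D and equal length")
    n = len(obs)
    if n < 2:
        raise InputError(f"need >= 2 pairs, got {n}")
    if n_params >= n:
        raise InputError(f"n_params={n_params} must be < n={n}")
    resid = obs - pred
    sse = float(np.sum(resid**2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("observed series has zero variance; R² undefined")
    mean_obs = float(obs.mean())
    if mean_obs == 0.0:
        raise UndefinedMetricError("observed mean is zero; CV% undefined")
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    rmse = float(np.sqrt(sse / n))
    return ValidationReport(
        model_name=model_name,
        n=n,
        r2=float(r2),
        adj_r2=float(adj_r2),
        rmse=rmse,
        cv_percent=100.0 * rmse / abs(mean_obs),
        residuals=resid,
    )


PredictorMap = Mapping[str, "ArrheniusModel | LogLogisticModel | Callable"]


def _predict(model, time_d: np.ndarray, temperature_C: float) -> np.ndarray:
    if isinstance(model, (ArrheniusModel, LogLogisticModel)):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            return np.asarray(predict_sh(model, temperature_C, time_d))
    if callable(model):
        return np.asarray(model(time_d, temperature_C), dtype=float)
    raise TypeError(f"unsupported predictor type {type(model)!r}")


def external_validation(
    model_families: Mapping[str, PredictorMap],
    holdout: KineticDataset,
    *,
    n_params: int | Mapping[str, int] = 2,
    include_day0: bool = True,
) -> dict[str, ValidationReport]:
    """Validate fitted predictors on data at a held-out temperature.

    ``model_families`` maps a family name (e.g. ``"loglogistic"``) to a
    per-treatment mapping of predictors — fitted secondary models or callables
    ``f(time_days, temperature_C) -> SH``.  Every treatment present in the
    holdout must have a predictor in every family.  Returns one pooled report
    per family (SST about the pooled observed mean) with per-treatment
    sub-reports; per-treatment reports are omitted where their metrics are
    undefined (e.g. < 2 pairs).
    """
    frame = holdout.frame
    if not include_day0:
        frame = frame[frame["time_d"] > 0]
    if frame.empty:
        raise InputError("holdout dataset is empty")

    reports: dict[str, ValidationReport] = {}
    for family, models in model_families.items():
        missing = sorted(set(frame["treatment"]) - set(models))
        if missing:
            raise MissingModelError(f"family {family!r} lacks models for treatments {missing}")
        obs_all, pred_all = [], []
        per_treatment: dict[str, ValidationReport] = {}
        p = n_params[family] if isinstance(n_params, Mapping) else n_params
        for treatment, sub in frame.groupby("treatment", sort=True):
            preds = np.concatenate(
                [
                    _predict(models[treatment], grp["time_d"].to_numpy(), float(T))
                    for T, grp in sub.groupby("temperature_C", sort=True)
                ]
            )
            obs = np.concatenate(
                [grp["sh_percent"].to_numpy() for _, grp in sub.groupby("temperature_C", sort=True)]
            )
            obs_all.append(obs)
            pred_all.append(preds)
            try:
                per_treatment[treatment] = score(obs, preds, n_params=p,
                                                 model_name=f"{family}:{treatment}")
            except ValidationError:
                pass
        obs_cat = np.concatenate(obs_all)
        pred_cat = np.concatenate(pred_all)
        pooled = score(obs_cat, pred_cat, n_params=p, model_name=family)
        reports[family] = ValidationReport(
            model_name=pooled.model_name,
            n=pooled.n,
            r2=pooled.r2,
            adj_r2=pooled.adj_r2,
            rmse=pooled.rmse,
            cv_percent=pooled.cv_percent,
            residuals=pooled.residuals,
            per_treatment=per_treatment,
        )
    return reports


def summary_table(reports: Mapping[str, ValidationReport]):
    """Tabular export mirroring the validation footer: model,r2,rmse,cv_percent."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"model": name, "r2": r.r2, "rmse": r.rmse, "cv_percent": r.cv_percent}
            for name, r in reports.items()
        ]
    )
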