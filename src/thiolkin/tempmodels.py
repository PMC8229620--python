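"""Secondary models: temperature dependence of the zero-order SH loss rate.

Two models are supported:

* Arrhenius: k(T) = k0 · exp(−Ea / (R·T_K)), with Ea the activation energy
  (kJ/mol) interpreted here as temperature sensitivity of SH loss, and k0 the
  pre-exponential factor (day⁻¹).  Fitted either on the linearized form
  ln k = ln k0 − Ea/(R·T) by closed-form OLS, or by Levenberg–Marquardt
  nonlinear least squares initialized from the linearized solution.

* Log-logistic: k(T) = m′ · softplus(c·(T − Tc)) with m′ fixed at 1,
  c (°C⁻¹) > 0 and Tc (°C).  The softplus ramp is near 0 well below Tc and
  asymptotically linear with slope c above it, so no activation-energy concept
  is needed.  Internal sign convention: the rate must increase with
  temperature, which for this dataset puts Tc below the fitted range
  (typically negative).

Combined with the zero-order primary model these give the full predictors
SH(t, T) = SH0 − k(T)·t evaluated by :func:`predict_sh`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

#: Universal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

#: Celsius → Kelvin offset matching the study's temperature grid (4 °C ↔ 277 K).
KELVIN_OFFSET = 273.0

#: Temperature range (°C) covered by the training design.
FITTED_RANGE_C = (4.0, 20.0)


class TempModelError(Exception):
    """Base class for secondary-model errors."""


class TempDomainError(TempModelError):
    """Rates or temperatures outside the model's domain (e.g. k <= 0)."""


class SingularDesignError(TempModelError):
    """All temperatures identical: temperature dependence not identifiable."""


class ConvergenceError(TempModelError):
    """Nonlinear least squares failed to converge."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted temperature range."""


class NegativePredictionWarning(UserWarning):
    """Predicted SH fell below 0 % (no clamping is applied)."""


def softplus(x):
    """Overflow-safe ln(1 + exp(x)); asymptotes to x for large x and 0 for large −x."""
    return np.logaddexp(0.0, np.asarray(x, dtype=float))


def celsius_to_kelvin(temperature_C):
    return np.asarray(temperature_C, dtype=float) + KELVIN_OFFSET


@dataclass(frozen=True)
class ArrheniusModel:
    """Fitted Arrhenius temperature dependence for one treatment.

    ``ea`` is stored in kJ/mol (converted to J/mol internally), ``k0`` in
    day⁻¹.  ``se_ea`` is the regression standard error of ea in kJ/mol.
    """

    treatment: str
    k0: float
    ea: float
    r2: float
    se_ea: float
    method: str = "linearized"

    def rate(self, temperature_C):
        T = celsius_to_kelvin(temperature_C)
        return self.k0 * np.exp(-self.ea * 1000.0 / (R_GAS * T))


@dataclass(frozen=True)
class LogLogisticModel:
    """Fitted log-logistic (softplus) temperature dependence for one treatment.

    rate(T) = mprime · ln(1 + exp(c·(T − tc))) with mprime pinned at 1.
    ``tc`` follows the internal convention under which the rate increases
    with temperature (tc typically negative for this dataset).
    """

    treatment: str
    c: float
    tc: float
    r2: float
    mprime: float = 1.0
    warning: str | None = None

    def rate(self, temperature_C):
        T = np.asarray(temperature_C, dtype=float)
        return self.mprime * softplus(self.c * (T - self.tc))


def fit_arrhenius(
    temperatures_K: Sequence[float],
    rates: Sequence[float],
    method: str = "linearized",
    *,
    treatment: str = "",
) -> ArrheniusModel:
    """Fit k = k0·exp(−Ea/(R·T)) to (temperature K, rate) pairs.

    ``linearized`` regresses ln k on 1/T by closed-form OLS: slope = −Ea/R,
    intercept = ln k0.  ``nonlinear`` runs Levenberg–Marquardt on the
    exponential form (parameters ln k0 and Ea), initialized from the
    linearized solution.  Ea is returned in kJ/mol.
    """
    T = np.asarray(temperatures_K, dtype=float)
    k = np.asarray(rates, dtype=float)
    if len(T) < 3:
        raise TempModelError(f"need >= 3 (T, k) pairs, got {len(T)}")
    if (k <= 0).any():
        raise TempDomainError("all rate constants must be positive")
    if (T <= 0).any():
        raise TempDomainError("absolute temperatures must be positive")
    if len(np.unique(T)) < 2:
        raise SingularDesignError("all temperatures identical")
    if method not in ("linearized", "nonlinear"):
        raise TempModelError(f"unknown method {method!r}")

    x = 1.0 / T
    y = np.log(k)
    slope, intercept = np.polyfit(x, y, 1)
    ln_k0, ea_j = float(intercept), float(-slope * R_GAS)

    if method == "nonlinear":
        def residuals(p):
            return np.exp(p[0] - p[1] / (R_GAS * T)) - k

        sol = least_squares(residuals, x0=[ln_k0, ea_j], method="lm",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
        if not sol.success:
            raise ConvergenceError(
                f"Levenberg–Marquardt did not converge after {sol.nfev} evaluations; "
                f"last residual norm {np.linalg.norm(sol.fun):.3g}"
            )
        ln_k0, ea_j = float(sol.x[0]), float(sol.x[1])
        resid = sol.fun
        sst = float(np.sum((k - k.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        # SE of ea from the Gauss-Newton covariance at the solution
        dof = max(len(k) - 2, 1)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * float(np.sum(resid**2)) / dof
            se_ea = float(np.sqrt(max(cov[1, 1], 0.0))) / 1000.0
        except np.linalg.LinAlgError:
            se_ea = float("nan")
    else:
        yhat = intercept + slope * x
        sse = float(np.sum((y - yhat) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        dof = max(len(k) - 2, 1)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_slope = np.sqrt(sse / dof / sxx) if sxx > 0 else float("nan")
        se_ea = float(se_slope * R_GAS) / 1000.0

    return ArrheniusModel(
        treatment=treatment,
        k0=float(np.exp(ln_k0)),
        ea=ea_j / 1000.0,
        r2=float(r2),
        se_ea=se_ea,
        method=method,
    )


def _loglogistic_init(T: np.ndarray, k: np.ndarray) -> tuple[float, float]:
    # slope of k vs T between the two highest temperatures; tc = T-intercept
    order = np.argsort(T)
    T2, T1 = T[order[-1]], T[order[-2]]
    k2, k1 = k[order[-1]], k[order[-2]]
    c0 = (k2 - k1) / (T2 - T1) if T2 != T1 else 0.5
    if not np.isfinite(c0) or c0 <= 0:
        c0 = 0.5
    tc0 = T2 - k2 / c0
    return float(c0), float(tc0)


def fit_loglogistic(
    temperatures_C: Sequence[float],
    rates: Sequence[float],
    *,
    treatment: str = "",
) -> LogLogisticModel:
    """Fit k = softplus(c·(T − tc)) (m′ = 1) by Levenberg–Marquardt.

    Initialization uses the line through the rates at the two highest
    temperatures (deep in the linear regime of the softplus).  c is kept
    positive by optimizing ln c.  Non-monotone rate sequences are fitted
    anyway but flagged in the returned model's ``warning`` field.
    """
    T = np.asarray(temperatures_C, dtype=float)
    k = np.asarray(rates, dtype=float)
    if len(T) < 3:
        raise TempModelError(f"need >= 3 (T, k) pairs, got {len(T)}")
    if (k <= 0).any():
        raise TempDomainError("all rate constants must be positive")
    if len(np.unique(T)) < 2:
        raise SingularDesignError("all temperatures identical")

    c0, tc0 = _loglogistic_init(T, k)

    def residuals(p):
        return softplus(np.exp(p[0]) * (T - p[1])) - k

    sol = least_squares(residuals, x0=[np.log(c0), tc0], method="lm",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
    if not sol.success:
        raise ConvergenceError(
            f"Levenberg–Marquardt did not converge after {sol.nfev} evaluations; "
            f"last residual norm {np.linalg.norm(sol.fun):.3g}"
        )
    c, tc = float(np.exp(sol.x[0])), float(sol.x[1])
    sst = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 - float(np.sum(sol.fun**2)) / sst if sst > 0 else 1.0

    warning = None
    order = np.argsort(T)
    if np.any(np.diff(k[order]) < 0):
        warning = "rates are not monotone increasing in temperature"
    return LogLogisticModel(treatment=treatment, c=c, tc=tc, r2=float(r2), warning=warning)


def rate_at(model: ArrheniusModel | LogLogisticModel, temperature_C: float):
    """Evaluate the fitted rate (day⁻¹) at a storage temperature in °C."""
    return model.rate(temperature_C)


def predict_sh(
    model: ArrheniusModel | LogLogisticModel,
    temperature_C: float,
    time_d,
    sh0: float = 100.0,
):
    """Combined predictor SH(t, T) = sh0 − rate(T)·t.

    Returns ``sh0`` exactly at t = 0.  Predictions are not clamped at 0, but
    a :class:`NegativePredictionWarning` is emitted when they fall below 0,
    and an :class:`ExtrapolationWarning` when T is outside the fitted range.
    """
    t = np.asarray(time_d, dtype=float)
    if (t < 0).any():
        raise TempDomainError("negative storage time")
    lo, hi = FITTED_RANGE_C
    if temperature_C < lo or temperature_C > hi:
        warnings.warn(
            f"predicting at {temperature_C} °C, outside the fitted range [{lo}, {hi}] °C",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = sh0 - rate_at(model, temperature_C) * t
    if (np.asarray(out) < 0).any():
        warnings.warn("predicted SH fell below 0 %", NegativePredictionWarning, stacklevel=2)
    return out if np.ndim(time_d) else float(out)


def models_from_table1(params=None) -> tuple[dict[str, ArrheniusModel], dict[str, LogLogisticModel]]:
    """Build per-treatment models from the packaged parameter table.

    Applies the fixture's Tc sign convention: ``negated`` (and, by default,
    ``unverifiable``) treatments use tc = −(printed magnitude); ``as_printed``
    keeps the printed sign.  Returns ({treatment: ArrheniusModel},
    {treatment: LogLogisticModel}).
    """
    if params is None:
        from .data_io import load_fixture

        params = load_fixture("table1_params")
    arrhenius: dict[str, ArrheniusModel] = {}
    loglogistic: dict[str, LogLogisticModel] = {}
    for row in params.itertuples(index=False):
        arrhenius[row.treatment] = ArrheniusModel(
            treatment=row.treatment,
            k0=float(row.k0_per_day),
            ea=float(row.ea_kJ_per_mol),
            r2=float(row.r2_arrhenius),
            se_ea=float(row.ea_sd),
            method="linearized",
        )
        tc = float(row.tc_printed_C)
        if row.tc_sign in ("negated", "unverifiable"):
            tc = -tc
        loglogistic[row.treatment] = LogLogisticModel(
            treatment=row.treatment,
            c=float(row.c_per_C),
            tc=tc,
            r2=float(row.r2_loglogistic),
            warning=("published predictions match neither Tc sign"
                     if row.tc_sign == "unverifiable" else None),
        )
    return arrhenius, loglogistic
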