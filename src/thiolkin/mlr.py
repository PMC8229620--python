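"""Dummy-coded multiple linear regression ranking antioxidant treatments.

The model is SH = β0 + βt·t + βT·T + Σe βe·I(treatment = e) + ε, where the
untreated control is the uncoded reference level: each treatment coefficient
βe is the average SH difference between extract e and the control across all
storage times and temperatures.  A larger βe means less thiol loss, i.e. a
stronger antioxidant effect in the meat matrix.  Coefficient significance is
assessed with two-sided t-tests on the OLS standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import KineticDataset


class MLRError(Exception):
    pass


class DesignError(MLRError):
    """Rank-deficient design matrix; the message names the collinear columns."""


class InsufficientDataError(MLRError):
    pass


@dataclass(frozen=True)
class MLRResult:
    """OLS fit of the dummy-coded treatment model.

    ``treatment_coefs`` has one row per non-reference treatment with columns
    ``beta`` (SH percent vs control), ``se``, ``t`` and ``p`` (two-sided).
    """

    intercept: float
    coef_time: float
    coef_temperature: float
    treatment_coefs: pd.DataFrame
    n: int
    r2: float
    reference: str
    resid_var: float
    base_pvalues: Mapping[str, float] = field(default_factory=dict, repr=False)

    def to_table(self) -> pd.DataFrame:
        """Export ``term,beta,p_value`` rows: treatments by descending β, then
        time, temperature and the intercept."""
        rows = [
            {"term": t, "beta": float(r.beta), "p_value": float(r.p)}
            for t, r in self.treatment_coefs.iterrows()
        ]
        rows.sort(key=lambda r: (-r["beta"], r["term"]))
        rows.append({"term": "time", "beta": self.coef_time,
                     "p_value": self.base_pvalues.get("time_d", float("nan"))})
        rows.append({"term": "temperature", "beta": self.coef_temperature,
                     "p_value": self.base_pvalues.get("temperature_C", float("nan"))})
        rows.append({"term": "intercept", "beta": self.intercept,
                     "p_value": self.base_pvalues.get("const", float("nan"))})
        return pd.DataFrame(rows)


def build_design(dataset: KineticDataset, reference: str = "control") -> tuple[pd.DataFrame, pd.Series]:
    """Build the design matrix and response for the dummy-coded model.

    Columns: ``const`` (intercept), ``time_d``, ``temperature_C``, then one
    0/1 indicator per non-reference treatment in alphabetical order.  The
    reference level is uncoded.  Raises :class:`DesignError` on rank
    deficiency, naming the collinear columns.
    """
    frame = dataset.frame
    treatments = dataset.treatments
    if reference not in treatments:
        raise MLRError(f"reference treatment {reference!r} not present in dataset")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "time_d": frame["time_d"].to_numpy(),
            "temperature_C": frame["temperature_C"].to_numpy(),
        }
    )
    for treatment in treatments:
        if treatment == reference:
            continue
        X[treatment] = (frame["treatment"] == treatment).astype(float).to_numpy()
    y = pd.Series(frame["sh_percent"].to_numpy(), name="sh_percent")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for col in X.columns:
            reduced = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(col)
        raise DesignError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X, y


def fit_mlr(design: pd.DataFrame, response: pd.Series, *, reference: str = "control") -> MLRResult:
    """Ordinary least squares on a design from :func:`build_design`."""
    n, p = design.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} observations but p={p} parameters")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < p:
        raise DesignError("design matrix is rank deficient")

    fit = sm.OLS(response.to_numpy(), design).fit()
    treatment_cols = [c for c in design.columns if c not in ("const", "time_d", "temperature_C")]
    coefs = pd.DataFrame(
        {
            "beta": fit.params[treatment_cols],
            "se": fit.bse[treatment_cols],
            "t": fit.tvalues[treatment_cols],
            "p": fit.pvalues[treatment_cols],
        }
    )
    return MLRResult(
        intercept=float(fit.params["const"]),
        coef_time=float(fit.params["time_d"]),
        coef_temperature=float(fit.params["temperature_C"]),
        treatment_coefs=coefs,
        n=n,
        r2=float(fit.rsquared),
        reference=reference,
        resid_var=float(fit.mse_resid) if n > p else 0.0,
        base_pvalues={
            "const": float(fit.pvalues["const"]),
            "time_d": float(fit.pvalues["time_d"]),
            "temperature_C": float(fit.pvalues["temperature_C"]),
        },
    )


def fit_treatment_effects(
    dataset: KineticDataset,
    reference: str = "control",
    *,
    temperatures: Sequence[float] | None = None,
    bonferroni: bool = False,
) -> MLRResult:
    """Convenience wrapper: build the design and fit in one step.

    ``temperatures`` restricts the rows (default: all, including the external
    validation temperature).  With ``bonferroni`` the treatment p-values are
    multiplied by the number of treatment coefficients (capped at 1).
    """
    data = dataset if temperatures is None else dataset.subset(temperatures=temperatures)
    X, y = build_design(data, reference)
    result = fit_mlr(X, y, reference=reference)
    if bonferroni:
        m = len(result.treatment_coefs)
        adj = result.treatment_coefs.copy()
        adj["p"] = np.minimum(adj["p"] * m, 1.0)
        result = MLRResult(
            intercept=result.intercept,
            coef_time=result.coef_time,
            coef_temperature=result.coef_temperature,
            treatment_coefs=adj,
            n=result.n,
            r2=result.r2,
            reference=reference,
            resid_var=result.resid_var,
            base_pvalues=result.base_pvalues,
        )
    return result


def rank_extracts(result: MLRResult) -> list[tuple[str, float, float]]:
    """Treatments ordered by descending β (ties broken alphabetically).

    Returns a list of (treatment, beta, p).  The top entries are the extracts
    that best preserved SH relative to the control.
    """
    items = [
        (treatment, float(row.beta), float(row.p))
        for treatment, row in result.treatment_coefs.iterrows()
    ]
    items.sort(key=lambda item: (-item[1], item[0]))
    return items
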