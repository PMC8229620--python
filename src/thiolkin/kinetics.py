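"""Zero-order (linear) decay fits of SH content per (treatment, temperature) group.

The primary kinetic model is zero order: SH(t) = SH0 − k·t with k ≥ 0 for a
decaying series.  Fits are ordinary least squares on the (time, SH) pairs of
one storage group; by default replicate measurements are averaged per time
point before fitting, which yields the same slope as fitting all points for a
balanced design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import KineticDataset


class FitError(Exception):
    """The design does not support the requested fit."""


class DegenerateDesignError(FitError):
    """All times identical: the slope is not identifiable."""


class MissingGroupError(FitError):
    """An expected (treatment, temperature) group has no data."""


class ConfigurationError(FitError):
    """Invalid fitting configuration (e.g. empty temperature selection)."""


@dataclass(frozen=True)
class ZeroOrderFit:
    """OLS fit of SH = sh0 − k·t for one (treatment, temperature) group.

    ``k`` is the loss rate in day⁻¹, reported as the negated slope so that a
    decaying series has k > 0.  ``order`` is the kinetic order, fixed at 0.
    """

    treatment: str
    temperature_C: float
    k: float
    sh0: float
    r2: float
    rmse: float
    n_points: int
    order: int = 0

    def predict(self, time_d) -> np.ndarray:
        return self.sh0 - self.k * np.asarray(time_d, dtype=float)


@dataclass(frozen=True)
class ZeroOrderFitResult:
    """All per-group fits plus metadata on skipped temperatures."""

    fits: tuple[ZeroOrderFit, ...]
    skipped_temperatures: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.fits)

    def __iter__(self):
        return iter(self.fits)

    def get(self, treatment: str, temperature_C: float) -> ZeroOrderFit:
        for fit in self.fits:
            if fit.treatment == treatment and fit.temperature_C == temperature_C:
                return fit
        raise MissingGroupError(f"no fit for ({treatment!r}, {temperature_C} °C)")

    def rate_table(self):
        """DataFrame export: treatment,temperature_C,k_per_day,sh0,r2,rmse,n_points."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "treatment": f.treatment,
                    "temperature_C": f.temperature_C,
                    "k_per_day": f.k,
                    "sh0": f.sh0,
                    "r2": f.r2,
                    "rmse": f.rmse,
                    "n_points": f.n_points,
                }
                for f in self.fits
            ]
        )


def fit_zero_order(
    times: Sequence[float],
    sh: Sequence[float],
    *,
    fix_intercept: bool = False,
    treatment: str = "",
    temperature_C: float = float("nan"),
) -> ZeroOrderFit:
    """Fit SH = sh0 − k·t to one group by closed-form OLS.

    With ``fix_intercept`` the intercept is pinned at 100 % (the normalized
    day-0 value) and only the slope is estimated.  Requires at least two
    distinct time points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(sh, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise FitError("times and sh must be 1-D sequences of equal length")
    if len(np.unique(t)) < 2:
        if len(t) >= 2 and np.ptp(y) == 0:
            raise DegenerateDesignError("all times and all sh values identical")
        raise FitError(f"need >= 2 distinct time points, got {len(np.unique(t))}")

    if fix_intercept:
        sh0 = 100.0
        slope = float(np.sum(t * (y - sh0)) / np.sum(t * t))
    else:
        slope, sh0 = np.polyfit(t, y, 1)
        slope, sh0 = float(slope), float(sh0)
    resid = y - (sh0 + slope * t)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        # zero-variance series: a perfect (numerically zero-residual) fit
        # scores 1, anything else is as uninformative as the mean predictor
        r2 = 1.0 if sse <= 1e-16 * max(1.0, float(np.sum(y**2))) else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return ZeroOrderFit(
        treatment=treatment,
        temperature_C=float(temperature_C),
        k=-slope,
        sh0=sh0,
        r2=r2,
        rmse=float(np.sqrt(sse / len(y))),
        n_points=len(y),
    )


def fit_all_groups(
    dataset: KineticDataset,
    temperatures: Sequence[float] | None = None,
    *,
    use_replicates: bool = False,
    fix_intercept: bool = False,
) -> ZeroOrderFitResult:
    """Fit every (treatment, temperature) group at the selected temperatures.

    ``temperatures`` selects the training subset (e.g. excluding the external
    validation temperature); groups at other temperatures present in the data
    are skipped and listed in ``skipped_temperatures``.  Every treatment in
    the dataset must have data at every selected temperature.
    """
    available = dataset.temperatures
    if temperatures is None:
        selected = list(available)
    else:
        selected = [float(T) for T in temperatures]
    if not selected:
        raise ConfigurationError("empty temperature selection")

    source = dataset.frame if use_replicates else dataset.replicate_means()
    fits = []
    for treatment in dataset.treatments:
        for T in selected:
            sub = source[(source["treatment"] == treatment) & (source["temperature_C"] == T)]
            if sub.empty:
                raise MissingGroupError(f"no data for group ({treatment!r}, {T} °C)")
            fits.append(
                fit_zero_order(
                    sub["time_d"].to_numpy(),
                    sub["sh_percent"].to_numpy(),
                    fix_intercept=fix_intercept,
                    treatment=treatment,
                    temperature_C=T,
                )
            )
    skipped = tuple(T for T in available if T not in selected)
    return ZeroOrderFitResult(fits=tuple(fits), skipped_temperatures=skipped)
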