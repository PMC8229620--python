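"""Long-format kinetic datasets of thiol (SH) content and packaged reference tables.

A kinetic dataset is a long-format table of SH measurements keyed by
``(treatment, temperature, time, replicate)``.  SH is expressed as percent of
the day-0 value, so every (treatment, temperature) group starts at 100 % by
construction after :func:`normalize_to_percent`.

The package ships two reference tables from the study design as plain CSV:
the per-treatment rate constants and fitted secondary-model parameters
(``table1_*``), and the observed/predicted SH series at the held-out 12 °C
storage temperature (``table4_*``).  See :func:`load_fixture`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Treatment vocabulary of the study design: untreated control plus 13 plant extracts.
STUDY_TREATMENTS: tuple[str, ...] = (
    "control",
    "allspice",
    "basil",
    "bay leaf",
    "black seed",
    "caraway",
    "cardamom",
    "clove",
    "garlic",
    "nutmeg",
    "onion",
    "oregano",
    "rosemary",
    "thyme",
)

#: Canonical CSV header for dataset interchange.
COLUMNS: tuple[str, ...] = ("treatment", "temperature_C", "time_d", "replicate", "sh_percent")

KEY_COLUMNS: tuple[str, ...] = ("treatment", "temperature_C", "time_d", "replicate")

FIXTURE_NAMES = ("table1_rates", "table1_params", "table4_observed", "table4_predicted")


class DataError(Exception):
    """Base class for dataset errors."""


class SchemaError(DataError):
    """A required column is missing or misnamed."""


class ParseError(DataError):
    """A cell could not be parsed as a number; the message names the file row."""


class IntegrityError(DataError):
    """Duplicate (treatment, temperature, time, replicate) keys."""


class NormalizationError(DataError):
    """A group cannot be normalized to percent-of-initial."""


class DomainError(DataError):
    """A value is outside its physically meaningful domain."""


class FixtureLookupError(DataError, KeyError):
    """Unknown packaged fixture name."""


@dataclass(frozen=True)
class KineticDataset:
    """Validated long-format SH measurements.

    Parameters
    ----------
    frame
        DataFrame with columns ``treatment`` (str), ``temperature_C`` (float),
        ``time_d`` (float, days, >= 0), ``replicate`` (int, >= 1) and
        ``sh_percent`` (float).  Row order is preserved.
    vocabulary
        Optional treatment vocabulary; when given, every label must belong to it.
    temperature_range
        Inclusive (low, high) bounds in °C that every temperature must satisfy.
    """

    frame: pd.DataFrame
    vocabulary: tuple[str, ...] | None = None
    temperature_range: tuple[float, float] = (-5.0, 40.0)

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        frame = frame.astype(
            {"treatment": str, "temperature_C": float, "time_d": float, "replicate": int, "sh_percent": float}
        )
        if (frame["time_d"] < 0).any():
            bad = frame.index[frame["time_d"] < 0][0]
            raise DomainError(f"negative time at row {bad}")
        lo, hi = self.temperature_range
        if ((frame["temperature_C"] < lo) | (frame["temperature_C"] > hi)).any():
            raise DomainError(f"temperature outside declared range [{lo}, {hi}] °C")
        if self.vocabulary is not None:
            unknown = sorted(set(frame["treatment"]) - set(self.vocabulary))
            if unknown:
                raise DomainError(f"treatment labels outside vocabulary: {unknown}")
        dup = frame.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = frame.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise IntegrityError(f"duplicate key {tuple(key)}")
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def treatments(self) -> list[str]:
        return sorted(self.frame["treatment"].unique())

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.frame["temperature_C"].unique())

    def groups(self) -> Iterator[tuple[tuple[str, float], pd.DataFrame]]:
        """Iterate over (treatment, temperature) groups in sorted key order."""
        for key, sub in self.frame.groupby(["treatment", "temperature_C"], sort=True):
            yield key, sub

    def subset(self, temperatures: Sequence[float] | None = None,
               treatments: Sequence[str] | None = None) -> "KineticDataset":
        """Restrict to the given temperatures and/or treatments."""
        frame = self.frame
        if temperatures is not None:
            frame = frame[frame["temperature_C"].isin(list(temperatures))]
        if treatments is not None:
            frame = frame[frame["treatment"].isin(list(treatments))]
        return KineticDataset(frame.reset_index(drop=True), self.vocabulary, self.temperature_range)

    def replicate_means(self) -> pd.DataFrame:
        """Mean SH per (treatment, temperature, time), averaging replicates."""
        return (
            self.frame.groupby(["treatment", "temperature_C", "time_d"], sort=True)["sh_percent"]
            .mean()
            .reset_index()
        )


def read_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    vocabulary: Sequence[str] | None = None,
    temperature_range: tuple[float, float] = (-5.0, 40.0),
) -> KineticDataset:
    """Read a long-format kinetic dataset from CSV.

    ``schema`` maps canonical column names (:data:`COLUMNS`) to the names used
    in the file; unmapped names are taken as-is.  The ``replicate`` column is
    optional and defaults to 1.  Malformed numeric cells raise
    :class:`ParseError` naming the offending file line (header = line 1).
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {schema.get(c, c): c for c in COLUMNS}  # file name -> canonical name
    raw = raw.rename(columns={src: dst for src, dst in rename.items() if src in raw.columns})
    required = [c for c in COLUMNS if c != "replicate"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}; found {list(raw.columns)}")
    if "replicate" not in raw.columns:
        raw["replicate"] = "1"

    out = pd.DataFrame({"treatment": raw["treatment"].astype(str).str.strip()})
    for col in ("temperature_C", "time_d", "sh_percent", "replicate"):
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"non-numeric value {raw[col][bad.idxmax()]!r} in column "
                             f"{col!r} at file line {line}")
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2
            raise ParseError(f"empty value in column {col!r} at file line {line}")
        out[col] = values
    out["replicate"] = out["replicate"].astype(int)
    if (out["replicate"] < 1).any():
        raise DomainError("replicate indices must be positive")
    vocab = tuple(vocabulary) if vocabulary is not None else None
    return KineticDataset(out, vocabulary=vocab, temperature_range=temperature_range)


def write_dataset(dataset: KineticDataset, path) -> None:
    """Write a dataset to the canonical CSV layout (round-trips with read_dataset)."""
    dataset.frame.to_csv(path, index=False, columns=list(COLUMNS))


def normalize_to_percent(raw: KineticDataset) -> KineticDataset:
    """Rescale each (treatment, temperature) group to percent of its time-0 mean.

    Every group must contain at least one time-0 record with a positive mean;
    each value is divided by that mean and multiplied by 100, so the group's
    time-0 mean becomes exactly 100.  Idempotent on already-normalized data.
    """
    frame = raw.frame.copy()
    scaled = np.empty(len(frame))
    for (treatment, temp), sub in frame.groupby(["treatment", "temperature_C"], sort=False):
        at0 = sub.loc[sub["time_d"] == 0.0, "sh_percent"]
        if at0.empty:
            raise NormalizationError(f"group ({treatment!r}, {temp} °C) has no time-0 record")
        mean0 = float(at0.mean())
        if mean0 <= 0:
            raise DomainError(f"group ({treatment!r}, {temp} °C) has non-positive time-0 mean {mean0}")
        scaled[sub.index] = sub["sh_percent"].to_numpy() / mean0 * 100.0
    frame["sh_percent"] = scaled
    return KineticDataset(frame, raw.vocabulary, raw.temperature_range)


def _fixture_text(filename: str) -> io.StringIO:
    text = (resources.files("thiolkin") / "data" / filename).read_text(encoding="utf-8")
    return io.StringIO(text)


def load_fixture(name: str) -> pd.DataFrame:
    """Return a packaged reference table.

    ``table1_rates``
        Per-treatment zero-order rate constants k (day⁻¹) at 277/281/289/293 K
        with replicate SDs; 14 treatments × 4 temperatures.
    ``table1_params``
        Per-treatment Arrhenius (Ea kJ/mol, k0 day⁻¹) and log-logistic
        (c °C⁻¹, Tc °C) parameters with SDs and fit R².  The ``tc_sign`` column
        flags the Tc sign convention: ``negated`` means the internal Tc (in
        rate = softplus(c·(T − Tc))) is the negative of the printed magnitude,
        which reproduces the published 12 °C predictions; ``as_printed`` keeps
        the printed sign; ``unverifiable`` marks treatments whose published
        predictions match neither sign (rosemary, cardamom).
    ``table4_observed``
        Observed SH (% of initial) at 12 °C for days 0–6 per treatment
        (columns ``treatment,time_d,sh_percent``); 14 × 6 rows.
    ``table4_predicted``
        Observed plus model-predicted SH at 12 °C (columns
        ``treatment,time_d,observed,pred_arrhenius,pred_loglogistic,pred_ann``).
    """
    if name not in FIXTURE_NAMES:
        raise FixtureLookupError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    if name == "table1_rates":
        return pd.read_csv(_fixture_text("table1_rates.csv"))
    if name == "table1_params":
        return pd.read_csv(_fixture_text("table1_params.csv"))
    table4 = pd.read_csv(_fixture_text("table4.csv"))
    if name == "table4_predicted":
        return table4
    out = table4.loc[:, ["treatment", "time_d", "observed"]].rename(columns={"observed": "sh_percent"})
    return out


def observed_holdout_dataset() -> KineticDataset:
    """The published 12 °C observed series as a :class:`KineticDataset` (replicate means)."""
    obs = load_fixture("table4_observed").copy()
    obs["temperature_C"] = 12.0
    obs["replicate"] = 1
    return KineticDataset(obs, vocabulary=STUDY_TREATMENTS)
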