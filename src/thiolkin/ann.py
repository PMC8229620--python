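"""MLP-ensemble regression of SH on (treatment, time, temperature).

The protocol trains 20 candidate single-hidden-layer perceptrons and retains
the 5 with the lowest validation-split error.  Each network has 16 inputs
(14-way one-hot treatment + min-max-scaled time and temperature), 4–10 hidden
neurons with tanh or exponential activation, and one output neuron with
identity, logistic, tanh or exponential activation.  Training minimizes the
sum-of-squares (SOS) error with BFGS for at most 200 iterations, on a seeded
70/15/15 learning/testing/validation split; feature and response scaling is
derived from the learning split only.  Ensemble prediction is the unweighted
mean of the members' inverse-scaled outputs.

The forward pass and analytic gradient are implemented directly so that the
full activation envelope (including the exponential units) is available;
optimization uses :func:`scipy.optimize.minimize`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .data_io import STUDY_TREATMENTS, KineticDataset

logger = logging.getLogger(__name__)

HIDDEN_ACTIVATIONS = ("tanh", "exponential")
OUTPUT_ACTIVATIONS = ("identity", "logistic", "tanh", "exponential")

# pre-activation clip for the exponential unit; keeps the loss finite
_EXP_CLIP = 50.0


class AnnError(Exception):
    pass


class EncodingError(AnnError):
    """Record cannot be encoded (unknown treatment label)."""


class TrainingError(AnnError):
    """Fewer finite candidates than the requested ensemble size."""


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "exponential":
        return np.exp(np.minimum(z, _EXP_CLIP))
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "identity":
        return z
    raise AnnError(f"unknown activation {name!r}")


def _activate_grad(name: str, a: np.ndarray, z: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation output a = f(z)
    if name == "tanh":
        return 1.0 - a**2
    if name == "exponential":
        return np.where(z < _EXP_CLIP, a, 0.0)
    if name == "logistic":
        return a * (1.0 - a)
    if name == "identity":
        return np.ones_like(a)
    raise AnnError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class AnnConfig:
    """Training protocol envelope.

    Defaults follow the study protocol: 20 candidates, best 5 retained,
    hidden layer of 4–10 neurons, BFGS capped at 200 iterations, 70/15/15
    learning/testing/validation split.
    """

    n_candidates: int = 20
    n_keep: int = 5
    hidden_range: tuple[int, int] = (4, 10)
    hidden_activations: tuple[str, ...] = HIDDEN_ACTIVATIONS
    output_activations: tuple[str, ...] = OUTPUT_ACTIVATIONS
    max_iterations: int = 200
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.split), 1.0):
            raise AnnError(f"split fractions must sum to 1, got {self.split}")
        if self.n_keep > self.n_candidates:
            raise AnnError("n_keep must be <= n_candidates")
        lo, hi = self.hidden_range
        if lo < 1 or hi < lo:
            raise AnnError(f"invalid hidden_range {self.hidden_range}")
        unknown = set(self.hidden_activations) - set(HIDDEN_ACTIVATIONS)
        unknown |= set(self.output_activations) - set(OUTPUT_ACTIVATIONS)
        if unknown:
            raise AnnError(f"unknown activations {sorted(unknown)}")


@dataclass(frozen=True)
class FeatureEncoder:
    """Maps (treatment, time, temperature) records to 16-component vectors.

    The first 14 components one-hot encode the treatment; the last two are
    time and temperature min-max scaled to the ranges seen in the learning
    split.  Exactly one indicator component is 1 per record.
    """

    vocabulary: tuple[str, ...] = STUDY_TREATMENTS
    time_range: tuple[float, float] = (0.0, 11.0)
    temperature_range: tuple[float, float] = (4.0, 20.0)

    @property
    def n_features(self) -> int:
        return len(self.vocabulary) + 2

    def _scale(self, value, bounds):
        lo, hi = bounds
        span = hi - lo if hi > lo else 1.0
        return (np.asarray(value, dtype=float) - lo) / span

    def encode(self, treatment: str, time_d: float, temperature_C: float) -> np.ndarray:
        if treatment not in self.vocabulary:
            raise EncodingError(f"unknown treatment {treatment!r}")
        x = np.zeros(self.n_features)
        x[self.vocabulary.index(treatment)] = 1.0
        x[-2] = self._scale(time_d, self.time_range)
        x[-1] = self._scale(temperature_C, self.temperature_range)
        return x

    def encode_frame(self, frame) -> np.ndarray:
        unknown = sorted(set(frame["treatment"]) - set(self.vocabulary))
        if unknown:
            raise EncodingError(f"unknown treatments {unknown}")
        X = np.zeros((len(frame), self.n_features))
        idx = {t: i for i, t in enumerate(self.vocabulary)}
        X[np.arange(len(frame)), [idx[t] for t in frame["treatment"]]] = 1.0
        X[:, -2] = self._scale(frame["time_d"].to_numpy(), self.time_range)
        X[:, -1] = self._scale(frame["temperature_C"].to_numpy(), self.temperature_range)
        return X


def encode_features(
    treatment: str,
    time_d: float,
    temperature_C: float,
    encoder: FeatureEncoder | None = None,
) -> np.ndarray:
    """Encode one record with the default (or a fitted) encoder."""
    return (encoder or FeatureEncoder()).encode(treatment, time_d, temperature_C)


@dataclass(frozen=True)
class MlpMember:
    """One trained network of the ensemble with its training metadata.

    ``errors`` are SOS on the scaled response per split; ``performance`` is
    the observed-predicted Pearson correlation per split on the percent scale.
    """

    hidden_size: int
    hidden_activation: str
    output_activation: str
    weights: np.ndarray  # packed (W1, b1, w2, b2)
    n_iterations: int
    errors: Mapping[str, float]
    performance: Mapping[str, float]

    def forward(self, X: np.ndarray) -> np.ndarray:
        n_in = X.shape[1]
        H = self.hidden_size
        W1, b1, w2, b2 = _unpack(self.weights, n_in, H)
        a1 = _activate(self.hidden_activation, X @ W1.T + b1)
        return _activate(self.output_activation, a1 @ w2 + b2)


def _n_params(n_in: int, hidden: int) -> int:
    return hidden * n_in + hidden + hidden + 1


def _unpack(w: np.ndarray, n_in: int, H: int):
    i = 0
    W1 = w[i : i + H * n_in].reshape(H, n_in); i += H * n_in
    b1 = w[i : i + H]; i += H
    w2 = w[i : i + H]; i += H
    b2 = w[i]
    return W1, b1, w2, b2


def _sos_and_grad(w, X, y, H, hidden_act, output_act):
    n_in = X.shape[1]
    W1, b1, w2, b2 = _unpack(w, n_in, H)
    z1 = X @ W1.T + b1
    a1 = _activate(hidden_act, z1)
    z2 = a1 @ w2 + b2
    yhat = _activate(output_act, z2)
    r = yhat - y
    loss = float(r @ r)

    dz2 = 2.0 * r * _activate_grad(output_act, yhat, z2)
    gw2 = a1.T @ dz2
    gb2 = dz2.sum()
    da1 = np.outer(dz2, w2)
    dz1 = da1 * _activate_grad(hidden_act, a1, z1)
    gW1 = dz1.T @ X
    gb1 = dz1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gw2, np.array([gb2])])
    return loss, grad


@dataclass(frozen=True)
class AnnEnsemble:
    """The retained best networks plus the encoder and response scaler."""

    members: tuple[MlpMember, ...]
    encoder: FeatureEncoder
    response_range: tuple[float, float]
    config: AnnConfig
    split_indices: Mapping[str, np.ndarray] = field(repr=False, default_factory=dict)

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.forward(X) for m in self.members], axis=0)

    def to_json(self) -> str:
        lo, hi = self.response_range
        payload = {
            "seed": self.config.seed,
            "response_range": [lo, hi],
            "encoder": {
                "vocabulary": list(self.encoder.vocabulary),
                "time_range": list(self.encoder.time_range),
                "temperature_range": list(self.encoder.temperature_range),
            },
            "members": [
                {
                    "hidden_size": m.hidden_size,
                    "hidden_activation": m.hidden_activation,
                    "output_activation": m.output_activation,
                    "n_iterations": m.n_iterations,
                    "errors": dict(m.errors),
                    "performance": dict(m.performance),
                    "weights": m.weights.tolist(),
                }
                for m in self.members
            ],
        }
        return json.dumps(payload, indent=1)


def _split_indices(n: int, split, rng) -> dict[str, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_test = int(round(split[1] * n))
    return {
        "train": np.sort(perm[:n_train]),
        "test": np.sort(perm[n_train : n_train + n_test]),
        "validation": np.sort(perm[n_train + n_test :]),
    }


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def train_ensemble(dataset: KineticDataset, config: AnnConfig | None = None) -> AnnEnsemble:
    """Train candidate MLPs and retain the best by validation-split SOS error.

    Fully reproducible given ``config.seed``: the split, the candidate
    architectures and the weight initializations are all drawn from one
    seeded generator, and BFGS is deterministic.  Candidates whose final loss
    is non-finite are discarded with a logged warning; a
    :class:`TrainingError` is raised if fewer than ``n_keep`` remain.
    """
    config = config or AnnConfig()
    frame = dataset.frame
    if frame.empty:
        raise AnnError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    idx = _split_indices(len(frame), config.split, rng)
    train_frame = frame.iloc[idx["train"]]

    vocabulary = tuple(t for t in STUDY_TREATMENTS if t in set(frame["treatment"]))
    if not vocabulary:
        vocabulary = tuple(sorted(set(frame["treatment"])))
    encoder = FeatureEncoder(
        vocabulary=vocabulary,
        time_range=(float(train_frame["time_d"].min()), float(train_frame["time_d"].max())),
        temperature_range=(
            float(train_frame["temperature_C"].min()),
            float(train_frame["temperature_C"].max()),
        ),
    )
    y_lo = float(train_frame["sh_percent"].min())
    y_hi = float(train_frame["sh_percent"].max())
    y_span = y_hi - y_lo if y_hi > y_lo else 1.0

    X = encoder.encode_frame(frame)
    y = (frame["sh_percent"].to_numpy() - y_lo) / y_span

    splits = {name: (X[i], y[i]) for name, i in idx.items()}
    n_in = encoder.n_features

    candidates: list[MlpMember] = []
    for c in range(config.n_candidates):
        H = int(rng.integers(config.hidden_range[0], config.hidden_range[1] + 1))
        hidden_act = str(rng.choice(config.hidden_activations))
        output_act = str(rng.choice(config.output_activations))
        w0 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=_n_params(n_in, H))

        sol = minimize(
            _sos_and_grad,
            w0,
            args=(splits["train"][0], splits["train"][1], H, hidden_act, output_act),
            jac=True,
            method="BFGS",
            options={"maxiter": config.max_iterations, "gtol": 1e-8},
        )
        member = MlpMember(
            hidden_size=H,
            hidden_activation=hidden_act,
            output_activation=output_act,
            weights=sol.x,
            n_iterations=int(sol.nit),
            errors={},
            performance={},
        )
        errors, performance = {}, {}
        finite = True
        for name, (Xs, ys) in splits.items():
            yhat = member.forward(Xs)
            if not np.all(np.isfinite(yhat)):
                finite = False
                break
            errors[name] = float(np.sum((yhat - ys) ** 2))
            performance[name] = _safe_corr(ys * y_span + y_lo, yhat * y_span + y_lo)
        if not finite or not np.isfinite(sol.fun):
            logger.warning("discarding candidate %d (%s/%s, H=%d): non-finite loss",
                           c, hidden_act, output_act, H)
            continue
        candidates.append(
            MlpMember(
                hidden_size=H,
                hidden_activation=hidden_act,
                output_activation=output_act,
                weights=sol.x,
                n_iterations=int(sol.nit),
                errors=errors,
                performance=performance,
            )
        )

    if len(candidates) < config.n_keep:
        raise TrainingError(
            f"only {len(candidates)} finite candidates, need {config.n_keep}"
        )
    candidates.sort(key=lambda m: m.errors["validation"])
    return AnnEnsemble(
        members=tuple(candidates[: config.n_keep]),
        encoder=encoder,
        response_range=(y_lo, y_hi),
        config=config,
        split_indices=idx,
    )


def predict_ensemble(ensemble: AnnEnsemble, records) -> np.ndarray:
    """Predict SH (%) as the unweighted member mean, inverse-scaled.

    ``records`` is a DataFrame with ``treatment``, ``time_d`` and
    ``temperature_C`` columns, or a sequence of (treatment, time, temperature)
    tuples.
    """
    import pandas as pd

    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["treatment", "time_d", "temperature_C"])
    X = ensemble.encoder.encode_frame(records)
    lo, hi = ensemble.response_range
    span = hi - lo if hi > lo else 1.0
    return ensemble.predict_scaled(X) * span + lo


def ensemble_predictor(ensemble: AnnEnsemble, treatment: str):
    """A per-treatment callable ``f(time_d, temperature_C) -> SH`` for validation."""
    import pandas as pd

    def predict(time_d, temperature_C):
        t = np.atleast_1d(np.asarray(time_d, dtype=float))
        frame = pd.DataFrame(
            {"treatment": treatment, "time_d": t, "temperature_C": float(temperature_C)}
        )
        return predict_ensemble(ensemble, frame)

    return predict
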