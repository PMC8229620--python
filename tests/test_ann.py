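"""Feature encoding, MLP ensemble training, prediction and reproducibility."""

import numpy as np
import pandas as pd
import pytest

import thiolkin as tk
from thiolkin.ann import AnnError, EncodingError, FeatureEncoder

SMALL = tk.AnnConfig(n_candidates=6, n_keep=3, max_iterations=150, seed=7)


@pytest.fixture(scope="module")
def training_data():
    data = tk.generate(tk.SyntheticConfig(seed=7, noise_sd=2.0))
    return data.subset(temperatures=(4.0, 8.0, 16.0, 20.0))


@pytest.fixture(scope="module")
def small_ensemble(training_data):
    return tk.train_ensemble(training_data, SMALL)


class TestEncoding:
    def test_range_endpoints_scale_to_zero_and_one(self):
        enc = FeatureEncoder(time_range=(0.0, 11.0), temperature_range=(4.0, 20.0))
        x = enc.encode("control", 0.0, 4.0)
        assert x[enc.vocabulary.index("control")] == 1.0
        assert (x[-2], x[-1]) == (0.0, 0.0)
        y = enc.encode("oregano", 11.0, 20.0)
        assert (y[-2], y[-1]) == (1.0, 1.0)

    def test_sixteen_components_exactly_one_indicator(self):
        enc = FeatureEncoder()
        for treatment in tk.STUDY_TREATMENTS:
            x = enc.encode(treatment, 3.0, 8.0)
            assert x.size == 16
            assert x[:14].sum() == 1.0
            assert set(np.unique(x[:14])) <= {0.0, 1.0}

    def test_unknown_treatment_rejected(self):
        with pytest.raises(EncodingError, match="ginger"):
            tk.encode_features("ginger", 0.0, 4.0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"split": (0.5, 0.2, 0.2)},
            {"n_candidates": 2, "n_keep": 5},
            {"hidden_range": (6, 4)},
            {"hidden_activations": ("relu",)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(AnnError):
            tk.AnnConfig(**kwargs)


class TestTraining:
    def test_keeps_requested_number_of_members(self, small_ensemble):
        assert len(small_ensemble.members) == 3
        for member in small_ensemble.members:
            assert 4 <= member.hidden_size <= 10
            assert set(member.errors) == {"train", "test", "validation"}

    def test_members_sorted_by_validation_error(self, small_ensemble):
        errs = [m.errors["validation"] for m in small_ensemble.members]
        assert errs == sorted(errs)

    def test_single_candidate_degenerate_config(self, training_data):
        config = tk.AnnConfig(n_candidates=1, n_keep=1, hidden_range=(4, 4),
                              max_iterations=50, seed=1)
        ensemble = tk.train_ensemble(training_data, config)
        assert len(ensemble.members) == 1
        assert ensemble.members[0].hidden_size == 4

    def test_same_seed_bitwise_reproducible(self, training_data, small_ensemble):
        again = tk.train_ensemble(training_data, SMALL)
        for a, b in zip(small_ensemble.members, again.members):
            assert a.errors == b.errors
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_scaler_from_training_split_only(self, small_ensemble, training_data):
        idx = small_ensemble.split_indices["train"]
        sub = training_data.frame.iloc[idx]
        assert small_ensemble.encoder.time_range == (sub["time_d"].min(), sub["time_d"].max())

    def test_noiseless_data_memorized(self):
        data = tk.generate(tk.SyntheticConfig(seed=2, noise_sd=0.0, replicates=1))
        training = data.subset(temperatures=(4.0, 8.0, 16.0, 20.0))
        config = tk.AnnConfig(n_candidates=8, n_keep=3, seed=2)
        ensemble = tk.train_ensemble(training, config)
        holdout = data.subset(temperatures=[12.0]).frame
        pred = tk.predict_ensemble(ensemble, holdout)
        report = tk.score(holdout["sh_percent"], pred)
        assert report.r2 >= 0.999
        assert ensemble.members[0].performance["train"] >= 0.999


class TestPrediction:
    def test_member_permutation_leaves_predictions_unchanged(self, small_ensemble, training_data):
        frame = training_data.frame.head(20)
        base = tk.predict_ensemble(small_ensemble, frame)
        permuted = tk.AnnEnsemble(
            members=tuple(reversed(small_ensemble.members)),
            encoder=small_ensemble.encoder,
            response_range=small_ensemble.response_range,
            config=small_ensemble.config,
        )
        np.testing.assert_allclose(tk.predict_ensemble(permuted, frame), base, rtol=1e-12)

    def test_identical_members_equal_single_member(self, small_ensemble, training_data):
        frame = training_data.frame.head(10)
        member = small_ensemble.members[0]
        cloned = tk.AnnEnsemble(
            members=(member, member, member),
            encoder=small_ensemble.encoder,
            response_range=small_ensemble.response_range,
            config=small_ensemble.config,
        )
        single = tk.AnnEnsemble(
            members=(member,),
            encoder=small_ensemble.encoder,
            response_range=small_ensemble.response_range,
            config=small_ensemble.config,
        )
        np.testing.assert_allclose(
            tk.predict_ensemble(cloned, frame), tk.predict_ensemble(single, frame), rtol=1e-12
        )

    def test_ensemble_not_worse_than_worst_member(self, small_ensemble, training_data):
        idx = small_ensemble.split_indices["validation"]
        frame = training_data.frame.iloc[idx]
        X = small_ensemble.encoder.encode_frame(frame)
        lo, hi = small_ensemble.response_range
        y = (frame["sh_percent"].to_numpy() - lo) / (hi - lo)
        ens_err = float(np.sum((small_ensemble.predict_scaled(X) - y) ** 2))
        worst = max(m.errors["validation"] for m in small_ensemble.members)
        assert ens_err <= worst + 1e-9

    def test_tuple_records_accepted(self, small_ensemble):
        preds = tk.predict_ensemble(small_ensemble, [("control", 0.0, 4.0), ("thyme", 2.0, 8.0)])
        assert preds.shape == (2,)

    def test_serialization_round_trips_metadata(self, small_ensemble):
        import json

        payload = json.loads(small_ensemble.to_json())
        assert len(payload["members"]) == 3
        assert payload["encoder"]["vocabulary"] == list(tk.STUDY_TREATMENTS)


def test_agreement_with_independent_mlp_implementation(training_data):
    """A scikit-learn MLP (lbfgs, tanh) on the same features reaches comparable
    holdout accuracy, cross-checking the hand-written network."""
    sklearn = pytest.importorskip("sklearn.neural_network")

    data = tk.generate(tk.SyntheticConfig(seed=7, noise_sd=2.0))
    holdout = data.subset(temperatures=[12.0]).frame
    config = tk.AnnConfig(n_candidates=4, n_keep=2, hidden_activations=("tanh",),
                          output_activations=("identity",), seed=7)
    ours = tk.train_ensemble(training_data, config)
    ours_r2 = tk.score(holdout["sh_percent"], tk.predict_ensemble(ours, holdout)).r2

    enc = ours.encoder
    X_train = enc.encode_frame(training_data.frame)
    y_train = training_data.frame["sh_percent"].to_numpy()
    lo, hi = y_train.min(), y_train.max()
    ref = sklearn.MLPRegressor(hidden_layer_sizes=(8,), activation="tanh", solver="lbfgs",
                               max_iter=2000, random_state=0).fit(X_train, (y_train - lo) / (hi - lo))
    ref_pred = ref.predict(enc.encode_frame(holdout)) * (hi - lo) + lo
    ref_r2 = tk.score(holdout["sh_percent"], ref_pred).r2

    assert ours_r2 >= 0.95 and ref_r2 >= 0.95
    assert abs(ours_r2 - ref_r2) < 0.05
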