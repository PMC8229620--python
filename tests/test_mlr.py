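"""Dummy-coded multiple linear regression: design building, OLS, ranking, coverage."""

import numpy as np
import pandas as pd
import pytest

import thiolkin as tk
from thiolkin.mlr import DesignError, InsufficientDataError, MLRError

from conftest import make_dataset


def linear_rows(treatments, offsets, noise_sd=0.0, seed=0, days=(0, 1, 2, 3), temps=(4.0, 12.0, 20.0)):
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in treatments:
        for T in temps:
            for d in days:
                sh = 100.0 - 8.0 * d - 1.3 * T + offsets.get(treatment, 0.0)
                rows.append((treatment, T, float(d), 1, sh + rng.normal(0, noise_sd)))
    return rows


class TestBuildDesign:
    def test_fourteen_treatments_give_sixteen_columns(self, noiseless_dataset):
        X, y = tk.build_design(noiseless_dataset, reference="control")
        assert X.shape[1] == 16
        assert len(y) == len(noiseless_dataset)

    def test_reference_only_dataset_has_no_dummies(self):
        ds = make_dataset(linear_rows(["control"], {}))
        X, _ = tk.build_design(ds, reference="control")
        assert list(X.columns) == ["const", "time_d", "temperature_C"]

    def test_two_treatments_one_indicator(self):
        ds = make_dataset(linear_rows(["control", "allspice"], {}))
        X, _ = tk.build_design(ds, reference="control")
        assert list(X.columns)[-1] == "allspice"
        on = ds.frame["treatment"] == "allspice"
        np.testing.assert_array_equal(X["allspice"].to_numpy(), on.astype(float).to_numpy())

    def test_absent_reference_rejected(self, noiseless_dataset):
        with pytest.raises(MLRError, match="placebo"):
            tk.build_design(noiseless_dataset, reference="placebo")

    def test_collinear_design_rejected(self):
        # constant temperature makes the temperature column collinear with the intercept
        ds = make_dataset(linear_rows(["control", "basil"], {}, temps=(12.0,)))
        with pytest.raises(DesignError, match="temperature_C"):
            tk.build_design(ds, reference="control")


class TestFitMlr:
    def test_exact_recovery_on_noiseless_data(self):
        offsets = {"oregano": 15.0, "thyme": 9.0}
        ds = make_dataset(linear_rows(["control", "oregano", "thyme"], offsets))
        X, y = tk.build_design(ds, reference="control")
        result = tk.fit_mlr(X, y)
        assert result.intercept == pytest.approx(100.0, abs=1e-9)
        assert result.coef_time == pytest.approx(-8.0, abs=1e-9)
        assert result.coef_temperature == pytest.approx(-1.3, abs=1e-9)
        assert result.treatment_coefs.loc["oregano", "beta"] == pytest.approx(15.0, abs=1e-9)

    def test_zero_response_gives_zero_coefficients(self):
        ds = make_dataset(
            [("control", T, float(d), 1, 0.0) for T in (4.0, 12.0) for d in range(4)]
            + [("basil", T, float(d), 1, 0.0) for T in (4.0, 12.0) for d in range(4)]
        )
        X, y = tk.build_design(ds, reference="control")
        result = tk.fit_mlr(X, y)
        assert result.intercept == pytest.approx(0.0, abs=1e-12)
        assert result.resid_var == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_data_rejected(self):
        ds = make_dataset(linear_rows(["control", "basil"], {}, days=(0, 1), temps=(4.0, 20.0)))
        X, y = tk.build_design(ds, reference="control")
        with pytest.raises(InsufficientDataError):
            tk.fit_mlr(X.iloc[:4], y.iloc[:4])  # n = p = 4

    def test_reference_rows_predicted_without_dummy_contribution(self):
        ds = make_dataset(linear_rows(["control", "basil"], {"basil": 5.0}))
        X, y = tk.build_design(ds, reference="control")
        result = tk.fit_mlr(X, y)
        ref = ds.frame["treatment"] == "control"
        manual = (
            result.intercept
            + result.coef_time * ds.frame.loc[ref, "time_d"]
            + result.coef_temperature * ds.frame.loc[ref, "temperature_C"]
        )
        np.testing.assert_allclose(manual, y[ref.to_numpy()], atol=1e-9)

    def test_row_permutation_invariance(self):
        rows = linear_rows(["control", "clove", "onion"], {"clove": 4.0}, noise_sd=2.0, seed=5)
        ds = make_dataset(rows)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(rows))
        ds_perm = make_dataset([rows[i] for i in perm])
        a = tk.fit_treatment_effects(ds, reference="control")
        b = tk.fit_treatment_effects(ds_perm, reference="control")
        pd.testing.assert_frame_equal(
            a.treatment_coefs.sort_index(), b.treatment_coefs.sort_index(), atol=1e-9, rtol=0
        )

    def test_bonferroni_inflates_pvalues(self):
        ds = make_dataset(linear_rows(["control", "clove", "onion"], {"clove": 1.0},
                                      noise_sd=2.0, seed=3))
        raw = tk.fit_treatment_effects(ds)
        adj = tk.fit_treatment_effects(ds, bonferroni=True)
        assert (adj.treatment_coefs["p"] >= raw.treatment_coefs["p"] - 1e-15).all()


class TestRankExtracts:
    def test_descending_beta_with_alphabetical_ties(self):
        coefs = pd.DataFrame(
            {"beta": [5.0, 9.0, 5.0], "se": [1.0] * 3, "t": [1.0] * 3, "p": [0.1] * 3},
            index=["onion", "oregano", "basil"],
        )
        result = tk.MLRResult(
            intercept=100.0, coef_time=-8.0, coef_temperature=-1.3,
            treatment_coefs=coefs, n=50, r2=0.9, reference="control", resid_var=1.0,
        )
        ranked = tk.rank_extracts(result)
        assert [r[0] for r in ranked] == ["oregano", "basil", "onion"]

    def test_single_extract_singleton(self):
        ds = make_dataset(linear_rows(["control", "thyme"], {"thyme": 3.0}))
        ranked = tk.rank_extracts(tk.fit_treatment_effects(ds))
        assert len(ranked) == 1 and ranked[0][0] == "thyme"

    def test_table_export_ends_with_continuous_terms(self):
        ds = make_dataset(linear_rows(["control", "thyme", "basil"], {"thyme": 3.0}))
        table = tk.fit_treatment_effects(ds).to_table()
        assert list(table["term"].iloc[-3:]) == ["time", "temperature", "intercept"]


def test_offset_recovery_at_moderate_sample_size():
    """Mean recovered oregano effect over 200 seeds is within +/-1 of the
    true +15 offset at roughly 400 observations per dataset."""
    betas = []
    for seed in range(200):
        data = tk.generate_linear(offsets={"oregano": 15.0}, replicates=1, seed=seed)
        result = tk.fit_treatment_effects(data)
        betas.append(float(result.treatment_coefs.loc["oregano", "beta"]))
    assert np.mean(betas) == pytest.approx(15.0, abs=1.0)


def test_confidence_interval_coverage():
    """Empirical 95 % CI coverage for a treatment effect is 95 +/- 3 % over 1000 seeds."""
    from scipy import stats

    hits = 0
    n_seeds = 1000
    for seed in range(n_seeds):
        ds = make_dataset(
            linear_rows(["control", "oregano"], {"oregano": 15.0}, noise_sd=2.0, seed=seed)
        )
        X, y = tk.build_design(ds, reference="control")
        result = tk.fit_mlr(X, y)
        row = result.treatment_coefs.loc["oregano"]
        half = stats.t.ppf(0.975, result.n - X.shape[1]) * row.se
        if row.beta - half <= 15.0 <= row.beta + half:
            hits += 1
    assert abs(hits / n_seeds - 0.95) <= 0.03
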