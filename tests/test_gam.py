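"""Additive-model fitting, prediction, model selection and serialization."""

import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from ampeff.errors import (
    DegenerateDesignError,
    IncomparableModelsError,
    ModelIOError,
    SchemaError,
    UnsupportedVersionError,
)
from ampeff.gam import (
    DEFAULT_SMOOTH_PAIRS,
    EfficiencyModel,
    compare_models_aic,
    fit_gam,
    gcv_score,
    load_model,
    predict_efficiency,
    save_model,
)
from ampeff.simulate import (
    DEFAULT_NOISE_SD,
    SimulationConfig,
    generate_dataset,
)

COVARIATES = [name for pair in DEFAULT_SMOOTH_PAIRS for name in pair]


def intercept_only_model(intercept=1.7, edf=1.0, n=10):
    return EfficiencyModel(
        intercept=intercept, terms=[], scale=0.0, n_train=n,
        edf_total=edf, rss=0.0, covariate_ranges={},
    )


class TestFitGam:
    def test_constant_response_reduces_to_intercept(self, small_dataset):
        df = small_dataset.copy()
        df["efficiency"] = 1.7
        model, summary = fit_gam(df)
        assert model.intercept == pytest.approx(1.7, abs=1e-6)
        assert summary.deviance_explained == pytest.approx(0.0, abs=1e-6)
        preds = predict_efficiency(model, df)
        np.testing.assert_allclose(preds["predicted"], 1.7, atol=1e-5)

    def test_summary_layout_exposes_per_smooth_edf_and_gcv(self, fitted_model):
        model, summary = fitted_model
        assert len(summary.smooth_terms) == 3
        for term in summary.smooth_terms:
            assert 1.0 <= term["edf"] <= 30.0
            assert 0.0 <= term["p_value"] <= 1.0
        assert summary.gcv_score > 0
        text = str(summary)
        assert "Deviance explained" in text and "GCV score" in text

    def test_recovers_generating_surface_within_twice_noise_sd(self, small_dataset):
        model, _ = fit_gam(small_dataset)
        pairs = small_dataset.drop_duplicates("pairId")
        pred = predict_efficiency(model, pairs, clamp=False)["raw"]
        rmse = float(np.sqrt(np.mean((pred - pairs["trueEfficiency"]) ** 2)))
        assert rmse < 2 * DEFAULT_NOISE_SD

    def test_out_of_sample_r2_near_signal_share(self, small_dataset, rng):
        """New noise draws around the same truth: R2 should sit near the
        oracle signal share 0.41 used by the generator."""
        model, _ = fit_gam(small_dataset)
        truth = small_dataset["trueEfficiency"].to_numpy()
        fresh = np.clip(truth + rng.normal(0, DEFAULT_NOISE_SD, len(truth)), 1, 2)
        pred = predict_efficiency(model, small_dataset, clamp=False)["raw"].to_numpy()
        ss_res = float(((fresh - pred) ** 2).sum())
        ss_tot = float(((fresh - fresh.mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot == pytest.approx(0.41, abs=0.08)

    def test_centering_identities(self, small_dataset, fitted_model):
        """Column-centred smooths: the intercept carries the mean response and
        training predictions average to it."""
        model, _ = fitted_model
        mean_eff = small_dataset["efficiency"].mean()
        assert model.intercept == pytest.approx(mean_eff, abs=1e-4)
        fitted = predict_efficiency(model, small_dataset, clamp=False)["raw"]
        assert fitted.mean() == pytest.approx(mean_eff, abs=1e-4)
        # a record at the covariate means deviates from the mean response only
        # through smooth curvature, bounded well inside the signal scale
        at_means = pd.DataFrame(
            {c: [small_dataset[c].astype(float).mean()] for c in COVARIATES}
        )
        pred = float(predict_efficiency(model, at_means)["predicted"].iloc[0])
        assert pred == pytest.approx(mean_eff, abs=0.1)

    def test_training_predictions_reproduce_fit(self, small_dataset, fitted_model):
        model, summary = fitted_model
        pred = predict_efficiency(model, small_dataset, clamp=False)["raw"].to_numpy()
        rss = float(((small_dataset["efficiency"].to_numpy() - pred) ** 2).sum())
        assert rss == pytest.approx(model.rss, rel=1e-8)

    def test_row_order_invariance(self, small_dataset, fitted_model):
        model, _ = fitted_model
        shuffled = small_dataset.sample(frac=1.0, random_state=3)
        model2, _ = fit_gam(shuffled)
        probe = small_dataset.drop_duplicates("pairId")
        p1 = predict_efficiency(model, probe, clamp=False)["raw"].to_numpy()
        p2 = predict_efficiency(model2, probe, clamp=False)["raw"].to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_too_few_records_rejected(self, small_dataset):
        with pytest.raises(Exception, match="at least 100"):
            fit_gam(small_dataset.head(50))

    def test_constant_covariate_named_in_error(self, small_dataset):
        df = small_dataset.copy()
        df["gcImbalance"] = 0.25
        with pytest.raises(DegenerateDesignError, match="gcImbalance"):
            fit_gam(df)


class TestPredict:
    def test_clamped_to_physical_range_with_flag(self, small_dataset, fitted_model):
        model, _ = fitted_model
        hot = dataclasses.replace(model, intercept=model.intercept + 0.6)
        preds = predict_efficiency(hot, small_dataset.drop_duplicates("pairId"))
        assert preds["predicted"].max() <= 2.0
        assert preds.loc[preds["raw"] > 2.0, "clamped"].all()
        assert (preds["predicted"] >= 1.0).all()

    def test_extrapolation_flagged(self, small_dataset, fitted_model):
        model, _ = fitted_model
        row = small_dataset.drop_duplicates("pairId").head(1).copy()
        row["lengthSequence"] = 5000.0
        assert predict_efficiency(model, row)["extrapolated"].iloc[0]

    def test_missing_covariate_listed(self, small_dataset, fitted_model):
        model, _ = fitted_model
        broken = small_dataset.drop(columns=["gcPrimers"])
        with pytest.raises(SchemaError, match="gcPrimers"):
            predict_efficiency(model, broken)


class TestGCV:
    def test_zero_residual_fit_scores_zero(self):
        model = intercept_only_model(intercept=1.7, edf=1.0)
        data = pd.DataFrame({"efficiency": [1.7] * 10})
        assert gcv_score(model, data) == 0.0

    def test_hand_computed_toy_value(self):
        # residuals all 0.1 over 10 points: GCV = 10 * 0.1 = n*rss/(n-edf)^2
        model = intercept_only_model(intercept=1.5, edf=1.0)
        data = pd.DataFrame({"efficiency": [1.6] * 10})
        expected = 10 * (10 * 0.1**2) / (10 - 1) ** 2
        assert gcv_score(model, data) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_residuals_at_fixed_edf(self):
        model = intercept_only_model(intercept=1.5, edf=1.0)
        near = pd.DataFrame({"efficiency": [1.52] * 10})
        far = pd.DataFrame({"efficiency": [1.7] * 10})
        assert gcv_score(model, near) < gcv_score(model, far)

    def test_edf_at_least_n_rejected(self):
        model = intercept_only_model(edf=10.0)
        with pytest.raises(Exception, match="edf"):
            gcv_score(model, pd.DataFrame({"efficiency": [1.5] * 10}))


class TestModelSelection:
    def test_identical_models_tie(self, fitted_model):
        model, _ = fitted_model
        preferred, delta = compare_models_aic(model, model)
        assert preferred is model
        assert delta == 0.0

    def test_different_data_incomparable(self, fitted_model):
        model, _ = fitted_model
        other = dataclasses.replace(model, data_fingerprint="deadbeef")
        with pytest.raises(IncomparableModelsError):
            compare_models_aic(model, other)

    def test_omitting_an_informative_smooth_is_penalized(self):
        """The full three-smooth model should win the AIC comparison against
        one missing an informative covariate pair, replicate by replicate."""
        wins = 0
        for seed in range(6):
            df = generate_dataset(SimulationConfig(seed=100 + seed, n_pairs=40,
                                                   n_replicates=5))
            full, _ = fit_gam(df)
            reduced, _ = fit_gam(df, smooth_pairs=DEFAULT_SMOOTH_PAIRS[:2])
            preferred, _ = compare_models_aic(full, reduced)
            wins += preferred is full
        assert wins >= 5

    def test_adding_a_noise_smooth_is_penalized_in_majority(self):
        """Appending a smooth over covariates outside the generating surface
        should usually cost more AIC than it buys."""
        extra = DEFAULT_SMOOTH_PAIRS + (("aCount", "tCount"),)
        wins = 0
        for seed in range(6):
            df = generate_dataset(SimulationConfig(seed=200 + seed, n_pairs=40,
                                                   n_replicates=5))
            base, _ = fit_gam(df)
            padded, _ = fit_gam(df, smooth_pairs=extra)
            preferred, _ = compare_models_aic(base, padded)
            wins += preferred is base
        assert wins >= 4


class TestSerialization:
    def test_round_trip_predicts_identically(self, small_dataset, fitted_model, tmp_path):
        model, _ = fitted_model
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        grid = small_dataset.drop_duplicates("pairId")
        p1 = predict_efficiency(model, grid, clamp=False)["raw"].to_numpy()
        p2 = predict_efficiency(loaded, grid, clamp=False)["raw"].to_numpy()
        assert np.max(np.abs(p1 - p2)) == 0.0

    def test_truncated_file_is_a_parse_error(self, fitted_model, tmp_path):
        model, _ = fitted_model
        path = tmp_path / "model.json"
        save_model(model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_version_mismatch_is_explicit(self, fitted_model, tmp_path):
        model, _ = fitted_model
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(UnsupportedVersionError):
            load_model(path)

    def test_externally_written_document_loads(self, tmp_path):
        """A minimal model document produced by another writer of the same
        format loads and predicts (intercept-only here)."""
        doc = {
            "format": "ampeff-gam", "format_version": 1,
            "intercept": 1.72, "scale": 0.01, "n_train": 200,
            "edf_total": 1.0, "rss": 2.0,
            "covariate_ranges": {}, "response_range": [1.0, 2.0],
            "data_fingerprint": "", "terms": [],
        }
        path = tmp_path / "external.json"
        path.write_text(json.dumps(doc))
        model = load_model(path)
        pred = predict_efficiency(model, pd.DataFrame(index=range(3)))
        np.testing.assert_allclose(pred["predicted"], 1.72)

    def test_non_model_json_rejected(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"hello": "world"}')
        with pytest.raises(ModelIOError):
            load_model(path)
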