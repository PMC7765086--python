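"""Metrics, the CV harness, symmetry diagnostics, grouped importance,
and the missing-data machinery."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phatg import (
    ConstantTargetError,
    ModelConfig,
    MonomerSpec,
    PolymerDataset,
    PolymerSample,
    TgModel,
    cross_validate,
    imputation_cv,
    imputation_experiment,
    importance,
    mae,
    r2,
    rmse,
    symmetry_gap,
)
from phatg.evaluation import ablation_experiment, impute_columns

HB3, HV3 = "CC(O)CC(=O)O", "CCC(O)CC(=O)O"

floats = st.floats(-1e3, 1e3, allow_nan=False)
vec = st.lists(floats, min_size=2, max_size=30)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.5])
        assert r2(y, y) == 1.0 and mae(y, y) == 0.0 and rmse(y, y) == 0.0

    def test_constant_offset(self):
        y = np.array([250.0, 260.0, 270.0])
        assert mae(y, y + 4.0) == pytest.approx(4.0)
        assert rmse(y, y - 4.0) == pytest.approx(4.0)

    def test_brute_force_oracle_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y, yh = rng.normal(size=20), rng.normal(size=20)
            # independent elementwise summation
            ss_res = sum((a - b) ** 2 for a, b in zip(y, yh))
            ss_tot = sum((a - np.mean(y)) ** 2 for a in y)
            assert r2(y, yh) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
            assert mae(y, yh) == pytest.approx(
                sum(abs(a - b) for a, b in zip(y, yh)) / 20, rel=1e-12)
            assert rmse(y, yh) == pytest.approx(np.sqrt(ss_res / 20), rel=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import mean_absolute_error, r2_score

        rng = np.random.default_rng(1)
        y, yh = rng.normal(size=25), rng.normal(size=25)
        assert r2(y, yh) == pytest.approx(r2_score(y, yh), rel=1e-12)
        assert mae(y, yh) == pytest.approx(mean_absolute_error(y, yh), rel=1e-12)

    def test_constant_target_is_error_state(self):
        with pytest.raises(ConstantTargetError):
            r2(np.full(5, 3.0), np.arange(5.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(y=vec, noise=vec)
    def test_rmse_at_least_mae(self, y, noise):
        m = min(len(y), len(noise))
        y, yh = np.array(y[:m]), np.array(y[:m]) + np.array(noise[:m])
        assert rmse(y, yh) >= mae(y, yh) - 1e-9


class TestCrossValidate:
    def test_perfect_oracle_all_folds_r2_one(self, small_dataset):
        ds, _ = small_dataset
        y_full = ds.tg

        def oracle(X_tr, y_tr, X_te, tr_idx, te_idx):
            return y_full[te_idx]

        rep = cross_validate(ds, model_kind=oracle, k=5, seed=0)
        assert all(fm["r2"] == pytest.approx(1.0) for fm in rep.fold_metrics)

    def test_mean_predictor_r2_near_zero(self, small_dataset):
        ds, _ = small_dataset

        def mean_kind(X_tr, y_tr, X_te, tr_idx, te_idx):
            return np.full(len(te_idx), y_tr.mean())

        rep = cross_validate(ds, model_kind=mean_kind, k=5, seed=0)
        assert rep.averages["r2"] == pytest.approx(0.0, abs=0.15)

    def test_report_shape_five_folds_plus_average(self, small_dataset, fast_config):
        ds, _ = small_dataset
        rep = cross_validate(ds, config=fast_config, model_kind="lasso", k=5, seed=1)
        assert len(rep.fold_metrics) == 5
        assert set(rep.averages) == {"r2", "mae", "rmse"}
        for m in ("r2", "mae", "rmse"):
            assert rep.averages[m] == pytest.approx(
                np.mean([fm[m] for fm in rep.fold_metrics]), rel=1e-12)
        assert rep.averages["rmse"] >= rep.averages["mae"]

    def test_small_test_fold_rejected(self, tiny_dataset):
        ds, _ = tiny_dataset
        with pytest.raises(ValueError):
            cross_validate(ds.subset(range(5)), model_kind="lasso", k=5, seed=0)

    def test_per_sample_predictions_cover_every_record(self, small_dataset,
                                                       fast_config):
        ds, _ = small_dataset
        rep = cross_validate(ds, config=fast_config, model_kind="lasso", k=5, seed=2)
        assert rep.per_sample["y_hat"].notna().all()
        assert len(rep.per_sample) == len(ds)


def _symmetric_pair_dataset():
    """Records with A == B at 50:50 — exact fixed points of mirroring."""
    s = PolymerSample(monomer_a=MonomerSpec(smiles=HB3),
                      monomer_b=MonomerSpec(smiles="OC(=O)CC(C)O"),
                      frac_a=50.0, mw=100.0, pdi=2.0, tg=260.0)
    t = PolymerSample(monomer_a=MonomerSpec(smiles=HV3),
                      monomer_b=MonomerSpec(smiles=HV3),
                      frac_a=50.0, mw=50.0, pdi=1.5, tg=250.0)
    return PolymerDataset(samples=[s, t] * 5)


class TestSymmetryGap:
    def test_fixed_point_dataset_gap_zero(self, fast_config):
        ds = _symmetric_pair_dataset()
        cfg = ModelConfig(n_bits=32, hidden_layers=1, width=8, dropout_rate=0.0,
                          epochs=5, batch_size=8)
        res = TgModel.from_dataset(ds, config=cfg).fit()
        assert symmetry_gap(res, ds) == pytest.approx(0.0, abs=1e-9)


def _linear_stub(n_bits, coef_frac, coef_mw, const, ignore_pdi=True):
    """A fake fitted-results object: a known linear function of the
    numeric slots, for exact Shapley checks."""
    cfg = ModelConfig(n_bits=n_bits)

    def predict(X):
        X = np.atleast_2d(X)
        return coef_frac * X[:, 2 * n_bits] + coef_mw * X[:, 2 * n_bits + 1] + const

    return SimpleNamespace(
        config=cfg,
        model=SimpleNamespace(feature_mask=("frac_a", "mw", "pdi")),
        predict=predict,
    )


class TestImportance:
    def test_ignored_feature_scores_zero(self, tiny_dataset):
        ds, _ = tiny_dataset
        stub = _linear_stub(8, coef_frac=2.0, coef_mw=0.5, const=100.0)
        rep = importance(stub, ds, n_samples=10, seed=0, n_background=5)
        assert rep.scores["pdi"] == 0.0
        assert rep.scores["monomer_a"] >= 0.0

    def test_linear_model_matches_closed_form_shapley(self, tiny_dataset):
        """For a linear model with marginal background masking the Shapley
        value of feature j at x is coef_j * (x_j - mean_background(x_j)),
        independently of the coalition enumeration."""
        ds, _ = tiny_dataset
        a, b = 2.0, -0.3
        stub = _linear_stub(8, coef_frac=a, coef_mw=b, const=50.0)
        rep = importance(stub, ds, n_samples=len(ds), seed=1, n_background=len(ds))
        from phatg import encode_many

        X = encode_many(ds.samples, 8)
        rng = np.random.default_rng(1)
        eval_idx = rng.choice(len(X), size=len(X), replace=False)
        bg_idx = rng.choice(len(X), size=len(X), replace=False)
        frac, mw = X[:, 16], X[:, 17]
        exp_frac = np.mean(np.abs(a * (frac[eval_idx] - frac[bg_idx].mean())))
        exp_mw = np.mean(np.abs(b * (mw[eval_idx] - mw[bg_idx].mean())))
        assert rep.scores["frac_a"] == pytest.approx(exp_frac, rel=1e-9)
        assert rep.scores["mw"] == pytest.approx(exp_mw, rel=1e-9)

    def test_invalid_sample_count(self, tiny_dataset):
        ds, _ = tiny_dataset
        stub = _linear_stub(8, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            importance(stub, ds, n_samples=0)


class TestAblation:
    def test_fingerprint_drop_unsupported(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="fingerprint"):
            ablation_experiment(ds, drop=("monomer_a",))

    def test_drop_both_mw_and_pdi_input_dim(self, small_dataset):
        ds, _ = small_dataset
        cfg = ModelConfig(n_bits=128)
        from phatg.model import _mask_columns

        cols = _mask_columns(cfg.n_bits, ("frac_a",))
        assert len(cols) == 257  # 2N + 1

    def test_drop_nothing_equals_plain_protocol(self, small_dataset, fast_config):
        ds, _ = small_dataset
        a = ablation_experiment(ds, config=fast_config, drop=(), k=5, seed=3,
                                model_kind="lasso")
        b = cross_validate(ds, config=fast_config, model_kind="lasso", k=5, seed=3)
        assert a.averages == b.averages


class TestImputation:
    def test_rows_already_at_mean_unchanged(self, small_dataset, fast_config):
        ds, _ = small_dataset
        res = TgModel.from_dataset(ds, config=fast_config, kind="lasso",
                                   params={"alpha": 0.1}).fit()
        from phatg import encode_many

        X = encode_many(ds.samples, fast_config.n_bits)
        mw_mean = X[:, 2 * fast_config.n_bits + 1].mean()
        Xa = X.copy()
        Xa[:, 2 * fast_config.n_bits + 1] = mw_mean  # rows sit exactly at mean
        Xi = impute_columns(Xa, fast_config.n_bits, ("mw",), {"mw": mw_mean})
        assert np.array_equal(Xa, Xi)
        assert np.allclose(res.predict(Xa), res.predict(Xi))

    def test_statistics_come_from_training_rows(self, small_dataset, fast_config):
        ds, _ = small_dataset
        res = TgModel.from_dataset(ds.subset(range(80)), config=fast_config,
                                   kind="lasso", params={"alpha": 0.1}).fit()
        metrics = imputation_experiment(res, ds, "mw", "mean")
        assert set(metrics) == {"r2", "mae", "rmse"}
        assert metrics["rmse"] >= metrics["mae"]

    def test_requires_kept_models(self, small_dataset, fast_config):
        ds, _ = small_dataset
        rep = cross_validate(ds, config=fast_config, model_kind="lasso", k=5, seed=0)
        with pytest.raises(ValueError, match="keep_models"):
            imputation_cv(rep, ds, fast_config, "mw", "mean")

    def test_bad_statistic_rejected(self, small_dataset, fast_config):
        ds, _ = small_dataset
        rep = cross_validate(ds, config=fast_config, model_kind="lasso", k=5,
                             seed=0, keep_models=True)
        with pytest.raises(ValueError, match="statistic"):
            imputation_cv(rep, ds, fast_config, "mw", "mode")
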