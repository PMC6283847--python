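"""SVR training, cross-validated evaluation, metrics, feature selection,
and RRV category binning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from glycoplan.features import Dataset
from glycoplan.fixtures import generate_linear_dataset
from glycoplan.model import (
    ModelConfig,
    RRVModel,
    classify_rrv_category,
    evaluate,
    mae,
    pcc,
    predict,
    rae,
    select_features_backward,
    train,
)


@pytest.fixture(scope="module")
def realizable():
    ds, truth = generate_linear_dataset(n=60, sigma=0.0, seed=11)
    return ds, truth


class TestTrainPredict:
    def test_noiseless_linear_truth_fits_nearly_exactly(self, realizable):
        ds, _ = realizable
        model = train(ds)
        assert pcc(ds.rrv, predict(model, ds.X)) >= 0.999

    def test_constant_target_is_training_error(self):
        X = pd.DataFrame({"f": [0.1, 0.5, 0.9]}, index=list("abc"))
        rrv = pd.Series([10.0] * 3, index=list("abc"))
        ds = Dataset(X=X, rrv=rrv, ln_rrv=pd.Series(np.log(rrv), index=rrv.index))
        with pytest.raises(ValueError):
            train(ds)

    def test_predictions_positive_even_for_all_zero_row(self, realizable):
        ds, _ = realizable
        model = train(ds)
        row = pd.DataFrame(
            np.zeros((1, ds.X.shape[1])), columns=ds.X.columns, index=["z"]
        )
        out = predict(model, row)
        assert np.isfinite(out).all() and (out > 0).all()

    def test_missing_feature_column_is_schema_error(self, realizable):
        ds, _ = realizable
        model = train(ds)
        with pytest.raises(KeyError) as e:
            predict(model, ds.X.drop(columns=["f00"]))
        assert "f00" in str(e.value)

    def test_saved_model_reloads_with_identical_predictions(self, realizable, tmp_path):
        ds, _ = realizable
        model = train(ds)
        path = tmp_path / "model.joblib"
        model.save(path)
        again = RRVModel.load(path)
        assert np.array_equal(predict(model, ds.X), predict(again, ds.X))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 5.0, 20.0])
        assert pcc(y, y) == pytest.approx(1.0)
        assert mae(y, y) == 0.0
        assert rae(y, y) == 0.0

    def test_mean_predictor_rae_is_exactly_one(self):
        rng = np.random.default_rng(3)
        y = rng.lognormal(5, 2, size=50)
        yhat = np.full_like(y, y.mean())
        assert rae(y, yhat) == 1.0

    def test_rae_undefined_for_constant_target(self):
        with pytest.raises(ValueError):
            rae(np.ones(5), np.zeros(5))


class TestEvaluate:
    def test_loocv_equals_n_fold_cv(self):
        ds, _ = generate_linear_dataset(n=25, sigma=0.2, seed=5)
        a = evaluate(ds, scheme="loocv")
        b = evaluate(ds, scheme="kfold", k=ds.n, seed=123)
        assert a.pcc == pytest.approx(b.pcc, abs=1e-12)
        assert a.mae == pytest.approx(b.mae, abs=1e-9)
        assert a.rae == pytest.approx(b.rae, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        ds, _ = generate_linear_dataset(n=10, seed=6)
        with pytest.raises(ValueError):
            evaluate(ds, scheme="kfold", k=11)

    def test_category_accuracy_one_for_self_consistent_predictions(self):
        # degenerate check via report construction on identical scales
        ds, _ = generate_linear_dataset(n=40, sigma=0.0, seed=8)
        rep = evaluate(ds)
        disagree = np.mean(
            [classify_rrv_category(a) != classify_rrv_category(b)
             for a, b in zip(ds.rrv, rep.predictions)]
        )
        assert rep.category_accuracy == pytest.approx(1.0 - disagree)

    def test_fold_local_rescaling_not_leaky(self):
        """evaluate() must equal a hand-rolled LOOCV that refits the scaler
        inside every fold, and differ from the leaky variant that fits the
        scaler once on the full data."""
        ds, _ = generate_linear_dataset(n=20, sigma=0.3, seed=9)
        # an off-scale row makes the full-data scaler visibly different
        X = ds.X.copy()
        X.iloc[0, 0] = 25.0
        ds = Dataset(X=X, rrv=ds.rrv, ln_rrv=ds.ln_rrv)
        cfg = ModelConfig()
        rep = evaluate(ds, cfg)

        Xn = ds.X.to_numpy()
        y = ds.ln_rrv.to_numpy()
        honest = np.empty_like(y)
        leaky = np.empty_like(y)
        full_scaler = MinMaxScaler(clip=True).fit(Xn)
        for i in range(len(y)):
            tr = np.arange(len(y)) != i
            sc = MinMaxScaler(clip=True).fit(Xn[tr])
            svr = SVR(kernel=cfg.kernel, C=cfg.C, epsilon=cfg.epsilon)
            svr.fit(sc.transform(Xn[tr]), y[tr])
            honest[i] = svr.predict(sc.transform(Xn[[i]]))[0]
            svr2 = SVR(kernel=cfg.kernel, C=cfg.C, epsilon=cfg.epsilon)
            svr2.fit(full_scaler.transform(Xn[tr]), y[tr])
            leaky[i] = svr2.predict(full_scaler.transform(Xn[[i]]))[0]
        got = np.log(rep.predictions.to_numpy())
        assert np.allclose(got, honest, atol=1e-8)
        assert not np.allclose(honest, leaky, atol=1e-8)


class TestFeatureSelection:
    def test_informative_kept_noise_removed_noiseless(self):
        ds, truth = generate_linear_dataset(
            n=60, n_informative=4, n_noise=8, sigma=0.0, seed=12
        )
        selected, trace = select_features_backward(ds, seed=0)
        assert set(truth["informative"]) <= set(selected)
        kept_noise = set(selected) & set(truth["noise"])
        assert len(kept_noise) <= 0.2 * len(truth["noise"])
        assert trace[0][1] is None and len(trace) >= 2

    def test_both_informative_features_survive(self):
        ds, truth = generate_linear_dataset(
            n=50, n_informative=2, n_noise=0, sigma=0.0, seed=13
        )
        selected, _ = select_features_backward(ds, seed=0)
        assert set(selected) == set(truth["informative"])

    def test_duplicate_column_resolved_deterministically(self):
        ds, truth = generate_linear_dataset(
            n=50, n_informative=3, n_noise=0, sigma=0.0, seed=14,
            duplicate_features=1,
        )
        sel_a, _ = select_features_backward(ds, seed=0)
        sel_b, _ = select_features_backward(ds, seed=0)
        assert sel_a == sel_b
        # exactly one of the duplicated pair survives
        assert ("f00" in sel_a) != ("dup00" in sel_a)

    def test_always_keep_pins_features(self):
        ds, truth = generate_linear_dataset(
            n=40, n_informative=2, n_noise=4, sigma=0.0, seed=15
        )
        selected, _ = select_features_backward(
            ds, seed=0, always_keep=["noise00"]
        )
        assert "noise00" in selected

    def test_single_feature_dataset_rejected(self):
        ds, _ = generate_linear_dataset(n=20, n_informative=1, n_noise=0, seed=16)
        with pytest.raises(ValueError):
            select_features_backward(ds)


class TestCategoryBinning:
    @pytest.mark.parametrize(
        "rrv,cat",
        [
            (72_000.0, "high"),      # most reactive fucose donor
            (1462.0, "medium"),      # sialyl disaccharide donor
            (4000.0, "medium"),
            (850.0, "low"),
            (263.0, "low"), (132.0, "low"), (51.0, "low"),
            (32.0, "low"), (18.2, "low"), (13.0, "low"),
            (1000.0, "low"),         # boundary: closed on the low side
            (15_000.0, "medium"),    # boundary: closed on the medium side
            (15_000.1, "high"),
            (0.0, "low"),
        ],
    )
    def test_bins(self, rrv, cat):
        assert classify_rrv_category(rrv) == cat

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_rrv_category(-0.1)
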