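"""Support-vector regression of ln(RRV), evaluation, and wrapper feature
selection.

The regressor is an epsilon-SVR on the ln(RRV) target with all features
min-max rescaled into [0, 1]; predictions are back-transformed with exp so
metrics can be reported on the RRV scale (where MAE magnitudes are
meaningful against RRVs up to 72,000) as well as on the ln scale.

Evaluation refits the whole preprocessing + regression pipeline inside every
cross-validation fold, so the rescaler never sees held-out rows.

Feature selection is a backward greedy wrapper: starting from the full set,
the single feature whose removal raises (or least lowers) the 5-fold
cross-validated Pearson correlation is dropped, down to one feature; the
returned subset is the smallest one whose CV PCC is within ``pcc_tol`` of
the trace maximum (a parsimony tie-break, since near-duplicate subsets often
score within noise of each other).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from .features import Dataset

__all__ = [
    "ModelConfig",
    "RRVModel",
    "EvalReport",
    "pcc",
    "mae",
    "rae",
    "train",
    "predict",
    "evaluate",
    "select_features_backward",
    "classify_rrv_category",
    "CATEGORY_EDGES",
]

#: RRV category bins: high (>15,000], medium (1,000-15,000], low [0-1,000].
CATEGORY_EDGES = (1_000.0, 15_000.0)


def classify_rrv_category(rrv: float) -> str:
    """Three-way reactivity category used to judge one-pot orderings."""
    if rrv < 0:
        raise ValueError(f"rrv must be >= 0, got {rrv}")
    if rrv > CATEGORY_EDGES[1]:
        return "high"
    if rrv > CATEGORY_EDGES[0]:
        return "medium"
    return "low"


def pcc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation coefficient."""
    return float(stats.pearsonr(np.asarray(y, float), np.asarray(yhat, float))[0])


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(y, float) - np.asarray(yhat, float))))


def rae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Relative absolute error: sum|yhat-y| / sum|mean(y)-y|.

    The mean predictor scores exactly 1 by construction.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    denom = np.sum(np.abs(y - y.mean()))
    if denom == 0:
        raise ValueError("RAE undefined: target is constant")
    return float(np.sum(np.abs(yhat - y)) / denom)


@dataclass(frozen=True)
class ModelConfig:
    """SVR hyperparameters (none are published for this problem; exposed)."""

    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 0.001
    gamma: str | float = "scale"

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _make_pipeline(config: ModelConfig) -> Pipeline:
    return Pipeline(
        [
            ("rescale", MinMaxScaler(clip=True)),
            ("svr", SVR(kernel=config.kernel, C=config.C,
                        epsilon=config.epsilon, gamma=config.gamma)),
        ]
    )


@dataclass
class RRVModel:
    """A fitted RRV predictor: pipeline + feature subset + metadata."""

    pipeline: Pipeline
    feature_names: list[str]
    config: ModelConfig
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "RRVModel":
        obj = joblib.load(path)
        if not isinstance(obj, RRVModel):
            raise TypeError(f"{path} does not hold an RRVModel")
        return obj


def train(
    dataset: Dataset,
    config: ModelConfig = ModelConfig(),
    feature_names: Sequence[str] | None = None,
) -> RRVModel:
    """Fit the pipeline on ln(RRV); deterministic given data and config."""
    names = list(feature_names) if feature_names is not None else list(dataset.X.columns)
    missing = [n for n in names if n not in dataset.X.columns]
    if missing:
        raise KeyError(f"dataset lacks features {missing}")
    y = dataset.ln_rrv.to_numpy()
    if np.ptp(y) == 0:
        raise ValueError("degenerate dataset: constant regression target")
    pipe = _make_pipeline(config)
    pipe.fit(dataset.X[names].to_numpy(), y)
    return RRVModel(
        pipeline=pipe,
        feature_names=names,
        config=config,
        meta={"n": dataset.n, "config_hash": config.hash()},
    )


def predict(model: RRVModel, rows: pd.DataFrame) -> np.ndarray:
    """Back-transformed predictions on the RRV scale (always > 0)."""
    missing = [n for n in model.feature_names if n not in rows.columns]
    if missing:
        raise KeyError(f"feature rows missing {missing}")
    ln_pred = model.pipeline.predict(rows[model.feature_names].to_numpy())
    return np.exp(ln_pred)


@dataclass
class EvalReport:
    """Cross-validated performance on both target scales."""

    scheme: str
    n: int
    n_features: int
    pcc: float
    mae: float
    rae: float
    pcc_ln: float
    mae_ln: float
    rae_ln: float
    per_category_pcc: dict[str, float]
    category_accuracy: float
    predictions: pd.Series | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "predictions"}
        return d


def _cv_predictions(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, splitter
) -> np.ndarray:
    """Out-of-fold ln-scale predictions; pipeline refit per training fold."""
    out = np.empty_like(y)
    pipe = _make_pipeline(config)
    for train_idx, test_idx in splitter.split(X):
        est = clone(pipe)
        est.fit(X[train_idx], y[train_idx])
        out[test_idx] = est.predict(X[test_idx])
    return out


def evaluate(
    dataset: Dataset,
    config: ModelConfig = ModelConfig(),
    scheme: str = "loocv",
    k: int | None = None,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> EvalReport:
    """LOOCV or k-fold evaluation with fold-local preprocessing.

    ``scheme='kfold'`` with ``k == n`` is identical to LOOCV: every fold is a
    single row trained on the rest.
    """
    names = list(feature_names) if feature_names is not None else list(dataset.X.columns)
    X = dataset.X[names].to_numpy()
    y_ln = dataset.ln_rrv.to_numpy()
    n = len(y_ln)
    if scheme == "loocv":
        splitter = LeaveOneOut()
    elif scheme == "kfold":
        if k is None or not 2 <= k <= n:
            raise ValueError(f"kfold needs 2 <= k <= n, got k={k}, n={n}")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        raise ValueError("scheme must be 'loocv' or 'kfold'")
    pred_ln = _cv_predictions(X, y_ln, config, splitter)

    y_rrv = dataset.rrv.to_numpy()
    pred_rrv = np.exp(pred_ln)
    cats_obs = [classify_rrv_category(v) for v in y_rrv]
    cats_pred = [classify_rrv_category(v) for v in pred_rrv]
    per_cat: dict[str, float] = {}
    for cat in ("high", "medium", "low"):
        idx = [i for i, c in enumerate(cats_obs) if c == cat]
        per_cat[cat] = (
            pcc(y_rrv[idx], pred_rrv[idx]) if len(idx) >= 2 else float("nan")
        )
    return EvalReport(
        scheme=scheme if scheme == "loocv" else f"kfold({k},{seed})",
        n=n,
        n_features=len(names),
        pcc=pcc(y_rrv, pred_rrv),
        mae=mae(y_rrv, pred_rrv),
        rae=rae(y_rrv, pred_rrv),
        pcc_ln=pcc(y_ln, pred_ln),
        mae_ln=mae(y_ln, pred_ln),
        rae_ln=rae(y_ln, pred_ln),
        per_category_pcc=per_cat,
        category_accuracy=float(
            np.mean([a == b for a, b in zip(cats_obs, cats_pred)])
        ),
        predictions=pd.Series(pred_rrv, index=dataset.X.index, name="predicted_rrv"),
    )


def _selection_score(
    X: pd.DataFrame, y_ln: np.ndarray, y_rrv: np.ndarray,
    names: Sequence[str], config: ModelConfig, cv: int, seed: int,
) -> float:
    """Pooled out-of-fold PCC (RRV scale) under seeded, category-stratified
    k-fold CV; falls back to plain k-fold when a category is too small."""
    cats = np.array([classify_rrv_category(v) for v in y_rrv])
    counts = pd.Series(cats).value_counts()
    Xn = X[list(names)].to_numpy()
    if counts.min() >= cv and len(counts) > 1:
        splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        splits = splitter.split(Xn, cats)
    else:
        splitter = KFold(n_splits=cv, shuffle=True, random_state=seed)
        splits = splitter.split(Xn)
    pred = np.empty_like(y_ln)
    pipe = _make_pipeline(config)
    for tr, te in splits:
        est = clone(pipe)
        est.fit(Xn[tr], y_ln[tr])
        pred[te] = est.predict(Xn[te])
    return pcc(y_rrv, np.exp(pred))


def select_features_backward(
    dataset: Dataset,
    config: ModelConfig = ModelConfig(),
    cv: int = 5,
    seed: int = 0,
    always_keep: Sequence[str] = (),
    min_features: int = 1,
    pcc_tol: float = 1e-4,
) -> tuple[list[str], list[tuple[int, str | None, float]]]:
    """Backward greedy wrapper selection by cross-validated PCC.

    Returns the selected feature names and the elimination trace as
    ``(n_features, dropped_feature, cv_pcc)`` tuples (the first entry has no
    dropped feature).  Ties on PCC drop the lexicographically last feature.
    ``always_keep`` pins features that may never be dropped (e.g. to retain
    complete sugar-type information).
    """
    names = list(dataset.X.columns)
    if len(names) < 2:
        raise ValueError("feature selection needs at least 2 features")
    y_ln = dataset.ln_rrv.to_numpy()
    y_rrv = dataset.rrv.to_numpy()
    keep = set(always_keep)
    missing = keep - set(names)
    if missing:
        raise KeyError(f"always_keep features not in dataset: {sorted(missing)}")

    current = list(names)
    score = _selection_score(dataset.X, y_ln, y_rrv, current, config, cv, seed)
    trace: list[tuple[int, str | None, float]] = [(len(current), None, score)]
    snapshots = [list(current)]
    while len(current) > max(min_features, len(keep), 1):
        best_drop: str | None = None
        best_score = -np.inf
        for cand in sorted(current, reverse=True):  # tie -> last name dropped
            if cand in keep:
                continue
            trial = [n for n in current if n != cand]
            s = _selection_score(dataset.X, y_ln, y_rrv, trial, config, cv, seed)
            if s > best_score:
                best_score = s
                best_drop = cand
        if best_drop is None:
            break
        current = [n for n in current if n != best_drop]
        trace.append((len(current), best_drop, best_score))
        snapshots.append(list(current))
    top = max(t[2] for t in trace)
    # smallest subset scoring within tolerance of the optimum
    best_i = max(
        (i for i, t in enumerate(trace) if t[2] >= top - pcc_tol),
        key=lambda i: i,
    )
    return snapshots[best_i], trace
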