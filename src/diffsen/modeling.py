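"""Feature selection, regularized model fitting and evaluation.

For each drug the resistance differential (DiffSen) is regressed on
transporter expression / genetic features:

* features are ranked by signed Pearson correlation with DiffSen on the
  training cells only, and the top-k enter the models;
* three candidate families are fitted — Lasso (L1) and Ridge (L2) with the
  penalty weight tuned on a logarithmic grid by seeded 5-fold
  cross-validation, and a Random Forest tuned over (variables-per-split,
  tree count) by out-of-bag error;
* the family with the best training-set score (mean CV Pearson r of
  held-out predictions; for the forest, the OOB-prediction r) predicts the
  held-out cells, and the model is called successful when the Pearson
  p-value of prediction vs truth is below alpha.

Nothing here ever touches test-set responses before evaluation; the
no-leakage property is part of the contract (and of the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold

from ._util import fanout_seed, pearson_with_p
from .core import compute_diffsen, split_train_test
from .exceptions import ModelingError, TransferRefused
from .io import DrugRecord

#: penalty-weight grid shared by lasso and ridge (sklearn ``alpha``)
LAMBDA_GRID: np.ndarray = np.logspace(-3, 2, 16)
#: random-forest tree-count grid
RF_TREES: tuple[int, ...] = (250, 500, 1000)
#: tie-break precedence when CV scores are exactly equal
FAMILY_PRECEDENCE: tuple[str, ...] = ("lasso", "ridge", "random_forest")


@dataclass
class FeatureSelection:
    """Correlation ranking of the full feature universe for one drug, plus
    the top-k subset that enters the models."""

    drug_id: str
    ranked_features: list[tuple[str, float, float]]  # (feature, r, p), r desc
    selected: list[str]

    @property
    def universe(self) -> list[str]:
        return [f for f, _, _ in self.ranked_features]


@dataclass
class CandidateFit:
    """One fitted model family with its tuned hyperparameters."""

    family: str
    hyperparameters: dict
    cv_score: float
    feature_ids: list[str]
    _estimator: object = field(repr=False)
    _x_mean: np.ndarray | None = field(default=None, repr=False)
    _x_sd: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in X.columns]
        if missing:
            raise ModelingError(f"missing features at prediction time: {missing}")
        M = X[self.feature_ids].to_numpy(float)
        if self._x_mean is not None:
            M = (M - self._x_mean) / self._x_sd
        return np.asarray(self._estimator.predict(M), dtype=float)


@dataclass
class ModelResult:
    """Outcome of training + evaluating one drug on one dataset pair."""

    drug_id: str
    train_dataset: str
    test_dataset: str
    model_family: str
    hyperparameters: dict
    cv_score: float
    test_r: float
    test_p: float
    n_train_cells: int
    n_test_cells: int
    seed: int
    success: bool
    selection: FeatureSelection | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "train_dataset": self.train_dataset,
            "test_dataset": self.test_dataset,
            "model_family": self.model_family,
            "cv_score": self.cv_score,
            "test_r": self.test_r,
            "test_p": self.test_p,
            "n_train_cells": self.n_train_cells,
            "n_test_cells": self.n_test_cells,
            "success": self.success,
        }


def select_features(
    features: pd.DataFrame, y: pd.Series, k: int, absolute: bool = False
) -> FeatureSelection:
    """Rank features by Pearson correlation with the target on training
    cells and keep the top k.

    ``features`` is features x cells and must already be restricted to (or
    is restricted here to) the training cells carried by ``y`` — selection
    never sees held-out cells.  Ranking is by signed r descending (set
    ``absolute`` for |r|), ties broken lexicographically by feature id;
    constant features get r = 0.
    """
    if k <= 0:
        raise ModelingError(f"k must be positive, got {k}")
    cells = [c for c in y.index if c in features.columns]
    X = features[cells].to_numpy(float)
    yv = y[cells].to_numpy(float)
    n = len(cells)
    yc = yv - yv.mean()
    ysd = yv.std(ddof=0)
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = X.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / n / np.where(xsd * ysd > 0, xsd * ysd, np.nan)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    from scipy import stats

    p = np.minimum(2.0 * stats.t.sf(np.abs(t), df=n - 2), 1.0)
    key = np.abs(r) if absolute else r
    order = sorted(range(len(features.index)), key=lambda i: (-key[i], features.index[i]))
    ranked = [(features.index[i], float(r[i]), float(p[i])) for i in order]
    selected = [f for f, _, _ in ranked[: min(k, len(ranked))]]
    return FeatureSelection(drug_id=str(y.name), ranked_features=ranked, selected=selected)


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (M - mean) / sd, mean, sd


def _cv_linear(M: np.ndarray, yv: np.ndarray, family: str, seed: int) -> tuple[float, float]:
    """Tune the penalty weight by 5-fold CV; returns (best_lambda, cv_score)."""
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    folds = list(kf.split(M))
    best_lam, best_score = None, -np.inf
    for lam in LAMBDA_GRID:
        scores = []
        for tr, te in folds:
            Ms, mean, sd = _standardize(M[tr])
            est = _make_linear(family, lam)
            est.fit(Ms, yv[tr])
            pred = est.predict((M[te] - mean) / sd)
            r, _ = pearson_with_p(pred, yv[te])
            scores.append(r)
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_lam, best_score = float(lam), score
    return best_lam, best_score


def _make_linear(family: str, lam: float):
    if family == "lasso":
        return Lasso(alpha=lam, max_iter=50000)
    return Ridge(alpha=lam)


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Fit a plain (unstandardized) lasso; returns (coefficients, intercept).

    Exposed for closed-form checks: with ``lam`` above the critical value
    ``max|X_c^T y_c| / n`` every coefficient is exactly zero.
    """
    est = Lasso(alpha=lam, max_iter=50000)
    est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Fit a plain ridge regression; returns (coefficients, intercept).

    In the ``lam`` → 0 limit this reproduces ordinary least squares on a
    full-rank problem.
    """
    est = Ridge(alpha=lam)
    est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_)


def _fit_rf_grid(M: np.ndarray, yv: np.ndarray, seed: int):
    """Random-forest grid search minimizing out-of-bag MSE.

    Variables-per-split runs over {sqrt(p), p/3, p/2}; for each, the tree
    count runs over :data:`RF_TREES` as *nested* forests (the k-tree forest
    is the first k trees of the largest forest, grown warm-start), with OOB
    predictions accumulated tree by tree and snapshotted at each grid size.
    Returns (mtry, n_trees, oob_pearson_r, fitted_forest) of the best cell.
    """
    n, p = M.shape
    mtry_grid = sorted({max(1, int(math.isqrt(p))), max(1, p // 3), max(1, p // 2)})
    best = None  # (err, mtry, ntrees, r, forest)
    for mtry in mtry_grid:
        rf = RandomForestRegressor(
            n_estimators=RF_TREES[-1],
            max_features=mtry,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(M, yv)
        pred_sum = np.zeros(n)
        counts = np.zeros(n)
        snapshots = {}
        for i, (tree, sampled) in enumerate(zip(rf.estimators_, rf.estimators_samples_), 1):
            inbag = np.bincount(sampled, minlength=n) > 0
            oob = ~inbag
            if oob.any():
                pred_sum[oob] += tree.predict(M[oob])
                counts[oob] += 1
            if i in RF_TREES:
                valid = counts > 0
                oob_pred = pred_sum[valid] / counts[valid]
                snapshots[i] = (
                    float(np.mean((oob_pred - yv[valid]) ** 2)),
                    oob_pred,
                    valid,
                )
        for ntrees in RF_TREES:
            err, oob_pred, valid = snapshots[ntrees]
            if best is None or err < best[0] - 1e-12:
                r, _ = pearson_with_p(oob_pred, yv[valid])
                best = (err, mtry, ntrees, r, rf)
    _, mtry, ntrees, r, rf = best
    if ntrees < len(rf.estimators_):
        rf.estimators_ = rf.estimators_[:ntrees]
        rf.n_estimators = ntrees
    return mtry, ntrees, r, rf


def fit_candidates(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    seed: int = 0,
    families: tuple[str, ...] = FAMILY_PRECEDENCE,
) -> list[CandidateFit]:
    """Fit and tune the candidate model families on the training cells.

    ``X_train`` is cells x features (selected features only).  Lasso/ridge
    are tuned over :data:`LAMBDA_GRID` by seeded 5-fold CV scored as the
    mean per-fold Pearson r between held-out predictions and truth; the
    random forest is tuned over (variables-per-split in {sqrt(p), p/3, p/2},
    trees in {250, 500, 1000}) minimizing out-of-bag mean squared error,
    with its comparable score the OOB-prediction Pearson r.
    """
    cells = list(X_train.index)
    if len(cells) < 25:
        raise ModelingError(
            f"need at least 25 training cells (5 per fold), got {len(cells)}"
        )
    yv = y_train.loc[cells].to_numpy(float)
    if np.std(yv) == 0:
        raise ModelingError("degenerate target: y is constant on training cells")
    M = X_train.to_numpy(float)
    p = M.shape[1]
    fits: list[CandidateFit] = []

    for family in families:
        if family in ("lasso", "ridge"):
            lam, score = _cv_linear(M, yv, family, seed)
            Ms, mean, sd = _standardize(M)
            est = _make_linear(family, lam)
            est.fit(Ms, yv)
            fits.append(
                CandidateFit(
                    family=family,
                    hyperparameters={"lambda": lam},
                    cv_score=score,
                    feature_ids=list(X_train.columns),
                    _estimator=est,
                    _x_mean=mean,
                    _x_sd=sd,
                )
            )
        elif family == "random_forest":
            mtry, ntrees, r, rf = _fit_rf_grid(M, yv, seed)
            fits.append(
                CandidateFit(
                    family="random_forest",
                    hyperparameters={"max_features": mtry, "n_trees": ntrees},
                    cv_score=r,
                    feature_ids=list(X_train.columns),
                    _estimator=rf,
                )
            )
        else:
            raise ModelingError(f"unknown model family {family!r}")
    return fits


def pick_best_and_evaluate(
    candidates: list[CandidateFit],
    X_test: pd.DataFrame,
    y_test: pd.Series,
    drug_id: str = "",
    train_dataset: str = "",
    test_dataset: str = "",
    alpha: float = 0.05,
    n_train_cells: int = 0,
    seed: int = 0,
    selection: FeatureSelection | None = None,
) -> ModelResult:
    """Evaluate the training-set winner on held-out cells.

    The winner is the candidate with the highest training score; exact ties
    fall back to the fixed precedence lasso < ridge < random_forest.
    """
    if not candidates:
        raise ModelingError("no candidates to evaluate")
    missing = [
        f for f in candidates[0].feature_ids if f not in X_test.columns
    ]
    if missing:
        raise ModelingError(f"test matrix lacks training features: {missing}")
    winner = min(
        candidates,
        key=lambda c: (-c.cv_score, FAMILY_PRECEDENCE.index(c.family)),
    )
    cells = list(X_test.index)
    pred = winner.predict(X_test)
    r, p = pearson_with_p(pred, y_test.loc[cells].to_numpy(float))
    return ModelResult(
        drug_id=drug_id,
        train_dataset=train_dataset,
        test_dataset=test_dataset,
        model_family=winner.family,
        hyperparameters=winner.hyperparameters,
        cv_score=winner.cv_score,
        test_r=r,
        test_p=p,
        n_train_cells=n_train_cells,
        n_test_cells=len(cells),
        seed=seed,
        success=bool(p < alpha),
        selection=selection,
    )


def within_dataset_run(
    drug: DrugRecord,
    dataset_name: str,
    sensitivity: pd.DataFrame,
    silencing: pd.DataFrame,
    features: pd.DataFrame,
    k: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    split_fraction: float = 0.7,
    diffsen_mode: str = "zscore",
) -> ModelResult:
    """The per-drug, single-dataset experiment: compute DiffSen, split
    70/30, select features and train on the training cells, evaluate on the
    held-out cells."""
    ds = compute_diffsen(drug, sensitivity, silencing, dataset=dataset_name, mode=diffsen_mode)
    y = ds.to_series()
    usable = [c for c in ds.cell_ids if c in features.columns]
    split = split_train_test(usable, fraction=split_fraction, seed=seed)
    y_train, y_test = y[split.train_cells], y[split.test_cells]
    sel = select_features(features[split.train_cells], y_train, k)
    X_train = features.loc[sel.selected, split.train_cells].T
    X_test = features.loc[sel.selected, split.test_cells].T
    candidates = fit_candidates(X_train, y_train, seed=seed)
    return pick_best_and_evaluate(
        candidates, X_test, y_test,
        drug_id=drug.drug_id,
        train_dataset=dataset_name,
        test_dataset=dataset_name,
        alpha=alpha,
        n_train_cells=len(split.train_cells),
        seed=seed,
        selection=sel,
    )


def cross_dataset_run(
    drug: DrugRecord,
    train_name: str,
    train_mats: dict[str, pd.DataFrame],
    test_name: str,
    test_mats: dict[str, pd.DataFrame],
    k: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    diffsen_mode: str = "zscore",
    min_test_cells: int = 10,
) -> ModelResult:
    """Train on every cell of one dataset, evaluate on another.

    Feature selection is restricted to features profiled in both datasets,
    and evaluation uses only test-dataset cells absent from the training
    dataset, so transfer performance is never inflated by shared cell
    lines.  Raises :class:`TransferRefused` when no shared features or too
    few eligible test cells remain.
    """
    shared_features = sorted(
        set(train_mats["features"].index) & set(test_mats["features"].index)
    )
    if not shared_features:
        raise TransferRefused("no_shared_features")
    ds_train = compute_diffsen(
        drug, train_mats["sensitivity"], train_mats["silencing"],
        dataset=train_name, mode=diffsen_mode,
    )
    ds_test = compute_diffsen(
        drug, test_mats["sensitivity"], test_mats["silencing"],
        dataset=test_name, mode=diffsen_mode,
    )
    train_cells = [c for c in ds_train.cell_ids if c in train_mats["features"].columns]
    train_cell_universe = set(train_mats["features"].columns)
    test_cells = [
        c for c in ds_test.cell_ids
        if c in test_mats["features"].columns and c not in train_cell_universe
    ]
    if len(test_cells) < min_test_cells:
        raise TransferRefused(
            "too_few_test_cells",
            f"{len(test_cells)} test-only cells (< {min_test_cells}) after "
            f"excluding cells shared with {train_name}",
        )
    y_train = ds_train.to_series()[train_cells]
    y_test = ds_test.to_series()[test_cells]
    feats_train = train_mats["features"].loc[shared_features]
    sel = select_features(feats_train[train_cells], y_train, k)
    X_train = feats_train.loc[sel.selected, train_cells].T
    X_test = test_mats["features"].loc[sel.selected, test_cells].T
    candidates = fit_candidates(X_train, y_train, seed=seed)
    return pick_best_and_evaluate(
        candidates, X_test, y_test,
        drug_id=drug.drug_id,
        train_dataset=train_name,
        test_dataset=test_name,
        alpha=alpha,
        n_train_cells=len(train_cells),
        seed=seed,
        selection=sel,
    )
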