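"""Gradient-boosted regression harness: k-fold cross-validation, random
hyperparameter search, and the fold-ensemble consensus predictor.

The regressor family is gradient-boosted decision trees (XGBoost); a small
registry exposes the common alternatives for comparison runs.  Metrics are
always computed on the pooled out-of-fold predictions, in which each training
row appears exactly once; the final model is the mean of the k fold models
from the best search iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (ExtraTreesRegressor, GradientBoostingRegressor,
                              RandomForestRegressor)
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

# --------------------------------------------------------------------------
# Training data
# --------------------------------------------------------------------------


@dataclass
class TrainingTable:
    """Feature rows with experimental ddG targets (kcal/mol)."""
    complex_ids: list[str]
    mutations: list[str]
    X: pd.DataFrame
    y: np.ndarray
    manifest_hash: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.X)
        if not (len(self.complex_ids) == len(self.mutations) == len(self.y)
                == n):
            raise ValueError("inconsistent table lengths")
        keys = list(zip(self.complex_ids, self.mutations))
        if len(set(keys)) != n:
            raise ValueError("duplicated (complex, mutation) keys")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite ddG values")

    def __len__(self):
        return len(self.y)

    def check_finite(self) -> None:
        values = self.X.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(values))
        if len(bad):
            r, c = bad[0]
            raise ValueError(f"non-finite feature: row {r} "
                             f"({self.complex_ids[r]} {self.mutations[r]}), "
                             f"column {self.X.columns[c]!r}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, feature_names,
                   manifest_hash: str) -> "TrainingTable":
        """Build from a table with pdb_id, mutation, ddg + feature columns."""
        return cls(frame["pdb_id"].tolist(), frame["mutation"].tolist(),
                   frame[list(feature_names)].copy(),
                   frame["ddg"].to_numpy(float), manifest_hash)


# --------------------------------------------------------------------------
# Regressor registry
# --------------------------------------------------------------------------


def _make_xgboost(params: dict, seed: int):
    defaults = dict(n_estimators=300, max_depth=4, learning_rate=0.05,
                    subsample=0.9, colsample_bytree=0.9, reg_alpha=0.0,
                    reg_lambda=1.0, min_child_weight=1.0)
    defaults.update(params)
    return XGBRegressor(random_state=seed, n_jobs=1, tree_method="hist",
                        verbosity=0, **defaults)


REGRESSORS = {
    "xgboost": _make_xgboost,
    "random_forest": lambda p, s: RandomForestRegressor(
        random_state=s, n_jobs=1, **p),
    "extra_trees": lambda p, s: ExtraTreesRegressor(
        random_state=s, n_jobs=1, **p),
    "gradient_boosting": lambda p, s: GradientBoostingRegressor(
        random_state=s, **p),
}


def default_hyperparameter_space() -> dict:
    """Documented default search dictionary for the boosted-tree regressor."""
    return {
        "n_estimators": ("int", 100, 2000),
        "max_depth": ("int", 2, 10),
        "learning_rate": ("log", 0.005, 0.3),
        "subsample": ("float", 0.5, 1.0),
        "colsample_bytree": ("float", 0.5, 1.0),
        "reg_alpha": ("float", 0.0, 10.0),
        "reg_lambda": ("float", 0.0, 10.0),
        "min_child_weight": ("int", 1, 10),
    }


def sample_hyperparameters(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        if isinstance(spec, (list, tuple)) and spec and spec[0] in (
                "int", "float", "log"):
            kind, lo, hi = spec
            if kind == "int":
                out[name] = int(rng.integers(lo, hi + 1))
            elif kind == "float":
                out[name] = float(rng.uniform(lo, hi))
            else:
                out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:  # explicit candidate list
            out[name] = spec[int(rng.integers(len(spec)))]
    return out


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


def evaluate(y_true, y_pred) -> tuple[float, float, float, float]:
    """(PCC, RMSE kcal/mol, slope, intercept of predicted-vs-true OLS)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise ValueError("need two equal-length vectors of size >= 3")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("correlation undefined for constant input")
    pcc = float(stats.pearsonr(y_true, y_pred).statistic)
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    slope, intercept = np.polyfit(y_true, y_pred, 1)
    return pcc, rmse, float(slope), float(intercept)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint validation-index sets covering 0..n-1, sizes within 1."""
    if not 2 <= k <= n:
        raise ValueError(f"k = {k} must satisfy 2 <= k <= n = {n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _train, test in splitter.split(np.arange(n))]


@dataclass
class CVResult:
    models: list
    oof_predictions: np.ndarray
    fold_indices: list[np.ndarray]
    pcc: float
    rmse: float
    slope: float
    intercept: float
    per_fold_pcc: list[float]
    hyperparameters: dict
    seed: int
    iteration: int = 0


def cross_validate(table: TrainingTable, hyperparams: dict | None = None,
                   k: int = 5, seed: int = 0, regressor: str = "xgboost",
                   iteration: int = 0) -> CVResult:
    """k-fold CV with pooled out-of-fold metrics (each row predicted once)."""
    if len(table) == 0:
        raise ValueError("empty training table")
    table.check_finite()
    hyperparams = dict(hyperparams or {})
    folds = kfold_split(len(table), k, seed)
    X = table.X.to_numpy(dtype=float)
    y = table.y
    oof = np.full(len(y), np.nan)
    models = []
    per_fold = []
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = REGRESSORS[regressor](hyperparams, seed + fold_id)
        model.fit(X[train_mask], y[train_mask])
        pred = model.predict(X[test_idx])
        oof[test_idx] = pred
        models.append(model)
        if len(test_idx) >= 3 and np.ptp(y[test_idx]) > 0 \
                and np.ptp(pred) > 0:
            per_fold.append(float(stats.pearsonr(y[test_idx],
                                                 pred).statistic))
        else:
            per_fold.append(float("nan"))
    assert not np.any(np.isnan(oof)), "out-of-fold partition incomplete"
    pcc, rmse, slope, intercept = evaluate(y, oof)
    return CVResult(models, oof, folds, pcc, rmse, slope, intercept,
                    per_fold, hyperparams, seed, iteration)


def random_search(table: TrainingTable, space: dict | None = None,
                  iterations: int = 1000, k: int = 5, seed: int = 0,
                  regressor: str = "xgboost"):
    """Random hyperparameter search over repeated k-fold CV.

    Returns (best CVResult by pooled PCC, full per-iteration log).
    """
    space = space or default_hyperparameter_space()
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best: CVResult | None = None
    for it in range(iterations):
        params = sample_hyperparameters(space, rng)
        it_seed = int(rng.integers(2 ** 31 - 1))
        result = cross_validate(table, params, k=k, seed=it_seed,
                                regressor=regressor, iteration=it)
        log.append({"iteration": it, "seed": it_seed, "pcc": result.pcc,
                    "rmse": result.rmse, "hyperparameters": params})
        if best is None or result.pcc > best.pcc:
            best = result
    return best, log


def repeated_cv(table: TrainingTable, hyperparams: dict | None = None,
                repeats: int = 50, k: int = 5, seed: int = 0,
                regressor: str = "xgboost"):
    """Repeat k-fold CV with fresh splits; summary of the pooled PCC.

    Returns (mean PCC, SD of PCC, list of per-repeat CVResult).
    """
    rng = np.random.default_rng(seed)
    results = [cross_validate(table, hyperparams,
                              k=k, seed=int(rng.integers(2 ** 31 - 1)),
                              regressor=regressor, iteration=r)
               for r in range(repeats)]
    pccs = np.array([r.pcc for r in results])
    return float(pccs.mean()), float(pccs.std(ddof=1)), results


# --------------------------------------------------------------------------
# Fold-ensemble bundle
# --------------------------------------------------------------------------


def _model_predict(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "get_booster") or not hasattr(model, "num_boosted_rounds"):
        try:
            return np.asarray(model.predict(X))
        except TypeError:
            pass
    import xgboost

    return np.asarray(model.predict(xgboost.DMatrix(X)))


@dataclass
class ModelBundle:
    """k fold models; the prediction is their mean."""
    models: list
    hyperparameters: dict
    manifest_hash: str
    task: str
    feature_names: list[str]
    seed: int
    regressor: str = "xgboost"
    metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        preds = np.stack([_model_predict(m, X) for m in self.models])
        return preds.mean(axis=0)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.regressor != "xgboost":
            raise ValueError("only boosted-tree bundles are serializable")
        for i, model in enumerate(self.models):
            booster = model.get_booster() if hasattr(model, "get_booster") \
                else model
            booster.save_model(directory / f"fold_{i}.json")
        info = {"hyperparameters": self.hyperparameters,
                "manifest_hash": self.manifest_hash, "task": self.task,
                "feature_names": self.feature_names, "seed": self.seed,
                "regressor": self.regressor, "k": len(self.models),
                "metadata": self.metadata, "format_version": 1}
        (directory / "bundle.json").write_text(json.dumps(info, indent=1))

    @classmethod
    def load(cls, directory, expected_manifest_hash: str | None = None
             ) -> "ModelBundle":
        directory = Path(directory)
        info = json.loads((directory / "bundle.json").read_text())
        if expected_manifest_hash is not None and \
                info["manifest_hash"] != expected_manifest_hash:
            raise ValueError(
                "feature manifest mismatch: bundle was trained with "
                f"{info['manifest_hash'][:12]}..., expected "
                f"{expected_manifest_hash[:12]}...")
        import xgboost

        models = []
        for i in range(info["k"]):
            booster = xgboost.Booster()
            booster.load_model(directory / f"fold_{i}.json")
            models.append(booster)
        return cls(models, info["hyperparameters"], info["manifest_hash"],
                   info["task"], info["feature_names"], info["seed"],
                   info["regressor"], info.get("metadata", {}))


def train_ensemble(table: TrainingTable, hyperparams: dict | None = None,
                   k: int = 5, seed: int = 0, regressor: str = "xgboost",
                   cv_result: CVResult | None = None) -> ModelBundle:
    """Retain the k fold models of a CV run as the consensus predictor."""
    if cv_result is None:
        cv_result = cross_validate(table, hyperparams, k=k, seed=seed,
                                   regressor=regressor)
    return ModelBundle(cv_result.models, cv_result.hyperparameters,
                       table.manifest_hash, table.meta.get("task", "protein"),
                       list(table.X.columns), cv_result.seed, regressor,
                       metadata={"pcc": cv_result.pcc,
                                 "rmse": cv_result.rmse,
                                 "slope": cv_result.slope,
                                 "intercept": cv_result.intercept})
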