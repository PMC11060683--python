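"""Gradient-boosted tree modeling of ASE with Shapley interpretation.

statsmodels-style surface: :class:`AseBoostModel` is configured from a
feature table (four presets mirror the study design — Model 0: all 46
predictors / 4 ASE classes; Model 1: 15 predictors / 4 classes; Model 2:
15 predictors / binary ASE vs no-ASE; Model 3: 15 predictors / regression on
the absolute TPM difference) and ``fit()`` returns an :class:`AseBoostResults`
carrying metrics, gain importances, ROC curves and TreeSHAP attributions.

Hyperparameters default to eta 0.3, gamma 0.001, max_depth 2, up to 100,000
rounds with early stopping after 200 stalled rounds on a validation subset
carved from the training split (never the test set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    f1_score,
    r2_score,
    recall_score,
    roc_curve,
)
from sklearn.model_selection import train_test_split

from .ase import MODEL_CLASSES
from .features import CATALOG, MODEL1_FEATURES

__all__ = [
    "BoostParams",
    "SplitSpec",
    "AseBoostModel",
    "AseBoostResults",
    "train_model",
    "evaluate_model",
    "feature_importance",
    "shap_explain",
]

_OBJECTIVES = {
    "multiclass": ("multi:softprob", "mlogloss"),
    "binary": ("binary:logistic", "logloss"),
    "regression": ("reg:squarederror", "rmse"),
}


@dataclass(frozen=True)
class BoostParams:
    eta: float = 0.3
    gamma: float = 0.001
    max_depth: int = 2
    nrounds: int = 100_000
    early_stopping_rounds: int = 200
    print_every_n: int = 100
    objective: str = "multiclass"
    seed: int = 0
    nthread: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.early_stopping_rounds >= self.nrounds:
            raise ValueError("early_stopping_rounds must be < nrounds")
        if self.objective not in _OBJECTIVES:
            raise ValueError(f"objective must be one of {sorted(_OBJECTIVES)}")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    validation_fraction: float = 0.20  # of the training split, for early stopping
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")

    @property
    def test_fraction(self) -> float:
        return 1.0 - self.train_fraction


class AseBoostModel:
    """A gradient-boosted ASE model specification bound to a feature table."""

    def __init__(
        self,
        table: pd.DataFrame,
        features: Sequence[str],
        response: str = "category",
        params: BoostParams = BoostParams(),
        split: SplitSpec = SplitSpec(),
    ) -> None:
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing}")
        if response not in table.columns:
            raise KeyError(f"response {response!r} absent from table")
        self.table = table
        self.features = list(features)
        self.response = response
        self.params = params
        self.split = split
        if params.objective in ("multiclass", "binary"):
            self.classes_ = sorted(table[response].astype(str).unique())
            if len(self.classes_) < 2:
                raise ValueError("classification needs >= 2 response classes")
            if params.objective == "binary" and len(self.classes_) != 2:
                raise ValueError("binary objective needs exactly 2 response groups")
        else:
            self.classes_ = None

    # -- preset constructors -------------------------------------------------

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        preset: str = "model1",
        params: Optional[BoostParams] = None,
        split: SplitSpec = SplitSpec(),
    ) -> "AseBoostModel":
        """The four study model presets.

        model0: 46 predictors, 4-class ASE category response.
        model1: the 15 retained predictors, 4-class category response.
        model2: 15 predictors, binary response (ASE = {Diff0, Diff2, Diff8}
                vs no-ASE = {Diff00}).
        model3: 15 predictors, regression on the absolute TPM difference.
        """
        preset = preset.lower()
        if preset == "model0":
            feats, response, objective = CATALOG.names, "category", "multiclass"
        elif preset == "model1":
            feats, response, objective = MODEL1_FEATURES, "category", "multiclass"
        elif preset == "model2":
            feats, response, objective = MODEL1_FEATURES, "ase_group", "binary"
            table = table.copy()
            unknown = set(table["category"].astype(str)) - set(MODEL_CLASSES)
            if unknown:
                raise ValueError(f"unexpected categories for model2: {sorted(unknown)}")
            table["ase_group"] = np.where(table["category"] == "Diff00", "no_ASE", "ASE")
        elif preset == "model3":
            feats, response, objective = MODEL1_FEATURES, "tpm_diff", "regression"
        else:
            raise ValueError(f"unknown preset {preset!r}")
        params = replace(params or BoostParams(), objective=objective)
        return cls(table, feats, response, params, split)

    # -- fitting -------------------------------------------------------------

    def _encode_response(self, y: pd.Series) -> np.ndarray:
        if self.classes_ is None:
            return y.to_numpy(dtype=float)
        codes = {c: i for i, c in enumerate(self.classes_)}
        return y.astype(str).map(codes).to_numpy(dtype=int)

    def fit(self) -> "AseBoostResults":
        X = self.table[self.features].to_numpy(dtype=float)
        y = self._encode_response(self.table[self.response])
        idx = np.arange(len(self.table))
        strat = y if (self.classes_ is not None and self.split.stratify) else None
        if strat is not None and np.bincount(y.astype(int)).min() < 4:
            warnings.warn("a response class has < 4 rows; falling back to unstratified split")
            strat = None
        idx_train, idx_test = train_test_split(
            idx,
            train_size=self.split.train_fraction,
            random_state=self.split.seed,
            stratify=strat,
        )
        strat_val = y[idx_train] if strat is not None else None
        idx_fit, idx_val = train_test_split(
            idx_train,
            test_size=self.split.validation_fraction,
            random_state=self.split.seed,
            stratify=strat_val,
        )
        objective, metric = _OBJECTIVES[self.params.objective]
        xgb_params = {
            "eta": self.params.eta,
            "gamma": self.params.gamma,
            "max_depth": self.params.max_depth,
            "objective": objective,
            "eval_metric": metric,
            "seed": self.params.seed,
            "nthread": self.params.nthread,
            "tree_method": "hist",
        }
        if self.params.objective == "multiclass":
            xgb_params["num_class"] = len(self.classes_)

        def dmat(rows):
            return xgb.DMatrix(X[rows], label=y[rows], feature_names=self.features)

        d_fit, d_val = dmat(idx_fit), dmat(idx_val)
        booster = xgb.train(
            xgb_params,
            d_fit,
            num_boost_round=self.params.nrounds,
            evals=[(d_val, "validation")],
            early_stopping_rounds=self.params.early_stopping_rounds,
            verbose_eval=False,
        )
        return AseBoostResults(
            model=self,
            booster=booster,
            idx_train=idx_train,
            idx_test=idx_test,
            X=X,
            y=y,
        )


class AseBoostResults:
    """Fitted ASE boosting model: metrics, importances, ROC, SHAP."""

    def __init__(self, model, booster, idx_train, idx_test, X, y) -> None:
        if np.intersect1d(idx_train, idx_test).size:
            raise AssertionError("train and test rows overlap")
        self.model = model
        self.booster = booster
        self.idx_train = idx_train
        self.idx_test = idx_test
        self._X = X
        self._y = y
        self.best_iteration = booster.best_iteration
        self.metrics = {
            "train": self._evaluate(idx_train),
            "test": self._evaluate(idx_test),
        }

    # -- prediction ----------------------------------------------------------

    @property
    def classes_(self):
        return self.model.classes_

    def _dmatrix(self, rows=None, X=None) -> xgb.DMatrix:
        if X is None:
            X = self._X if rows is None else self._X[rows]
        return xgb.DMatrix(X, feature_names=self.model.features)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels (classification) or values (regression)."""
        raw = self.booster.predict(
            self._dmatrix(X=np.asarray(X, dtype=float)),
            iteration_range=(0, self.best_iteration + 1),
        )
        if self.classes_ is None:
            return raw
        if raw.ndim == 2:
            codes = raw.argmax(axis=1)
        else:
            codes = (raw >= 0.5).astype(int)
        return np.asarray(self.classes_)[codes]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.booster.predict(
            self._dmatrix(X=np.asarray(X, dtype=float)),
            iteration_range=(0, self.best_iteration + 1),
        )
        if raw.ndim == 1 and self.classes_ is not None:
            return np.column_stack([1.0 - raw, raw])
        return raw

    # -- evaluation ----------------------------------------------------------

    def _evaluate(self, rows: np.ndarray) -> dict:
        X, y = self._X[rows], self._y[rows]
        if self.classes_ is None:
            pred = self.predict(X)
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            return {"rmse": rmse, "r2": float(r2_score(y, pred))}
        proba = self.predict_proba(X)
        codes = proba.argmax(axis=1)
        roc = {}
        aucs = []
        for i, cls in enumerate(self.classes_):
            binary = (y == i).astype(int)
            if binary.min() == binary.max():
                continue
            fpr, tpr, _ = roc_curve(binary, proba[:, i])
            roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
            aucs.append(roc[cls]["auc"])
        labels = list(range(len(self.classes_)))
        return {
            "accuracy": float(accuracy_score(y, codes)),
            "macro_f1": float(f1_score(y, codes, average="macro", zero_division=0)),
            "macro_sensitivity": float(
                recall_score(y, codes, average="macro", zero_division=0)
            ),
            "per_class_f1": dict(
                zip(self.classes_, f1_score(y, codes, average=None, labels=labels, zero_division=0))
            ),
            "macro_auc": float(np.mean(aucs)) if aucs else float("nan"),
            "roc": roc,
            "confusion": confusion_matrix(y, codes, labels=labels),
        }

    # -- interpretation ------------------------------------------------------

    def feature_importance(self) -> pd.Series:
        """Gain importances normalized to sum 1, descending; ties lexicographic."""
        gain = self.booster.get_score(importance_type="gain")
        values = np.array([gain.get(f, 0.0) for f in self.model.features])
        total = values.sum()
        if total > 0:
            values = values / total
        ser = pd.Series(values, index=self.model.features)
        return ser.sort_index().sort_values(ascending=False, kind="stable")

    def shap(self, rows: Optional[np.ndarray] = None, top_k: int = 5) -> dict:
        """TreeSHAP attributions (tree-path-dependent Shapley values).

        Returns mean |attribution| per feature, the top_k features ranked by
        it, per-row (feature value, attribution) pairs for dependence plots,
        and the raw contribution array whose per-row sum (plus base value)
        equals the model margin.
        """
        if rows is None:
            rows = self.idx_test
        X = self._X[rows]
        contribs = self.booster.predict(
            self._dmatrix(X=X),
            pred_contribs=True,
            iteration_range=(0, self.best_iteration + 1),
        )
        n_feat = len(self.model.features)
        if contribs.ndim == 3:  # multiclass: (rows, classes, features + bias)
            attr = contribs[:, :, :n_feat]
            mean_abs = np.abs(attr).mean(axis=(0, 1))
            proba = self.predict_proba(X)
            picked = proba.argmax(axis=1)
            per_row_attr = attr[np.arange(len(X)), picked, :]
        else:
            attr = contribs[:, :n_feat]
            mean_abs = np.abs(attr).mean(axis=0)
            per_row_attr = attr
        summary = (
            pd.Series(mean_abs, index=self.model.features)
            .sort_index()
            .sort_values(ascending=False, kind="stable")
        )
        if top_k > n_feat:
            warnings.warn(f"top_k={top_k} exceeds feature count; clipped to {n_feat}")
            top_k = n_feat
        top = list(summary.index[:top_k])
        dependence = {
            f: pd.DataFrame(
                {
                    "value": X[:, self.model.features.index(f)],
                    "attribution": per_row_attr[:, self.model.features.index(f)],
                }
            )
            for f in top
        }
        return {
            "mean_abs_attribution": summary,
            "top_features": top,
            "dependence": dependence,
            "contributions": contribs,
        }

    # -- reporting -----------------------------------------------------------

    def report(self) -> dict:
        """JSON-serializable model report."""
        def metrics_block(m):
            if self.classes_ is None:
                return {k: m[k] for k in ("rmse", "r2")}
            return {
                "accuracy": m["accuracy"],
                "macro_f1": m["macro_f1"],
                "macro_sensitivity": m["macro_sensitivity"],
                "macro_auc": m["macro_auc"],
                "per_class_auc": {c: v["auc"] for c, v in m["roc"].items()},
            }

        return {
            "objective": self.model.params.objective,
            "n_predictors": len(self.model.features),
            "predictors": self.model.features,
            "response": self.model.response,
            "response_classes": self.classes_,
            "n_rows": int(len(self._X)),
            "best_iteration": int(self.best_iteration),
            "train": metrics_block(self.metrics["train"]),
            "test": metrics_block(self.metrics["test"]),
            "importance": self.feature_importance().to_dict(),
        }

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "ASE gradient-boosted model",
            "=" * 60,
            f"objective: {self.model.params.objective}"
            f"   predictors: {len(self.model.features)}"
            f"   rows: {len(self._X)}",
            f"response: {self.model.response}"
            + (f"   classes: {', '.join(self.classes_)}" if self.classes_ else ""),
            f"best iteration: {self.best_iteration}",
            "-" * 60,
        ]
        for split in ("train", "test"):
            m = self.metrics[split]
            if self.classes_ is None:
                lines.append(f"{split:>5}: RMSE {m['rmse']:.4g}  R2 {m['r2']:.4f}")
            else:
                lines.append(
                    f"{split:>5}: accuracy {m['accuracy']:.3f}"
                    f"  macro F1 {m['macro_f1']:.3f}"
                    f"  macro sensitivity {m['macro_sensitivity']:.3f}"
                    f"  macro AUC {m['macro_auc']:.3f}"
                )
        lines.append("-" * 60)
        lines.append("top features by gain importance:")
        for name, val in self.feature_importance().head(10).items():
            lines.append(f"  {name:<32} {val:.4f}")
        return "\n".join(lines)


# -- functional surface -----------------------------------------------------

def train_model(
    table: pd.DataFrame,
    features: Sequence[str],
    response: str,
    params: BoostParams = BoostParams(),
    split: SplitSpec = SplitSpec(),
) -> AseBoostResults:
    """Train a gradient-boosted model; see :class:`AseBoostModel`."""
    if len(table) < 100:
        raise ValueError("need >= 100 rows to fit a model")
    return AseBoostModel(table, features, response, params, split).fit()


def evaluate_model(results: AseBoostResults) -> dict:
    """Held-out metrics of a fitted model."""
    return results.metrics["test"]


def feature_importance(results: AseBoostResults) -> pd.Series:
    return results.feature_importance()


def shap_explain(results: AseBoostResults, rows=None, top_k: int = 5) -> dict:
    return results.shap(rows=rows, top_k=top_k)
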