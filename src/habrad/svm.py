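"""SVM diagnostic model: grid-searched, cross-validated, Platt-calibrated.

The hyperparameter grid is 4 linear configurations (C in 0.1, 1, 10, 100)
plus 16 RBF configurations (the same C grid crossed with gamma in 0.001,
0.01, 0.1, 1), scored by mean AUC over seeded stratified 10-fold
cross-validation.  Ties break toward the linear kernel, then smaller C,
then smaller gamma.  The winning configuration is refitted on all training
data and a two-parameter sigmoid (Platt scaling) is fitted on the
out-of-fold decision values to produce probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .selection import SelectionConfig, _as_matrix, impute_median, run_cascade


@dataclass
class SVMConfig:
    kernels: tuple[str, ...] = ("linear", "rbf")
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be nonempty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def grid(self) -> list[dict]:
        """The configuration list in tie-break priority order."""
        out = []
        if "linear" in self.kernels:
            for c in self.C_grid:
                out.append({"kernel": "linear", "C": c, "gamma": None})
        if "rbf" in self.kernels:
            for c in self.C_grid:
                for g in self.gamma_grid:
                    out.append({"kernel": "rbf", "C": c, "gamma": g})
        return out


@dataclass
class TrainedModel:
    """Refit SVM plus standardization, calibration and CV diagnostics."""

    config: dict
    svc: SVC
    mean: np.ndarray
    std: np.ndarray
    feature_names: list[str]
    calibration: tuple[float, float]          # sigmoid (a, b)
    cv_auc: dict[str, float]                  # config key -> mean fold AUC
    fold_aucs: list[float]                    # per-fold AUC of chosen config
    selection_frequency: dict[str, int] = field(default_factory=dict)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def decision_values(self, table) -> np.ndarray:
        X, names = _as_matrix(table)
        if names != self.feature_names and len(names) != len(self.feature_names):
            raise ValueError("feature schema mismatch")
        X = impute_median(X)
        return self.svc.decision_function(self.standardize(X))

    def summary_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "cv_auc": self.cv_auc,
            "fold_aucs": self.fold_aucs,
            "calibration": list(self.calibration),
            "n_features": len(self.feature_names),
        })


def _config_key(cfg: dict) -> str:
    if cfg["kernel"] == "linear":
        return f"linear C={cfg['C']:g}"
    return f"rbf C={cfg['C']:g} gamma={cfg['gamma']:g}"


def _make_svc(cfg: dict, seed: int) -> SVC:
    kwargs = {"kernel": cfg["kernel"], "C": cfg["C"], "random_state": seed}
    if cfg["kernel"] == "rbf":
        kwargs["gamma"] = cfg["gamma"]
    return SVC(**kwargs)


def grid_search(table, labels, config: SVMConfig | None = None) -> TrainedModel:
    """Exhaustive grid search by mean cross-validated fold AUC."""
    config = config or SVMConfig()
    X, names = _as_matrix(table)
    X = impute_median(X)
    y = np.asarray(labels, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < config.folds:
        raise ValueError(
            f"need >= {config.folds} subjects per class for "
            f"{config.folds}-fold stratified CV"
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    folds = list(skf.split(Z, y))
    for _, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("a CV fold lacks both classes")

    cv_auc: dict[str, float] = {}
    best = None
    best_fold_aucs = None
    best_oof = None
    for cfg in config.grid():
        fold_aucs = []
        oof = np.zeros(len(y))
        for train_idx, test_idx in folds:
            svc = _make_svc(cfg, config.seed)
            svc.fit(Z[train_idx], y[train_idx])
            dec = svc.decision_function(Z[test_idx])
            oof[test_idx] = dec
            fold_aucs.append(roc_auc_score(y[test_idx], dec))
        key = _config_key(cfg)
        mean_auc = float(np.mean(fold_aucs))
        cv_auc[key] = mean_auc
        # grid order encodes the tie-break: linear first, then smaller C/gamma
        if best is None or mean_auc > cv_auc[_config_key(best)]:
            best = cfg
            best_fold_aucs = [float(a) for a in fold_aucs]
            best_oof = oof.copy()

    final = _make_svc(best, config.seed)
    final.fit(Z, y)
    a, b = _fit_platt(best_oof, y)
    return TrainedModel(dict(best), final, mean, std, names, (a, b),
                        cv_auc, best_fold_aucs)


def _fit_platt(decision_values: np.ndarray, y: np.ndarray
               ) -> tuple[float, float]:
    """Two-parameter sigmoid on decision values (logistic fit)."""
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(decision_values.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def predict_proba(model: TrainedModel, table) -> np.ndarray:
    """Calibrated disease-class probabilities, strictly inside (0, 1)."""
    dec = model.decision_values(table)
    a, b = model.calibration
    p = 1.0 / (1.0 + np.exp(-(a * dec + b)))
    eps = 1e-12
    return np.clip(p, eps, 1 - eps)


def fold_selection_frequency(table, labels,
                             selection_config: SelectionConfig | None = None,
                             folds: int = 10, seed: int = 0
                             ) -> dict[str, int]:
    """Run the full selection cascade inside each CV fold; count survivals."""
    selection_config = selection_config or SelectionConfig()
    X, names = _as_matrix(table)
    y = np.asarray(labels, dtype=np.int64)
    df = pd.DataFrame(X, columns=names)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    freq = {name: 0 for name in names}
    for train_idx, _ in skf.split(X, y):
        trace = run_cascade(df.iloc[train_idx], y[train_idx], selection_config)
        for name in trace.lasso_survivors:
            freq[name] += 1
    return freq
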