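"""Three-stage feature-selection cascade: Pearson filter, mRMR, LASSO.

Stage 1 removes one member of every feature pair with |Pearson r| above the
redundancy threshold (default 0.9), keeping the member more correlated with
the class label.  Stage 2 greedily selects features maximizing mutual
information with the label minus mean mutual information with the already
selected set (the "difference" mRMR criterion).  Stage 3 fits an
L1-penalized logistic model with a cross-validated penalty and retains
features whose standardized coefficient magnitude is strictly greater than
the retention threshold (default 0.0004).

Survivor sets are nested (LASSO within mRMR within Pearson within all) and
the whole cascade is deterministic given the seed and input column order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    pearson_threshold: float = 0.9
    mrmr_keep: int = 100
    mrmr_variant: str = "difference"
    mi_bins: int = 8
    lasso_Cs: tuple[float, ...] = tuple(np.logspace(-2, 2, 10))
    lasso_cv_folds: int = 5
    coef_threshold: float = 0.0004
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pearson_threshold < 1:
            raise ValueError("pearson_threshold must be in (0, 1)")
        if self.coef_threshold < 0:
            raise ValueError("coef_threshold must be >= 0")
        if self.mrmr_variant not in ("difference", "quotient"):
            raise ValueError("mrmr_variant must be 'difference' or 'quotient'")


@dataclass
class SelectionTrace:
    """Survivors after each stage plus per-feature diagnostics."""

    all_features: list[str]
    pearson_survivors: list[str]
    mrmr_survivors: list[str] = field(default_factory=list)
    lasso_survivors: list[str] = field(default_factory=list)
    stats: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self._check_nested()

    def _check_nested(self):
        sets = [set(self.all_features), set(self.pearson_survivors),
                set(self.mrmr_survivors), set(self.lasso_survivors)]
        for outer, inner in zip(sets, sets[1:]):
            if inner and not inner <= outer:
                raise ValueError("survivor sets are not nested")

    def to_json(self) -> str:
        return json.dumps({
            "all_features": self.all_features,
            "pearson_survivors": self.pearson_survivors,
            "mrmr_survivors": self.mrmr_survivors,
            "lasso_survivors": self.lasso_survivors,
            "stats": self.stats,
        })


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=np.float64), [str(c) for c in table.columns]
    X = np.asarray(table, dtype=np.float64)
    return X, [f"f{i}" for i in range(X.shape[1])]


def impute_median(X: np.ndarray) -> np.ndarray:
    """Replace NaN by the per-column median of the observed values."""
    X = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = np.isnan(col)
        if bad.any():
            good = col[~bad]
            col[bad] = np.median(good) if good.size else 0.0
    return X


# ---------------------------------------------------------------------------
# stage 1: Pearson redundancy filter
# ---------------------------------------------------------------------------

def pearson_filter(table, labels, threshold: float = 0.9) -> SelectionTrace:
    """Greedy redundancy removal over |r| > threshold pairs.

    Pairs (i, j), i < j, are visited in column order; a pair is skipped when
    either member has already been dropped; otherwise the member with the
    lower |point-biserial correlation to the label| is dropped (tie: the
    later column).  Zero-variance columns are dropped up front.
    """
    X, names = _as_matrix(table)
    y = np.asarray(labels, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    X = impute_median(X)
    n, p = X.shape
    std = X.std(axis=0)
    dropped = std == 0
    n_const = int(dropped.sum())
    if n_const:
        logger.info("pearson filter: dropping %d zero-variance features",
                    n_const)
    Z = np.zeros_like(X)
    ok = ~dropped
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / std[ok]
    yc = (y - y.mean())
    ysd = yc.std()
    relevance = np.abs(Z.T @ yc) / (n * ysd) if ysd > 0 else np.zeros(p)

    max_r = np.zeros(p)
    block = 1024
    for start in range(0, p, block):
        stop = min(start + block, p)
        # correlations of this column block against all columns
        C = (Z[:, start:stop].T @ Z) / n
        for i in range(start, stop):
            if dropped[i]:
                continue
            row = C[i - start]
            js = np.flatnonzero(np.abs(row[i + 1:]) > threshold) + i + 1
            for j in js:
                if dropped[i]:
                    break
                if dropped[j]:
                    continue
                r = abs(row[j])
                max_r[i] = max(max_r[i], r)
                max_r[j] = max(max_r[j], r)
                if relevance[i] >= relevance[j]:
                    dropped[j] = True
                else:
                    dropped[i] = True
    survivors = [names[i] for i in range(p) if not dropped[i]]
    stats = {names[i]: {"relevance": float(relevance[i]),
                        "max_abs_r": float(max_r[i])} for i in range(p)}
    return SelectionTrace(names, survivors, stats=stats)


# ---------------------------------------------------------------------------
# stage 2: mRMR
# ---------------------------------------------------------------------------

def _equal_frequency_codes(X: np.ndarray, bins: int) -> np.ndarray:
    """Per-column equal-frequency discretization into integer codes."""
    n, p = X.shape
    codes = np.empty((n, p), dtype=np.int64)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(p):
        edges = np.unique(np.quantile(X[:, j], qs))
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes


def _mi_from_codes(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    """Mutual information (bits) between two integer code vectors."""
    n = len(a)
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(np.float64) / n
    pa = np.bincount(a, minlength=ka).astype(np.float64) / n
    pb = np.bincount(b, minlength=kb).astype(np.float64) / n
    outer = np.outer(pa, pb).ravel()
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def mrmr_select(table, labels, m: int = 100, variant: str = "difference",
                mi_bins: int = 8) -> SelectionTrace:
    """Greedy forward mRMR selection of up to ``m`` features."""
    if m <= 0:
        raise ValueError("m must be positive")
    X, names = _as_matrix(table)
    X = impute_median(X)
    y = np.asarray(labels, dtype=np.int64)
    n, p = X.shape
    m = min(m, p)
    codes = _equal_frequency_codes(X, mi_bins)
    n_classes = int(y.max()) + 1
    rel = np.array([_mi_from_codes(codes[:, j], y, mi_bins, n_classes)
                    for j in range(p)])
    selected: list[int] = []
    red_sum = np.zeros(p)
    remaining = set(range(p))
    for _ in range(m):
        if selected:
            mean_red = red_sum / len(selected)
            if variant == "difference":
                score = rel - mean_red
            else:
                score = rel / (mean_red + np.finfo(float).eps)
        else:
            score = rel.copy()
        score_masked = np.where(
            [j in remaining for j in range(p)], score, -np.inf)
        pick = int(np.argmax(score_masked))  # first max -> earliest column
        selected.append(pick)
        remaining.discard(pick)
        picked_codes = codes[:, pick]
        for j in remaining:
            red_sum[j] += _mi_from_codes(codes[:, j], picked_codes,
                                         mi_bins, mi_bins)
    survivors = [names[j] for j in selected]
    stats = {names[j]: {"mi_relevance": float(rel[j])} for j in range(p)}
    return SelectionTrace(names, names, survivors, stats=stats)


# ---------------------------------------------------------------------------
# stage 3: LASSO-logistic
# ---------------------------------------------------------------------------

def lasso_select(table, labels, config: SelectionConfig | None = None
                 ) -> SelectionTrace:
    """L1-penalized logistic selection with a cross-validated penalty.

    Features are z-scored first, so the strict ``|coef| > coef_threshold``
    retention rule applies to standardized coefficients.
    """
    config = config or SelectionConfig()
    X, names = _as_matrix(table)
    X = impute_median(X)
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - X.mean(axis=0)) / std
    cv = StratifiedKFold(n_splits=config.lasso_cv_folds, shuffle=True,
                         random_state=config.seed)
    folds = list(cv.split(Z, y))

    def _fit(C, Ztr, ytr):
        m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                               random_state=config.seed, max_iter=2000)
        m.fit(Ztr, ytr)
        return m

    best_C, best_score = None, -np.inf
    for C in config.lasso_Cs:  # grid order breaks ties toward smaller C
        scores = []
        for tr_idx, te_idx in folds:
            if len(np.unique(y[te_idx])) < 2:
                continue
            m = _fit(C, Z[tr_idx], y[tr_idx])
            dec = m.decision_function(Z[te_idx])
            scores.append(roc_auc_score(y[te_idx], dec))
        if not scores:
            raise ValueError("no CV fold contains both classes")
        score = float(np.mean(scores))
        if score > best_score:
            best_C, best_score = C, score
    coefs = _fit(best_C, Z, y).coef_.ravel()
    survivors = [names[j] for j in range(len(names))
                 if abs(coefs[j]) > config.coef_threshold]
    stats = {names[j]: {"lasso_coef": float(coefs[j])}
             for j in range(len(names))}
    return SelectionTrace(names, names, names, survivors, stats=stats)


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_cascade(table, labels, config: SelectionConfig | None = None
                ) -> SelectionTrace:
    """Pearson -> mRMR -> LASSO; returns the merged trace."""
    config = config or SelectionConfig()
    X, names = _as_matrix(table)
    df = pd.DataFrame(X, columns=names)
    t1 = pearson_filter(df, labels, config.pearson_threshold)
    df2 = df[t1.pearson_survivors]
    t2 = mrmr_select(df2, labels, config.mrmr_keep, config.mrmr_variant,
                     config.mi_bins)
    df3 = df[t2.mrmr_survivors]
    t3 = lasso_select(df3, labels, config)
    stats: dict[str, dict] = {}
    for tr in (t1, t2, t3):
        for k, v in tr.stats.items():
            stats.setdefault(k, {}).update(v)
    return SelectionTrace(names, t1.pearson_survivors, t2.mrmr_survivors,
                          t3.lasso_survivors, stats)
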