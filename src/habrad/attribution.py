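"""Per-feature Shapley attributions for a fitted classifier.

The estimator is Monte-Carlo permutation sampling: for each explained
subject, feature values are switched from a random background draw to the
subject's own values in random order, and each feature is credited with the
change in model output it causes, averaged over permutations.  The exact
Shapley values satisfy local accuracy (baseline + sum of attributions =
model output); the Monte-Carlo estimate is nudged onto that simplex by
spreading the small residual equally over the features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .selection import _as_matrix
from .svm import TrainedModel, predict_proba


@dataclass
class AttributionResult:
    phi: np.ndarray                  # (n_subjects, n_features)
    baseline: float                  # expected model output over background
    outputs: np.ndarray              # model output per explained subject
    feature_names: list[str]

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)


def _as_predictor(model):
    if isinstance(model, TrainedModel):
        return lambda X: predict_proba(model, X)
    if callable(model):
        return model
    raise TypeError("model must be a TrainedModel or a callable")


def shapley_attributions(model, background, subjects, n_samples: int = 64,
                         seed: int = 0, background_cap: int = 100
                         ) -> AttributionResult:
    """Monte-Carlo Shapley attributions of ``subjects`` rows.

    ``n_samples`` permutations are drawn per subject; each permutation is
    paired with one background row whose values stand in for "absent"
    features.  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    predict = _as_predictor(model)
    B, names = _as_matrix(background)
    X, x_names = _as_matrix(subjects)
    if X.shape[1] != B.shape[1]:
        raise ValueError("subjects and background have different features")
    if B.shape[0] == 0:
        raise ValueError("background is empty")
    rng = np.random.default_rng(seed)
    if len(B) > background_cap:
        B = B[rng.choice(len(B), size=background_cap, replace=False)]
    n, p = X.shape
    baseline = float(np.mean(predict(B)))
    outputs = np.asarray(predict(X), dtype=np.float64)
    phi = np.zeros((n, p))
    for i in range(n):
        x = X[i]
        acc = np.zeros(p)
        for s in range(n_samples):
            perm = rng.permutation(p)
            # cycle through the background so every row is used equally —
            # this removes the background-sampling term from the variance
            b = B[s % len(B)]
            # walk b -> x feature by feature; evaluate all steps in one call
            steps = np.tile(b, (p + 1, 1))
            z = b.copy()
            for t, j in enumerate(perm):
                z[j] = x[j]
                steps[t + 1] = z
            vals = np.asarray(predict(steps), dtype=np.float64)
            acc[perm] += np.diff(vals)
        phi_i = acc / n_samples
        # enforce local accuracy; distributing the residual proportionally
        # to |phi| keeps genuinely inert features at exactly zero
        residual = (outputs[i] - baseline) - phi_i.sum()
        weight = np.abs(phi_i)
        total = weight.sum()
        phi[i] = phi_i + residual * (weight / total if total > 0
                                     else np.full(p, 1.0 / p))
    return AttributionResult(phi, baseline, outputs, names)


def rank_features(result: AttributionResult, top_n: int = 10
                  ) -> list[dict]:
    """Features ordered by descending mean |phi| (ties: column order).

    Each entry carries the mean |phi| and the cumulative share of the total
    attribution mass captured up to and including that feature.
    """
    if result.phi.size == 0:
        raise ValueError("empty attribution result")
    mean_abs = result.mean_abs()
    order = np.argsort(-mean_abs, kind="stable")
    total = mean_abs.sum()
    out = []
    cum = 0.0
    for rank, j in enumerate(order[:top_n], start=1):
        cum += mean_abs[j]
        out.append({
            "rank": rank,
            "feature": result.feature_names[j],
            "mean_abs_shap": float(mean_abs[j]),
            "cumulative_share": float(cum / total) if total > 0 else 0.0,
        })
    return out
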