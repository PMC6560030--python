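"""Pairwise linear SVM cross-classification and decision values.

Classifiers are trained on localizer beta patterns and applied, without
retraining, to learning-phase patterns (cross-classification: no
within-phase cross-validated inference is ever drawn).  The pair scheme is
fixed by discriminability: faces vs scenes, scenes vs faces, and objects
vs faces, each an L2-regularized linear SVM (LIBSVM) at fixed cost c = 1.
Class counts are equalized within each localizer mini-block by seeded
random discard before training.

Raw SVM margins are mapped to decision values in [0, 1] through a
one-parameter symmetric logistic (Platt-style) link fitted on the
localizer margins.  The link has no intercept, so a pattern on the
decision boundary maps to exactly 0.5, and it is strictly increasing, so
margins and decision values share their rank order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .simulate import VoxelPatternSet

#: target -> contrast category, as selected by localizer discriminability.
PAIR_SCHEME = {"face": "scene", "scene": "face", "object": "face"}


@dataclass
class PairwiseClassifier:
    target_category: str
    contrast_category: str
    weights: np.ndarray
    intercept: float
    platt_scale: float           # decision value = sigmoid(platt_scale * margin)
    cost: float = 1.0
    n_train_per_class: int = 0
    seed: int = 0

    def margins(self, patterns: np.ndarray) -> np.ndarray:
        X = np.asarray(patterns, float)
        if X.shape[1] != len(self.weights):
            raise ValueError(
                f"voxel dimension mismatch: {X.shape[1]} != {len(self.weights)}")
        return X @ self.weights + self.intercept

    def decision_values(self, patterns: np.ndarray) -> np.ndarray:
        return _sigmoid(self.platt_scale * self.margins(patterns))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(z / 2.0))


def _fit_platt_scale(margins: np.ndarray, labels: np.ndarray) -> float:
    """MLE of the positive scale in p = sigmoid(a*margin).

    Uses Platt's smoothed targets (n+1)/(n+2) and 1/(n+2) instead of hard
    0/1 labels, which keeps the optimum finite when the training margins
    are separable (otherwise the scale would diverge and the mapped values
    saturate at exactly 0 and 1).
    """
    m = np.asarray(margins, float)
    y = np.asarray(labels, float)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    t = np.where(y > 0, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(log_a):
        p = np.clip(_sigmoid(np.exp(log_a) * m), 1e-12, 1 - 1e-12)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-3), np.log(100.0)),
                                   method="bounded")
    return float(np.exp(res.x))


def _balance_miniblocks(events: pd.DataFrame, target: str, contrast: str,
                        rng: np.random.Generator) -> np.ndarray:
    """Row indices keeping equal target/contrast counts per mini-block."""
    keep: list[int] = []
    for _, mb in events.groupby("miniblock"):
        pos = mb.index[mb["category"] == target].to_numpy()
        neg = mb.index[mb["category"] == contrast].to_numpy()
        n = min(len(pos), len(neg))
        if len(pos) > n:
            pos = rng.choice(pos, size=n, replace=False)
        if len(neg) > n:
            neg = rng.choice(neg, size=n, replace=False)
        keep.extend(pos)
        keep.extend(neg)
    return np.sort(np.asarray(keep, dtype=int))


def train_pairwise(localizer: VoxelPatternSet, seed: int = 0,
                   cost: float = 1.0) -> dict[str, PairwiseClassifier]:
    """Train the three pairwise category classifiers on localizer betas."""
    ev = localizer.events.reset_index(drop=True)
    out = {}
    rng = np.random.default_rng(seed)
    for target, contrast in PAIR_SCHEME.items():
        for cat in (target, contrast):
            if (ev["category"] == cat).sum() == 0:
                raise ValueError(f"no localizer trials of category {cat!r}")
        idx = _balance_miniblocks(ev, target, contrast, rng)
        X = localizer.betas[idx]
        y = (ev.loc[idx, "category"] == target).to_numpy().astype(int)
        svm = SVC(kernel="linear", C=cost)
        svm.fit(X, y)
        w = svm.coef_.ravel()
        b = float(svm.intercept_[0])
        margins = X @ w + b
        out[target] = PairwiseClassifier(
            target_category=target, contrast_category=contrast,
            weights=w, intercept=b,
            platt_scale=_fit_platt_scale(margins, y),
            cost=cost, n_train_per_class=int(y.sum()), seed=seed)
    return out


def decision_values(classifiers: dict[str, PairwiseClassifier],
                    learning: VoxelPatternSet) -> pd.DataFrame:
    """Apply trained classifiers to every learning-phase event.

    Returns the event metadata plus, per category, the raw margin
    (``margin_<cat>``) and the bounded decision value (``dv_<cat>``), a
    parametric variable in [0, 1] expressing how well the pattern is
    described by that category's classifier.
    """
    table = learning.events.copy().reset_index(drop=True)
    for cat, clf in classifiers.items():
        m = clf.margins(learning.betas)
        table[f"margin_{cat}"] = m
        table[f"dv_{cat}"] = _sigmoid(clf.platt_scale * m)
    return table


def generalization_auc(dv_table: pd.DataFrame,
                       classifiers: dict[str, PairwiseClassifier],
                       scale: bool = True) -> dict[str, float]:
    """Cross-phase classification of on-screen stimuli at S1 and S3.

    For each category, the AUC of its decision values for events whose
    on-screen stimulus is the target versus the contrast category,
    reported chance-relative as (AUC − 0.5) x 100 (``scale=False`` gives
    raw AUC).  Undefined (single-class) cases come back as NaN.
    """
    sub = dv_table[dv_table["state"].isin(["S1", "S3"])]
    out = {}
    for cat, clf in classifiers.items():
        rel = sub[sub["onscreen_category"].isin([cat, clf.contrast_category])]
        y = (rel["onscreen_category"] == cat).to_numpy().astype(int)
        if len(np.unique(y)) < 2:
            out[cat] = np.nan
            continue
        auc = roc_auc_score(y, rel[f"dv_{cat}"].to_numpy())
        out[cat] = (auc - 0.5) * 100.0 if scale else auc
    return out


def crossphase_performance(dv_table: pd.DataFrame,
                           classifiers: dict[str, PairwiseClassifier]) -> dict[str, float]:
    """Generalization score used for exclusion: the regression coefficient
    of concatenated S1 and S3 decision values on the target-versus-contrast
    indicator (+1 when the on-screen stimulus is the target category, −1
    when it is the contrast category)."""
    sub = dv_table[dv_table["state"].isin(["S1", "S3"])]
    out = {}
    for cat, clf in classifiers.items():
        rel = sub[sub["onscreen_category"].isin([cat, clf.contrast_category])]
        if len(rel) < 3 or rel["onscreen_category"].nunique() < 2:
            out[cat] = np.nan
            continue
        x = np.where(rel["onscreen_category"] == cat, 1.0, -1.0)
        X = np.column_stack([np.ones(len(x)), x])
        coef, *_ = np.linalg.lstsq(X, rel[f"dv_{cat}"].to_numpy(), rcond=None)
        out[cat] = float(coef[1])
    return out


def exclusion_check(performance: dict[str, float]) -> tuple[dict[str, bool], bool]:
    """Validity flags from cross-phase generalization performance.

    A category is invalid when its classifier failed to generalize across
    task phases (coefficient <= 0, or undefined); a participant whose
    classifiers fail for every category is excluded entirely.
    Returns (per-category validity, include_participant).
    """
    valid = {cat: bool(np.isfinite(v) and v > 0) for cat, v in performance.items()}
    return valid, any(valid.values())
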