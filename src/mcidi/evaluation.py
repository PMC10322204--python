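"""Discrimination performance evaluation.

Confusion matrices (MCI is the positive class; a subject is predicted MCI
when the index value is at or above the threshold), the six standard
metrics — sensitivity, specificity, positive and negative predictive value,
F-measure, accuracy — ROC/AUC, k-fold cross-validation of the *entire*
pipeline (feature screen, PCA, lasso and threshold are refit on the training
folds only, so no selection leakage), Welch's unequal-variance t-test for
group separation, and the Pearson correlation between the index and the
MMSE score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import prep
from .config import PipelineConfig

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CvReport",
    "confusion",
    "metrics",
    "roc_auc",
    "kfold_cv",
    "group_t_test",
    "mmse_correlation",
    "round_half_up",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the printed-table convention)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _as_mci_bool(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        return y == "MCI"
    return y.astype(bool)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with MCI as the positive class."""

    tp: int  # MCI predicted MCI
    fn: int  # MCI predicted healthy
    fp: int  # healthy predicted MCI
    tn: int  # healthy predicted healthy

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class MetricsReport:
    """The six discrimination metrics (plus optional AUC) for one cohort.

    A metric with a zero denominator is reported as None (undefined), never
    as 0. ``rounded()`` gives the 2-decimal half-up values used in printed
    tables.
    """

    cm: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f_measure: Optional[float]
    accuracy: Optional[float]
    auc: Optional[float] = None
    cohort: str = ""

    _FIELDS = ("sensitivity", "specificity", "ppv", "npv", "f_measure", "accuracy")

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if getattr(self, k) is None else round_half_up(getattr(self, k), ndigits))
            for k in self._FIELDS
        }

    def to_dict(self) -> dict:
        out = {"cohort": self.cohort, "confusion": self.cm.to_dict(), "auc": self.auc}
        out.update({k: getattr(self, k) for k in self._FIELDS})
        out["rounded"] = self.rounded()
        return out


def confusion(values, labels, threshold: float) -> ConfusionMatrix:
    """Confusion counts for index values at a threshold (MCI when >= tau)."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    v = np.asarray(values, dtype=float)
    y = _as_mci_bool(labels)
    pred = v >= threshold
    return ConfusionMatrix(
        tp=int((pred & y).sum()),
        fn=int((~pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
    )


def metrics(
    cm: ConfusionMatrix, auc: Optional[float] = None, cohort: str = ""
) -> MetricsReport:
    """The six metrics from a confusion matrix; undefined where 0/0."""

    def _ratio(num, den):
        return None if den == 0 else num / den

    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f = None
    else:
        f = 2.0 * ppv * sens / (ppv + sens)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    return MetricsReport(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f_measure=f,
        accuracy=acc,
        auc=auc,
        cohort=cohort,
    )


def roc_auc(values, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve points and rank-based AUC of the index (MCI positive).

    Returns ``((fpr, tpr), auc)``. The AUC is the Mann–Whitney probability
    that a random MCI subject scores above a random healthy subject (ties
    counted 1/2) and equals the trapezoidal area under the curve.
    """
    from sklearn.metrics import roc_curve

    v = np.asarray(values, dtype=float)
    y = _as_mci_bool(labels)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    pos, neg = v[y], v[~y]
    ranks = stats.rankdata(v)
    u = ranks[y].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    fpr, tpr, _ = roc_curve(y.astype(int), v)
    return (fpr, tpr), auc


def group_t_test(values, labels) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test of MCI vs healthy index means.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom;
    t is signed MCI-minus-healthy.
    """
    v = np.asarray(values, dtype=float)
    y = _as_mci_bool(labels)
    a, b = v[y], v[~y]
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs >= 2 subjects per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def mmse_correlation(values, mmse) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between index and MMSE score."""
    v = np.asarray(values, dtype=float)
    m = np.asarray(mmse, dtype=float)
    if v.size != m.size or v.size < 3:
        raise ValueError("need >= 3 aligned (index, MMSE) pairs")
    r, p = stats.pearsonr(v, m)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# k-fold cross-validation of the whole pipeline


@dataclass(frozen=True)
class CvReport:
    """Pooled and per-fold cross-validation metrics."""

    k: int
    pooled: MetricsReport
    fold_metrics: list
    fold_sizes: list
    seed: int

    def fold_means(self) -> dict:
        """Across-fold means of sensitivity/specificity/accuracy (defined folds)."""
        out = {}
        for key in ("sensitivity", "specificity", "accuracy"):
            vals = [getattr(f, key) for f in self.fold_metrics if getattr(f, key) is not None]
            out[key] = float(np.mean(vals)) if vals else None
        return out

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "pooled": self.pooled.to_dict(),
            "fold_means": self.fold_means(),
            "folds": [f.to_dict() for f in self.fold_metrics],
            "fold_sizes": self.fold_sizes,
        }


def kfold_cv(
    utterances: pd.DataFrame,
    labels: pd.DataFrame,
    k: Optional[int] = None,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
    max_redraws: int = 20,
    fit_fn=None,
) -> CvReport:
    """Stratified k-fold cross-validation of the full pipeline.

    For each fold the complete derivation — three-stage feature screen, PCA,
    repeat-averaged lasso and BER threshold — is refit on the training folds
    only and applied to the held-out subjects; pooled held-out predictions
    give the reported metrics (per-fold metrics are also retained). ``k = n``
    gives leave-one-out. A fold split whose training part lacks both classes
    is redrawn with a new seed (logged), up to ``max_redraws`` times.

    ``fit_fn(train_utterances, train_labels, config, seed)`` may replace the
    default pipeline; it must return an object with ``predict(diffs)`` and a
    ``threshold`` attribute (useful for baselines and leakage checks).
    """
    from .model import McidiModel  # local import to avoid a cycle

    if fit_fn is None:

        def fit_fn(train_utt, train_labels, cfg, fold_seed):
            return McidiModel.from_tables(train_utt, train_labels, config=cfg).fit(
                seed=fold_seed
            )

    config = config or PipelineConfig()
    k = config.cv_folds if k is None else int(k)
    seed = config.seed if seed is None else int(seed)
    n = len(labels)
    if k > n or k < 2:
        raise ValueError(f"k must be in 2..{n}, got {k}")
    groups = labels["group"].to_numpy()
    subject_ids = labels["subject_id"].to_numpy()

    from sklearn.model_selection import KFold

    min_class = min(np.bincount((groups == "MCI").astype(int)))
    for attempt in range(max_redraws + 1):
        split_seed = seed + attempt
        if k <= min_class:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
        else:  # leave-one-out and near-LOO folds cannot be stratified
            splitter = KFold(n_splits=k, shuffle=True, random_state=split_seed)
        folds = list(splitter.split(np.zeros(n), groups))
        if all(len(np.unique(groups[tr])) == 2 for tr, _ in folds):
            break
        logger.warning("fold draw %d left a single-class training set; redrawing", attempt)
    else:  # pragma: no cover - stratified splits essentially always succeed
        raise RuntimeError("could not draw folds with both classes in every training set")

    pred_values = np.full(n, np.nan)
    fold_reports, fold_sizes = [], []
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        train_subjects = set(subject_ids[train_idx])
        train_utt = utterances[utterances["subject_id"].isin(train_subjects)]
        train_labels = labels.iloc[train_idx].reset_index(drop=True)
        fold_results = fit_fn(
            train_utt, train_labels, config, split_seed + 1000 * (fold_idx + 1)
        )

        test_subjects = set(subject_ids[test_idx])
        test_utt = utterances[utterances["subject_id"].isin(test_subjects)]
        means = prep.average_by_state(test_utt)
        test_diffs = prep.compute_difference(
            means, labels=labels.iloc[test_idx]
        )
        values = np.asarray(fold_results.predict(test_diffs), dtype=float)
        cm = confusion(values, groups[test_idx], fold_results.threshold)
        fold_reports.append(metrics(cm, cohort=f"fold{fold_idx + 1}"))
        fold_sizes.append(int(len(test_idx)))
        # pooling uses each fold's own threshold: store the binary decision
        pred_values[test_idx] = (values >= fold_results.threshold).astype(float)

    pooled_cm = ConfusionMatrix(
        tp=int(((pred_values == 1) & (groups == "MCI")).sum()),
        fn=int(((pred_values == 0) & (groups == "MCI")).sum()),
        fp=int(((pred_values == 1) & (groups == "healthy")).sum()),
        tn=int(((pred_values == 0) & (groups == "healthy")).sum()),
    )
    pooled = metrics(pooled_cm, cohort=f"cv_pooled_k{k}")
    return CvReport(
        k=k, pooled=pooled, fold_metrics=fold_reports, fold_sizes=fold_sizes, seed=seed
    )
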