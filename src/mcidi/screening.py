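"""Three-stage feature screen.

Stage 1 keeps features whose calculation-vs-reading state effect is
significant in the per-feature random-intercept model (utterance-level rows,
no averaging, no multiple-testing correction; default level 1%). Stage 2
keeps features whose per-subject difference has absolute Pearson correlation
with the MMSE score above a threshold (default 0.15, strict inequality).
Stage 3 ranks the survivors by single-feature ROC AUC for the healthy-vs-MCI
contrast and keeps the top n (default: the number of training subjects, so
the downstream covariance matrix keeps full rank). The masks are nested by
construction and the whole cascade is deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LmmDesign
from .prep import STATE_CALCULATION, feature_columns, validate_utterance_table

__all__ = [
    "ScreeningMasks",
    "glmm_screen",
    "correlation_screen",
    "feature_auc",
    "auc_rank_select",
    "screen_features",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreeningMasks:
    """Per-stage boolean masks plus per-feature diagnostics.

    All arrays are aligned with ``features``. ``p_values`` are stage-1 Wald
    p-values for the state effect; ``r_values`` stage-2 Pearson correlations
    with MMSE (NaN where undefined); ``auc_values`` oriented single-feature
    AUCs (NaN outside the stage-2 survivors).
    """

    features: list
    stage1: np.ndarray
    stage2: np.ndarray
    stage3: np.ndarray
    p_values: np.ndarray
    r_values: np.ndarray
    auc_values: np.ndarray
    alpha: float = 0.01
    corr_threshold: float = 0.15
    n_select: Optional[int] = None
    exclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.stage2 & ~self.stage1).any() or (self.stage3 & ~self.stage2).any():
            raise ValueError("screening masks must be nested: stage3 ⊆ stage2 ⊆ stage1")

    @property
    def selected(self) -> list:
        """Feature names surviving all three stages, in column order."""
        return [f for f, keep in zip(self.features, self.stage3) if keep]

    def funnel(self) -> dict:
        """Feature counts at each stage (the selection funnel)."""
        return {
            "input": len(self.features),
            "stage1_state_significant": int(self.stage1.sum()),
            "stage2_mmse_correlated": int(self.stage2.sum()),
            "stage3_auc_selected": int(self.stage3.sum()),
        }

    def to_dict(self) -> dict:
        def _listify(a):
            return [None if np.isnan(v) else float(v) for v in a]

        return {
            "features": list(map(str, self.features)),
            "stage1": self.stage1.astype(bool).tolist(),
            "stage2": self.stage2.astype(bool).tolist(),
            "stage3": self.stage3.astype(bool).tolist(),
            "p_values": _listify(self.p_values),
            "r_values": _listify(self.r_values),
            "auc_values": _listify(self.auc_values),
            "alpha": self.alpha,
            "corr_threshold": self.corr_threshold,
            "n_select": self.n_select,
            "exclusions": self.exclusions,
            "funnel": self.funnel(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningMasks":
        def _arr(key):
            return np.array(
                [np.nan if v is None else v for v in d[key]], dtype=float
            )

        return cls(
            features=list(d["features"]),
            stage1=np.asarray(d["stage1"], dtype=bool),
            stage2=np.asarray(d["stage2"], dtype=bool),
            stage3=np.asarray(d["stage3"], dtype=bool),
            p_values=_arr("p_values"),
            r_values=_arr("r_values"),
            auc_values=_arr("auc_values"),
            alpha=d["alpha"],
            corr_threshold=d["corr_threshold"],
            n_select=d["n_select"],
            exclusions=dict(d.get("exclusions", {})),
        )


def glmm_screen(
    table: pd.DataFrame, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 1: per-feature random-intercept state-effect test at level alpha.

    Operates on utterance-level (non-averaged) rows. Returns ``(mask,
    p_values)`` over the table's feature columns; features whose fit fails
    are excluded with a logged reason (p-value NaN).
    """
    validate_utterance_table(table)
    feats = feature_columns(table)
    design = LmmDesign(
        table["subject_id"].to_numpy(),
        (table["state"] == STATE_CALCULATION).to_numpy(dtype=float),
    )
    pvals = np.full(len(feats), np.nan)
    for j, name in enumerate(feats):
        try:
            pvals[j] = design.fit(table[name].to_numpy(dtype=float)).p_value
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            logger.warning("state-effect fit failed for %s: %s", name, exc)
    mask = np.zeros(len(feats), dtype=bool)
    ok = np.isfinite(pvals)
    mask[ok] = pvals[ok] < alpha
    return mask, pvals


def correlation_screen(
    diffs: pd.DataFrame, mmse, threshold: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2: keep features with |Pearson r(difference, MMSE)| > threshold.

    ``diffs`` holds subject-level (averaged) feature differences. A
    zero-variance feature has undefined correlation and is excluded (r NaN).
    Returns ``(mask, r_values)``.
    """
    x = diffs.to_numpy(dtype=float)
    m = np.asarray(mmse, dtype=float)
    if x.shape[0] != m.size:
        raise ValueError("difference matrix and MMSE scores are misaligned")
    xc = x - x.mean(axis=0)
    mc = m - m.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ mc / np.where(denom > 0, denom, 1.0), np.nan)
    mask = np.abs(r) > threshold
    mask &= np.isfinite(r)
    return mask, r


def feature_auc(values, labels, orientation: str = "max") -> float:
    """Single-feature ROC AUC for the healthy-vs-MCI contrast.

    Rank-based (Mann–Whitney) AUC: the probability that a random MCI
    subject's value exceeds a random healthy subject's, ties counted 1/2.
    With ``orientation="max"`` (default) returns ``max(a, 1 - a)`` so
    discriminability is ranked regardless of effect direction;
    ``orientation="raw"`` returns the raw MCI-positive AUC.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    pos = v[y == "MCI"] if y.dtype.kind in "UO" else v[y.astype(bool)]
    neg = v[y == "healthy"] if y.dtype.kind in "UO" else v[~y.astype(bool)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("feature_auc needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    a = u / (pos.size * neg.size)
    return float(max(a, 1.0 - a)) if orientation == "max" else float(a)


def auc_rank_select(
    diffs: pd.DataFrame,
    labels,
    n_select: int,
    candidates: Optional[np.ndarray] = None,
    orientation: str = "max",
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 3: keep the top ``n_select`` candidate features by AUC.

    Ties are broken by ascending feature (column) index so the selection is
    stable; when fewer candidates than ``n_select`` exist, all are kept.
    Returns ``(mask, auc_values)`` with AUC NaN outside the candidate set.
    """
    feats = list(diffs.columns)
    if candidates is None:
        candidates = np.ones(len(feats), dtype=bool)
    aucs = np.full(len(feats), np.nan)
    idx = np.where(candidates)[0]
    for j in idx:
        aucs[j] = feature_auc(diffs.iloc[:, j], labels, orientation=orientation)
    mask = np.zeros(len(feats), dtype=bool)
    if idx.size:
        order = sorted(idx, key=lambda j: (-aucs[j], j))
        mask[order[: int(n_select)]] = True
    return mask, aucs


def screen_features(
    table: pd.DataFrame,
    diffs: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.01,
    corr_threshold: float = 0.15,
    n_select: Optional[int] = None,
    auc_orientation: str = "max",
) -> ScreeningMasks:
    """Run the full three-stage cascade and return nested masks.

    ``table`` carries utterance-level rows (stage 1); ``diffs`` the
    subject-level differences aligned with ``labels`` (stages 2-3).
    ``n_select`` defaults to the number of subjects.
    """
    feats = feature_columns(table)
    if list(diffs.columns) != feats:
        raise ValueError("difference matrix columns do not match the utterance table")
    if n_select is None:
        n_select = len(diffs)
    stage1, pvals = glmm_screen(table, alpha=alpha)
    mask2, r = correlation_screen(diffs, labels["mmse"], threshold=corr_threshold)
    stage2 = stage1 & mask2
    stage3, aucs = auc_rank_select(
        diffs,
        labels["group"],
        n_select,
        candidates=stage2,
        orientation=auc_orientation,
    )
    aucs[~stage2] = np.nan
    exclusions = {}
    failed = [feats[j] for j in np.where(~np.isfinite(pvals))[0]]
    if failed:
        exclusions["stage1_fit_failed"] = failed
    degenerate = [feats[j] for j in np.where(stage1 & ~np.isfinite(r))[0]]
    if degenerate:
        exclusions["stage2_zero_variance"] = degenerate
    masks = ScreeningMasks(
        features=feats,
        stage1=stage1,
        stage2=stage2,
        stage3=stage3,
        p_values=pvals,
        r_values=r,
        auc_values=aucs,
        alpha=alpha,
        corr_threshold=corr_threshold,
        n_select=int(n_select),
        exclusions=exclusions,
    )
    logger.info("feature selection funnel: %s", masks.funnel())
    return masks
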