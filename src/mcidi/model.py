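"""The MCI discrimination index (MCIDI) model.

The selected feature differences are aggregated by principal component
analysis — components are retained up to a cumulative explained-variance
contribution of 80% — and an L1-regularized logistic regression is fitted on
the component scores with the MCI group coded 1. Because the penalty weight
is chosen by cross-validation with random fold splits, the fit varies from
run to run; it is therefore repeated (20 times by default) and the
regression coefficients are averaged. With averaged intercept ``alpha_0``
and coefficients ``alpha_i`` the index is the logistic function

    MCIDI = 1 / (1 + exp(-(alpha_0 + sum_i alpha_i * PC_i)))

so it lies in (0, 1) and reads as the modelled probability of MCI. The
decision threshold separating the groups is the value minimizing the
balanced error rate (BER) of the training-set index values.

The public surface follows the Model/Results convention:
``McidiModel.from_tables(utterances, labels).fit()`` returns a
:class:`McidiResults` carrying the fitted transform, averaged coefficients,
threshold and diagnostics, with ``predict``/``evaluate``/``summary``
methods and JSON (de)serialization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from . import evaluation, prep, screening
from .config import PipelineConfig

__all__ = [
    "PcaModel",
    "McidiModel",
    "McidiResults",
    "fit_pca_80",
    "fit_stabilized_lasso",
    "compute_mcidi",
    "ber",
    "select_threshold",
]

logger = logging.getLogger(__name__)

_EVR_TOL = 1e-12  # float-sum slack for the inclusive 80% rule


@dataclass(frozen=True)
class PcaModel:
    """Fitted PCA transform for the selected feature differences.

    ``loadings`` holds the m retained orthonormal component vectors (m x k);
    ``explained_variance_ratio`` / ``explained_variance`` cover the full
    spectrum so discarded-mass identities remain checkable. Verification
    cohorts are projected with the *training* centering/scaling parameters.
    """

    feature_names: list
    mean: np.ndarray
    scale: Optional[np.ndarray]
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    m: int
    target: float

    def transform(self, diffs: pd.DataFrame) -> np.ndarray:
        """Project a difference matrix onto the retained components."""
        missing = [f for f in self.feature_names if f not in diffs.columns]
        if missing:
            raise ValueError(f"difference matrix lacks fitted features: {missing}")
        x = diffs[self.feature_names].to_numpy(dtype=float) - self.mean
        if self.scale is not None:
            x = x / self.scale
        return x @ self.loadings.T

    def to_dict(self) -> dict:
        return {
            "feature_names": list(map(str, self.feature_names)),
            "mean": self.mean.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "m": self.m,
            "target": self.target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            feature_names=list(d["feature_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=None if d["scale"] is None else np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(
                d["explained_variance_ratio"], dtype=float
            ),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            m=int(d["m"]),
            target=float(d["target"]),
        )


def fit_pca_80(
    diffs: pd.DataFrame, target: float = 0.80, scale: bool = True
) -> PcaModel:
    """PCA of the difference matrix, retaining components up to ``target``.

    The number of retained components m is the smallest count whose
    cumulative explained-variance ratio reaches the target (inclusive rule).
    With ``scale=True`` (default) features are standardized first
    (correlation-matrix PCA); features are always centered.
    """
    x = diffs.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 subjects")
    mean = x.mean(axis=0)
    xc = x - mean
    scale_vec = None
    if scale:
        scale_vec = xc.std(axis=0, ddof=1)
        if (scale_vec == 0).any():
            bad = [diffs.columns[j] for j in np.where(scale_vec == 0)[0]]
            raise ValueError(f"zero-variance features cannot be standardized: {bad}")
        xc = xc / scale_vec
    if not (xc.std(axis=0) > 0).any():
        raise ValueError("difference matrix has no variance")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(xc)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    reached = np.where(cum >= target - _EVR_TOL)[0]
    m = int(reached[0]) + 1 if reached.size else len(evr)
    return PcaModel(
        feature_names=list(diffs.columns),
        mean=mean,
        scale=scale_vec,
        loadings=pca.components_[:m].copy(),
        explained_variance_ratio=evr.copy(),
        explained_variance=pca.explained_variance_.copy(),
        m=m,
        target=target,
    )


def fit_stabilized_lasso(
    scores: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 20,
    seed: int = 0,
    cv_folds: int = 5,
    n_penalties: int = 100,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Repeat-averaged L1 logistic regression on component scores.

    Each repeat fits an L1-penalized logistic regression with MCI coded 1
    and the intercept unpenalized; the penalty weight is chosen by
    stratified cross-validation at minimum mean binomial deviance over a
    data-driven log-spaced path running from the smallest penalty that zeroes
    every coefficient down four decades (the R-glmnet convention). Only the
    random fold assignment differs between repeats — the stated source of
    run-to-run variation the averaging suppresses. Returns ``(alpha0,
    alphas, per_repeat)`` where ``per_repeat`` stacks each repeat's
    ``[intercept, coefficients]`` row.
    """
    scores = np.asarray(scores, dtype=float)
    y01 = _as_mci_bool(y).astype(int)
    if scores.ndim != 2 or scores.shape[0] != y01.size:
        raise ValueError("scores must be (n_subjects, m) aligned with labels")
    if y01.all() or not y01.any():
        raise ValueError("stabilized lasso needs both classes present")
    n = y01.size
    lam_max = np.abs(scores.T @ (y01 - y01.mean())).max() / n
    lam_max = max(lam_max, 1e-10)
    lambdas = np.geomspace(lam_max, lam_max * 1e-4, n_penalties)
    cs_path = 1.0 / (n * lambdas)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_repeats):
        fold_seed = int(rng.integers(2**31 - 1))
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
        est = LogisticRegressionCV(
            Cs=cs_path,
            cv=cv,
            penalty="l1",
            solver="saga",
            scoring="neg_log_loss",
            max_iter=2000,
            tol=1e-4,
            random_state=fold_seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(scores, y01)
            rows.append(np.concatenate([est.intercept_, est.coef_.ravel()]))
        except Exception as exc:  # separation or non-convergence
            warnings.warn(
                f"cross-validated lasso repeat failed ({exc}); "
                "falling back to the strongest penalty"
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fallback = LogisticRegression(
                    C=float(cs_path.min()),
                    penalty="l1",
                    solver="saga",
                    max_iter=2000,
                    tol=1e-4,
                )
                fallback.fit(scores, y01)
            rows.append(np.concatenate([fallback.intercept_, fallback.coef_.ravel()]))
    per_repeat = np.vstack(rows)
    avg = per_repeat.mean(axis=0)
    return float(avg[0]), avg[1:], per_repeat


def compute_mcidi(alpha0: float, alphas: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Logistic index value for component-score rows: in (0, 1)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    eta = alpha0 + scores @ np.asarray(alphas, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def ber(fpr: float, fnr: float, mode: str = "arithmetic") -> float:
    """Balanced error rate of a false-positive / false-negative rate pair.

    ``arithmetic`` (default) is the standard (FPR + FNR) / 2; ``harmonic``
    is the literal harmonic mean 2*FPR*FNR/(FPR+FNR), defined as 0 when both
    rates vanish.
    """
    if not (0 <= fpr <= 1 and 0 <= fnr <= 1):
        raise ValueError("rates must be in [0, 1]")
    if mode == "arithmetic":
        return (fpr + fnr) / 2.0
    if mode == "harmonic":
        return 0.0 if fpr + fnr == 0 else 2.0 * fpr * fnr / (fpr + fnr)
    raise ValueError(f"unknown BER mode {mode!r}")


def _ber_curve(values: np.ndarray, y_mci: np.ndarray, mode: str):
    """BER at each candidate threshold (midpoints of sorted uniques + {0,1})."""
    uniq = np.unique(values)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    candidates = np.unique(candidates)
    n_mci = int(y_mci.sum())
    n_healthy = int((~y_mci).sum())
    bers = np.empty(candidates.size)
    for i, tau in enumerate(candidates):
        pred = values >= tau
        fpr = float((pred & ~y_mci).sum()) / n_healthy
        fnr = float((~pred & y_mci).sum()) / n_mci
        bers[i] = ber(fpr, fnr, mode=mode)
    return candidates, bers


def select_threshold(values, labels, mode: str = "arithmetic") -> float:
    """BER-minimizing decision threshold over the index values.

    Candidates are the midpoints between consecutive sorted unique values
    plus the boundaries {0, 1}; the smallest candidate achieving the minimal
    BER is returned (prediction rule: MCI when value >= threshold).
    """
    values = np.asarray(values, dtype=float)
    y_mci = _as_mci_bool(labels)
    if y_mci.all() or not y_mci.any():
        raise ValueError("threshold selection needs both classes present")
    candidates, bers = _ber_curve(values, y_mci, mode)
    return float(candidates[int(np.argmin(bers))])


def _as_mci_bool(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        bad = set(np.unique(y)) - {"MCI", "healthy"}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        return y == "MCI"
    return y.astype(bool)


# ---------------------------------------------------------------------------
# Model / Results


class McidiModel:
    """MCI discrimination model over a (selected) difference matrix.

    Parameters
    ----------
    diffs
        Subject-by-feature difference matrix (calculation minus reading). If
        ``masks`` is given only its surviving features are used; otherwise
        every column is treated as already selected.
    labels
        Label table aligned with ``diffs`` rows (needs ``group``; ``mmse``
        enables correlation diagnostics).
    config
        :class:`~mcidi.config.PipelineConfig`; defaults reproduce the
        reference settings.
    masks
        Optional :class:`~mcidi.screening.ScreeningMasks` from the
        three-stage screen.

    Use :meth:`from_tables` to build the model straight from an
    utterance-level table: it validates, averages by state, differences, and
    runs the screen.
    """

    def __init__(
        self,
        diffs: pd.DataFrame,
        labels: pd.DataFrame,
        config: Optional[PipelineConfig] = None,
        masks: Optional[screening.ScreeningMasks] = None,
    ) -> None:
        self.config = config or PipelineConfig()
        if isinstance(labels, pd.Series):
            labels = pd.DataFrame({"subject_id": diffs.index, "group": labels.values})
        if len(diffs) != len(labels):
            raise ValueError("difference matrix and label table are misaligned")
        self.diffs = diffs
        self.labels = labels.reset_index(drop=True)
        self.masks = masks
        selected = masks.selected if masks is not None else list(diffs.columns)
        if not selected:
            raise ValueError("no features survived selection; cannot fit")
        self.selected_features = selected

    @classmethod
    def from_tables(
        cls,
        utterances: pd.DataFrame,
        labels: pd.DataFrame,
        config: Optional[PipelineConfig] = None,
    ) -> "McidiModel":
        """Build the model from utterance-level data, running the screen."""
        config = config or PipelineConfig()
        prep.validate_utterance_table(utterances)
        means = prep.average_by_state(utterances, validate=False)
        diffs = prep.compute_difference(means, labels=labels)
        masks = screening.screen_features(
            utterances,
            diffs,
            labels,
            alpha=config.alpha,
            corr_threshold=config.corr_threshold,
            n_select=config.n_select,
            auc_orientation=config.auc_orientation,
        )
        return cls(diffs, labels, config=config, masks=masks)

    def fit(self, seed: Optional[int] = None) -> "McidiResults":
        """Fit PCA, the repeat-averaged lasso and the BER threshold."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        x = self.diffs[self.selected_features]
        pca = fit_pca_80(x, target=cfg.pca_target, scale=cfg.pca_scale)
        scores = pca.transform(x)
        y = self.labels["group"].to_numpy()
        alpha0, alphas, per_repeat = fit_stabilized_lasso(
            scores,
            y,
            n_repeats=cfg.n_repeats,
            seed=seed,
            cv_folds=cfg.lasso_cv_folds,
            n_penalties=cfg.n_penalties,
        )
        train_index = compute_mcidi(alpha0, alphas, scores)
        threshold = select_threshold(train_index, y, mode=cfg.ber_mode)
        return McidiResults(
            model=self,
            pca=pca,
            alpha0=alpha0,
            alphas=alphas,
            per_repeat=per_repeat,
            threshold=threshold,
            seed=seed,
        )


class McidiResults:
    """Fitted MCIDI: transform, averaged coefficients, threshold, diagnostics."""

    def __init__(
        self,
        pca: PcaModel,
        alpha0: float,
        alphas: np.ndarray,
        threshold: float,
        seed: int,
        model: Optional[McidiModel] = None,
        per_repeat: Optional[np.ndarray] = None,
        config: Optional[PipelineConfig] = None,
    ) -> None:
        self.model = model
        self.pca = pca
        self.alpha0 = float(alpha0)
        self.alphas = np.asarray(alphas, dtype=float)
        self.per_repeat = per_repeat
        self.threshold = float(threshold)
        self.seed = int(seed)
        self.config = config if config is not None else (
            model.config if model is not None else PipelineConfig()
        )

    # -- parameters -------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        """Averaged intercept and component coefficients, statsmodels-style."""
        names = ["alpha_0"] + [f"alpha_{i + 1}" for i in range(self.alphas.size)]
        return pd.Series(
            np.concatenate([[self.alpha0], self.alphas]), index=names, name="params"
        )

    @property
    def coefficient_se(self) -> Optional[pd.Series]:
        """Across-repeat standard deviation of each coefficient (stability)."""
        if self.per_repeat is None:
            return None
        sd = self.per_repeat.std(axis=0, ddof=1) if len(self.per_repeat) > 1 else (
            np.zeros(self.per_repeat.shape[1])
        )
        return pd.Series(sd, index=self.params.index, name="repeat_sd")

    # -- prediction -------------------------------------------------------

    def predict(self, diffs: Optional[pd.DataFrame] = None) -> pd.Series:
        """MCIDI values for a difference matrix (training data by default)."""
        if diffs is None:
            if self.model is None:
                raise ValueError("no training data attached; pass a difference matrix")
            diffs = self.model.diffs
        scores = self.pca.transform(diffs)
        return pd.Series(
            compute_mcidi(self.alpha0, self.alphas, scores),
            index=diffs.index,
            name="mcidi",
        )

    def predict_from_tables(self, utterances: pd.DataFrame) -> pd.Series:
        """MCIDI values straight from an utterance-level table."""
        means = prep.average_by_state(utterances)
        return self.predict(prep.compute_difference(means))

    def classify(self, mcidi_values) -> np.ndarray:
        """Group prediction: MCI when MCIDI >= threshold."""
        v = np.asarray(mcidi_values, dtype=float)
        return np.where(v >= self.threshold, "MCI", "healthy")

    # -- evaluation -------------------------------------------------------

    def evaluate(
        self,
        diffs: Optional[pd.DataFrame] = None,
        labels: Optional[pd.DataFrame] = None,
        cohort: str = "training",
    ) -> "evaluation.MetricsReport":
        """Confusion-matrix metrics + ROC AUC on a cohort (default training)."""
        if labels is None:
            if self.model is None:
                raise ValueError("no training labels attached")
            labels = self.model.labels
        values = self.predict(diffs).to_numpy()
        groups = labels["group"].to_numpy()
        cm = evaluation.confusion(values, groups, self.threshold)
        auc = evaluation.roc_auc(values, groups)[1]
        return evaluation.metrics(cm, auc=auc, cohort=cohort)

    def plot_roc(self, diffs=None, labels=None, ax=None):
        """ROC curve of the index on a cohort (training by default)."""
        import matplotlib.pyplot as plt

        if labels is None:
            if self.model is None:
                raise ValueError("no training labels attached")
            labels = self.model.labels
        values = self.predict(diffs).to_numpy()
        (fpr, tpr), auc = evaluation.roc_auc(values, labels["group"].to_numpy())
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"MCIDI (AUC = {auc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted index."""
        cfg = self.config
        lines = [
            "MCI discrimination index (MCIDI) fit",
            "=" * 52,
            f"retained components (m): {self.pca.m:>6d}"
            f"   cumulative EVR: {self.pca.explained_variance_ratio[: self.pca.m].sum():.3f}",
            f"selected features:       {len(self.pca.feature_names):>6d}",
            f"lasso repeats averaged:  {cfg.n_repeats:>6d}"
            f"   CV folds: {cfg.lasso_cv_folds}",
            f"decision threshold tau:  {self.threshold:>9.4f} (BER mode: {cfg.ber_mode})",
            f"seed: {self.seed}   config hash: {cfg.hash()}",
            "-" * 52,
            f"{'coefficient':<12}{'mean':>12}{'repeat sd':>12}",
        ]
        se = self.coefficient_se
        for name, value in self.params.items():
            sd = "" if se is None else f"{se[name]:>12.4f}"
            lines.append(f"{name:<12}{value:>12.4f}{sd}")
        if self.model is not None and self.model.masks is not None:
            lines.append("-" * 52)
            lines.append(f"selection funnel: {self.model.masks.funnel()}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "mcidi-model",
            "version": 1,
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "seed": self.seed,
            "pca": self.pca.to_dict(),
            "alpha0": self.alpha0,
            "alphas": self.alphas.tolist(),
            "threshold": self.threshold,
            "per_repeat": None
            if self.per_repeat is None
            else self.per_repeat.tolist(),
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "McidiResults":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "mcidi-model":
            raise ValueError(f"{path} is not a serialized MCIDI model")
        return cls(
            pca=PcaModel.from_dict(d["pca"]),
            alpha0=d["alpha0"],
            alphas=np.asarray(d["alphas"], dtype=float),
            threshold=d["threshold"],
            seed=d["seed"],
            per_repeat=None
            if d["per_repeat"] is None
            else np.asarray(d["per_repeat"], dtype=float),
            config=PipelineConfig.from_dict(d["config"]),
        )
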