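"""Pipeline configuration.

All tunables of the MCIDI derivation live in :class:`PipelineConfig`. The
defaults reproduce the published analysis settings: a 1% significance level
for the per-feature state-effect screen, an |r| > 0.15 MMSE-correlation
filter, AUC-ranked selection capped at the number of training subjects, PCA
retained up to 80% cumulative explained variance, and 20 repeats of
cross-validated L1 logistic regression whose coefficients are averaged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables for the full screening + modelling pipeline.

    Parameters
    ----------
    alpha
        Significance level of the stage-1 random-intercept state-effect test
        (no multiple-testing correction is applied).
    corr_threshold
        Stage-2 keeps features with ``|r| > corr_threshold`` between the
        per-subject feature difference and the MMSE score (strict inequality).
    n_select
        Stage-3 cap: number of features kept in descending-AUC order. ``None``
        means "number of training subjects", the rank-deficiency-avoiding
        default.
    auc_orientation
        ``"max"`` ranks features by ``max(a, 1 - a)`` (direction-agnostic);
        ``"raw"`` ranks by the raw MCI-vs-healthy AUC.
    pca_target
        Cumulative explained-variance ratio at which components stop being
        retained (inclusive rule: the smallest m with cumulative ratio >= target).
    pca_scale
        If True (default) PCA is run on standardized differences
        (correlation-matrix PCA); otherwise on centered raw differences.
    n_repeats
        Number of independent L1-logistic fits whose coefficients are averaged.
    lasso_cv_folds
        Stratified folds used inside each repeat to pick the penalty weight.
    n_penalties
        Length of the log-spaced penalty path searched by cross-validation.
    ber_mode
        ``"arithmetic"`` (default): BER = (FPR + FNR) / 2. ``"harmonic"``:
        BER = 2*FPR*FNR/(FPR+FNR), the literal harmonic mean (degenerate at
        single-class predictions; provided for completeness).
    cv_folds
        Default k for k-fold cross-validation of the whole pipeline.
    healthy_min, mci_min
        MMSE cutoffs: score >= healthy_min is healthy, mci_min..healthy_min-1
        is MCI, below mci_min is cognitive disease (merged into MCI).
    seed
        Seed for every stochastic element (lasso fold splits, CV folds).
    """

    alpha: float = 0.01
    corr_threshold: float = 0.15
    n_select: Optional[int] = None
    auc_orientation: str = "max"
    pca_target: float = 0.80
    pca_scale: bool = True
    n_repeats: int = 20
    lasso_cv_folds: int = 5
    n_penalties: int = 100
    ber_mode: str = "arithmetic"
    cv_folds: int = 5
    healthy_min: int = 28
    mci_min: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 <= self.corr_threshold < 1:
            raise ConfigError(
                f"corr_threshold must be in [0, 1), got {self.corr_threshold}"
            )
        if self.n_select is not None and self.n_select < 1:
            raise ConfigError(f"n_select must be >= 1, got {self.n_select}")
        if not 0 < self.pca_target <= 1:
            raise ConfigError(f"pca_target must be in (0, 1], got {self.pca_target}")
        if self.n_repeats < 1:
            raise ConfigError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.ber_mode not in ("arithmetic", "harmonic"):
            raise ConfigError(f"unknown ber_mode {self.ber_mode!r}")
        if self.auc_orientation not in ("max", "raw"):
            raise ConfigError(f"unknown auc_orientation {self.auc_orientation!r}")
        if not 0 <= self.mci_min <= self.healthy_min <= 30:
            raise ConfigError(
                f"need 0 <= mci_min <= healthy_min <= 30, got "
                f"({self.mci_min}, {self.healthy_min})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"configuration file {path} must hold a mapping")
        return cls.from_dict(raw)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def hash(self) -> str:
        """Stable short hash of the configuration, embedded in all outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
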