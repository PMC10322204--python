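"""Synthetic dual-task voice-feature cohorts.

No recordings ship with the pipeline, so this module generates utterance-level
feature tables with the statistical structure the analysis assumes. Each
feature follows the repeated-measures random-intercept model

    f_ikp = mu_p + b_ip + s_ik * (beta1_p + gamma_p * (30 - MMSE_i)) + eps_ikp

with ``s = 1`` for calculation-task rows and ``0`` for reading rows. Features
play one of three roles:

* ``null`` — no state effect at all (beta1 = gamma = 0);
* ``state_only`` — the calculation state shifts the feature (beta1 != 0) but
  the shift is unrelated to cognition (gamma = 0);
* ``state_mmse`` — the state shift grows with cognitive deficit: gamma > 0
  multiplies the subject's MMSE points below 30, so the calc-minus-reading
  difference carries the diagnostic signal (the dual-task hypothesis: a
  harder task perturbs prosody more the further cognition has declined).

Subjects are split into healthy and MCI groups deterministically
(``round(n * prop_mci)`` MCI subjects, randomly placed), MMSE scores are
drawn per group and clamped to the clinical cutoff ranges in strict mode,
and the calculation-utterance count per subject is a rounded normal clipped
from below — mirroring the observed mean/SD of roughly 5.4 (1.2) answers per
subject with two readings each.

One global seed governs everything; per-subject sub-streams are spawned
deterministically so cohorts are reproducible row for row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .prep import STATE_CALCULATION, STATE_READING, make_label_table

__all__ = ["SyntheticConfig", "GroundTruth", "draw_cohort", "write_cohort"]


class SyntheticConfigError(ValueError):
    """Raised when a synthetic-cohort configuration is invalid."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the reference study conditions.

    ``mmse_params`` maps group -> (mean, sd) of the normal the integer MMSE
    score is rounded from; in ``strict_cutoffs`` mode draws are clamped into
    the group's clinical range (healthy 28-30, MCI 24-27) so labels and
    cutoff-derived groups coincide. ``frac_state_only``/``frac_state_mmse``
    set the feature-role mix; the remainder are pure-noise nulls.
    ``block_correlation`` optionally correlates the per-subject random
    intercepts within each feature-role block.

    ``feature_seed`` pins the feature-level parameters (role assignment,
    baselines, effect signs) independently of the subject draws: two cohorts
    generated with the same ``feature_seed`` but different ``seed`` share
    the same planted feature structure while enrolling different subjects —
    a verification population for a model trained on the first cohort. With
    ``feature_seed=None`` (default) feature parameters derive from ``seed``.
    """

    n_subjects: int = 198
    prop_mci: float = 48 / 198
    n_features: int = 300
    frac_state_only: float = 0.60
    frac_state_mmse: float = 0.08
    mmse_params: dict = field(
        default_factory=lambda: {"healthy": (29.6, 0.6), "mci": (26.0, 0.9)}
    )
    strict_cutoffs: bool = True
    state_effect_size: float = 0.5
    mmse_link_slope: float = 0.14
    subject_sd: float = 1.0
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    block_correlation: float = 0.0
    utterance_count_params: tuple = (5.39, 1.21)
    min_utterances: int = 3
    n_reading: int = 2
    seed: int = 0
    feature_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_features < 1:
            raise SyntheticConfigError("need >= 2 subjects and >= 1 feature")
        if not 0 < self.prop_mci < 1:
            raise SyntheticConfigError(f"prop_mci must be in (0,1), got {self.prop_mci}")
        if min(self.frac_state_only, self.frac_state_mmse) < 0 or (
            self.frac_state_only + self.frac_state_mmse > 1
        ):
            raise SyntheticConfigError(
                "feature-role fractions must be >= 0 and sum to <= 1"
            )
        for name in ("subject_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise SyntheticConfigError(f"{name} must be > 0")
        if not 0 <= self.block_correlation < 1:
            raise SyntheticConfigError("block_correlation must be in [0, 1)")
        if self.min_utterances < 1 or self.n_reading < 1:
            raise SyntheticConfigError("utterance counts must be >= 1")

    def feature_names(self) -> list:
        width = max(4, len(str(self.n_features)))
        return [f"f{j + 1:0{width}d}" for j in range(self.n_features)]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for use as a selection-stage oracle."""

    roles: dict  # feature name -> {"null", "state_only", "state_mmse"}
    groups: dict  # subject_id -> true group
    beta1: dict  # feature name -> realized state-effect coefficient

    def features_with_role(self, role: str) -> list:
        return [f for f, r in self.roles.items() if r == role]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"roles": self.roles, "groups": self.groups, "beta1": self.beta1},
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(roles=d["roles"], groups=d["groups"], beta1=d["beta1"])


_MMSE_RANGES = {"healthy": (28, 30), "mci": (24, 27)}


def _draw_mmse(rng: np.random.Generator, group: str, cfg: SyntheticConfig) -> int:
    mean, sd = cfg.mmse_params[group]
    score = int(np.clip(np.round(rng.normal(mean, sd)), 0, 30))
    if cfg.strict_cutoffs:
        lo, hi = _MMSE_RANGES[group]
        score = int(np.clip(score, lo, hi))
    return score


def _draw_utterance_count(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    mean, sd = cfg.utterance_count_params
    return int(max(cfg.min_utterances, np.round(rng.normal(mean, sd))))


def draw_cohort(
    config: Optional[SyntheticConfig] = None, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic cohort.

    Returns ``(utterances, labels, truth)``: the long-format utterance table,
    the per-subject label table (subject_id, mmse, group, category) and the
    planted ground truth. Fully reproducible: the same config and seed give
    bit-identical tables. ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    global_rng = np.random.default_rng(root.spawn(1)[0])
    subject_streams = root.spawn(cfg.n_subjects + 1)[1:]
    if cfg.feature_seed is None:
        feat_rng = global_rng  # feature parameters ride the cohort stream
    else:
        feat_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.feature_seed).spawn(1)[0]
        )

    p = cfg.n_features
    names = cfg.feature_names()
    n_mmse = int(round(cfg.frac_state_mmse * p))
    n_state = int(round(cfg.frac_state_only * p))
    roles = np.array(
        ["state_mmse"] * n_mmse + ["state_only"] * n_state + ["null"] * (p - n_mmse - n_state)
    )
    feat_rng.shuffle(roles)

    mu = feat_rng.normal(0.0, cfg.baseline_sd, size=p)
    has_state = roles != "null"
    beta1 = np.where(
        has_state, cfg.state_effect_size * feat_rng.choice([-1.0, 1.0], size=p), 0.0
    )
    gamma = np.where(roles == "state_mmse", cfg.mmse_link_slope, 0.0)

    n_mci = int(round(cfg.n_subjects * cfg.prop_mci))
    group_flags = np.zeros(cfg.n_subjects, dtype=bool)
    group_flags[global_rng.permutation(cfg.n_subjects)[:n_mci]] = True

    # block-structured random-intercept correlation (shared factor per role)
    rho = cfg.block_correlation
    block_of = {"null": 0, "state_only": 1, "state_mmse": 2}
    blocks = np.array([block_of[r] for r in roles])

    width = len(str(cfg.n_subjects))
    subject_ids, mmse_scores = [], []
    frames = []
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(subject_streams[i])
        sid = f"S{i + 1:0{width}d}"
        group = "mci" if group_flags[i] else "healthy"
        mmse = _draw_mmse(rng, group, cfg)
        n_calc = _draw_utterance_count(rng, cfg)
        if rho > 0:
            shared = rng.normal(0.0, 1.0, size=3)[blocks]
            b = cfg.subject_sd * (
                np.sqrt(1 - rho) * rng.normal(0.0, 1.0, size=p) + np.sqrt(rho) * shared
            )
        else:
            b = rng.normal(0.0, cfg.subject_sd, size=p)
        n_rows = n_calc + cfg.n_reading
        s = np.zeros(n_rows)
        s[:n_calc] = 1.0
        eps = rng.normal(0.0, cfg.noise_sd, size=(n_rows, p))
        state_term = beta1 + gamma * (30 - mmse)
        values = mu + b + s[:, None] * state_term + eps
        frame = pd.DataFrame(values, columns=names)
        frame.insert(0, "subject_id", sid)
        frame.insert(
            1,
            "state",
            [STATE_CALCULATION] * n_calc + [STATE_READING] * cfg.n_reading,
        )
        frame.insert(
            2,
            "utterance_index",
            list(range(1, n_calc + 1)) + list(range(1, cfg.n_reading + 1)),
        )
        frames.append(frame)
        subject_ids.append(sid)
        mmse_scores.append(mmse)

    utterances = pd.concat(frames, ignore_index=True)
    labels = make_label_table(subject_ids, mmse_scores)
    truth = GroundTruth(
        roles=dict(zip(names, roles.tolist())),
        groups={
            sid: ("MCI" if flag else "healthy")
            for sid, flag in zip(subject_ids, group_flags)
        },
        beta1=dict(zip(names, beta1.tolist())),
    )
    return utterances, labels, truth


def write_cohort(
    utterances: pd.DataFrame,
    labels: pd.DataFrame,
    truth: Optional[GroundTruth],
    out_dir: str,
) -> dict:
    """Write a cohort as delimited text (+ JSON ground truth); returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "utterances": os.path.join(out_dir, "utterances.csv"),
        "labels": os.path.join(out_dir, "labels.csv"),
    }
    utterances.to_csv(paths["utterances"], index=False)
    labels[["subject_id", "mmse", "group"]].to_csv(paths["labels"], index=False)
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.json")
        truth.to_json(paths["truth"])
    return paths
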