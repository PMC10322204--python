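"""Feature preparation: utterance tables, state means, feature differences.

The analysis operates on a long-format utterance table — one row per
(subject, state, utterance) with numeric acoustic feature columns, where
``state`` is either the mental-calculation task or the numerical-sequence
reading baseline. Per subject and state the utterance rows are averaged, and
the core analysis object is the *feature difference*: the calculation-state
mean minus the reading-state mean, one row per subject.

Clinical group assignment follows the standard MMSE cutoffs: scores >= 28 are
healthy, 24-27 mild cognitive impairment (MCI), <= 23 cognitive disease (CD);
CD subjects are merged into the MCI group but keep an internal flag so cohort
summaries remain producible.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "STATE_CALCULATION",
    "STATE_READING",
    "classify_mmse",
    "mmse_category",
    "make_label_table",
    "validate_utterance_table",
    "average_by_state",
    "compute_difference",
    "feature_columns",
    "read_utterance_table",
    "read_label_table",
    "from_wide_functionals",
    "ValidationError",
]

STATE_CALCULATION = "calculation"
STATE_READING = "reading"
_STATES = (STATE_CALCULATION, STATE_READING)

ID_COLUMNS = ("subject_id", "state", "utterance_index")


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's preconditions."""


def mmse_category(
    score: int, healthy_min: int = 28, mci_min: int = 24
) -> str:
    """Three-way MMSE category: ``healthy``, ``MCI`` or ``CD``.

    Scores of ``healthy_min`` (default 28) or above are healthy, scores from
    ``mci_min`` (default 24) to ``healthy_min - 1`` are MCI, and anything
    below ``mci_min`` is cognitive disease (CD).
    """
    score = int(score)
    if not 0 <= score <= 30:
        raise ValidationError(f"MMSE score must be in 0..30, got {score}")
    if score >= healthy_min:
        return "healthy"
    if score >= mci_min:
        return "MCI"
    return "CD"


def classify_mmse(score: int, healthy_min: int = 28, mci_min: int = 24) -> str:
    """Two-group assignment from an MMSE score: CD is merged into MCI."""
    cat = mmse_category(score, healthy_min=healthy_min, mci_min=mci_min)
    return "healthy" if cat == "healthy" else "MCI"


def make_label_table(
    subject_ids: Iterable, mmse: Iterable[int], healthy_min: int = 28, mci_min: int = 24
) -> pd.DataFrame:
    """Build a label table (subject_id, mmse, group, category) from scores."""
    mmse = pd.Series(list(mmse), dtype=int)
    cats = [mmse_category(s, healthy_min, mci_min) for s in mmse]
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "mmse": mmse.to_numpy(),
            "group": ["healthy" if c == "healthy" else "MCI" for c in cats],
            "category": cats,
        }
    )


def feature_columns(table: pd.DataFrame) -> list:
    """Feature column names of an utterance table (everything non-key)."""
    return [c for c in table.columns if c not in ID_COLUMNS]


def validate_utterance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format utterance table invariants.

    Every subject must have at least one calculation and one reading row and
    every feature value must be finite. Returns the table unchanged on
    success; raises :class:`ValidationError` listing offending subjects or
    columns otherwise.
    """
    missing = [c for c in ("subject_id", "state") if c not in table.columns]
    if missing:
        raise ValidationError(f"utterance table lacks required columns {missing}")
    bad_states = set(table["state"].unique()) - set(_STATES)
    if bad_states:
        raise ValidationError(
            f"unknown states {sorted(bad_states)}; expected {_STATES}"
        )
    feats = feature_columns(table)
    if not feats:
        raise ValidationError("utterance table has no feature columns")
    values = table[feats].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = [feats[j] for j in np.where(~np.isfinite(values).all(axis=0))[0]]
        raise ValidationError(f"non-finite values in feature columns {bad}")
    states_per_subject = table.groupby("subject_id")["state"].agg(set)
    incomplete = sorted(
        str(s) for s, st in states_per_subject.items() if st != set(_STATES)
    )
    if incomplete:
        raise ValidationError(
            "subjects missing a recording state (need both calculation and "
            f"reading): {incomplete}"
        )
    return table


def average_by_state(table: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Per-(subject, state) unweighted mean of the utterance rows.

    Returns a frame indexed by (subject_id, state) with the feature columns
    plus an ``n_utterances`` count column. Any utterance count >= 1 is
    handled; a subject missing a state entirely is rejected during
    validation.
    """
    if validate:
        validate_utterance_table(table)
    feats = feature_columns(table)
    grouped = table.groupby(["subject_id", "state"], sort=True)
    means = grouped[feats].mean()
    means["n_utterances"] = grouped.size()
    return means


def compute_difference(
    means: pd.DataFrame, labels: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Calculation-minus-reading feature difference, one row per subject.

    ``means`` is the output of :func:`average_by_state`. If ``labels`` is
    given, rows are ordered to match its ``subject_id`` column; otherwise
    subjects are sorted.
    """
    feats = [c for c in means.columns if c != "n_utterances"]
    by_state = {
        state: means.xs(state, level="state")[feats] for state in _STATES
    }
    calc, read = by_state[STATE_CALCULATION], by_state[STATE_READING]
    missing = set(calc.index).symmetric_difference(read.index)
    if missing:
        raise ValidationError(
            f"subjects missing one state: {sorted(map(str, missing))}"
        )
    diff = calc - read.loc[calc.index]
    if labels is not None:
        wanted = list(labels["subject_id"])
        absent = sorted(str(s) for s in wanted if s not in diff.index)
        if absent:
            raise ValidationError(f"label table subjects without voice data: {absent}")
        diff = diff.loc[wanted]
    else:
        diff = diff.sort_index()
    diff.index.name = "subject_id"
    return diff


# ---------------------------------------------------------------------------
# I/O adapters


def read_utterance_table(path: str) -> pd.DataFrame:
    """Read a comma-separated long-format utterance table."""
    table = pd.read_csv(path)
    validate_utterance_table(table)
    return table


def read_label_table(path: str, healthy_min: int = 28, mci_min: int = 24) -> pd.DataFrame:
    """Read a label table; derives group/category from MMSE when absent."""
    labels = pd.read_csv(path)
    for col in ("subject_id", "mmse"):
        if col not in labels.columns:
            raise ValidationError(f"label table lacks required column {col!r}")
    cats = [mmse_category(s, healthy_min, mci_min) for s in labels["mmse"]]
    if "group" not in labels.columns:
        labels["group"] = ["healthy" if c == "healthy" else "MCI" for c in cats]
    if "category" not in labels.columns:
        labels["category"] = cats
    return labels


def from_wide_functionals(
    frame: pd.DataFrame,
    subject_col: str,
    state_col: str,
    calculation_value,
    reading_value,
    utterance_col: Optional[str] = None,
) -> pd.DataFrame:
    """Adapt a wide per-segment functional export to the long utterance format.

    Acoustic-feature extractors typically emit one row per audio segment with
    named numeric columns. This maps arbitrary subject/state column names and
    state encodings onto the canonical ``subject_id``/``state``/
    ``utterance_index`` keys; every remaining numeric column becomes a
    feature column.
    """
    out = pd.DataFrame({"subject_id": frame[subject_col]})
    state_map = {calculation_value: STATE_CALCULATION, reading_value: STATE_READING}
    states = frame[state_col].map(state_map)
    if states.isna().any():
        bad = sorted(set(frame.loc[states.isna(), state_col].astype(str)))
        raise ValidationError(f"unmapped state values {bad}")
    out["state"] = states.to_numpy()
    if utterance_col is not None:
        out["utterance_index"] = frame[utterance_col].to_numpy()
    else:
        out["utterance_index"] = out.groupby(["subject_id", "state"]).cumcount() + 1
    drop = {subject_col, state_col} | ({utterance_col} if utterance_col else set())
    for col in frame.columns:
        if col in drop:
            continue
        if pd.api.types.is_numeric_dtype(frame[col]):
            out[col] = frame[col].to_numpy(dtype=float)
    return validate_utterance_table(out)
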