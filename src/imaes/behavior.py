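"""Behavioral pipeline: filtering rules, the cross-modality dissimilarity
score, and the high/low experience split.

The dissimilarity score quantifies, per subject and stimulus, how much the
ratings given under mental imagery diverge from those given under visual
perception: the squared perception-minus-imagery difference summed over the
three rating dimensions.  0 means identical responses; the theoretical
maximum is 3 * 6^2 = 108.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import RATING_DIMS

__all__ = [
    "complete_case_filter",
    "dissimilarity_score",
    "label_experience",
    "subset_high_vividness",
]

log = logging.getLogger(__name__)


class EmptyDataError(ValueError):
    """Raised when a filtering step removes every row."""


def complete_case_filter(
    ratings: pd.DataFrame, dims: tuple[str, ...] = RATING_DIMS
) -> pd.DataFrame:
    """Drop rows with any missing rating (complete-case analysis).

    Per-dimension missingness rates are logged.  Raises
    :class:`EmptyDataError` if nothing survives.
    """
    n = len(ratings)
    if n == 0:
        raise EmptyDataError("ratings table is empty")
    for dim in dims:
        rate = ratings[dim].isna().mean()
        if rate > 0:
            log.info("missingness in %r: %.1f%%", dim, 100 * rate)
    out = ratings.dropna(subset=list(dims)).copy()
    if out.empty:
        raise EmptyDataError("complete-case filter removed all rows")
    log.info("complete cases: %d of %d rows kept", len(out), n)
    return out


def dissimilarity_score(
    ratings: pd.DataFrame, dims: tuple[str, ...] = RATING_DIMS
) -> pd.DataFrame:
    """Per-(subject, stimulus) squared rating difference across modalities.

    Returns a table with columns ``subject_id``, ``stimulus_id``, ``score``
    and ``vividness`` (from the paired imagery trial).  Pairs lacking one of
    the two modalities, or containing missing ratings, are skipped with a log
    entry — consistent with complete-case analysis.
    """
    required = {"subject_id", "stimulus_id", "modality", *dims}
    missing_cols = required - set(ratings.columns)
    if missing_cols:
        raise ValueError(f"ratings table lacks columns {sorted(missing_cols)}")
    dup = ratings.duplicated(subset=["subject_id", "stimulus_id", "modality"])
    if dup.any():
        raise ValueError(
            "duplicated (subject, stimulus, modality) rows: "
            f"{ratings.loc[dup, ['subject_id', 'stimulus_id', 'modality']].iloc[0].tolist()}"
        )
    clean = ratings.dropna(subset=list(dims))
    wide = clean.pivot(
        index=["subject_id", "stimulus_id"], columns="modality", values=list(dims)
    )
    have_both = wide.notna().all(axis=1)
    n_skipped = int((~have_both).sum())
    if n_skipped:
        log.info("skipped %d (subject, stimulus) pairs lacking a modality", n_skipped)
    wide = wide[have_both]
    per = np.column_stack([wide[(d, "perception")] for d in dims])
    img = np.column_stack([wide[(d, "imagery")] for d in dims])
    score = ((per - img) ** 2).sum(axis=1)
    out = wide.index.to_frame(index=False)
    out["score"] = score
    if "vividness" in ratings.columns:
        viv = (
            ratings[ratings["modality"] == "imagery"]
            .set_index(["subject_id", "stimulus_id"])["vividness"]
        )
        out["vividness"] = viv.reindex(
            pd.MultiIndex.from_frame(out[["subject_id", "stimulus_id"]])
        ).to_numpy()
    return out


def label_experience(
    ratings: pd.DataFrame, dimension: str = "moving"
) -> pd.DataFrame:
    """Split trials into high/low experience on one rating dimension.

    The scale midpoint (4) is excluded; 1-3 map to ``low`` and 5-7 to
    ``high``.  Adds an ``experience`` column; rows at the midpoint (or with a
    missing rating) are dropped.  Cell counts are logged.
    """
    if dimension not in ratings.columns:
        raise ValueError(f"dimension {dimension!r} not in ratings table")
    r = ratings[dimension]
    keep = r.notna() & (r != 4)
    out = ratings[keep].copy()
    out["experience"] = np.where(out[dimension] > 4, "high", "low")
    counts = out.groupby(["experience", "modality", "stimulus_type"], sort=True).size()
    log.info("experience cell counts:\n%s", counts.to_string())
    return out


def subset_high_vividness(
    ratings: pd.DataFrame, levels: tuple[int, ...] = (6, 7)
) -> pd.DataFrame:
    """Keep only the most vividly imagined trials and their perception pairs.

    Imagery rows are retained when vividness is in ``levels``; each retained
    imagery trial keeps its matching perception trial so paired analyses stay
    balanced.  An empty result warns rather than raising.
    """
    if "vividness" not in ratings.columns:
        raise ValueError("ratings table has no vividness column")
    imagery = ratings["modality"] == "imagery"
    vivid_keys = ratings.loc[
        imagery & ratings["vividness"].isin(levels), ["subject_id", "stimulus_id"]
    ]
    keys = set(map(tuple, vivid_keys.to_numpy()))
    mask = [
        (s, st) in keys
        for s, st in zip(ratings["subject_id"], ratings["stimulus_id"])
    ]
    out = ratings[np.asarray(mask)].copy()
    if out.empty:
        log.warning("high-vividness subset is empty")
    else:
        retained = out[out["modality"] == "imagery"].groupby("subject_id").size()
        log.info("high-vividness trials per subject:\n%s", retained.to_string())
    return out
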