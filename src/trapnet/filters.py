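"""Candidate-interaction filter cascade.

Three stages, applied in order on a spectral-count matrix:

1. control filter — any protein detected in at least one negative-control
   experiment (even with a single spectral count) is treated as background
   and removed globally, for every bait and condition;
2. replicate summation — spectral counts are summed within each
   bait x condition replicate group, yielding one candidate interaction per
   (bait, prey, condition) with a nonzero summed count;
3. one-hit-wonder removal — a bait-prey pair supported by a single summed
   PSM only (no condition reaching a summed count of 2) is dropped.

Surviving candidates are classed by summed count: ``one_hit`` (1),
``weak`` (2) and ``strong`` (>= 3).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .counts import ROLE_BAIT, CountMatrix

logger = logging.getLogger("trapnet")

STRENGTH_ONE_HIT = "one_hit"
STRENGTH_WEAK = "weak"
STRENGTH_STRONG = "strong"
STRENGTH_ABSENT = "absent"

CANDIDATE_COLUMNS = ("bait", "prey", "condition", "summed_count", "strength")

ONE_HIT_PER_CONDITION = "per_condition"
ONE_HIT_COMBINED = "combined"


def classify_strength(summed_count: int, weak_value: int = 2, strong_min: int = 3) -> str:
    """Class of a summed replicate-group spectral count.

    1 is a one-hit wonder, ``weak_value`` (default 2) up to ``strong_min``-1
    is weak, ``strong_min`` (default 3) and above is strong.
    """
    if summed_count < 1:
        raise ValueError("summed_count must be >= 1 for a candidate")
    if summed_count >= strong_min:
        return STRENGTH_STRONG
    if summed_count >= weak_value:
        return STRENGTH_WEAK
    return STRENGTH_ONE_HIT


def control_filter(matrix: CountMatrix) -> CountMatrix:
    """Drop every protein detected in any control experiment.

    Removal is global: one nonzero count in one control column removes the
    protein from all baits and both conditions. Raises if the matrix holds
    no control columns (the filter would be vacuous).
    """
    control_cols = matrix.control_columns()
    if not control_cols:
        raise ValueError("control_filter requires >= 1 control experiment column")
    in_control = matrix.counts[control_cols].to_numpy().sum(axis=1) > 0
    removed = [p for p, flag in zip(matrix.counts.index, in_control) if flag]
    kept = matrix.counts.loc[~in_control]
    # proteins seen only in controls vanish entirely; re-check row support
    support = kept.to_numpy().sum(axis=1) > 0
    kept = kept.loc[support]
    logger.info(
        "control_filter: removed %d background proteins, %d retained",
        len(removed), len(kept),
    )
    return CountMatrix(kept.copy(), matrix.meta.copy())


def sum_replicates(
    matrix: CountMatrix,
    weak_value: int = 2,
    strong_min: int = 3,
) -> pd.DataFrame:
    """Sum counts within each bait x condition replicate group.

    Returns the candidate table (bait, prey, condition, summed_count,
    strength); zero-sum groups emit no candidate. The matrix is expected to
    be control-filtered already; the summation itself does not check that.
    """
    rows: list[tuple[str, str, str, int, str]] = []
    meta = matrix.meta
    bait_meta = meta.loc[meta["role"] == ROLE_BAIT]
    for (bait, condition), grp in bait_meta.groupby(["bait", "condition"], sort=True):
        cols = list(grp["experiment_id"])
        sums = matrix.counts[cols].to_numpy().sum(axis=1)
        for prey, s in zip(matrix.counts.index, sums):
            if s > 0:
                rows.append(
                    (bait, prey, condition, int(s), classify_strength(int(s), weak_value, strong_min))
                )
    out = pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))
    return out.sort_values(["bait", "prey", "condition"], ignore_index=True)


def drop_one_hit_wonders(
    candidates: pd.DataFrame,
    mode: str = ONE_HIT_PER_CONDITION,
    keep_one_hit_presence: bool = True,
) -> pd.DataFrame:
    """Remove pairs supported only by a single summed PSM.

    In the default ``per_condition`` mode a (bait, prey) pair survives iff
    its summed count reaches 2 in at least one condition; in ``combined``
    mode the sums of both conditions are added before the test. For a
    surviving pair, per-condition entries with a summed count of 1 are kept
    as presence evidence but stay flagged ``one_hit`` (they confer no
    strength) unless ``keep_one_hit_presence`` is false, in which case they
    are dropped too.
    """
    if mode not in (ONE_HIT_PER_CONDITION, ONE_HIT_COMBINED):
        raise ValueError(f"unknown one-hit-wonder mode: {mode!r}")
    if candidates.empty:
        return candidates.copy()
    grouped = candidates.groupby(["bait", "prey"])["summed_count"]
    if mode == ONE_HIT_PER_CONDITION:
        surviving = grouped.max() >= 2
    else:
        surviving = grouped.sum() >= 2
    keys = pd.MultiIndex.from_frame(candidates[["bait", "prey"]])
    keep = surviving.reindex(keys).to_numpy()
    out = candidates.loc[keep]
    if not keep_one_hit_presence:
        out = out.loc[out["summed_count"] >= 2]
    n_dropped_pairs = int((~surviving).sum())
    if n_dropped_pairs:
        logger.info("drop_one_hit_wonders: removed %d one-hit pairs", n_dropped_pairs)
    return out.reset_index(drop=True)


def run_cascade(
    matrix: CountMatrix,
    weak_value: int = 2,
    strong_min: int = 3,
    one_hit_mode: str = ONE_HIT_PER_CONDITION,
    keep_one_hit_presence: bool = True,
) -> pd.DataFrame:
    """Control filter, replicate summation and one-hit removal, composed."""
    filtered = control_filter(matrix)
    cands = sum_replicates(filtered, weak_value=weak_value, strong_min=strong_min)
    return drop_one_hit_wonders(cands, mode=one_hit_mode, keep_one_hit_presence=keep_one_hit_presence)
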