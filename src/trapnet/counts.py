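"""Spectral-count matrix: assembly, validation and the pre-filter census.

The central data structure joins a proteins x experiments matrix of
non-negative integer spectral counts (PSM counts per protein per LC-MS/MS
run) to per-experiment metadata: which bait was expressed, the treatment
condition, the biological replicate index, and whether the run is a bait
experiment or a negative-control experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("trapnet")

ROLE_BAIT = "bait_experiment"
ROLE_CONTROL = "control_experiment"
ROLES = (ROLE_BAIT, ROLE_CONTROL)

CONDITION_UNTREATED = "untreated"
CONDITION_TNF = "TNF"
CONDITION_NA = "not_applicable"
DEFAULT_CONDITIONS = (CONDITION_UNTREATED, CONDITION_TNF)

META_COLUMNS = ("experiment_id", "bait", "condition", "replicate", "role")

DEFAULT_DECOY_PREFIX = "REV_"


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check an experiment-metadata table and return it with canonical dtypes.

    Requires columns ``experiment_id, bait, condition, replicate, role``;
    experiment ids unique; (bait, condition, replicate) unique among bait
    experiments; control baits disjoint from study baits.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    meta["experiment_id"] = meta["experiment_id"].astype(str)
    meta["bait"] = meta["bait"].astype(str)
    meta["condition"] = meta["condition"].astype(str)
    meta["replicate"] = meta["replicate"].astype(int)
    meta["role"] = meta["role"].astype(str)

    dup = meta["experiment_id"][meta["experiment_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate experiment_id: {sorted(set(dup))}")
    bad_role = set(meta["role"]) - set(ROLES)
    if bad_role:
        raise ValueError(f"unknown role values: {sorted(bad_role)}")
    if (meta["replicate"] < 1).any():
        raise ValueError("replicate indices must be >= 1")

    is_bait = meta["role"] == ROLE_BAIT
    bait_rows = meta.loc[is_bait]
    key = bait_rows[["bait", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValueError("(bait, condition, replicate) not unique among bait experiments")
    study_baits = set(bait_rows["bait"])
    control_baits = set(meta.loc[~is_bait, "bait"])
    clash = study_baits & control_baits
    if clash:
        raise ValueError(f"control experiments use study baits: {sorted(clash)}")
    return meta


@dataclass
class CountMatrix:
    """Non-negative integer spectral counts (proteins x experiments) + metadata.

    ``counts`` is indexed by protein accession with one column per
    experiment_id; ``meta`` is the validated experiment table. Every protein
    row has a nonzero count in at least one experiment and decoy accessions
    are excluded at assembly time.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = validate_meta(self.meta)
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("duplicate protein accessions in count matrix")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("spectral counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")
        meta_ids = list(self.meta["experiment_id"])
        if set(counts.columns) != set(meta_ids):
            raise ValueError("count matrix columns do not match metadata experiment_ids")
        # canonical column order follows the metadata table
        counts = counts.loc[:, meta_ids]
        if len(counts) and not (counts.to_numpy().sum(axis=1) > 0).all():
            raise ValueError("every protein must have a nonzero count in >= 1 experiment")
        self.counts = counts

    # -- column helpers -------------------------------------------------

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def baits(self) -> list[str]:
        m = self.meta
        return sorted(set(m.loc[m["role"] == ROLE_BAIT, "bait"]))

    @property
    def conditions(self) -> list[str]:
        m = self.meta
        seen: list[str] = []
        for c in m.loc[m["role"] == ROLE_BAIT, "condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def control_columns(self) -> list[str]:
        m = self.meta
        return list(m.loc[m["role"] == ROLE_CONTROL, "experiment_id"])

    def bait_columns(self, bait: str | None = None, condition: str | None = None) -> list[str]:
        m = self.meta
        mask = m["role"] == ROLE_BAIT
        if bait is not None:
            mask &= m["bait"] == bait
        if condition is not None:
            mask &= m["condition"] == condition
        return list(m.loc[mask, "experiment_id"])

    def subset_proteins(self, keep: Iterable[str]) -> "CountMatrix":
        keep = [p for p in self.counts.index if p in set(keep)]
        return CountMatrix(self.counts.loc[keep].copy(), self.meta.copy())


def assemble(
    per_experiment_tables: Mapping[str, Mapping[str, int]],
    meta: pd.DataFrame,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> CountMatrix:
    """Join per-experiment ``protein -> count`` maps into one matrix.

    The protein set is the union over all tables; absent entries are zero.
    Hits against the reversed (decoy) database — accessions starting with
    ``decoy_prefix`` — are dropped, with the number of dropped entries
    logged. Unknown experiment ids and negative counts are rejected.
    """
    meta = validate_meta(meta)
    meta_ids = list(meta["experiment_id"])
    table_ids = [str(k) for k in per_experiment_tables]
    unknown = set(table_ids) - set(meta_ids)
    if unknown:
        raise ValueError(f"experiment_id not in metadata: {sorted(unknown)}")
    absent = set(meta_ids) - set(table_ids)
    if absent:
        raise ValueError(f"metadata experiment_id without a count table: {sorted(absent)}")

    n_decoy = 0
    columns: dict[str, dict[str, int]] = {}
    for exp_id, table in per_experiment_tables.items():
        col: dict[str, int] = {}
        for protein, count in table.items():
            protein = str(protein)
            count = int(count)
            if count < 0:
                raise ValueError(f"negative count for {protein} in {exp_id}")
            if decoy_prefix and protein.startswith(decoy_prefix):
                n_decoy += 1
                continue
            if count:
                col[protein] = col.get(protein, 0) + count
        columns[str(exp_id)] = col
    if n_decoy:
        logger.info("assemble: dropped %d decoy entries (prefix %r)", n_decoy, decoy_prefix)

    proteins = sorted({p for col in columns.values() for p in col})
    counts = pd.DataFrame(0, index=proteins, columns=meta_ids, dtype=np.int64)
    for exp_id, col in columns.items():
        for protein, count in col.items():
            counts.at[protein, exp_id] = count
    counts.index.name = "protein"
    return CountMatrix(counts, meta)


def census(matrix: CountMatrix) -> tuple[int, int]:
    """Pre-filter census: (distinct proteins, distinct bait-prey interactions).

    A prey counts as identified for a bait when it has a nonzero spectral
    count in at least one of that bait's experiments (either condition, any
    replicate). Control columns never contribute interactions; bait
    self-identifications are included.
    """
    n_proteins = len(matrix.counts)
    n_interactions = 0
    for bait in matrix.baits:
        cols = matrix.bait_columns(bait)
        if not cols:
            continue
        hit = matrix.counts[cols].to_numpy().sum(axis=1) > 0
        n_interactions += int(hit.sum())
    return n_proteins, n_interactions
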