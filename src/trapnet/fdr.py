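"""Target/decoy false-discovery rate at the PSM level.

Searches are run against the target database and a sequence-reversed decoy
database; per spectrum only the highest-scoring match across both searches
is retained, and the FDR is the fraction of retained PSMs that hit the
decoy database: decoys / (targets + decoys).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class PSMRecord:
    spectrum_id: str
    protein: str
    peptide: str
    score: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not self.spectrum_id:
            raise ValueError("spectrum_id must be nonempty")
        if not self.score == self.score or self.score in (float("inf"), float("-inf")):
            raise ValueError("score must be finite")


def best_psm_per_spectrum(psms: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Keep the highest-scoring match per spectrum (target or decoy).

    A score tie between a target and a decoy match resolves to the decoy,
    the conservative choice for FDR estimation. Idempotent; returns records
    ordered by spectrum id.
    """
    best: dict[str, PSMRecord] = {}
    for rec in psms:
        cur = best.get(rec.spectrum_id)
        if cur is None or rec.score > cur.score or (
            rec.score == cur.score and rec.is_decoy and not cur.is_decoy
        ):
            best[rec.spectrum_id] = rec
    return [best[s] for s in sorted(best)]


def compute_fdr(psms: Sequence[PSMRecord]) -> float:
    """decoys / all PSMs over an already best-per-spectrum-reduced list.

    An empty list has FDR 0 by convention (nothing reported, nothing
    false).
    """
    if not psms:
        return 0.0
    n_decoy = sum(1 for rec in psms if rec.is_decoy)
    return n_decoy / len(psms)


def aggregate_fdr(runs: Iterable[Sequence[PSMRecord]]) -> float:
    """Global FDR over several runs: summed decoys over summed totals.

    Each run is reduced to its best PSM per spectrum first (spectrum ids
    are scoped per run, as in separate LC-MS/MS acquisitions).
    """
    n_decoy = 0
    n_total = 0
    for run in runs:
        reduced = best_psm_per_spectrum(run)
        n_decoy += sum(1 for rec in reduced if rec.is_decoy)
        n_total += len(reduced)
    return n_decoy / n_total if n_total else 0.0


def read_psm_tsv(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> list[PSMRecord]:
    """Read a PSM table: spectrum_id, protein, peptide, score[, is_decoy].

    Without an ``is_decoy`` column the flag is inferred from the accession
    prefix (default ``REV_``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "protein": str})
    required = {"spectrum_id", "protein", "peptide", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    if "is_decoy" in df.columns:
        flags = df["is_decoy"].astype(str).str.lower().isin(("1", "true", "yes"))
    else:
        flags = df["protein"].str.startswith(decoy_prefix)
    return [
        PSMRecord(str(r.spectrum_id), str(r.protein), str(r.peptide), float(r.score), bool(f))
        for r, f in zip(df.itertuples(index=False), flags)
    ]


def write_psm_tsv(psms: Sequence[PSMRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(p.spectrum_id, p.protein, p.peptide, p.score, p.is_decoy) for p in psms],
        columns=["spectrum_id", "protein", "peptide", "score", "is_decoy"],
    ).to_csv(path, sep="\t", index=False)
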