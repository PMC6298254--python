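"""File formats: count/metadata/candidate TSVs, reference sets, and
network exports (SIF, GraphML, PSI-MITAB 2.5, node/edge attribute tables).

Wide count TSV is canonical (first column ``protein``, one column per
experiment id, mirroring a deposited spectral-count table); a long dialect
(experiment_id, protein, count) is also read. Every writer has a matching
reader; GraphML and node/edge tables round-trip the full data model, SIF
is documented as lossy (topology only).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .counts import CountMatrix, validate_meta
from .filters import CANDIDATE_COLUMNS
from .network import NODE_CLASS_UNANNOTATED, ReferenceInteractionSet

logger = logging.getLogger("trapnet")

SIF_RELATION = "interacts-with"
MITAB_COLUMNS = 15
EXPORT_FORMATS = ("SIF", "GraphML", "MITAB25", "node_table", "edge_table")


# --- count matrices -----------------------------------------------------

def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    """Wide dialect: protein accession first, one column per experiment."""
    matrix.counts.rename_axis("protein").to_csv(path, sep="\t")


def write_meta_tsv(matrix_or_meta, path: str | Path) -> None:
    meta = matrix_or_meta.meta if isinstance(matrix_or_meta, CountMatrix) else matrix_or_meta
    meta.to_csv(path, sep="\t", index=False)


def read_counts_tsv(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a wide count TSV plus its experiment-metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t")
    return CountMatrix(counts, validate_meta(meta))


def read_counts_long_tsv(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read the long dialect: columns experiment_id, protein, count."""
    long = pd.read_csv(counts_path, sep="\t", dtype={"experiment_id": str, "protein": str})
    required = {"experiment_id", "protein", "count"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"long count table missing columns: {sorted(missing)}")
    meta = validate_meta(pd.read_csv(meta_path, sep="\t"))
    wide = (
        long.pivot_table(index="protein", columns="experiment_id", values="count",
                         aggfunc="sum", fill_value=0)
        .astype(int)
    )
    for exp_id in meta["experiment_id"]:
        if exp_id not in wide.columns:
            wide[exp_id] = 0
    return CountMatrix(wide, meta)


# --- candidates and ground truth ---------------------------------------

def write_candidates_tsv(candidates: pd.DataFrame, path: str | Path) -> None:
    candidates.loc[:, list(CANDIDATE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"bait": str, "prey": str, "condition": str})
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    df["summed_count"] = df["summed_count"].astype(int)
    return df


def write_ground_truth_tsv(truth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


# --- reference interaction sets ----------------------------------------

def read_reference_tsv(path: str | Path, version_label: str = "") -> ReferenceInteractionSet:
    """Two-column TSV of accession pairs (header optional: protein_a/protein_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["protein_a", "protein_b"]:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    pairs = [(a, b) for a, b in df.iloc[:, :2].itertuples(index=False)]
    return ReferenceInteractionSet(pairs, version_label=version_label or str(path))


def write_reference_tsv(reference: ReferenceInteractionSet, path: str | Path) -> None:
    pd.DataFrame(reference.pairs(), columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_biogrid_tab(
    path: str | Path,
    column_a: str = "Official Symbol Interactor A",
    column_b: str = "Official Symbol Interactor B",
    version_label: str = "",
) -> ReferenceInteractionSet:
    """Read a BioGRID tab-delimited subset; identifier columns configurable."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (column_a, column_b):
        if col not in df.columns:
            raise ValueError(f"BioGRID table missing column {col!r}")
    pairs = list(df[[column_a, column_b]].itertuples(index=False, name=None))
    return ReferenceInteractionSet(pairs, version_label=version_label or str(path))


# --- network exports ----------------------------------------------------

def _edge_records(net: nx.DiGraph) -> pd.DataFrame:
    rows = []
    for u, v, d in net.edges(data=True):
        rows.append({"bait": u, "prey": v, **d})
    df = pd.DataFrame(rows)
    lead = ["bait", "prey"]
    return df.loc[:, lead + [c for c in df.columns if c not in lead]].sort_values(
        lead, ignore_index=True
    )


def _node_records(net: nx.DiGraph) -> pd.DataFrame:
    rows = [{"accession": n, **d} for n, d in net.nodes(data=True)]
    df = pd.DataFrame(rows)
    lead = ["accession"]
    return df.loc[:, lead + [c for c in df.columns if c not in lead]].sort_values(
        lead, ignore_index=True
    )


def write_sif(net: nx.DiGraph, path: str | Path) -> None:
    """Topology-only export: one ``BAIT interacts-with PREY`` line per edge."""
    if net.number_of_edges() == 0:
        raise ValueError("refusing to write an empty network as SIF")
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{SIF_RELATION}\t{v}\n")


def read_sif(path: str | Path) -> nx.DiGraph:
    net = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] != SIF_RELATION:
                raise ValueError(f"malformed SIF line: {line!r}")
            net.add_edge(parts[0], parts[2])
    return net


def write_graphml(net: nx.DiGraph, path: str | Path) -> None:
    if net.number_of_edges() == 0 and net.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network as GraphML")
    out = net.copy()
    out.graph["conditions"] = "|".join(net.graph.get("conditions", ()))
    nx.write_graphml(out, path)


def read_graphml(path: str | Path) -> nx.DiGraph:
    net = nx.read_graphml(path)
    net = nx.DiGraph(net)
    conditions = net.graph.get("conditions", "")
    net.graph["conditions"] = conditions.split("|") if conditions else []
    return net


def write_node_table(net: nx.DiGraph, path: str | Path) -> None:
    _node_records(net).to_csv(path, sep="\t", index=False)


def write_edge_table(net: nx.DiGraph, path: str | Path) -> None:
    _edge_records(net).to_csv(path, sep="\t", index=False)


def read_network_tables(node_path: str | Path, edge_path: str | Path) -> nx.DiGraph:
    """Rebuild a network from its node and edge attribute tables."""
    nodes = pd.read_csv(node_path, sep="\t", dtype={"accession": str})
    edges = pd.read_csv(edge_path, sep="\t", dtype={"bait": str, "prey": str})
    net = nx.DiGraph()
    for row in nodes.to_dict(orient="records"):
        acc = row.pop("accession")
        net.add_node(acc, **row)
    for row in edges.to_dict(orient="records"):
        u, v = row.pop("bait"), row.pop("prey")
        net.add_edge(u, v, **row)
    conds = [c.removeprefix("strength_") for c in edges.columns if c.startswith("strength_")]
    net.graph["conditions"] = conds
    if "dynamics" in edges.columns:
        net.graph["dynamics_classified"] = True
    if "known" in edges.columns:
        net.graph["known_annotated"] = True
    return net


def write_mitab25(net: nx.DiGraph, path: str | Path, db: str = "uniprotkb") -> None:
    """PSI-MITAB 2.5: 15 tab-separated columns per interaction.

    Identifier columns carry ``db:accession``; the interaction-detection
    method is fixed to a protein complementation assay term; the confidence
    column carries per-condition summed spectral counts and strengths.
    Unpopulated columns hold ``-``.
    """
    conditions = net.graph.get("conditions", ("untreated", "TNF"))
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            d = net.edges[u, v]
            conf_parts = []
            for cond in conditions:
                count = d.get(f"count_{cond}", 0)
                strength = d.get(f"strength_{cond}", "absent")
                conf_parts.append(f"spectral-count-{cond}:{count}({strength})")
            cols = [
                f"{db}:{u}",                      # 1 id A
                f"{db}:{v}",                      # 2 id B
                "-", "-", "-", "-",               # 3-6 alt ids / aliases
                'psi-mi:"MI:0090"(protein complementation assay)',  # 7 detection
                "-",                              # 8 first author
                "-",                              # 9 publication id
                "-", "-",                         # 10-11 taxids
                'psi-mi:"MI:0914"(association)',  # 12 interaction type
                "-",                              # 13 source db
                "-",                              # 14 interaction id
                "|".join(conf_parts),             # 15 confidence
            ]
            assert len(cols) == MITAB_COLUMNS
            fh.write("\t".join(cols) + "\n")


def read_mitab25(path: str | Path) -> pd.DataFrame:
    """Parse a MITAB 2.5 file back into a table; enforces 15 columns/line."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != MITAB_COLUMNS:
                raise ValueError(f"MITAB line {i} has {len(parts)} columns, expected {MITAB_COLUMNS}")
            rows.append(parts)
    return pd.DataFrame(rows, columns=[f"c{i}" for i in range(1, MITAB_COLUMNS + 1)])


def export_network(net: nx.DiGraph, fmt: str, path: str | Path) -> Path:
    """Dispatch on format token: SIF, GraphML, MITAB25, node_table, edge_table."""
    path = Path(path)
    if fmt == "SIF":
        write_sif(net, path)
    elif fmt == "GraphML":
        write_graphml(net, path)
    elif fmt == "MITAB25":
        write_mitab25(net, path)
    elif fmt == "node_table":
        write_node_table(net, path)
    elif fmt == "edge_table":
        write_edge_table(net, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}")
    return path
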