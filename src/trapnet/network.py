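"""Bait-prey interaction networks: extensive and lean.

The extensive network holds one directed bait -> prey edge per surviving
candidate pair, carrying per-condition summed counts and strength classes.
Edges are then labeled by their dynamics under TNF stimulation (appears /
disappears / independent), flagged known or novel against a reference
interaction set, and pruned into the lean network: strong edges only,
self-loops removed, preys kept when they reach degree >= 3 in the strong
graph or are rescued as known partners of a bait.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Tuple

import networkx as nx
import pandas as pd

from .filters import (
    STRENGTH_ABSENT,
    STRENGTH_STRONG,
)

logger = logging.getLogger("trapnet")

DYNAMICS_APPEARS = "appears"
DYNAMICS_DISAPPEARS = "disappears"
DYNAMICS_INDEPENDENT = "independent"

NODE_CLASS_UNANNOTATED = "unannotated"

LEAN_ORDER_SELFLOOP_FIRST = "selfloop_first"  # remove self-loops, then compute degrees
LEAN_ORDER_DEGREE_FIRST = "degree_first"      # degrees include self-loops

DEGREE_GRAPH_STRONG = "strong"
DEGREE_GRAPH_EXTENSIVE = "extensive"


class ReferenceInteractionSet:
    """Unordered known protein pairs (BioGRID-style reference).

    Pairs are stored symmetrically: ``(a, b)`` is a member iff ``(b, a)``
    is. Self-pairs ``(a, a)`` are supported.
    """

    def __init__(self, pairs: Iterable[Tuple[str, str]], version_label: str = ""):
        self._pairs = frozenset(frozenset((str(a), str(b))) for a, b in pairs)
        self.version_label = version_label

    def contains(self, a: str, b: str) -> bool:
        return frozenset((str(a), str(b))) in self._pairs

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        a, b = pair
        return self.contains(a, b)

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReferenceInteractionSet) and self._pairs == other._pairs

    def pairs(self) -> list[tuple[str, str]]:
        """Canonical (sorted within pair) list of the stored pairs."""
        out = []
        for fs in self._pairs:
            members = sorted(fs)
            if len(members) == 1:
                out.append((members[0], members[0]))
            else:
                out.append((members[0], members[1]))
        return sorted(out)


@dataclass
class LeanReport:
    """Bookkeeping of the lean-network derivation."""

    n_nodes: int
    n_edges: int
    rescued_nodes: int
    rescued_edges: int
    self_loops_removed: int
    known_self_loops_removed: int


def _strength_key(condition: str) -> str:
    return f"strength_{condition}"


def _present_key(condition: str) -> str:
    return f"present_{condition}"


def _count_key(condition: str) -> str:
    return f"count_{condition}"


def build_extensive(
    candidates: pd.DataFrame,
    conditions: tuple[str, str] = ("untreated", "TNF"),
) -> nx.DiGraph:
    """One directed bait -> prey edge per candidate pair.

    Per-condition summed counts and strengths become edge attributes
    (``absent`` / count 0 for a condition without a candidate); the node set
    is baits plus preys, with ``is_bait`` marking source nodes. Baits
    identified as preys of other baits stay single nodes with incoming
    edges.
    """
    net = nx.DiGraph(conditions=list(conditions))
    if candidates.empty:
        return net
    unknown = set(candidates["condition"]) - set(conditions)
    if unknown:
        raise ValueError(f"candidate conditions not in {conditions}: {sorted(unknown)}")
    baits = set(candidates["bait"])
    for node in baits | set(candidates["prey"]):
        net.add_node(node, is_bait=node in baits, node_class=NODE_CLASS_UNANNOTATED)
    for (bait, prey), grp in candidates.groupby(["bait", "prey"], sort=True):
        attrs: dict = {}
        for cond in conditions:
            row = grp.loc[grp["condition"] == cond]
            if len(row):
                count = int(row["summed_count"].iloc[0])
                strength = str(row["strength"].iloc[0])
            else:
                count, strength = 0, STRENGTH_ABSENT
            attrs[_count_key(cond)] = count
            attrs[_strength_key(cond)] = strength
            attrs[_present_key(cond)] = strength != STRENGTH_ABSENT
        net.add_edge(bait, prey, **attrs)
    logger.info(
        "build_extensive: %d nodes, %d edges", net.number_of_nodes(), net.number_of_edges()
    )
    return net


def classify_dynamics(net: nx.DiGraph) -> nx.DiGraph:
    """Label every edge appears / disappears / independent.

    ``appears``: present under stimulation only; ``disappears``: present
    untreated only; ``independent``: present in both. The three labels
    partition the edges (an edge absent in both conditions cannot exist).
    """
    base, stim = net.graph.get("conditions", ("untreated", "TNF"))
    for u, v, d in net.edges(data=True):
        p_base, p_stim = d[_present_key(base)], d[_present_key(stim)]
        if p_base and p_stim:
            d["dynamics"] = DYNAMICS_INDEPENDENT
        elif p_stim:
            d["dynamics"] = DYNAMICS_APPEARS
        elif p_base:
            d["dynamics"] = DYNAMICS_DISAPPEARS
        else:
            raise ValueError(f"edge {u}->{v} present in neither condition")
    net.graph["dynamics_classified"] = True
    return net


def annotate_known(net: nx.DiGraph, reference: ReferenceInteractionSet) -> nx.DiGraph:
    """Flag each edge known/novel by unordered membership in the reference."""
    n_known = 0
    for u, v, d in net.edges(data=True):
        d["known"] = reference.contains(u, v)
        n_known += d["known"]
    net.graph["known_annotated"] = True
    net.graph["reference_version"] = reference.version_label
    logger.info(
        "annotate_known: %d known, %d novel edges",
        n_known, net.number_of_edges() - n_known,
    )
    return net


def overlap_counts(net: nx.DiGraph) -> tuple[int, int]:
    """(known, novel) edge counts of an annotated network."""
    known = sum(1 for _, _, d in net.edges(data=True) if d.get("known"))
    return known, net.number_of_edges() - known


def dynamics_counts(net: nx.DiGraph) -> dict[str, int]:
    out = {DYNAMICS_INDEPENDENT: 0, DYNAMICS_APPEARS: 0, DYNAMICS_DISAPPEARS: 0}
    for _, _, d in net.edges(data=True):
        out[d["dynamics"]] += 1
    return out


def _is_strong(d: dict, conditions: Iterable[str]) -> bool:
    return any(d[_strength_key(c)] == STRENGTH_STRONG for c in conditions)


def build_lean(
    net: nx.DiGraph,
    degree_threshold: int = 3,
    order: str = LEAN_ORDER_SELFLOOP_FIRST,
    degree_graph: str = DEGREE_GRAPH_STRONG,
) -> tuple[nx.DiGraph, LeanReport]:
    """Visualization-grade subgraph of the extensive network.

    Fixed rule order (default): (1) keep edges strong in >= 1 condition;
    (2) remove bait self-loops; (3) compute each non-bait prey's degree in
    the resulting strong graph; (4) retain a prey iff its degree reaches
    ``degree_threshold`` or it has a known strong edge (the rescue that
    prevents false negatives); bait nodes survive whenever they keep an
    edge. ``order='degree_first'`` computes degrees before self-loop
    removal and ``degree_graph='extensive'`` counts degrees in the full
    extensive graph instead — switches for reproduction attempts, since
    the rule order is not uniquely determined by the published counts.

    Returns the lean network and a report with rescued-node/edge and
    removed-self-loop counts.
    """
    if not net.graph.get("dynamics_classified"):
        raise ValueError("classify_dynamics must run before build_lean")
    if not net.graph.get("known_annotated"):
        raise ValueError("annotate_known must run before build_lean")
    if order not in (LEAN_ORDER_SELFLOOP_FIRST, LEAN_ORDER_DEGREE_FIRST):
        raise ValueError(f"unknown lean order mode: {order!r}")
    if degree_graph not in (DEGREE_GRAPH_STRONG, DEGREE_GRAPH_EXTENSIVE):
        raise ValueError(f"unknown degree_graph mode: {degree_graph!r}")
    conditions = net.graph.get("conditions", ("untreated", "TNF"))

    strong_edges = [(u, v) for u, v, d in net.edges(data=True) if _is_strong(d, conditions)]
    strong = net.edge_subgraph(strong_edges).copy() if strong_edges else nx.DiGraph(**net.graph)

    self_loops = [(u, v) for u, v in strong.edges if u == v]
    known_self_loops = sum(1 for u, v in self_loops if strong.edges[u, v].get("known"))

    if degree_graph == DEGREE_GRAPH_STRONG:
        degree_source = strong
    else:
        degree_source = net
    if order == LEAN_ORDER_DEGREE_FIRST:
        degrees = dict(degree_source.degree())
    strong.remove_edges_from(self_loops)
    if order == LEAN_ORDER_SELFLOOP_FIRST:
        if degree_graph == DEGREE_GRAPH_EXTENSIVE:
            pruned = degree_source.copy()
            pruned.remove_edges_from([(u, v) for u, v in pruned.edges if u == v])
            degrees = dict(pruned.degree())
        else:
            degrees = dict(strong.degree())

    retained: set[str] = set()
    rescued: set[str] = set()
    for node, attrs in strong.nodes(data=True):
        if attrs.get("is_bait"):
            retained.add(node)  # baits exempt; isolated baits dropped below
            continue
        deg = degrees.get(node, 0)
        has_known = any(
            strong.edges[u, v].get("known")
            for u, v in itertools.chain(strong.in_edges(node), strong.out_edges(node))
        )
        if deg >= degree_threshold:
            retained.add(node)
        elif has_known:
            retained.add(node)
            rescued.add(node)

    lean = strong.subgraph(retained).copy()
    # a rescued prey contributes only its known edges; rescue never
    # introduces a pair absent from the reference set
    lean.remove_edges_from(
        [(u, v) for u, v, d in lean.edges(data=True)
         if (u in rescued or v in rescued) and not d.get("known")]
    )
    lean.remove_nodes_from([n for n, deg in list(lean.degree()) if deg == 0])
    rescued_edges = sum(1 for u, v in lean.edges if u in rescued or v in rescued)
    report = LeanReport(
        n_nodes=lean.number_of_nodes(),
        n_edges=lean.number_of_edges(),
        rescued_nodes=len(rescued & set(lean.nodes)),
        rescued_edges=rescued_edges,
        self_loops_removed=len(self_loops),
        known_self_loops_removed=known_self_loops,
    )
    logger.info(
        "build_lean: %d nodes, %d edges (%d proteins / %d interactions rescued; "
        "%d self-loops removed)",
        report.n_nodes, report.n_edges, report.rescued_nodes, report.rescued_edges,
        report.self_loops_removed,
    )
    return lean, report
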