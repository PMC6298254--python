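"""Independent brute-force reimplementations used as test oracles.

Deliberately written with plain loops and set operations, independent of
the vectorised/graph-library code paths they check.
"""

from collections import Counter


def brute_force_best_psm(psms):
    """Per-spectrum max by exhaustive scan; target/decoy ties -> decoy."""
    by_spectrum = {}
    for rec in psms:
        by_spectrum.setdefault(rec.spectrum_id, []).append(rec)
    out = []
    for sid in sorted(by_spectrum):
        group = by_spectrum[sid]
        top_score = max(r.score for r in group)
        top = [r for r in group if r.score == top_score]
        decoys = [r for r in top if r.is_decoy]
        out.append(decoys[0] if decoys else top[0])
    return out


def brute_force_cascade(matrix, mode="per_condition"):
    """Control filter + replicate summation + one-hit removal by hand.

    Returns the surviving candidate set as
    {(bait, prey, condition, summed_count, strength)}.
    """
    counts, meta = matrix.counts, matrix.meta
    controls = [
        e for e, r in zip(meta["experiment_id"], meta["role"])
        if r == "control_experiment"
    ]
    assert controls, "cascade oracle needs control columns"
    background = {
        p for p in counts.index
        if any(int(counts.at[p, c]) > 0 for c in controls)
    }
    bait_meta = meta[meta["role"] == "bait_experiment"]
    sums = {}
    for p in counts.index:
        if p in background:
            continue
        for bait in sorted(set(bait_meta["bait"])):
            for cond in sorted(set(bait_meta["condition"])):
                cols = bait_meta[(bait_meta["bait"] == bait) & (bait_meta["condition"] == cond)]
                s = sum(int(counts.at[p, c]) for c in cols["experiment_id"])
                if s > 0:
                    sums[(bait, p, cond)] = s
    result = set()
    for (bait, p, cond), s in sums.items():
        same_pair = [s2 for (b2, p2, _), s2 in sums.items() if b2 == bait and p2 == p]
        keep = max(same_pair) >= 2 if mode == "per_condition" else sum(same_pair) >= 2
        if keep:
            strength = "one_hit" if s == 1 else ("weak" if s == 2 else "strong")
            result.add((bait, p, cond, s, strength))
    return result


def brute_force_lean(net, threshold=3, order="selfloop_first", degree_graph="strong"):
    """Exhaustive application of the lean-network rules; returns the edge set."""
    conds = net.graph["conditions"]
    strong = {
        (u, v) for u, v, d in net.edges(data=True)
        if any(d[f"strength_{c}"] == "strong" for c in conds)
    }
    known = {(u, v) for u, v, d in net.edges(data=True) if d.get("known")}
    loops = {(u, v) for u, v in strong if u == v}
    if degree_graph == "strong":
        base_edges = strong
    else:
        base_edges = set(net.edges)
    if order == "selfloop_first":
        base_edges = {(u, v) for u, v in base_edges if u != v}
    degree = Counter()
    for u, v in base_edges:
        degree[u] += 1
        degree[v] += 1  # a self-loop contributes 2, matching DiGraph.degree
    surviving = strong - loops
    baits = {n for n, d in net.nodes(data=True) if d.get("is_bait")}
    preys = {n for e in surviving for n in e} - baits
    retained, rescued = set(), set()
    for p in preys:
        has_known = any((u, v) in known for (u, v) in surviving if p in (u, v))
        if degree.get(p, 0) >= threshold:
            retained.add(p)
        elif has_known:
            retained.add(p)
            rescued.add(p)
    edges = set()
    for u, v in surviving:
        if not all(n in baits or n in retained for n in (u, v)):
            continue
        if (u in rescued or v in rescued) and (u, v) not in known:
            continue
        edges.add((u, v))
    return edges
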