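"""Structural controllability of the molecule-level signaling graph.

Following the maximum-matching framework for linear structural
controllability, a directed network with N nodes and a maximum matching M
(in the bipartite out-copy/in-copy representation, one left/right copy per
node, an edge (u_out, v_in) per link u→v) needs

    N_D = max(N − |M|, 1)

independently controlled *driver nodes* — exactly the nodes left unmatched
on their in-copy.  f_D = N_D / N measures how distributed control is.  A
node is *critical* when its removal strictly increases f_D: losing it
disconnects regulators from targets in the matching structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import networkx as nx
import pandas as pd

from .map_model import MolecularMap


@dataclass
class ControllabilityResult:
    matching: set[tuple[str, str]]
    drivers: set[str]
    n_drivers: int
    f_d: float
    n_nodes: int
    critical: dict[str, bool] = field(default_factory=dict)


def _matching_bigraph(g: nx.DiGraph) -> tuple[nx.Graph, list]:
    b = nx.Graph()
    # deterministic insertion order fixes the Hopcroft-Karp tie-breaking
    nodes = sorted(g.nodes)
    tops = [("out", u) for u in nodes]
    b.add_nodes_from(tops, bipartite=0)
    b.add_nodes_from((("in", v) for v in nodes), bipartite=1)
    for u in nodes:
        for v in sorted(g.successors(u)):
            b.add_edge(("out", u), ("in", v))  # self-loops allowed (u == v)
    return b, tops


def max_matching(g: nx.DiGraph) -> set[tuple[str, str]]:
    """Maximum-cardinality matching of the out-copy/in-copy bipartite graph,
    returned as a set of directed edges (u, v) of ``g``."""
    b, tops = _matching_bigraph(g)
    hk = nx.bipartite.hopcroft_karp_matching(b, top_nodes=tops)
    return {
        (u[1], v[1]) for u, v in hk.items() if u[0] == "out"
    }


def has_augmenting_path(g: nx.DiGraph, matching: set[tuple[str, str]]) -> bool:
    """True iff the given matching admits an augmenting path (i.e., is not
    maximum).  Direct check used by the maximality property tests."""
    b, tops = _matching_bigraph(g)
    matched_edges = {(("out", u), ("in", v)) for u, v in matching}
    matched_left = {e[0] for e in matched_edges}
    matched_right = {e[1] for e in matched_edges}
    # BFS over alternating paths from every free left node
    frontier = [u for u in tops if u not in matched_left]
    seen = set(frontier)
    while frontier:
        nxt = []
        for u in frontier:
            for v in b.neighbors(u):
                if v not in matched_right:
                    return True
                # follow the matched edge back to the left side
                (mu,) = [x for x, y in matched_edges if y == v]
                if mu not in seen:
                    seen.add(mu)
                    nxt.append(mu)
        frontier = nxt
    return False


def drivers_and_fd(g: nx.DiGraph) -> ControllabilityResult:
    """Driver nodes, N_D and f_D.  With a perfect matching a single
    arbitrary node (lowest id) is the designated driver, so N_D ≥ 1."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph has no controllability result")
    m = max_matching(g)
    matched_in = {v for _, v in m}
    drivers = set(g.nodes) - matched_in
    n_d = max(n - len(m), 1)
    if not drivers:
        drivers = {min(g.nodes)}
    assert len(drivers) == n_d
    return ControllabilityResult(
        matching=m, drivers=drivers, n_drivers=n_d, f_d=n_d / n, n_nodes=n
    )


def critical_nodes(g: nx.DiGraph) -> dict[str, bool]:
    """Per-node criticality: f_D recomputed from scratch on g − v; critical
    iff it strictly exceeds f_D(g)."""
    if g.number_of_nodes() < 2:
        raise ValueError("criticality needs at least 2 nodes")
    base = drivers_and_fd(g).f_d
    out: dict[str, bool] = {}
    for v in g.nodes:
        h = g.copy()
        h.remove_node(v)
        out[v] = drivers_and_fd(h).f_d > base
    return out


def analyze(g: nx.DiGraph) -> ControllabilityResult:
    """Full controllability analysis: matching, drivers, f_D and critical
    flags."""
    res = drivers_and_fd(g)
    if g.number_of_nodes() >= 2:
        res.critical = critical_nodes(g)
    return res


def criticality_summaries(
    result: ControllabilityResult,
    scores,
    m: MolecularMap,
    merge: dict[str, str] | None = None,
    threshold: float = 0.2,
) -> dict[str, float]:
    """Fractions of critical nodes among high- vs low-bow-tie-score nodes
    (b > threshold, strict) and among complexes vs monomeric proteins.

    ``scores`` is a :class:`~stressnet.bowtie.BowtieScores`; ``merge`` maps
    species id → merged-molecule key (identity when omitted).  Undefined
    fractions (empty group) come back as NaN.  The four fractions are the
    per-map pairs consumed by the paired comparisons across maps.
    """
    merge = merge or {}
    by_id = m.species_by_id
    b = scores.table["b"]
    groups: dict[str, list[bool]] = {
        "high_b": [], "low_b": [], "complex": [], "protein": []
    }
    for v, crit in result.critical.items():
        sp = by_id.get(v)
        if sp is None or sp.entity_class not in ("protein", "complex"):
            continue
        key = merge.get(v, v)
        bv = float(b.get(key, 0.0))
        groups["high_b" if bv > threshold else "low_b"].append(crit)
        groups[sp.entity_class].append(crit)

    def frac(xs: list[bool]) -> float:
        return sum(xs) / len(xs) if xs else math.nan

    return {
        "critical_fraction_high_b": frac(groups["high_b"]),
        "critical_fraction_low_b": frac(groups["low_b"]),
        "critical_fraction_complexes": frac(groups["complex"]),
        "critical_fraction_proteins": frac(groups["protein"]),
        "n_high_b": len(groups["high_b"]),
        "n_low_b": len(groups["low_b"]),
        "n_complexes": len(groups["complex"]),
        "n_proteins": len(groups["protein"]),
    }


def write_controllability_tsv(
    result: ControllabilityResult, m: MolecularMap | None, path
) -> None:
    classes = {s.id: s.entity_class for s in m.species} if m else {}
    rows = [
        dict(
            node_id=v,
            is_driver=v in result.drivers,
            is_critical=result.critical.get(v, False),
            entity_class=classes.get(v, ""),
        )
        for v in sorted(
            set(result.critical) | result.drivers | {u for e in result.matching for u in e}
        )
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
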