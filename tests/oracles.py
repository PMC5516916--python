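"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the algorithm used by the implementation:
simple-path tallies come from networkx's recursive path enumerator,
betweenness from explicit all-shortest-path counting, maximum matchings from
exhaustive branch-and-bound over edge subsets, and colored subgraph classes
from combinations() plus a full k!-permutation canonical form.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx


# ---------------------------------------------------------------------------
# paths / bow-tie

def brute_path_tally(g: nx.DiGraph, sources, targets, max_len):
    """(total, per-node containment, per-target counts) via
    nx.all_simple_paths (cutoff counts edges)."""
    total = 0
    contain: Counter = Counter()
    per_target: Counter = Counter()
    for s in sources:
        for t in targets:
            if s == t or s not in g or t not in g:
                continue
            for path in nx.all_simple_paths(g, s, t, cutoff=max_len):
                total += 1
                per_target[t] += 1
                contain.update(path)
    return total, contain, per_target


def brute_bowtie(g, sources, targets, max_len=30):
    total, contain, _ = brute_path_tally(g, sources, targets, max_len)
    if total == 0:
        return {n: 0.0 for n in g}, 0
    return {n: contain.get(n, 0) / total for n in g}, total


def brute_weighted_bowtie(g, sources, targets, weights, max_len=30):
    wtotal = 0.0
    contain: Counter = Counter()
    for s in sources:
        for t in targets:
            if s == t:
                continue
            w = weights.get(t, 0.0)
            for path in nx.all_simple_paths(g, s, t, cutoff=max_len):
                wtotal += w
                for n in path:
                    contain[n] += w
    if wtotal == 0:
        return {n: 0.0 for n in g}
    return {n: contain.get(n, 0.0) / wtotal for n in g}


def brute_betweenness(g: nx.DiGraph):
    """Endpoint-excluding betweenness by explicit shortest-path counting,
    normalized by (N-1)(N-2)."""
    nodes = list(g)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2)
    return {v: bc[v] / norm for v in nodes} if norm else bc


# ---------------------------------------------------------------------------
# matching

def brute_max_matching_size(g: nx.DiGraph) -> int:
    """Maximum matching cardinality of the out-copy/in-copy bipartite graph
    by branch-and-bound over the directed edge list."""
    edges = sorted(g.edges())
    best = 0

    def rec(i, used_tail, used_head, size):
        nonlocal best
        if size + (len(edges) - i) <= best:
            return
        if i == len(edges):
            best = max(best, size)
            return
        u, v = edges[i]
        if u not in used_tail and v not in used_head:
            rec(i + 1, used_tail | {u}, used_head | {v}, size + 1)
        rec(i + 1, used_tail, used_head, size)

    rec(0, frozenset(), frozenset(), 0)
    return best


def brute_fd(g: nx.DiGraph) -> float:
    n = g.number_of_nodes()
    return max(n - brute_max_matching_size(g), 1) / n


# ---------------------------------------------------------------------------
# colored subgraphs

def graph_codes(g):
    """(kind map, pairwise color-bit codes) of a colored bipartite graph."""
    from stressnet.motifs import COLOR_BIT

    kind = {u: ("m" if g.nodes[u]["kind"] == "molecule" else "r") for u in g}
    code = {}
    for u, v, color in g.edges(keys=True):
        code[(u, v)] = code.get((u, v), 0) | COLOR_BIT[color]
    return kind, code


def brute_canonical(nodes, kind, code) -> tuple:
    """Minimal encoding over *all* k! permutations (the implementation only
    searches permutations within invariant groups)."""
    k = len(nodes)
    best = None
    for perm in itertools.permutations(nodes):
        enc = (
            tuple(kind[u] for u in perm),
            tuple(code.get((perm[a], perm[b]), 0)
                  for a in range(k) for b in range(k) if a != b),
        )
        if best is None or enc < best:
            best = enc
    return best


def brute_colored_census(g, k) -> Counter:
    """Connected induced k-subgraph class counts via combinations()."""
    kind, code = graph_codes(g)
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    und.add_edges_from((u, v) for u, v in g.edges())
    counts: Counter = Counter()
    for sub in itertools.combinations(sorted(g.nodes), k):
        if not nx.is_connected(und.subgraph(sub)):
            continue
        counts[brute_canonical(sub, kind, code)] += 1
    return counts


def brute_colored_isomorphic(g1, g2) -> bool:
    """Permutation search honoring node kinds and edge colors."""
    if g1.number_of_nodes() != g2.number_of_nodes():
        return False
    k1, c1 = graph_codes(g1)
    k2, c2 = graph_codes(g2)
    n1, n2 = sorted(g1.nodes), sorted(g2.nodes)
    for perm in itertools.permutations(n2):
        mapping = dict(zip(n1, perm))
        if any(k1[u] != k2[mapping[u]] for u in n1):
            continue
        if all(
            c1.get((u, v), 0) == c2.get((mapping[u], mapping[v]), 0)
            for u in n1 for v in n1 if u != v
        ):
            return True
    return False


def random_colored_bipartite(rng, n_mol, n_rxn, p=0.3):
    """Random colored bipartite process graph for oracle comparisons."""
    g = nx.MultiDiGraph()
    mols = [f"m{i}" for i in range(n_mol)]
    rxns = [f"r{i}" for i in range(n_rxn)]
    g.add_nodes_from(mols, kind="molecule")
    g.add_nodes_from(rxns, kind="reaction")
    for mm in mols:
        for rr in rxns:
            if rng.random() < p:
                g.add_edge(mm, rr, key="reactant", color="reactant")
            if rng.random() < p:
                g.add_edge(rr, mm, key="product", color="product")
            if rng.random() < p / 2:
                g.add_edge(mm, rr, key="modifier", color="modifier")
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    return g
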