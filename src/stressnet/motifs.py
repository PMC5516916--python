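"""Colored network-motif discovery on bipartite process graphs.

Connected induced k-node subgraphs (default k=6) of the molecule/reaction
bipartite graph are enumerated exhaustively (ESU over the undirected
skeleton), aggregated into isomorphism classes that respect node kinds and
the three edge colors (reactant / product / modifier), and scored against a
color-preserving edge-switch null model: a class is a motif when its real
count is at least ``min_count`` (default 5), its empirical one-sided p is
below 0.05 and its z-score against the null exceeds 2.

Signatures are permutation-invariant string keys: ``"mmrrmm:<k*k codes>"``
where each code is the OR of color bits (reactant=1, product=2, modifier=4)
on the ordered node pair, under the lexicographically minimal admissible
node ordering.
"""

from __future__ import annotations

import itertools
import math
import random
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd

COLOR_BIT = {"reactant": 1, "product": 2, "modifier": 4}
BIT_COLOR = {1: "reactant", 2: "product", 4: "modifier"}

SIGNIFICANCE = dict(p_max=0.05, z_min=2.0, min_count=5)


# ---------------------------------------------------------------------------
# internal indexed form

def _index_graph(g: nx.MultiDiGraph):
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    kind = ["m" if g.nodes[u]["kind"] == "molecule" else "r" for u in nodes]
    code: dict[tuple[int, int], int] = {}
    nbrs: list[set[int]] = [set() for _ in nodes]
    for u, v, color in g.edges(keys=True):
        iu, iv = idx[u], idx[v]
        code[(iu, iv)] = code.get((iu, iv), 0) | COLOR_BIT[color]
        nbrs[iu].add(iv)
        nbrs[iv].add(iu)
    return nodes, kind, code, nbrs


# ---------------------------------------------------------------------------
# ESU enumeration of connected induced k-subgraphs

def _esu(n: int, nbrs: list[set[int]], k: int):
    """Yield each connected induced k-node subset exactly once."""
    if k == 1:
        for v in range(n):
            yield (v,)
        return
    for v in range(n):
        ext = {u for u in nbrs[v] if u > v}
        if ext:
            yield from _extend((v,), ext, v, nbrs, k, {v} | nbrs[v])


def _extend(sub, ext, v, nbrs, k, closed):
    if len(sub) + 1 == k:
        for w in ext:
            yield sub + (w,)
        return
    ext = set(ext)
    while ext:
        w = ext.pop()
        new_ext = ext | {u for u in nbrs[w] if u > v and u not in closed}
        yield from _extend(sub + (w,), new_ext, v, nbrs, k, closed | {w} | nbrs[w])


# ---------------------------------------------------------------------------
# canonical colored signatures

def _signature_local(kinds: tuple[str, ...], local: list[list[int]]) -> str:
    """Canonical string for a k-node colored subgraph given as a local
    adjacency code matrix (codes 0..7) and per-node kinds."""
    k = len(kinds)
    # invariant refinement: kind + sorted out/in code multisets, then one
    # round including neighbor invariants, to cut the permutation search
    inv = []
    for a in range(k):
        row = tuple(sorted(local[a][b] for b in range(k) if b != a))
        col = tuple(sorted(local[b][a] for b in range(k) if b != a))
        inv.append((kinds[a], row, col))
    inv2 = []
    for a in range(k):
        around = tuple(sorted(
            (local[a][b], local[b][a], inv[b]) for b in range(k) if b != a
        ))
        inv2.append((inv[a], around))
    order = sorted(range(k), key=lambda a: repr(inv2[a]))
    # permutations only within equal-invariant groups
    groups: list[list[int]] = []
    for a in order:
        if groups and inv2[groups[-1][-1]] == inv2[a]:
            groups[-1].append(a)
        else:
            groups.append([a])
    best: tuple | None = None
    for perm_parts in itertools.product(
        *(itertools.permutations(grp) for grp in groups)
    ):
        perm = [a for part in perm_parts for a in part]
        enc = tuple(
            local[perm[a]][perm[b]] for a in range(k) for b in range(k) if a != b
        )
        if best is None or enc < best:
            best = enc
    kinds_sorted = "".join(kinds[a] for a in order)  # equal for all perms in a group
    return kinds_sorted + ":" + "".join(map(str, best))


def canonical_signature(g: nx.MultiDiGraph) -> str:
    """Canonical signature of a whole (small) colored bipartite graph."""
    nodes, kind, code, _ = _index_graph(g)
    k = len(nodes)
    local = [
        [code.get((a, b), 0) if a != b else 0 for b in range(k)] for a in range(k)
    ]
    return _signature_local(tuple(kind), local)


def decode_signature(sig: str) -> tuple[list[str], list[list[list[str]]]]:
    """Decode a signature into (node kinds, k×k edge-color-list matrix)."""
    kinds_s, codes_s = sig.split(":")
    k = len(kinds_s)
    kinds = ["molecule" if c == "m" else "reaction" for c in kinds_s]
    mat: list[list[list[str]]] = [[[] for _ in range(k)] for _ in range(k)]
    it = iter(codes_s)
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            c = int(next(it))
            mat[a][b] = [BIT_COLOR[bit] for bit in (1, 2, 4) if c & bit]
    return kinds, mat


def enumerate_colored_subgraphs(g: nx.MultiDiGraph, k: int = 6) -> Counter:
    """Count every weakly connected induced k-node subgraph by signature."""
    if not (1 <= k <= 8):
        raise ValueError("k must be between 1 and 8")
    nodes, kind, code, nbrs = _index_graph(g)
    counts: Counter = Counter()
    if k > len(nodes):
        return counts
    cache: dict[tuple, str] = {}
    for sub in _esu(len(nodes), nbrs, k):
        local = [
            [code.get((ia, ib), 0) if ia != ib else 0 for ib in sub] for ia in sub
        ]
        kinds = tuple(kind[ia] for ia in sub)
        # cheap normal form as memo key: rows/kinds under an invariant sort
        order = sorted(
            range(k),
            key=lambda a: (kinds[a], sorted(local[a]), sorted(r[a] for r in local)),
        )
        key = (
            tuple(kinds[a] for a in order),
            tuple(local[a][b] for a in order for b in order),
        )
        sig = cache.get(key)
        if sig is None:
            sig = _signature_local(kinds, local)
            cache[key] = sig
        counts[sig] += 1
    return counts


# ---------------------------------------------------------------------------
# null model

def switch_randomize(
    g: nx.MultiDiGraph, seed: int, n_switches: int | None = None
) -> nx.MultiDiGraph:
    """Degree-preserving randomization by same-color head swaps.

    Two edges of one color exchange their head endpoints; a swap is rejected
    when it would duplicate an existing (source, target, color) edge.  This
    preserves every node's per-color in- and out-degree and bipartiteness.
    ``n_switches`` is the number of attempted swaps per color (default
    10 × the color's edge count).
    """
    rng = random.Random(seed)
    by_color: dict[str, list[list[str]]] = {c: [] for c in COLOR_BIT}
    for u, v, color in g.edges(keys=True):
        by_color[color].append([u, v])
    existing = {
        color: {(u, v) for u, v in edges} for color, edges in by_color.items()
    }
    for color in sorted(by_color):
        edges = by_color[color]
        have = existing[color]
        ne = len(edges)
        if ne < 2:
            continue
        attempts = n_switches if n_switches is not None else 10 * ne
        for _ in range(attempts):
            i = rng.randrange(ne)
            j = rng.randrange(ne)
            if i == j:
                continue
            (u1, v1), (u2, v2) = edges[i], edges[j]
            if v1 == v2 or u1 == u2:
                continue
            if (u1, v2) in have or (u2, v1) in have:
                continue
            have.discard((u1, v1))
            have.discard((u2, v2))
            have.add((u1, v2))
            have.add((u2, v1))
            edges[i][1] = v2
            edges[j][1] = v1
    out = nx.MultiDiGraph(name=g.name)
    out.add_nodes_from(g.nodes(data=True))
    for color, edges in by_color.items():
        for u, v in edges:
            out.add_edge(u, v, key=color, color=color)
    return out


# ---------------------------------------------------------------------------
# significance

def motif_significance(
    real_counts: Counter,
    g: nx.MultiDiGraph,
    n_random: int = 100,
    seed: int = 0,
    k: int = 6,
    n_switches: int | None = None,
    p_max: float = SIGNIFICANCE["p_max"],
    z_min: float = SIGNIFICANCE["z_min"],
    min_count: int = SIGNIFICANCE["min_count"],
) -> pd.DataFrame:
    """Score every observed signature against ``n_random`` switch-randomized
    null graphs.  Returns a catalog DataFrame indexed by signature with
    columns count, null_mean, null_sd, z, p, significant.

    z = (real − null mean)/null sd, with sd = 0 mapped to +inf when the real
    count exceeds the null mean and 0 otherwise; p is the empirical fraction
    of null graphs whose count reaches the real count.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    sigs = sorted(real_counts)
    null = np.zeros((n_random, len(sigs)))
    pos = {s: i for i, s in enumerate(sigs)}
    for r in range(n_random):
        rg = switch_randomize(g, seed=seed + r, n_switches=n_switches)
        for s, c in enumerate_colored_subgraphs(rg, k=k).items():
            i = pos.get(s)
            if i is not None:
                null[r, i] = c
    rows = []
    for s in sigs:
        i = pos[s]
        real = real_counts[s]
        mean = float(null[:, i].mean())
        sd = float(null[:, i].std(ddof=0))
        if sd == 0.0:
            z = math.inf if real > mean else 0.0
        else:
            z = (real - mean) / sd
        p = float((null[:, i] >= real).mean())
        rows.append(
            dict(
                signature=s, count=real, null_mean=mean, null_sd=sd, z=z, p=p,
                significant=(p < p_max and z > z_min and real >= min_count),
            )
        )
    return pd.DataFrame(rows).set_index("signature")


def common_and_specific(
    catalogs: dict[str, pd.DataFrame],
    positives: set[str] = frozenset(),
    negatives: set[str] = frozenset(),
    reference_mode: str = "significant",
    min_count: int = SIGNIFICANCE["min_count"],
) -> tuple[set[str], set[str]]:
    """Cross-map motif calling.

    ``common``: signatures significant in every catalog that is neither a
    positive nor a negative reference.  ``specific``: common signatures also
    present in all positives and absent from all negatives, where presence in
    a reference map is either full significance (``reference_mode=
    "significant"``) or mere frequency, count ≥ min_count
    (``reference_mode="frequent"``).
    """
    if not catalogs:
        raise ValueError("no catalogs")
    core_maps = [n for n in catalogs if n not in positives | negatives]

    def member(cat: pd.DataFrame, mode: str) -> set[str]:
        if mode == "significant":
            return set(cat.index[cat["significant"]])
        if mode == "frequent":
            return set(cat.index[cat["count"] >= min_count])
        raise ValueError(f"unknown reference_mode {mode!r}")

    common: set[str] | None = None
    for name in core_maps:
        s = member(catalogs[name], "significant")
        common = s if common is None else common & s
    common = common or set()
    specific = set(common)
    for name in positives:
        specific &= member(catalogs[name], reference_mode)
    for name in negatives:
        specific -= member(catalogs[name], reference_mode)
    return common, specific


def monocolor_mode(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Forget edge colors: same topology, every edge the single color
    ``link`` (parallel same-direction edges collapse).  Node kinds are kept
    so enumeration semantics stay comparable."""
    out = nx.MultiDiGraph(name=g.name)
    out.add_nodes_from(g.nodes(data=True))
    seen = set()
    for u, v in g.edges():
        if (u, v) not in seen:
            seen.add((u, v))
            out.add_edge(u, v, key="link", color="link")
    return out


def monocolor_counts(g: nx.MultiDiGraph, k: int = 6) -> Counter:
    """Enumeration of the color-blind graph.

    Implemented by encoding the single color as the reactant bit, so all
    signature machinery applies unchanged.
    """
    mono = monocolor_mode(g)
    relabeled = nx.MultiDiGraph(name=mono.name)
    relabeled.add_nodes_from(mono.nodes(data=True))
    for u, v in mono.edges():
        relabeled.add_edge(u, v, key="reactant", color="reactant")
    return enumerate_colored_subgraphs(relabeled, k=k)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    """Catalog TSV plus a companion JSON decoding each signature."""
    import json
    from pathlib import Path

    path = Path(path)
    catalog.to_csv(path, sep="\t")
    decoded = {
        sig: dict(zip(("node_kinds", "edges"), decode_signature(sig)))
        for sig in catalog.index
    }
    path.with_suffix(".signatures.json").write_text(json.dumps(decoded, indent=1))
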