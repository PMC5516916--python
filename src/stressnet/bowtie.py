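"""Bow-tie scoring of signaling graphs.

The bow-tie score b(m) of a molecule m is the fraction of simple directed
source→target paths (stimuli → stress-responsive mRNAs, path length capped
at 30 edges) that pass through m.  Nodes with b(m) above a threshold
(default 0.2, strict) are called candidate bow-tie cores.  A weighted
variant multiplies each path by the magnitude of the differential-expression
log-fold change of its target mRNA, highlighting the cores that carry
signal under a specific condition.

Scores are reported per *merged molecule* — species differing only in
modification state or localization share a key (see
:func:`stressnet.map_model.collapse_states`); a merged key's score is the
maximum over its member species, which keeps b within [0, 1].
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 30
DEFAULT_CORE_THRESHOLD = 0.2
DEFAULT_PATH_CAP = 10_000_000


@dataclass(frozen=True)
class SourceTargetSpec:
    """Path endpoints: stimuli as sources, mRNAs as targets."""

    sources: frozenset[str]
    targets: frozenset[str]
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self):
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.sources & self.targets:
            raise ValueError("sources and targets must be disjoint")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")

    @classmethod
    def from_map(cls, m, max_len: int = DEFAULT_MAX_LEN) -> "SourceTargetSpec":
        return cls(frozenset(m.stimuli), frozenset(m.mrnas), max_len)


@dataclass
class PathTally:
    """Exact simple-path tallies between the source and target sets."""

    total: int = 0
    containment: Counter = field(default_factory=Counter)  # node -> #paths
    per_target: Counter = field(default_factory=Counter)   # target -> #paths
    truncated: bool = False


@dataclass
class BowtieScores:
    """Per-merged-molecule scores plus run metadata.

    ``table`` is indexed by merged-molecule key with columns
    b, b_weighted, betweenness, degree, role, is_core; ``role`` separates
    path endpoints (source / target) from scored molecules.
    """

    table: pd.DataFrame
    total_paths: int
    truncated: bool
    flags: list[str] = field(default_factory=list)

    @property
    def b(self) -> pd.Series:
        return self.table["b"]


# ---------------------------------------------------------------------------
# path enumeration

def enumerate_st_paths(
    g: nx.DiGraph,
    spec: SourceTargetSpec,
    visitor=None,
    path_cap: int = DEFAULT_PATH_CAP,
) -> PathTally:
    """Depth-first enumeration of every simple source→target path of at most
    ``max_len`` edges.  Paths may pass through other sources or targets; a
    path ending in one target and continuing to another counts once per
    target reached.  ``visitor`` (if given) is called with each path (a node
    list).  If any (source, target) pair exceeds ``path_cap`` counted paths
    the tally is marked truncated and further paths for that pair are
    ignored (a warning, not an exception).
    """
    missing = (spec.sources | spec.targets) - set(g.nodes)
    if missing:
        raise KeyError(f"spec nodes absent from graph: {sorted(missing)}")
    tally = PathTally()
    targets = spec.targets
    succ = {u: sorted(g.successors(u)) for u in g.nodes}
    pair_counts: Counter = Counter()

    for s in sorted(spec.sources):
        path = [s]
        on_path = {s}

        def dfs(u: str, depth: int) -> None:
            for v in succ[u]:
                if v in on_path:
                    continue
                path.append(v)
                if v in targets:
                    if pair_counts[(s, v)] >= path_cap:
                        if not tally.truncated:
                            tally.truncated = True
                            log.warning(
                                "path cap %d reached for pair (%s, %s); "
                                "tallies are truncated", path_cap, s, v,
                            )
                    else:
                        pair_counts[(s, v)] += 1
                        tally.total += 1
                        tally.per_target[v] += 1
                        tally.containment.update(path)
                        if visitor is not None:
                            visitor(list(path))
                if depth < spec.max_len:
                    on_path.add(v)
                    dfs(v, depth + 1)
                    on_path.discard(v)
                path.pop()

        dfs(s, 1)
    return tally


# ---------------------------------------------------------------------------
# scores

def _roles(nodes, spec: SourceTargetSpec, merge: dict[str, str]) -> dict[str, str]:
    roles: dict[str, str] = {}
    for n in nodes:
        key = merge.get(n, n)
        if n in spec.sources:
            roles[key] = "source"
        elif n in spec.targets:
            roles.setdefault(key, "target")
            if roles[key] != "source":
                roles[key] = "target"
        else:
            roles.setdefault(key, "molecule")
    return roles


def _assemble(
    g: nx.DiGraph,
    spec: SourceTargetSpec,
    merge: dict[str, str] | None,
    node_b: dict[str, float],
    total: int,
    truncated: bool,
    flags: list[str],
    node_bw: dict[str, float] | None = None,
) -> BowtieScores:
    merge = merge or {}
    btw, deg = betweenness_and_degree(g)
    keys = sorted({merge.get(n, n) for n in g.nodes})
    roles = _roles(g.nodes, spec, merge)
    rows = {
        k: dict(b=0.0, b_weighted=np.nan, betweenness=0.0, degree=0, role=roles[k],
                is_core=False)
        for k in keys
    }
    if node_bw is not None:
        for k in keys:
            rows[k]["b_weighted"] = 0.0
    for n in g.nodes:
        k = merge.get(n, n)
        rows[k]["b"] = max(rows[k]["b"], node_b.get(n, 0.0))
        rows[k]["betweenness"] = max(rows[k]["betweenness"], btw[n])
        rows[k]["degree"] = max(rows[k]["degree"], deg[n])
        if node_bw is not None:
            rows[k]["b_weighted"] = max(rows[k]["b_weighted"], node_bw.get(n, 0.0))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "molecule_key"
    scores = BowtieScores(
        table=table, total_paths=total, truncated=truncated, flags=flags,
    )
    call_cores(scores)
    return scores


def bowtie_scores(
    g: nx.DiGraph,
    spec: SourceTargetSpec,
    merge: dict[str, str] | None = None,
    path_cap: int = DEFAULT_PATH_CAP,
) -> BowtieScores:
    """Unweighted bow-tie scores: b(m) = (#S→T paths containing m) / (#S→T
    paths), pooled over all source/target pairs.  ``merge`` maps species id
    → merged-molecule key (identity when omitted).  With no connecting path
    all scores are 0 and the result is flagged."""
    tally = enumerate_st_paths(g, spec, path_cap=path_cap)
    flags = []
    if tally.total == 0:
        flags.append("no connecting paths")
        node_b = {}
    else:
        node_b = {n: c / tally.total for n, c in tally.containment.items()}
    return _assemble(g, spec, merge, node_b, tally.total, tally.truncated, flags)


def weighted_bowtie_scores(
    g: nx.DiGraph,
    spec: SourceTargetSpec,
    expression: pd.Series,
    target_genes: dict[str, str] | None = None,
    merge: dict[str, str] | None = None,
    weight_mode: str = "abs",
    path_cap: int = DEFAULT_PATH_CAP,
) -> BowtieScores:
    """Expression-weighted scores: each path carries the |log2 fold change|
    of its target mRNA (``weight_mode="positive"`` clips negative LFCs to 0
    instead).  ``expression`` maps gene symbol → log2FC; ``target_genes``
    maps target node id → gene symbol (node ids are tried directly when
    omitted).  Targets with no expression value get weight 0 and are logged.
    """
    if weight_mode not in ("abs", "positive"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    target_genes = target_genes or {}
    weights: dict[str, float] = {}
    unmatched = []
    for t in spec.targets:
        gene = target_genes.get(t, t)
        if gene in expression.index:
            lfc = float(expression[gene])
            weights[t] = abs(lfc) if weight_mode == "abs" else max(lfc, 0.0)
        else:
            weights[t] = 0.0
            unmatched.append(t)
    if unmatched:
        log.warning("targets with no expression value (weight 0): %s",
                    sorted(unmatched))

    wtotal = 0.0
    wcontain: Counter = Counter()

    def visit(path):
        nonlocal wtotal
        w = weights[path[-1]]
        if w == 0.0:
            return
        wtotal += w
        for n in path:
            wcontain[n] += w

    tally = enumerate_st_paths(g, spec, visitor=visit, path_cap=path_cap)
    flags = []
    node_b = (
        {n: c / tally.total for n, c in tally.containment.items()}
        if tally.total else {}
    )
    if not tally.total:
        flags.append("no connecting paths")
    if wtotal == 0.0:
        flags.append("zero total path weight")
        node_bw: dict[str, float] = {}
    else:
        node_bw = {n: w / wtotal for n, w in wcontain.items()}
    return _assemble(
        g, spec, merge, node_b, tally.total, tally.truncated, flags,
        node_bw=node_bw,
    )


def betweenness_and_degree(g: nx.DiGraph):
    """Directed shortest-path betweenness (endpoint-excluding, normalized by
    (N−1)(N−2)) and total degree (in + out) per node."""
    btw = nx.betweenness_centrality(g, normalized=True)
    deg = {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}
    return btw, deg


def call_cores(
    scores: BowtieScores, threshold: float = DEFAULT_CORE_THRESHOLD
) -> set[str]:
    """Candidate bow-tie cores: merged molecules with b strictly above the
    threshold (endpoint roles excluded).  Sets the is_core flags in place."""
    t = scores.table
    mask = (t["b"] > threshold) & (t["role"] == "molecule")
    t["is_core"] = mask
    return set(t.index[mask])


def score_r2(scores: BowtieScores) -> float:
    """R² of the OLS fit of betweenness on b over scored molecules (all
    roles).  NaN when fewer than 2 nodes or b has zero variance."""
    t = scores.table
    x = t["b"].to_numpy(float)
    y = t["betweenness"].to_numpy(float)
    if len(x) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# I/O

def read_expression_table(path) -> pd.Series:
    """Two-column TSV (gene, log2FC); '#' comments allowed."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene", "log2fc"],
        dtype={"gene": str},
    )
    if df["log2fc"].isna().any() or not np.isfinite(df["log2fc"]).all():
        raise ValueError(f"{path}: non-finite log2FC values")
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene entries")
    return df.set_index("gene")["log2fc"]


def write_scores_tsv(scores: BowtieScores, path) -> None:
    out = scores.table.sort_values("b", ascending=False)
    out.to_csv(path, sep="\t")
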