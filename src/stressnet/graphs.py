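"""Graph views of a molecular map.

Two projections drive all downstream analyses:

* the **bipartite process graph** — molecules and reactions both become
  nodes; directed edges are colored ``reactant`` (molecule→reaction),
  ``product`` (reaction→molecule) or ``modifier`` (molecule→reaction,
  catalysis/inhibition polarity deliberately ignored).  Used for colored
  network-motif discovery.

* the **signaling graph** — a molecule-level digraph in which every reaction
  contributes edges u→v for each u in reactants ∪ modifiers and each v in
  products (signal flows from everything driving a reaction to everything it
  makes).  Used for path (bow-tie) and controllability analyses.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .map_model import MolecularMap, copy_map

EDGE_COLORS = ("reactant", "product", "modifier")
TRIVIAL_REACTION_CLASSES = frozenset({"transcription", "translation"})


def to_bipartite(
    m: MolecularMap, exclude_classes: Iterable[str] = ()
) -> nx.MultiDiGraph:
    """Colored bipartite process graph; reactions whose class is in
    ``exclude_classes`` are omitted and molecules left isolated are dropped."""
    exclude = frozenset(exclude_classes)
    g = nx.MultiDiGraph(name=m.name)
    for s in m.species:
        g.add_node(s.id, kind="molecule", entity_class=s.entity_class)
    for r in m.reactions:
        if r.reaction_class in exclude:
            continue
        g.add_node(r.id, kind="reaction", reaction_class=r.reaction_class)
        for sid in dict.fromkeys(r.reactants):
            g.add_edge(sid, r.id, key="reactant", color="reactant")
        for sid in dict.fromkeys(r.products):
            g.add_edge(r.id, sid, key="product", color="product")
        for sid in dict.fromkeys(sid for sid, _ in r.modifiers):
            g.add_edge(sid, r.id, key="modifier", color="modifier")
    g.remove_nodes_from(
        [n for n, d in g.nodes(data=True)
         if d["kind"] == "molecule" and g.degree(n) == 0]
    )
    assert_bipartite(g)
    return g


def to_signaling(m: MolecularMap, drivers: str = "reactants_and_modifiers") -> nx.DiGraph:
    """Molecule-level signal-flow digraph.

    ``drivers`` selects which reaction participants emit edges toward the
    products: the default treats both reactants and modifiers as signal
    carriers; ``"modifiers_only"`` restricts to catalytic influence.
    Duplicate molecule pairs arising from different reactions merge into one
    edge whose ``provenance`` lists every (reaction id, tail role) pair.
    """
    if drivers not in ("reactants_and_modifiers", "modifiers_only"):
        raise ValueError(f"unknown drivers mode {drivers!r}")
    g = nx.DiGraph(name=m.name)
    g.add_nodes_from(s.id for s in m.species)
    for r in m.reactions:
        tails: list[tuple[str, str]] = [(sid, "modifier") for sid, _ in r.modifiers]
        if drivers == "reactants_and_modifiers":
            tails += [(sid, "reactant") for sid in r.reactants]
        for u, role in tails:
            for v in r.products:
                if u == v:
                    continue
                if g.has_edge(u, v):
                    g[u][v]["provenance"].append((r.id, role))
                else:
                    g.add_edge(u, v, provenance=[(r.id, role)])
    return g


def drop_trivial_reactions(x):
    """Remove transcription/translation reactions (motif-analysis input).

    Accepts either a :class:`MolecularMap` (returns a copy without those
    reactions) or a bipartite process graph (returns a copy without those
    reaction nodes, dropping molecule nodes left isolated).
    """
    if isinstance(x, MolecularMap):
        m = copy_map(x)
        m.reactions = [
            r for r in m.reactions if r.reaction_class not in TRIVIAL_REACTION_CLASSES
        ]
        return m
    g = x.copy()
    g.remove_nodes_from(
        [n for n, d in g.nodes(data=True)
         if d.get("kind") == "reaction"
         and d.get("reaction_class") in TRIVIAL_REACTION_CLASSES]
    )
    g.remove_nodes_from(
        [n for n, d in g.nodes(data=True)
         if d.get("kind") == "molecule" and g.degree(n) == 0]
    )
    return g


def assert_bipartite(g: nx.MultiDiGraph) -> None:
    """Raise AssertionError if any edge violates the color/kind contract."""
    for u, v, color in g.edges(keys=True):
        ku, kv = g.nodes[u]["kind"], g.nodes[v]["kind"]
        if color in ("reactant", "modifier"):
            assert (ku, kv) == ("molecule", "reaction"), (u, v, color, ku, kv)
        elif color == "product":
            assert (ku, kv) == ("reaction", "molecule"), (u, v, color, ku, kv)
        else:
            raise AssertionError(f"unknown edge color {color!r} on ({u}, {v})")


def export_graphml(g, path) -> None:
    """GraphML export for external viewers (provenance lists flattened to
    semicolon-joined strings, which GraphML attributes require)."""
    h = g.copy()
    for u, v, data in h.edges(data=True):
        if "provenance" in data:
            data["provenance"] = ";".join(
                f"{rid}:{role}" for rid, role in data["provenance"]
            )
    nx.write_graphml(h, path)


def export_edge_list(g, path) -> None:
    """Edge-list TSV (source, target, color-or-role, provenance)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["source", "target", "label", "provenance"])
        if g.is_multigraph():
            for u, v, color in g.edges(keys=True):
                w.writerow([u, v, color, ""])
        else:
            for u, v, data in g.edges(data=True):
                prov = ";".join(f"{rid}:{role}" for rid, role in data.get("provenance", []))
                w.writerow([u, v, "signal", prov])
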