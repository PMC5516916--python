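"""Synthetic maps, expression tables and annotation tables.

The generator emulates the layered bow-tie organisation of a stress-response
map: a wide layer of external stimuli feeds upstream sensor proteins, which
converge onto a deliberately narrow core layer, which fans out to downstream
effectors that drive transcription of the stress-responsive mRNA targets.
Every stimulus→mRNA route traverses the core layer by construction (there
are no skip edges), so the planted core's bow-tie scores are predictable.
A ground-truth record accompanies each map so recovery of cores, motifs and
critical nodes can be scored without re-deriving it.

Default sizes (8 stimuli, 5 core molecules, 40 intermediates split evenly
into upstream and downstream layers, 30 mRNA targets) keep exhaustive path
enumeration fast.  The wings are sparse random layers (``edge_density``,
default 0.3) while the core is a *cascade*: every upstream sensor feeds its
first element and its last element fans out downstream, the way sequential
kinases of a signaling pathway sit on essentially every stimulus→output
path.  Planted core nodes therefore have bow-tie score exactly 1, while a
wing node's score is its share of path traffic, strictly smaller — the
margin that makes the planted core recoverable and its members unavoidable
cut nodes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .map_model import (
    MolecularMap,
    Reaction,
    Species,
    assign_gene_symbols,
)


class GenerationError(ValueError):
    """Parameters cannot produce a valid layered bow-tie map."""


@dataclass(frozen=True)
class MapGenParams:
    n_stimuli: int = 8
    n_targets: int = 30
    core_size: int = 5
    n_intermediates: int = 40
    edge_density: float = 0.3
    p_complex: float = 0.2
    p_reversible_inhibitor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_stimuli, self.n_targets, self.core_size,
               self.n_intermediates) < 1:
            raise GenerationError("all layer sizes must be >= 1")
        for p in (self.edge_density, self.p_complex,
                  self.p_reversible_inhibitor):
            if not 0.0 <= p <= 1.0:
                raise GenerationError("probabilities must lie in [0, 1]")
        if self.edge_density == 0.0:
            raise GenerationError(
                "edge_density 0 cannot connect stimuli to targets through the core"
            )
        if self.core_size > 25:
            raise GenerationError(
                "a core cascade longer than 25 steps exceeds the standard "
                "30-edge path cap"
            )


@dataclass
class GroundTruth:
    """Planted structure of a generated map, sufficient to score recovery."""

    stimulus_ids: list[str] = field(default_factory=list)
    upstream_ids: list[str] = field(default_factory=list)
    core_ids: list[str] = field(default_factory=list)
    downstream_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)
    cut_node_ids: list[str] = field(default_factory=list)
    modules: list[dict] = field(default_factory=list)
    signaling_edges: list[tuple[str, str]] = field(default_factory=list)
    species_class_tally: dict[str, int] = field(default_factory=dict)
    reaction_class_tally: dict[str, int] = field(default_factory=dict)
    target_genes: dict[str, str] = field(default_factory=dict)

    def save(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _layer_edges(rng, sources, sinks, density):
    """Random inter-layer edges at the given density; every source gets at
    least one out-edge and every sink at least one in-edge."""
    edges = {
        (u, v)
        for u in sources for v in sinks
        if rng.random() < density
    }
    for u in sources:
        if not any(e[0] == u for e in edges):
            edges.add((u, sinks[rng.integers(len(sinks))]))
    for v in sinks:
        if not any(e[1] == v for e in edges):
            edges.add((sources[rng.integers(len(sources))], v))
    return sorted(edges)


def gen_stress_map(params: MapGenParams) -> tuple[MolecularMap, GroundTruth]:
    """Layered stimulus→upstream→core→downstream→mRNA map plus ground truth.

    Inter-layer connections are state-transition reactions (one per edge);
    each mRNA target gets a single transcription reaction whose reactant is
    its gene and whose modifiers are its downstream regulators.  With
    probability ``p_complex`` a core/intermediate node is a two-component
    complex; with probability ``p_reversible_inhibitor`` a core node gets a
    planted reversible complex-formation module (association +
    dissociation with a private trigger molecule).
    """
    rng = np.random.default_rng(params.seed)
    gt = GroundTruth()
    m = MolecularMap(name=f"synthetic_stress_map_seed{params.seed}")

    def add_species(sid, name, cls, **kw):
        sp = Species(id=sid, name=name, entity_class=cls, **kw)
        m.species.append(sp)
        return sp

    n_up = max(params.n_intermediates // 2, 1)
    n_down = max(params.n_intermediates - n_up, 1)

    for i in range(params.n_stimuli):
        sid = f"st{i:02d}"
        add_species(sid, f"STRESS{i}", "ion" if i % 2 else "simple_molecule")
        gt.stimulus_ids.append(sid)
        m.stimuli.add(sid)

    def add_layer(prefix, label, count, ids):
        for i in range(count):
            sid = f"{prefix}{i:02d}"
            if rng.random() < params.p_complex:
                ca = add_species(f"{sid}ca", f"{label}{i}A", "protein")
                cb = add_species(f"{sid}cb", f"{label}{i}B", "protein")
                add_species(sid, f"{label}{i}", "complex",
                            components=[ca.id, cb.id])
            else:
                add_species(sid, f"{label}{i}", "protein")
            ids.append(sid)

    add_layer("up", "UPS", n_up, gt.upstream_ids)
    add_layer("co", "CORE", params.core_size, gt.core_ids)
    add_layer("dn", "DWN", n_down, gt.downstream_ids)

    for j in range(params.n_targets):
        gid, rid = f"gn{j:02d}", f"mr{j:02d}"
        add_species(gid, f"TGT{j}", "gene")
        add_species(rid, f"TGT{j}", "rna")
        gt.gene_ids.append(gid)
        gt.target_ids.append(rid)
        gt.target_genes[rid] = f"TGT{j}"
        m.mrnas.add(rid)

    # wings are random sparse layers; the core is a cascade every signal
    # funnels through (upstream converges on its first element, the last
    # element fans out to the downstream layer) — the bow-tie waist
    rxn_i = 0
    core_chain = list(zip(gt.core_ids, gt.core_ids[1:]))
    wiring = (
        _layer_edges(rng, gt.stimulus_ids, gt.upstream_ids, params.edge_density)
        + [(u, gt.core_ids[0]) for u in gt.upstream_ids]
        + core_chain
        + [(gt.core_ids[-1], d) for d in gt.downstream_ids]
    )
    for u, v in wiring:
        m.reactions.append(
            Reaction(id=f"re{rxn_i:03d}", reaction_class="state_transition",
                     reactants=[u], products=[v])
        )
        gt.signaling_edges.append((u, v))
        rxn_i += 1

    # transcription: gene --(modifiers: downstream regulators)--> mRNA
    down = gt.downstream_ids
    regulators = {rid: [] for rid in gt.target_ids}
    for d in down:
        hit = [rid for rid in gt.target_ids if rng.random() < params.edge_density]
        if not hit:
            hit = [gt.target_ids[rng.integers(len(gt.target_ids))]]
        for rid in hit:
            regulators[rid].append(d)
    for gid, rid in zip(gt.gene_ids, gt.target_ids):
        regs = regulators[rid] or [down[rng.integers(len(down))]]
        m.reactions.append(
            Reaction(id=f"re{rxn_i:03d}", reaction_class="transcription",
                     reactants=[gid], products=[rid],
                     modifiers=[(d, "positive") for d in regs])
        )
        gt.signaling_edges.append((gid, rid))
        gt.signaling_edges.extend((d, rid) for d in regs)
        rxn_i += 1

    # reversible-inhibitor modules on core nodes
    for i, cid in enumerate(gt.core_ids):
        if rng.random() < params.p_reversible_inhibitor:
            rec = plant_reversible_complex(
                m, cid, inhibitor_name=f"INH{i}",
                abundance_ratio=float(rng.integers(4, 160)),
                trigger_name=f"TRG{i}",
            )
            gt.modules.append(rec)

    assign_gene_symbols(m)
    m.validate()

    from .map_model import map_summary

    summary = map_summary(m)
    for cat in ("species", "reactions"):
        sub = summary[(summary.category == cat) & (summary.subcategory != "total")]
        tally = dict(zip(sub.subcategory, sub["count"].astype(int)))
        if cat == "species":
            gt.species_class_tally = tally
        else:
            gt.reaction_class_tally = tally

    gt.cut_node_ids = _cut_nodes(m, gt)
    return m, gt


def _cut_nodes(m: MolecularMap, gt: GroundTruth) -> list[str]:
    """Interior nodes whose removal disconnects every stimulus from every
    target (these must have bow-tie score 1 and are expected critical)."""
    from .graphs import to_signaling
    import networkx as nx

    g = to_signaling(m)
    ends = set(gt.stimulus_ids) | set(gt.target_ids)

    def connected(h) -> bool:
        reach = set()
        for s in gt.stimulus_ids:
            if s in h:
                reach |= nx.descendants(h, s)
        return bool(reach & set(gt.target_ids))

    if not connected(g):
        raise GenerationError("generated map has no stimulus→target path")
    out = []
    for v in g.nodes:
        if v in ends:
            continue
        h = g.copy()
        h.remove_node(v)
        if not connected(h):
            out.append(v)
    return sorted(out)


def plant_reversible_complex(
    m: MolecularMap,
    target_id: str,
    inhibitor_name: str,
    abundance_ratio: float = 50.0,
    trigger_name: str | None = None,
) -> dict:
    """Plant a reversible complex-formation module on ``target_id``.

    Adds an inhibitor protein and a target:inhibitor complex, an association
    reaction (target + inhibitor → complex) and a dissociation reaction
    (complex → target + inhibitor) — the colored "reversible complex
    formation" substructure.  ``abundance_ratio`` (inhibitor:target molar
    excess, the buffer capacity of the module) is stored as species
    metadata.  With ``trigger_name`` a private small molecule is added as
    positive modifier of the dissociation (the cAMP-releases-the-inhibitor
    pattern), making the module an exact six-node substructure.

    Returns a record naming the created species/reactions; the map is
    modified in place.
    """
    by_id = m.species_by_id
    if target_id not in by_id:
        raise KeyError(f"unknown target species {target_id!r}")
    target = by_id[target_id]
    base = f"{target_id}_{inhibitor_name.lower()}"
    inhibitor = Species(
        id=f"{base}_i", name=inhibitor_name, entity_class="protein",
        meta={"abundance_ratio": abundance_ratio},
    )
    complex_sp = Species(
        id=f"{base}_c", name=f"{target.name}/{inhibitor_name}",
        entity_class="complex", components=[target_id, inhibitor.id],
    )
    m.species.extend([inhibitor, complex_sp])
    assoc = Reaction(
        id=f"{base}_assoc", reaction_class="association",
        reactants=[target_id, inhibitor.id], products=[complex_sp.id],
    )
    dissoc = Reaction(
        id=f"{base}_dissoc", reaction_class="dissociation",
        reactants=[complex_sp.id], products=[target_id, inhibitor.id],
    )
    rec = dict(
        target=target_id, inhibitor=inhibitor.id, complex=complex_sp.id,
        association=assoc.id, dissociation=dissoc.id, trigger=None,
        abundance_ratio=abundance_ratio,
    )
    if trigger_name is not None:
        trigger = Species(
            id=f"{base}_t", name=trigger_name, entity_class="simple_molecule"
        )
        m.species.append(trigger)
        dissoc.modifiers.append((trigger.id, "positive"))
        rec["trigger"] = trigger.id
    m.reactions.extend([assoc, dissoc])
    # keep the complex gene-symbol invariant without reassigning everything
    inhibitor.gene_symbols = frozenset({inhibitor_name.upper()})
    complex_sp.gene_symbols = target.gene_symbols | inhibitor.gene_symbols
    return rec


def reversible_complex_signature(with_trigger: bool = True, k: int | None = None) -> str:
    """Canonical signature of the planted module in isolation (6 nodes with
    the trigger, 5 without) — computed, not hard-coded, so it always matches
    the current signature encoding."""
    from .graphs import to_bipartite
    from .motifs import canonical_signature

    m = MolecularMap(name="module")
    t = Species(id="t", name="T", entity_class="protein")
    m.species.append(t)
    plant_reversible_complex(
        m, "t", "I", trigger_name="X" if with_trigger else None
    )
    assign_gene_symbols(m)
    g = to_bipartite(m)
    assert g.number_of_nodes() == (6 if with_trigger else 5), k
    return canonical_signature(g)


def gen_expression(
    m: MolecularMap,
    upregulated_targets: set[str],
    mu: float = 2.0,
    sigma: float = 0.5,
    baseline_sigma: float = 0.2,
    seed: int = 0,
    target_genes: dict[str, str] | None = None,
) -> pd.Series:
    """Expression table over the map's target genes: upregulated targets get
    log2FC ~ Normal(mu, sigma), the rest Normal(0, baseline_sigma)."""
    from .map_model import genes_of

    rng = np.random.default_rng(seed)
    unknown = set(upregulated_targets) - m.mrnas
    if unknown:
        raise KeyError(f"upregulated targets not in map mrnas: {sorted(unknown)}")
    rows = {}
    for rid in sorted(m.mrnas):
        if target_genes and rid in target_genes:
            gene = target_genes[rid]
        else:
            gs = genes_of(m, {rid})
            gene = sorted(gs)[0] if gs else rid
        if rid in upregulated_targets:
            rows[gene] = mu + sigma * rng.standard_normal()
        else:
            rows[gene] = baseline_sigma * rng.standard_normal()
    return pd.Series(rows, name="log2fc")


def gen_annotations(
    genes,
    critical: set[str] = frozenset(),
    p_lethal: float = 0.2,
    p_synthetic_lethal_given_critical: float = 0.6,
    p_synthetic_lethal_given_noncritical: float = 0.3,
    gi_rate_critical: float = 4.0,
    gi_rate_noncritical: float = 1.0,
    copy_limit_log_mean: float = 3.0,
    copy_limit_log_sigma: float = 1.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table with group-dependent effect sizes.

    Lethality is a Bernoulli flag shared by both groups (the study
    conditions show no critical/non-critical difference there); synthetic
    lethality is Bernoulli with a group-dependent probability; negative
    genetic-interaction counts are Poisson with group-dependent rates; gTOW
    copy-number limits are log-normal, independent of criticality.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in sorted(genes):
        is_crit = g in critical
        p_sl = (p_synthetic_lethal_given_critical if is_crit
                else p_synthetic_lethal_given_noncritical)
        gi = (gi_rate_critical if is_crit else gi_rate_noncritical)
        rows.append(dict(
            gene=g,
            lethal=bool(rng.random() < p_lethal),
            synthetic_lethal=bool(rng.random() < p_sl),
            negative_gi_count=int(rng.poisson(gi)),
            copy_number_limit=float(np.exp(
                copy_limit_log_mean + copy_limit_log_sigma * rng.standard_normal()
            )),
            stress_phenotypes=frozenset(),
        ))
    return pd.DataFrame(rows).set_index("gene")
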