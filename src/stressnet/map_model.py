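"""Molecular interaction maps: species, reactions and map-level statistics.

A :class:`MolecularMap` is the in-memory form of a CellDesigner-dialect SBML
process-description map: typed molecular species (proteins, complexes, genes,
RNAs, small molecules, ...) connected by typed reactions (state transitions,
associations/dissociations, transcription/translation, transport).  Two node
subsets carry the analysis semantics: *stimuli* (external signals, the path
sources) and *mrnas* (stress-responsive transcripts, the path targets).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

ENTITY_CLASSES = frozenset(
    {"protein", "complex", "gene", "rna", "simple_molecule", "ion", "drug",
     "phenotype", "unknown"}
)

REACTION_CLASSES = frozenset(
    {"state_transition", "association", "dissociation", "transcription",
     "translation", "transport", "other"}
)

MODIFIER_CLASSES = frozenset({"positive", "negative", "unknown"})

# suffix/prefix decorations that mark activation or modification state in
# display names, stripped before deriving a gene symbol
_STATE_DECOR = re.compile(
    r"(^p-)|([-_ ]?(P{1,3}|act|active|inact|inactive|ox|red|star)$)|(\*+$)",
    re.IGNORECASE,
)
_PARENS = re.compile(r"\s*\(.*?\)\s*")


class MapValidationError(ValueError):
    """A MolecularMap invariant is violated."""


@dataclass
class Species:
    """One molecular species (a map glyph), possibly a complex of others."""

    id: str
    name: str
    entity_class: str = "unknown"
    state_mods: list[tuple[str, str]] = field(default_factory=list)
    compartment: str = "default"
    components: list[str] = field(default_factory=list)
    gene_symbols: frozenset[str] = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise MapValidationError(
                f"species {self.id!r}: unknown entity_class {self.entity_class!r}"
            )
        self.gene_symbols = frozenset(self.gene_symbols)
        self.state_mods = [tuple(m) for m in self.state_mods]


@dataclass
class Reaction:
    """One typed reaction with reactants, products and (signed) modifiers."""

    id: str
    reaction_class: str = "state_transition"
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    modifiers: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reaction_class not in REACTION_CLASSES:
            raise MapValidationError(
                f"reaction {self.id!r}: unknown reaction_class {self.reaction_class!r}"
            )
        self.modifiers = [tuple(m) for m in self.modifiers]
        for _, mclass in self.modifiers:
            if mclass not in MODIFIER_CLASSES:
                raise MapValidationError(
                    f"reaction {self.id!r}: unknown modifier class {mclass!r}"
                )


@dataclass
class MolecularMap:
    """A named collection of species and reactions plus source/target sets."""

    name: str = ""
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    stimuli: set[str] = field(default_factory=set)
    mrnas: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.stimuli = set(self.stimuli)
        self.mrnas = set(self.mrnas)

    # -- lookups ---------------------------------------------------------
    @property
    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def species_ids(self) -> set[str]:
        return {s.id for s in self.species}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`MapValidationError` on any broken invariant."""
        ids: set[str] = set()
        for s in self.species:
            if s.id in ids:
                raise MapValidationError(f"duplicate species id {s.id!r}")
            ids.add(s.id)
        rids: set[str] = set()
        by_id = self.species_by_id
        for s in self.species:
            if (s.entity_class == "complex") != bool(s.components):
                raise MapValidationError(
                    f"species {s.id!r}: components nonempty iff complex"
                )
            dangling = [c for c in s.components if c not in ids]
            if dangling:
                raise MapValidationError(
                    f"complex {s.id!r}: unknown component ids {dangling}"
                )
            if s.entity_class == "complex":
                want = frozenset().union(
                    *(by_id[c].gene_symbols for c in s.components)
                )
                if s.gene_symbols != want:
                    raise MapValidationError(
                        f"complex {s.id!r}: gene_symbols != union over components"
                    )
        for r in self.reactions:
            if r.id in rids:
                raise MapValidationError(f"duplicate reaction id {r.id!r}")
            rids.add(r.id)
            if not r.reactants or not r.products:
                raise MapValidationError(
                    f"reaction {r.id!r}: reactants and products must be nonempty"
                )
            dangling = [
                x for x in (*r.reactants, *r.products, *(m for m, _ in r.modifiers))
                if x not in ids
            ]
            if dangling:
                raise MapValidationError(
                    f"reaction {r.id!r}: dangling species references {dangling}"
                )
        for label, group in (("stimuli", self.stimuli), ("mrnas", self.mrnas)):
            unknown = group - ids
            if unknown:
                raise MapValidationError(f"{label} not in species: {sorted(unknown)}")
        overlap = self.stimuli & self.mrnas
        if overlap:
            raise MapValidationError(f"stimuli/mrnas overlap: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# gene symbols

def derive_gene_symbol(name: str) -> str:
    """Gene symbol from a display name: parentheticals and state decorations
    stripped, uppercased.  Empty result means "no gene"."""
    base = _PARENS.sub(" ", name).strip()
    prev = None
    while prev != base:
        prev = base
        base = _STATE_DECOR.sub("", base).strip()
    return base.upper()


def assign_gene_symbols(
    m: MolecularMap, aliases: dict[str, str] | None = None
) -> None:
    """Populate ``gene_symbols`` in place: name-derived for gene products,
    component union for complexes.  ``aliases`` maps species name → symbol and
    overrides the derivation."""
    aliases = aliases or {}
    by_id = m.species_by_id
    for s in m.species:
        if s.entity_class == "complex":
            continue
        if s.gene_symbols:
            continue  # explicit annotation wins
        if s.entity_class in {"protein", "gene", "rna"}:
            sym = aliases.get(s.name) or derive_gene_symbol(s.name)
            s.gene_symbols = frozenset({sym}) if sym else frozenset()
    # complexes in dependency order (components may themselves be complexes)
    done: set[str] = set()

    def fill(s: Species) -> None:
        if s.id in done:
            return
        done.add(s.id)
        if s.entity_class == "complex":
            for c in s.components:
                fill(by_id[c])
            s.gene_symbols = frozenset().union(
                *(by_id[c].gene_symbols for c in s.components)
            )

    for s in m.species:
        fill(s)


def genes_of(m: MolecularMap, species_ids: set[str]) -> frozenset[str]:
    """Union of gene symbols over the given species, complexes expanded."""
    by_id = m.species_by_id
    unknown = set(species_ids) - by_id.keys()
    if unknown:
        raise KeyError(f"unknown species ids: {sorted(unknown)}")
    out: set[str] = set()

    def walk(sid: str) -> None:
        s = by_id[sid]
        out.update(s.gene_symbols)
        for c in s.components:
            walk(c)

    for sid in species_ids:
        walk(sid)
    return frozenset(out)


# ---------------------------------------------------------------------------
# map statistics

_SPECIES_GROUPS = {
    "protein": "proteins",
    "complex": "complexes",
    "gene": "genes_and_rnas",
    "rna": "genes_and_rnas",
    "simple_molecule": "other_molecules",
    "ion": "other_molecules",
    "drug": "other_molecules",
    "phenotype": "other_molecules",
    "unknown": "other",
}

_REACTION_GROUPS = {
    "association": "associations_and_dissociations",
    "dissociation": "associations_and_dissociations",
    "state_transition": "state_transitions",
    "transcription": "transcriptions_and_translations",
    "translation": "transcriptions_and_translations",
    "transport": "transports",
    "other": "other",
}


def map_summary(m: MolecularMap) -> pd.DataFrame:
    """Species and reaction counts grouped the way map statistics are usually
    tabulated.  Returns a DataFrame (category, subcategory, count); group
    counts sum to the species / reaction totals."""
    rows: list[tuple[str, str, int]] = []
    for cat, groups, items, key in (
        ("species", _SPECIES_GROUPS, m.species, lambda s: s.entity_class),
        ("reactions", _REACTION_GROUPS, m.reactions, lambda r: r.reaction_class),
    ):
        counts = dict.fromkeys(dict.fromkeys(groups.values()), 0)
        for it in items:
            counts[groups[key(it)]] += 1
        rows.append((cat, "total", len(items)))
        rows.extend((cat, sub, n) for sub, n in counts.items())
    return pd.DataFrame(rows, columns=["category", "subcategory", "count"])


# ---------------------------------------------------------------------------
# state collapsing (merged molecules)

def collapse_states(m: MolecularMap) -> dict[str, str]:
    """Map each species id to a merged-molecule key.

    Two species merge iff they share name and entity class and, for
    complexes, the same multiset of component keys — modification state and
    compartment are ignored.  This is the node identity under which score
    distributions are reported.
    """
    by_id = m.species_by_id
    memo: dict[str, str] = {}

    def key(sid: str) -> str:
        if sid in memo:
            return memo[sid]
        s = by_id[sid]
        if s.entity_class == "complex":
            parts = sorted(key(c) for c in s.components)
            k = f"complex:{s.name}[{'+'.join(parts)}]"
        else:
            k = f"{s.entity_class}:{s.name}"
        memo[sid] = k
        return k

    return {s.id: key(s.id) for s in m.species}


def copy_map(m: MolecularMap) -> MolecularMap:
    """Deep-enough copy (species and reactions are fresh objects)."""
    return MolecularMap(
        name=m.name,
        species=[replace(s, state_mods=list(s.state_mods),
                         components=list(s.components),
                         meta=dict(s.meta)) for s in m.species],
        reactions=[replace(r, reactants=list(r.reactants),
                           products=list(r.products),
                           modifiers=list(r.modifiers)) for r in m.reactions],
        stimuli=set(m.stimuli),
        mrnas=set(m.mrnas),
    )
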