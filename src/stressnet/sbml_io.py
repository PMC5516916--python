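"""Reading and writing CellDesigner-dialect SBML (Level 2) maps.

The reader understands the subset of the CellDesigner 4.x extension the
analyses need — species identity classes, modification states, included
(complex-component) species, reaction types and modifier polarity — and
falls back to SBML core plus SBO terms when the extension is absent, so
plain SBML and third-party maps still load (classes then default to
``unknown`` / ``other``).

Source/target designation (external stimuli, stress-responsive mRNAs) is not
part of the CellDesigner vocabulary.  It is taken from, in order of
precedence: a sidecar config (YAML/JSON: ``stimuli``, ``mrnas``, ``aliases``
keys; entries match species ids, exact names, or ``fnmatch`` name patterns),
an embedded tool annotation written by :func:`write_celldesigner`, or an
auto-detection heuristic (RNA species → targets; small molecules / ions /
drugs with no producing reaction → stimuli) that is logged when used.
"""

from __future__ import annotations

import fnmatch
import json
import logging
from pathlib import Path

import yaml
from lxml import etree

from .map_model import (
    MolecularMap,
    Reaction,
    Species,
    assign_gene_symbols,
)

log = logging.getLogger(__name__)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"
TOOL_NS = "urn:stressnet:map-annotation"

_NSMAP = {None: SBML_NS, "celldesigner": CD_NS, "stressnet": TOOL_NS}


class SBMLParseError(ValueError):
    """The file is not well-formed XML or not a usable SBML map."""


# CellDesigner species classes <-> our entity classes
_CD_CLASS = {
    "PROTEIN": "protein",
    "COMPLEX": "complex",
    "GENE": "gene",
    "RNA": "rna",
    "ANTISENSE_RNA": "rna",
    "SIMPLE_MOLECULE": "simple_molecule",
    "ION": "ion",
    "DRUG": "drug",
    "PHENOTYPE": "phenotype",
}
_CD_CLASS_INV = {
    "protein": "PROTEIN",
    "complex": "COMPLEX",
    "gene": "GENE",
    "rna": "RNA",
    "simple_molecule": "SIMPLE_MOLECULE",
    "ion": "ION",
    "drug": "DRUG",
    "phenotype": "PHENOTYPE",
    "unknown": "UNKNOWN",
}

# SBO fallbacks for plain-SBML files
_SBO_ENTITY = {
    "SBO:0000252": "protein",
    "SBO:0000297": "complex",
    "SBO:0000253": "complex",
    "SBO:0000243": "gene",
    "SBO:0000278": "rna",
    "SBO:0000250": "rna",
    "SBO:0000247": "simple_molecule",
    "SBO:0000327": "simple_molecule",
}

_CD_REACTION = {
    "STATE_TRANSITION": "state_transition",
    "KNOWN_TRANSITION_OMITTED": "state_transition",
    "UNKNOWN_TRANSITION": "state_transition",
    "HETERODIMER_ASSOCIATION": "association",
    "DISSOCIATION": "dissociation",
    "TRANSCRIPTION": "transcription",
    "TRANSLATION": "translation",
    "TRANSPORT": "transport",
}
_CD_REACTION_INV = {
    "state_transition": "STATE_TRANSITION",
    "association": "HETERODIMER_ASSOCIATION",
    "dissociation": "DISSOCIATION",
    "transcription": "TRANSCRIPTION",
    "translation": "TRANSLATION",
    "transport": "TRANSPORT",
    "other": "UNKNOWN_TRANSITION_TYPE",
}

_CD_MODTYPE = {
    "CATALYSIS": "positive",
    "UNKNOWN_CATALYSIS": "positive",
    "TRIGGER": "positive",
    "PHYSICAL_STIMULATION": "positive",
    "INHIBITION": "negative",
    "UNKNOWN_INHIBITION": "negative",
}
_CD_MODTYPE_INV = {
    "positive": "CATALYSIS",
    "negative": "INHIBITION",
    "unknown": "MODULATION",
}


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _find(el: etree._Element, path: str) -> etree._Element | None:
    return el.find(path, namespaces={"sbml": SBML_NS, "cd": CD_NS, "sn": TOOL_NS})


def _findall(el: etree._Element, path: str) -> list[etree._Element]:
    return el.findall(path, namespaces={"sbml": SBML_NS, "cd": CD_NS, "sn": TOOL_NS})


# ---------------------------------------------------------------------------
# reading

def read_celldesigner(
    path: str | Path,
    config: str | Path | dict | None = None,
) -> MolecularMap:
    """Parse an SBML/CellDesigner file into a :class:`MolecularMap`.

    Raises :class:`SBMLParseError` on malformed XML and
    :class:`~stressnet.map_model.MapValidationError` on dangling references.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLParseError(f"cannot parse {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise SBMLParseError(
            f"{path}: root element is <{etree.QName(root).localname}>, expected <sbml>"
        )
    model = next(
        (c for c in root if etree.QName(c).localname == "model"), None
    )
    if model is None:
        raise SBMLParseError(f"{path}: no <model> element")

    species: list[Species] = []
    components: dict[str, list[str]] = {}

    for sp in _iter_local(model, "listOfSpecies", "species"):
        species.append(_parse_species(sp))
    # CellDesigner keeps complex components in listOfIncludedSpecies inside
    # the model annotation
    for inc in _findall(
        model,
        "sbml:annotation/cd:extension/cd:listOfIncludedSpecies/cd:species",
    ) + _findall(model, "sbml:annotation/cd:listOfIncludedSpecies/cd:species"):
        s = _parse_included_species(inc)
        if s is None:
            continue
        sp_obj, parent = s
        species.append(sp_obj)
        components.setdefault(parent, []).append(sp_obj.id)

    by_id = {s.id: s for s in species}
    for parent, comp_ids in components.items():
        if parent in by_id:
            by_id[parent].components.extend(comp_ids)
            if by_id[parent].entity_class not in ("complex",):
                by_id[parent].entity_class = "complex"

    reactions = [
        _parse_reaction(rx) for rx in _iter_local(model, "listOfReactions", "reactions")
    ]

    m = MolecularMap(
        name=model.get("name") or model.get("id") or path.stem,
        species=species,
        reactions=reactions,
    )

    embedded = _read_tool_annotation(model, m)
    cfg = _load_config(config)
    aliases = dict(cfg.get("aliases", {})) if cfg else {}
    assign_gene_symbols(m, aliases=aliases)

    if cfg and ("stimuli" in cfg or "mrnas" in cfg):
        m.stimuli = _match_species(m, cfg.get("stimuli", []))
        m.mrnas = _match_species(m, cfg.get("mrnas", [])) - m.stimuli
    elif not embedded:
        _autodetect_sources_targets(m)

    m.validate()
    return m


def _iter_local(model, list_name, kind):
    for lst in model:
        if etree.QName(lst).localname == list_name:
            for el in lst:
                if isinstance(el.tag, str):
                    yield el
    return


def _parse_species(sp: etree._Element) -> Species:
    sid = sp.get("id")
    if not sid:
        raise SBMLParseError("species element without id")
    cls = "unknown"
    mods: list[tuple[str, str]] = []
    identity = _find(sp, "sbml:annotation/cd:extension/cd:speciesIdentity")
    if identity is None:
        identity = _find(sp, "sbml:annotation/cd:speciesIdentity")
    if identity is not None:
        cls_el = _find(identity, "cd:class")
        if cls_el is not None and cls_el.text:
            cls = _CD_CLASS.get(cls_el.text.strip().upper(), "unknown")
        for mod in _findall(
            identity, "cd:state/cd:listOfModifications/cd:modification"
        ):
            mods.append((mod.get("residue", ""), mod.get("state", "")))
    elif sp.get("sboTerm") in _SBO_ENTITY:
        cls = _SBO_ENTITY[sp.get("sboTerm")]
    comp_el = _find(sp, "sbml:annotation/sn:components")
    comps = (comp_el.text or "").split() if comp_el is not None else []
    gs_el = _find(sp, "sbml:annotation/sn:geneSymbols")
    gene_symbols = frozenset((gs_el.text or "").split()) if gs_el is not None else frozenset()
    meta_el = _find(sp, "sbml:annotation/sn:meta")
    meta = json.loads(meta_el.text) if meta_el is not None and meta_el.text else {}
    if comps and cls == "unknown":
        cls = "complex"
    return Species(
        id=sid,
        name=sp.get("name", sid),
        entity_class=cls,
        state_mods=mods,
        compartment=sp.get("compartment", "default"),
        components=comps,
        gene_symbols=gene_symbols,
        meta=meta,
    )


def _parse_included_species(inc: etree._Element):
    sid = inc.get("id")
    if sid is None:
        return None
    parent_el = _find(inc, "cd:annotation/cd:complexSpecies")
    parent = parent_el.text.strip() if parent_el is not None and parent_el.text else None
    cls = "unknown"
    cls_el = _find(inc, "cd:annotation/cd:speciesIdentity/cd:class")
    if cls_el is not None and cls_el.text:
        cls = _CD_CLASS.get(cls_el.text.strip().upper(), "unknown")
    if parent is None:
        return None
    return (
        Species(id=sid, name=inc.get("name", sid), entity_class=cls),
        parent,
    )


def _parse_reaction(rx: etree._Element) -> Reaction:
    rid = rx.get("id")
    if not rid:
        raise SBMLParseError("reaction element without id")
    rclass = "other"
    rt = _find(rx, "sbml:annotation/cd:extension/cd:reactionType")
    if rt is None:
        rt = _find(rx, "sbml:annotation/cd:reactionType")
    if rt is not None and rt.text:
        rclass = _CD_REACTION.get(rt.text.strip().upper(), "other")
    reactants = [
        sr.get("species")
        for sr in _findall(rx, "sbml:listOfReactants/sbml:speciesReference")
    ]
    products = [
        sr.get("species")
        for sr in _findall(rx, "sbml:listOfProducts/sbml:speciesReference")
    ]
    # per-modifier polarity from the celldesigner modification list
    polarity: dict[str, str] = {}
    for mod in _findall(
        rx, "sbml:annotation/cd:extension/cd:listOfModification/cd:modification"
    ) + _findall(rx, "sbml:annotation/cd:listOfModification/cd:modification"):
        mtype = _CD_MODTYPE.get((mod.get("type") or "").upper(), "unknown")
        for msid in (mod.get("modifiers") or mod.get("aliases") or "").split(","):
            if msid:
                polarity[msid] = mtype
    modifiers = [
        (sr.get("species"), polarity.get(sr.get("species"), "unknown"))
        for sr in _findall(rx, "sbml:listOfModifiers/sbml:modifierSpeciesReference")
    ]
    return Reaction(
        id=rid,
        reaction_class=rclass,
        reactants=reactants,
        products=products,
        modifiers=modifiers,
    )


def _read_tool_annotation(model: etree._Element, m: MolecularMap) -> bool:
    info = _find(model, "sbml:annotation/sn:info")
    if info is None:
        return False
    st = _find(info, "sn:stimuli")
    mr = _find(info, "sn:mrnas")
    m.stimuli = set((st.text or "").split()) if st is not None else set()
    m.mrnas = set((mr.text or "").split()) if mr is not None else set()
    return True


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, dict):
        return config
    text = Path(config).read_text()
    if str(config).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _match_species(m: MolecularMap, patterns: list[str]) -> set[str]:
    ids = m.species_ids()
    out: set[str] = set()
    for pat in patterns:
        if pat in ids:
            out.add(pat)
            continue
        hits = {s.id for s in m.species if s.name == pat or fnmatch.fnmatch(s.name, pat)}
        if not hits:
            log.warning("source/target pattern %r matched no species", pat)
        out |= hits
    return out


def _autodetect_sources_targets(m: MolecularMap) -> None:
    """Heuristic fallback: RNAs are targets; boundary small molecules / ions /
    drugs / phenotypes with no producing reaction are stimuli."""
    produced = {p for r in m.reactions for p in r.products}
    m.mrnas = {s.id for s in m.species if s.entity_class == "rna"}
    m.stimuli = {
        s.id
        for s in m.species
        if s.entity_class in {"simple_molecule", "ion", "drug", "phenotype"}
        and s.id not in produced
    } - m.mrnas
    if m.stimuli or m.mrnas:
        log.warning(
            "map %r: stimuli/mRNAs auto-detected (%d stimuli, %d mRNAs); "
            "supply a sidecar config to override",
            m.name, len(m.stimuli), len(m.mrnas),
        )


# ---------------------------------------------------------------------------
# writing

def write_celldesigner(m: MolecularMap, path: str | Path) -> None:
    """Serialize a map as SBML L2V4 with CellDesigner extension annotations.

    The output reparses via :func:`read_celldesigner` to an equal map.
    """
    m.validate()
    root = etree.Element(_q(SBML_NS, "sbml"), nsmap=_NSMAP, level="2", version="4")
    model = etree.SubElement(root, _q(SBML_NS, "model"))
    model.set("id", _sanitize_id(m.name) or "map")
    if m.name:
        model.set("name", m.name)

    ann = etree.SubElement(model, _q(SBML_NS, "annotation"))
    info = etree.SubElement(ann, _q(TOOL_NS, "info"))
    etree.SubElement(info, _q(TOOL_NS, "stimuli")).text = " ".join(sorted(m.stimuli))
    etree.SubElement(info, _q(TOOL_NS, "mrnas")).text = " ".join(sorted(m.mrnas))

    comps = sorted({s.compartment for s in m.species} | {"default"})
    loc = etree.SubElement(model, _q(SBML_NS, "listOfCompartments"))
    for c in comps:
        etree.SubElement(loc, _q(SBML_NS, "compartment"), id=c, size="1")

    los = etree.SubElement(model, _q(SBML_NS, "listOfSpecies"))
    for s in m.species:
        el = etree.SubElement(
            los, _q(SBML_NS, "species"),
            id=s.id, name=s.name, compartment=s.compartment,
            initialAmount="0",
        )
        sann = etree.SubElement(el, _q(SBML_NS, "annotation"))
        ext = etree.SubElement(sann, _q(CD_NS, "extension"))
        ident = etree.SubElement(ext, _q(CD_NS, "speciesIdentity"))
        etree.SubElement(ident, _q(CD_NS, "class")).text = _CD_CLASS_INV[s.entity_class]
        if s.state_mods:
            state = etree.SubElement(ident, _q(CD_NS, "state"))
            lom = etree.SubElement(state, _q(CD_NS, "listOfModifications"))
            for residue, st in s.state_mods:
                etree.SubElement(
                    lom, _q(CD_NS, "modification"), residue=residue, state=st
                )
        if s.components:
            etree.SubElement(sann, _q(TOOL_NS, "components")).text = " ".join(
                s.components
            )
        if s.gene_symbols and s.entity_class != "complex":
            etree.SubElement(sann, _q(TOOL_NS, "geneSymbols")).text = " ".join(
                sorted(s.gene_symbols)
            )
        if s.meta:
            etree.SubElement(sann, _q(TOOL_NS, "meta")).text = json.dumps(
                s.meta, sort_keys=True
            )

    lor = etree.SubElement(model, _q(SBML_NS, "listOfReactions"))
    for r in m.reactions:
        el = etree.SubElement(lor, _q(SBML_NS, "reaction"), id=r.id, reversible="false")
        rann = etree.SubElement(el, _q(SBML_NS, "annotation"))
        ext = etree.SubElement(rann, _q(CD_NS, "extension"))
        etree.SubElement(ext, _q(CD_NS, "reactionType")).text = _CD_REACTION_INV[
            r.reaction_class
        ]
        if r.modifiers:
            lomod = etree.SubElement(ext, _q(CD_NS, "listOfModification"))
            for sid, mclass in r.modifiers:
                etree.SubElement(
                    lomod, _q(CD_NS, "modification"),
                    type=_CD_MODTYPE_INV[mclass], modifiers=sid,
                )
        lre = etree.SubElement(el, _q(SBML_NS, "listOfReactants"))
        for sid in r.reactants:
            etree.SubElement(lre, _q(SBML_NS, "speciesReference"), species=sid)
        lpr = etree.SubElement(el, _q(SBML_NS, "listOfProducts"))
        for sid in r.products:
            etree.SubElement(lpr, _q(SBML_NS, "speciesReference"), species=sid)
        if r.modifiers:
            lmo = etree.SubElement(el, _q(SBML_NS, "listOfModifiers"))
            for sid, _ in r.modifiers:
                etree.SubElement(
                    lmo, _q(SBML_NS, "modifierSpeciesReference"), species=sid
                )

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _sanitize_id(name: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in name)
    if out and out[0].isdigit():
        out = "_" + out
    return out
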