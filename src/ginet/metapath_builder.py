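"""Conversion of one parsed pathway into a meta-pathway edge list.

The meta-pathway encoding makes signaling cascades and metabolic reactions
share one graph grammar.  Every reaction or relation is split in two steps
through an *intermediate* node that uniquely identifies the complex of
substrate(s) with (or without) the catalysing enzyme:

* type 1  subunit -> complex        (composition of enzyme complexes)
* type 2  enzyme  -> intermediate   (the enzyme joins the substrate)
* type 3  substrate -> intermediate
* type 4  intermediate -> product

Because an intermediate encodes the enzyme identity, isoenzymes catalysing
the same reaction get distinct intermediates, and the enzyme of a metabolic
reaction becomes reachable from whatever signaling cascade regulates it —
the structure that makes crosstalk analysis possible.  Edges from the
intermediate back to the enzyme (enzyme release) are intentionally absent:
the enzyme is unchanged by the reaction and keeping the edge would create
shortcuts without information.

Signaling relations (PPrel/PCrel) are encoded the same way, reading the
upstream effector as the "enzyme" and the downstream target as both
substrate and product (a signaling event modifies its target, it does not
consume it): U -> ITM[V|U] -> V, plus the V -> ITM[V|U] substrate edge.
The activation/inhibition annotation is carried on the type-2 edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ginet.complex_registry import (
    COMPLEX_PREFIX,
    EnzymeUnit,
    GroupExpansionError,
    complex_edges,
    expand_group,
)
from ginet.kgml_io import KgmlEntry, KgmlReaction, KgmlRelation, PathwayDoc

ITM_PREFIX = "ITM["
ITM_SUFFIX = "]"
ITM_SUBSTRATE_JOIN = ";"
ITM_ENZYME_SEP = "|"

#: KGML identifier prefixes denoting chemical species rather than genes
COMPOUND_PREFIXES = ("cpd:", "gl:", "dr:")

#: relation subtype -> edge sign; subtypes absent here are neutral
SUBTYPE_SIGNS = {
    "activation": "activation",
    "expression": "activation",
    "inhibition": "inhibition",
    "repression": "inhibition",
}

#: entry types that contribute nodes by default (map/ortholog opt-in)
DEFAULT_NODE_ENTRY_TYPES = frozenset({"gene", "compound", "group", "enzyme"})


class ConversionError(ValueError):
    pass


def node_class(value: str) -> str:
    """Classify a canonical node id: gene, compound, complex or intermediate."""
    if value.startswith(ITM_PREFIX):
        return "intermediate"
    if value.startswith(COMPLEX_PREFIX):
        return "complex"
    if value.startswith(COMPOUND_PREFIXES):
        return "compound"
    return "gene"


@dataclass(frozen=True, order=True)
class MetaEdge:
    source: str
    target: str
    edge_type: int  # 1..4
    sign: str  # activation | inhibition | neutral
    pathway_id: str = ""

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity without provenance; duplicates share this key."""
        return (self.source, self.target, self.edge_type, self.sign)

    @property
    def relation_label(self) -> str:
        label = f"t{self.edge_type}"
        if self.sign != "neutral":
            label += f":{self.sign}"
        return label


@dataclass
class MetaPathway:
    pathway_id: str
    edges: frozenset[MetaEdge] = field(default_factory=frozenset)

    @property
    def nodes(self) -> set[str]:
        return {e.source for e in self.edges} | {e.target for e in self.edges}

    def sorted_edges(self) -> list[MetaEdge]:
        return sorted(self.edges)


def intermediate_id(
    substrates: Iterable[str], enzyme: EnzymeUnit | str | None = None
) -> str:
    """Canonical id of the intermediate of ``substrates`` (+ optional enzyme).

    ``ITM[s1;s2|enzyme]`` with substrates sorted; the enzyme slot is the
    unit id (gene, ``CPLX[...]``) or the upstream effector of a signaling
    relation, empty for an uncatalysed reaction.  Identical substrates
    under different enzymes therefore produce distinct intermediates.
    """
    subs = sorted(set(substrates))
    if not subs:
        raise ConversionError("intermediate requires at least one substrate")
    if enzyme is None:
        enz = ""
    elif isinstance(enzyme, EnzymeUnit):
        enz = enzyme.unit_id
    else:
        enz = enzyme
    return f"{ITM_PREFIX}{ITM_SUBSTRATE_JOIN.join(subs)}{ITM_ENZYME_SEP}{enz}{ITM_SUFFIX}"


def parse_intermediate(value: str) -> tuple[tuple[str, ...], str]:
    """Split an intermediate id into (substrates, enzyme); enzyme may be ''."""
    if node_class(value) != "intermediate":
        raise ValueError(f"not an intermediate id: {value!r}")
    inner = value[len(ITM_PREFIX) : -len(ITM_SUFFIX)]
    subs_part, _, enzyme = inner.partition(ITM_ENZYME_SEP)
    return tuple(subs_part.split(ITM_SUBSTRATE_JOIN)), enzyme


def entry_units(entry: KgmlEntry, doc: PathwayDoc) -> list[EnzymeUnit]:
    """Resolve an entry into concrete enzyme units.

    A plain entry listing several gene ids is KEGG's isoenzyme convention:
    each name becomes its own monomer unit.  A group entry is a complex
    whose slots are its components; each component contributes its own
    alternatives (a nested group contributes its expanded units), and the
    Cartesian product over slots yields the units.
    """
    return _entry_units(entry, doc, frozenset())


def _entry_units(
    entry: KgmlEntry, doc: PathwayDoc, seen: frozenset[int]
) -> list[EnzymeUnit]:
    if entry.entry_id in seen:
        raise ConversionError(
            f"cyclic group nesting at entry {entry.entry_id} in {doc.pathway_id}"
        )
    if entry.entry_type != "group":
        if not entry.names:
            raise GroupExpansionError(f"entry {entry.entry_id} has no names")
        return [EnzymeUnit((name,)) for name in sorted(set(entry.names))]
    seen = seen | {entry.entry_id}
    # one slot per component; a component's alternatives are its own units
    slot_alternatives: list[list[tuple[str, ...]]] = []
    for cid in entry.component_refs:
        component = doc.entries[cid]
        slot_alternatives.append(
            [u.members for u in _entry_units(component, doc, seen)]
        )
    units: set[EnzymeUnit] = set()
    from itertools import product as _product

    for combo in _product(*slot_alternatives):
        members: set[str] = set()
        for member_tuple in combo:
            members.update(member_tuple)
        units.add(EnzymeUnit(tuple(sorted(members))))
    return sorted(units, key=lambda u: u.unit_id)


def _entry_node_values(entry: KgmlEntry) -> list[str]:
    """Node ids an entry stands for (one per name; isoenzymes split)."""
    return sorted(set(entry.names))


def relation_sign(subtypes: Sequence[str]) -> str:
    """Map KGML relation subtypes to an edge sign.

    Activation-like subtypes win over inhibition-like ones if a file lists
    both (not observed in practice); everything else (binding/association,
    phosphorylation alone, indirect effect, ...) is neutral.
    """
    signs = {SUBTYPE_SIGNS.get(s) for s in subtypes}
    if "activation" in signs:
        return "activation"
    if "inhibition" in signs:
        return "inhibition"
    return "neutral"


def convert_reaction(
    reaction: KgmlReaction,
    enzyme_units: Sequence[EnzymeUnit],
    doc: PathwayDoc,
    pathway_id: str | None = None,
) -> list[MetaEdge]:
    """Meta-edges of one metabolic reaction.

    A reversible reaction is split into two directed reactions; each
    direction and each enzyme unit gets its own intermediate, so the edge
    count of a reversible reaction is exactly twice its irreversible
    counterpart.  Only molecules present in the file appear — no lookup of
    full reaction equations, which keeps ubiquitous cofactors (ATP, NADH,
    ...) from short-circuiting unrelated pathways.
    """
    pid = doc.pathway_id if pathway_id is None else pathway_id

    def values(eids: Iterable[int]) -> list[str]:
        vals: list[str] = []
        for eid in eids:
            if eid not in doc.entries:
                raise ConversionError(
                    f"reaction {reaction.reaction_id}: unresolvable entry {eid}"
                )
            vals.extend(_entry_node_values(doc.entries[eid]))
        return sorted(set(vals))

    substrates = values(reaction.substrate_ids)
    products = values(reaction.product_ids)
    directions = [(substrates, products)]
    if reaction.direction == "reversible":
        directions.append((products, substrates))

    units: Sequence[EnzymeUnit | None] = list(enzyme_units) or [None]
    edges: list[MetaEdge] = []
    for unit in units:
        if unit is not None and unit.is_complex:
            edges.extend(complex_edges(unit, pid))
        for subs, prods in directions:
            itm = intermediate_id(subs, unit)
            if unit is not None:
                edges.append(MetaEdge(unit.unit_id, itm, 2, "neutral", pid))
            for s in subs:
                edges.append(MetaEdge(s, itm, 3, "neutral", pid))
            for p in prods:
                edges.append(MetaEdge(itm, p, 4, "neutral", pid))
    return edges


def convert_relation(
    rel: KgmlRelation,
    doc: PathwayDoc,
    pathway_id: str | None = None,
    mirror_binding: bool = False,
) -> list[MetaEdge]:
    """Meta-edges of one signaling relation (PPrel or PCrel).

    The upstream entry U acts on the downstream entry V through the
    intermediate ITM[V|U]: U->ITM (type 2, carrying the activation or
    inhibition sign), V->ITM (type 3) and ITM->V (type 4).  Group entries
    are resolved to their enzyme units, one triplet per unit combination.
    With ``mirror_binding``, undirected binding/association relations also
    emit the reciprocal triplet.
    """
    if rel.rel_type not in ("PPrel", "PCrel"):
        raise ConversionError(
            f"relation {rel.entry1}->{rel.entry2} has type {rel.rel_type!r}; "
            "only PPrel/PCrel convert"
        )
    pid = doc.pathway_id if pathway_id is None else pathway_id
    sign = relation_sign(rel.subtypes)

    def resolve(eid: int) -> list[tuple[str, EnzymeUnit | None]]:
        entry = doc.entries[eid]
        if entry.entry_type == "compound":
            return [(v, None) for v in _entry_node_values(entry)]
        units = entry_units(entry, doc)
        return [(u.unit_id, u) for u in units]

    upstream = resolve(rel.entry1)
    downstream = resolve(rel.entry2)

    edges: list[MetaEdge] = []
    seen_units: set[EnzymeUnit] = set()

    def triplet(u_val: str, v_val: str, edge_sign: str) -> None:
        itm = intermediate_id([v_val], u_val)
        edges.append(MetaEdge(u_val, itm, 2, edge_sign, pid))
        edges.append(MetaEdge(v_val, itm, 3, "neutral", pid))
        edges.append(MetaEdge(itm, v_val, 4, "neutral", pid))

    for u_val, u_unit in upstream:
        for v_val, v_unit in downstream:
            for unit in (u_unit, v_unit):
                if unit is not None and unit.is_complex and unit not in seen_units:
                    seen_units.add(unit)
                    edges.extend(complex_edges(unit, pid))
            triplet(u_val, v_val, sign)
            if mirror_binding and "binding/association" in rel.subtypes:
                triplet(v_val, u_val, sign)
    return edges


def build_metapathway(
    doc: PathwayDoc,
    include_map_entries: bool = False,
    mirror_binding: bool = False,
) -> MetaPathway:
    """Convert a whole pathway document into one de-duplicated meta-pathway.

    Reactions contribute intermediate expansions per enzyme unit; PPrel and
    PCrel relations contribute signaling triplets; multi-subunit enzyme
    complexes contribute their type-1 composition edges.  Entries of type
    ``map`` (links to other pathway maps) and ``ortholog`` carry no
    species-specific molecule and are skipped unless requested.
    """
    allowed = set(DEFAULT_NODE_ENTRY_TYPES)
    if include_map_entries:
        allowed |= {"map", "ortholog"}

    def usable(eid: int) -> bool:
        entry = doc.entries.get(eid)
        return entry is not None and entry.entry_type in allowed

    edges: set[MetaEdge] = set()
    for reaction in doc.reactions:
        if not all(usable(e) for e in (*reaction.substrate_ids, *reaction.product_ids)):
            continue
        units: list[EnzymeUnit] = []
        for eid in reaction.enzyme_entry_ids:
            if usable(eid):
                units.extend(entry_units(doc.entries[eid], doc))
        units = sorted(set(units), key=lambda u: u.unit_id)
        edges.update(convert_reaction(reaction, units, doc))
    for rel in doc.relations:
        if rel.rel_type not in ("PPrel", "PCrel"):
            continue
        if not (usable(rel.entry1) and usable(rel.entry2)):
            continue
        edges.update(convert_relation(rel, doc, mirror_binding=mirror_binding))
    # collapse provenance-free duplicates (same pathway here, so key-level)
    deduped = {e.key: e for e in sorted(edges)}
    return MetaPathway(pathway_id=doc.pathway_id, edges=frozenset(deduped.values()))


def check_metapathway(mp: MetaPathway) -> list[str]:
    """Structural violations of the meta-pathway invariants (empty = ok).

    Checks that every intermediate has an incoming type-3 and an outgoing
    type-4 edge, that intermediates never appear where the grammar forbids
    them, and that no enzyme-release edge (intermediate -> its own enzyme)
    exists.
    """
    problems: list[str] = []
    in3: set[str] = set()
    out4: set[str] = set()
    intermediates = {n for n in mp.nodes if node_class(n) == "intermediate"}
    for e in mp.edges:
        if e.edge_type in (1, 2, 3) and node_class(e.source) == "intermediate":
            problems.append(f"intermediate as source of type {e.edge_type}: {e}")
        if e.edge_type == 4 and node_class(e.target) == "intermediate":
            problems.append(f"intermediate as target of type 4: {e}")
        if e.edge_type == 3 and node_class(e.target) == "intermediate":
            in3.add(e.target)
        if e.edge_type == 4 and node_class(e.source) == "intermediate":
            out4.add(e.source)
        if node_class(e.source) == "intermediate":
            _, enzyme = parse_intermediate(e.source)
            if enzyme and e.target == enzyme:
                problems.append(f"enzyme-release edge present: {e}")
    for itm in intermediates - in3:
        problems.append(f"intermediate without incoming type-3 edge: {itm}")
    for itm in intermediates - out4:
        problems.append(f"intermediate without outgoing type-4 edge: {itm}")
    return problems


def write_metapath_sif(mp: MetaPathway, path) -> None:
    """Write a meta-pathway as SIF (source, relation-label, target).

    The relation label is ``t<1-4>`` with an optional ``:activation`` /
    ``:inhibition`` suffix; rows sorted lexicographically for diff-stable
    output.  A ``.provenance.tsv`` sidecar records the pathway id per edge.
    """
    from ginet import gin_assembler  # single SIF implementation lives there

    gin_assembler.write_sif(gin_assembler.metapathways_to_gin([mp]), path)
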