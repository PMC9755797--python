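"""Reading, validating and writing KGML pathway files.

KGML is KEGG's XML dialect for pathway maps.  A file holds ``entry``
elements (genes, compounds, groups/complexes, map links), ``reaction``
elements (substrates/products referencing entries, catalysed by the entries
whose ``reaction`` attribute names them) and ``relation`` elements (PPrel
protein-protein and PCrel protein-compound signaling edges).

This module parses those files into a neutral in-memory representation
(:class:`PathwayDoc`); no graph semantics are applied here.  Graph
construction lives in :mod:`ginet.metapath_builder`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

#: entry types KGML uses that this pipeline understands
KNOWN_ENTRY_TYPES = frozenset(
    {"gene", "compound", "group", "map", "ortholog", "enzyme"}
)

#: relation types carrying signaling semantics; everything else is "other"
SIGNALING_REL_TYPES = frozenset({"PPrel", "PCrel"})


class KgmlParseError(ValueError):
    """Raised for malformed XML; the message names the offending line."""


class KgmlValidationError(ValueError):
    """Raised when a file references entry ids that do not exist."""


@dataclass(frozen=True)
class KgmlEntry:
    """One ``entry`` element: a gene, compound, group, map link etc.

    ``names`` may hold several KEGG identifiers for a single entry — KEGG's
    convention for isoenzymes sharing one box on the map.  ``reaction_ref``
    is the verbatim ``reaction`` attribute (possibly several space-separated
    reaction names).  ``component_refs`` is non-empty only for groups.
    """

    entry_id: int
    entry_type: str
    names: tuple[str, ...]
    reaction_ref: str | None = None
    component_refs: tuple[int, ...] = ()

    def reaction_names(self) -> tuple[str, ...]:
        return tuple(self.reaction_ref.split()) if self.reaction_ref else ()


@dataclass(frozen=True)
class KgmlReaction:
    reaction_id: str
    direction: str  # "reversible" | "irreversible"
    substrate_ids: tuple[int, ...]
    product_ids: tuple[int, ...]
    enzyme_entry_ids: tuple[int, ...]


@dataclass(frozen=True)
class KgmlRelation:
    entry1: int
    entry2: int
    rel_type: str  # "PPrel" | "PCrel" | "other"
    subtypes: tuple[str, ...]
    raw_type: str = ""  # verbatim KGML type for rel_type == "other"


@dataclass
class PathwayDoc:
    """Parsed contents of one KGML file."""

    pathway_id: str
    species_code: str
    title: str = ""
    entries: dict[int, KgmlEntry] = field(default_factory=dict)
    reactions: tuple[KgmlReaction, ...] = ()
    relations: tuple[KgmlRelation, ...] = ()

    def entries_of_type(self, entry_type: str) -> Iterator[KgmlEntry]:
        for entry in self.entries.values():
            if entry.entry_type == entry_type:
                yield entry


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    message: str
    element: str
    severity: str = "error"  # "error" | "info"


def _canonical_reactions(
    reactions: Iterable[KgmlReaction],
) -> tuple[KgmlReaction, ...]:
    return tuple(
        sorted(
            reactions,
            key=lambda r: (r.reaction_id, r.direction, r.substrate_ids),
        )
    )


def _canonical_relations(
    relations: Iterable[KgmlRelation],
) -> tuple[KgmlRelation, ...]:
    return tuple(
        sorted(
            relations,
            key=lambda r: (r.entry1, r.entry2, r.rel_type, r.subtypes),
        )
    )


def parse_kgml(xml_text: str | bytes) -> PathwayDoc:
    """Parse one KGML document into a :class:`PathwayDoc`.

    Entries are keyed by id and reactions/relations stored in a canonical
    sort order, so the result is independent of element order in the file.

    Raises
    ------
    KgmlParseError
        for malformed XML (the message carries the line number).
    KgmlValidationError
        when a reaction or relation references an entry id that does not
        exist in the file.
    """
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message shape
        raise KgmlParseError(f"malformed KGML at line {exc.lineno}: {exc.msg}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"root element is <{root.tag}>, expected <pathway>")

    raw_name = root.get("name", "")  # e.g. "path:hsa04010"
    pathway_id = raw_name.split(":")[-1] if raw_name else ""
    species = root.get("org", "") or (pathway_id[:3] if pathway_id else "")
    title = root.get("title", "")

    entries: dict[int, KgmlEntry] = {}
    for el in root.findall("entry"):
        entry_id = int(el.get("id"))
        if entry_id in entries:
            raise KgmlValidationError(f"duplicate entry id {entry_id}")
        names = tuple(el.get("name", "").split())
        components = tuple(int(c.get("id")) for c in el.findall("component"))
        entries[entry_id] = KgmlEntry(
            entry_id=entry_id,
            entry_type=el.get("type", ""),
            names=names,
            reaction_ref=el.get("reaction"),
            component_refs=components,
        )

    # enzymes of a reaction = entries whose reaction attribute names it
    enzymes_by_reaction: dict[str, list[int]] = {}
    for entry in entries.values():
        for rname in entry.reaction_names():
            enzymes_by_reaction.setdefault(rname, []).append(entry.entry_id)

    reactions = []
    dangling: list[int] = []
    for el in root.findall("reaction"):
        rname = el.get("name", "")
        substrates = tuple(int(s.get("id")) for s in el.findall("substrate"))
        products = tuple(int(p.get("id")) for p in el.findall("product"))
        for eid in (*substrates, *products):
            if eid not in entries:
                dangling.append(eid)
        reactions.append(
            KgmlReaction(
                reaction_id=rname,
                direction=el.get("type", "irreversible"),
                substrate_ids=substrates,
                product_ids=products,
                enzyme_entry_ids=tuple(sorted(enzymes_by_reaction.get(rname, []))),
            )
        )

    relations = []
    for el in root.findall("relation"):
        e1, e2 = int(el.get("entry1")), int(el.get("entry2"))
        for eid in (e1, e2):
            if eid not in entries:
                dangling.append(eid)
        raw_type = el.get("type", "")
        rel_type = raw_type if raw_type in SIGNALING_REL_TYPES else "other"
        subtypes = tuple(s.get("name", "") for s in el.findall("subtype"))
        relations.append(
            KgmlRelation(
                entry1=e1,
                entry2=e2,
                rel_type=rel_type,
                subtypes=subtypes,
                raw_type=raw_type,
            )
        )

    for entry in entries.values():
        for cid in entry.component_refs:
            if cid not in entries:
                dangling.append(cid)

    if dangling:
        ids = ", ".join(str(i) for i in sorted(set(dangling)))
        raise KgmlValidationError(f"dangling entry reference(s): {ids}")

    return PathwayDoc(
        pathway_id=pathway_id,
        species_code=species,
        title=title,
        entries=dict(sorted(entries.items())),
        reactions=_canonical_reactions(reactions),
        relations=_canonical_relations(relations),
    )


def validate_pathway(
    doc: PathwayDoc, include_info: bool = False
) -> list[ValidationIssue]:
    """Check the structural invariants of a :class:`PathwayDoc`.

    Returns an empty list iff every invariant holds.  Issues are data, not
    exceptions, so a caller can triage them.  Self-relations are legal KGML
    and reported only as ``info`` records (hidden unless ``include_info``).
    """
    issues: list[ValidationIssue] = []

    def dangling(eid: int, where: str) -> None:
        issues.append(
            ValidationIssue(
                kind="dangling_reference",
                message=f"{where} references unknown entry id {eid}",
                element=str(eid),
            )
        )

    for entry in doc.entries.values():
        if entry.entry_type == "group":
            if len(entry.component_refs) < 2:
                issues.append(
                    ValidationIssue(
                        kind="degenerate_group",
                        message=(
                            f"group entry {entry.entry_id} has "
                            f"{len(entry.component_refs)} component(s); need >= 2"
                        ),
                        element=str(entry.entry_id),
                    )
                )
            for cid in entry.component_refs:
                if cid not in doc.entries:
                    dangling(cid, f"group {entry.entry_id}")
        else:
            if not entry.names:
                issues.append(
                    ValidationIssue(
                        kind="empty_names",
                        message=f"entry {entry.entry_id} has no names",
                        element=str(entry.entry_id),
                    )
                )
        if entry.entry_type not in KNOWN_ENTRY_TYPES:
            issues.append(
                ValidationIssue(
                    kind="unknown_entry_type",
                    message=(
                        f"entry {entry.entry_id} has unrecognised type "
                        f"{entry.entry_type!r}"
                    ),
                    element=str(entry.entry_id),
                )
            )

    for reaction in doc.reactions:
        if not reaction.substrate_ids or not reaction.product_ids:
            issues.append(
                ValidationIssue(
                    kind="empty_reaction_side",
                    message=f"reaction {reaction.reaction_id} lacks substrates or products",
                    element=reaction.reaction_id,
                )
            )
        if reaction.direction not in ("reversible", "irreversible"):
            issues.append(
                ValidationIssue(
                    kind="bad_direction",
                    message=(
                        f"reaction {reaction.reaction_id} direction "
                        f"{reaction.direction!r}"
                    ),
                    element=reaction.reaction_id,
                )
            )
        for eid in (
            *reaction.substrate_ids,
            *reaction.product_ids,
            *reaction.enzyme_entry_ids,
        ):
            if eid not in doc.entries:
                dangling(eid, f"reaction {reaction.reaction_id}")

    for rel in doc.relations:
        for eid in (rel.entry1, rel.entry2):
            if eid not in doc.entries:
                dangling(eid, f"relation {rel.entry1}->{rel.entry2}")
        if rel.entry1 == rel.entry2:
            issues.append(
                ValidationIssue(
                    kind="self_relation",
                    message=f"relation {rel.entry1}->{rel.entry2} is a self-relation",
                    element=str(rel.entry1),
                    severity="info",
                )
            )

    if include_info:
        return issues
    return [i for i in issues if i.severity == "error"]


def serialize_kgml(doc: PathwayDoc) -> str:
    """Write a :class:`PathwayDoc` back to KGML text (canonical order).

    ``parse_kgml(serialize_kgml(doc))`` equals ``doc`` field by field; the
    output is byte-stable, so serialisation is usable for fixtures and
    round-trip testing.  Graphics attributes are never emitted (they are
    dropped at parse time).
    """
    root = etree.Element(
        "pathway",
        name=f"path:{doc.pathway_id}",
        org=doc.species_code,
        title=doc.title,
    )
    for entry in sorted(doc.entries.values(), key=lambda e: e.entry_id):
        attrs = {
            "id": str(entry.entry_id),
            "name": " ".join(entry.names),
            "type": entry.entry_type,
        }
        if entry.reaction_ref:
            attrs["reaction"] = entry.reaction_ref
        el = etree.SubElement(root, "entry", **attrs)
        for cid in entry.component_refs:
            etree.SubElement(el, "component", id=str(cid))
    for rel in _canonical_relations(doc.relations):
        el = etree.SubElement(
            root,
            "relation",
            entry1=str(rel.entry1),
            entry2=str(rel.entry2),
            type=rel.raw_type or rel.rel_type,
        )
        for name in rel.subtypes:
            etree.SubElement(el, "subtype", name=name, value="")
    for reaction in _canonical_reactions(doc.reactions):
        el = etree.SubElement(
            root, "reaction", name=reaction.reaction_id, type=reaction.direction
        )
        for sid in reaction.substrate_ids:
            name = " ".join(doc.entries[sid].names) if sid in doc.entries else ""
            etree.SubElement(el, "substrate", id=str(sid), name=name)
        for pid in reaction.product_ids:
            name = " ".join(doc.entries[pid].names) if pid in doc.entries else ""
            etree.SubElement(el, "product", id=str(pid), name=name)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def load_kgml_dir(directory: str | Path, pattern: str = "*.xml") -> list[PathwayDoc]:
    """Parse every KGML file matching ``pattern`` under ``directory``."""
    directory = Path(directory)
    docs = [parse_kgml(p.read_bytes()) for p in sorted(directory.glob(pattern))]
    return docs


def doc_to_json(doc: PathwayDoc) -> str:
    """Debug dump of a PathwayDoc as JSON (entries keyed by id)."""
    payload = {
        "pathway_id": doc.pathway_id,
        "species_code": doc.species_code,
        "title": doc.title,
        "entries": {str(k): asdict(v) for k, v in doc.entries.items()},
        "reactions": [asdict(r) for r in doc.reactions],
        "relations": [asdict(r) for r in doc.relations],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
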