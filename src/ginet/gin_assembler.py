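"""Merging meta-pathways into a species-level Global Integrative Network.

A GIN is the union of all meta-pathways of one species with redundant
edges (the same relation appearing in several pathway maps) collapsed to a
single edge that remembers every contributing pathway.  The graph is
serialised as SIF (simple interaction file): three tab-separated columns
``source  relation-label  target``, the interchange format Cytoscape and
igraph read directly.  A sidecar TSV carries per-edge pathway provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from ginet.metapath_builder import (
    MetaEdge,
    MetaPathway,
    node_class,
    parse_intermediate,
)

_REL_LABEL_RE = re.compile(r"^t([1-4])(?::(activation|inhibition))?$")


class SifFormatError(ValueError):
    pass


class MergeError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GinEdge:
    """One de-duplicated GIN edge; provenance lists contributing pathways."""

    source: str
    target: str
    edge_type: int
    sign: str
    provenance: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.source, self.target, self.edge_type, self.sign)

    @property
    def relation_label(self) -> str:
        label = f"t{self.edge_type}"
        if self.sign != "neutral":
            label += f":{self.sign}"
        return label


@dataclass
class GIN:
    species_code: str
    edges: frozenset[GinEdge] = field(default_factory=frozenset)

    @property
    def nodes(self) -> set[str]:
        return {e.source for e in self.edges} | {e.target for e in self.edges}

    def sorted_edges(self) -> list[GinEdge]:
        return sorted(self.edges, key=lambda e: (e.source, e.relation_label, e.target))

    def to_digraph(self) -> nx.DiGraph:
        """Plain directed graph; edge types are not discriminated."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GIN):
            return NotImplemented
        return self.species_code == other.species_code and self.edges == other.edges


@dataclass
class SubnetLabeling:
    """Numeric labels for weakly connected components with > 10 nodes.

    Label 1 is the largest component; labels increase with decreasing
    size (ties broken by the lexicographically smallest member node).
    Nodes in components of 10 or fewer nodes stay unlabeled.
    """

    assignments: dict[str, int]
    component_sizes: dict[int, int]

    def nodes_of(self, label: int) -> set[str]:
        return {n for n, lab in self.assignments.items() if lab == label}


def species_of_pathway(pathway_id: str) -> str:
    """Leading alphabetic organism code of a KEGG-style pathway id."""
    match = re.match(r"^([A-Za-z]+)", pathway_id)
    return match.group(1) if match else ""


def _collapse(edges: Iterable[tuple[tuple, frozenset[str]]]) -> frozenset[GinEdge]:
    by_key: dict[tuple, set[str]] = {}
    for key, prov in edges:
        by_key.setdefault(key, set()).update(prov)
    return frozenset(
        GinEdge(*key, provenance=frozenset(prov)) for key, prov in by_key.items()
    )


def metapathways_to_gin(paths: Iterable[MetaPathway], species_code: str | None = None) -> GIN:
    return merge_metapathways(list(paths), species_code=species_code)


def merge_metapathways(
    paths: Iterable[MetaPathway], species_code: str | None = None
) -> GIN:
    """Union meta-pathways into one GIN, collapsing duplicate edges.

    Edges identical up to provenance merge into one edge whose provenance
    is the union of contributing pathway ids — this is where relations
    shared by overlapping pathway maps become a single GIN edge.  The
    operation is idempotent, commutative and associative.  All pathways
    must belong to one species (checked from the pathway-id prefix unless
    ``species_code`` is given explicitly).
    """
    paths = list(paths)
    codes = {species_of_pathway(p.pathway_id) for p in paths if p.pathway_id}
    if species_code is None:
        if len(codes) > 1:
            raise MergeError(f"mixed species codes in merge: {sorted(codes)}")
        species_code = next(iter(codes), "")
    elif codes - {species_code}:
        raise MergeError(
            f"pathways of species {sorted(codes - {species_code})} "
            f"cannot merge into a {species_code} GIN"
        )
    pairs = [
        (e.key, frozenset({e.pathway_id} if e.pathway_id else set()))
        for p in paths
        for e in p.edges
    ]
    return GIN(species_code=species_code, edges=_collapse(pairs))


def merge_gins(*gins: GIN) -> GIN:
    """Union of already-merged GINs (same species), provenance preserved."""
    codes = {g.species_code for g in gins if g.species_code}
    if len(codes) > 1:
        raise MergeError(f"mixed species codes in merge: {sorted(codes)}")
    pairs = [(e.key, e.provenance) for g in gins for e in g.edges]
    return GIN(species_code=next(iter(codes), ""), edges=_collapse(pairs))


def write_sif(gin: GIN, path: str | Path) -> None:
    """Write a GIN as canonical SIF plus a provenance sidecar.

    Rows sort lexicographically by (source, relation-label, target), so a
    given GIN always produces byte-identical files.  The sidecar
    ``<path>.prov.tsv`` stores the species code and the comma-joined
    pathway ids behind each edge; :func:`read_sif` restores both.
    """
    path = Path(path)
    rows = gin.sorted_edges()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for e in rows:
            fh.write(f"{e.source}\t{e.relation_label}\t{e.target}\n")
    with open(_sidecar(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#species={gin.species_code}\n")
        for e in rows:
            prov = ",".join(sorted(e.provenance))
            fh.write(f"{e.source}\t{e.relation_label}\t{e.target}\t{prov}\n")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".prov.tsv")


def parse_relation_label(label: str) -> tuple[int, str]:
    match = _REL_LABEL_RE.match(label)
    if not match:
        raise SifFormatError(f"unrecognised relation label {label!r}")
    return int(match.group(1)), match.group(2) or "neutral"


def read_sif(path: str | Path) -> GIN:
    """Read a SIF file (and its provenance sidecar if present) into a GIN."""
    path = Path(path)
    provenance: dict[tuple, frozenset[str]] = {}
    species = ""
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#species="):
                    species = line.split("=", 1)[1]
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise SifFormatError(
                        f"{sidecar}:{lineno}: expected 4 tab-separated fields"
                    )
                src, label, dst, prov = parts
                etype, sign = parse_relation_label(label)
                provenance[(src, dst, etype, sign)] = frozenset(
                    p for p in prov.split(",") if p
                )
    edges: set[GinEdge] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SifFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            src, label, dst = parts
            etype, sign = parse_relation_label(label)
            key = (src, dst, etype, sign)
            edges.add(GinEdge(*key, provenance=provenance.get(key, frozenset())))
    return GIN(species_code=species, edges=frozenset(edges))


def label_subnets(gin: GIN, min_size: int = 10) -> SubnetLabeling:
    """Label weakly connected components with more than ``min_size`` nodes.

    Weak connectivity is used deliberately: the GIN is directed, but a
    sub-network in the assembly sense is a piece of the drawing, not a
    strongly connected region.  Components are ranked by decreasing size,
    ties broken by lexicographically smallest member, and numbered from 1
    (the largest).
    """
    graph = gin.to_digraph()
    components = sorted(
        (sorted(c) for c in nx.weakly_connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    assignments: dict[str, int] = {}
    sizes: dict[int, int] = {}
    label = 0
    for comp in components:
        if len(comp) <= min_size:
            continue
        label += 1
        sizes[label] = len(comp)
        for node in comp:
            assignments[node] = label
    return SubnetLabeling(assignments=assignments, component_sizes=sizes)


def classify_nodes(gin: GIN) -> dict[str, str]:
    """Partition nodes into ``compound_related`` vs ``protein_only``.

    Compound nodes, and intermediates that include a compound in any slot
    (substrates or the effector of a compound-driven signaling relation),
    are compound-related; genes, complexes and protein-only intermediates
    are not.
    """
    result: dict[str, str] = {}
    for node in gin.nodes:
        cls = node_class(node)
        if cls == "compound":
            related = True
        elif cls == "intermediate":
            substrates, enzyme = parse_intermediate(node)
            parts = list(substrates) + ([enzyme] if enzyme else [])
            related = any(node_class(p) == "compound" for p in parts)
        else:
            related = False
        result[node] = "compound_related" if related else "protein_only"
    return result


def gin_stats(gin: GIN) -> dict[str, float]:
    """Summary counts of a GIN (all computed, nothing cached).

    Returns node/edge/intermediate/complex counts, the fraction of
    compound-related nodes, and the fraction of nodes inside the largest
    sub-network (subnet 1).  Empty GIN gives all zeros.
    """
    nodes = gin.nodes
    n = len(nodes)
    if n == 0:
        return {
            "node_count": 0,
            "edge_count": 0,
            "intermediate_count": 0,
            "complex_count": 0,
            "compound_related_fraction": 0.0,
            "subnet1_fraction": 0.0,
        }
    classes = classify_nodes(gin)
    n_compound_related = sum(1 for v in classes.values() if v == "compound_related")
    largest = max(
        (len(c) for c in nx.weakly_connected_components(gin.to_digraph())),
        default=0,
    )
    return {
        "node_count": n,
        "edge_count": len(gin.edges),
        "intermediate_count": sum(
            1 for v in nodes if node_class(v) == "intermediate"
        ),
        "complex_count": sum(1 for v in nodes if node_class(v) == "complex"),
        "compound_related_fraction": n_compound_related / n,
        "subnet1_fraction": largest / n,
    }


def write_stats(gin: GIN, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(gin_stats(gin), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_subnet_labels(labeling: SubnetLabeling, path: str | Path) -> None:
    """Two-column TSV: node, subnet label (labeled nodes only)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for node in sorted(labeling.assignments):
            fh.write(f"{node}\t{labeling.assignments[node]}\n")


def edges_from_mapping(
    species_code: str, edge_rows: Iterable[Mapping]
) -> GIN:  # pragma: no cover - convenience constructor
    edges = frozenset(
        GinEdge(
            source=r["source"],
            target=r["target"],
            edge_type=int(r.get("edge_type", 2)),
            sign=r.get("sign", "neutral"),
            provenance=frozenset(r.get("provenance", ())),
        )
        for r in edge_rows
    )
    return GIN(species_code=species_code, edges=edges)
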