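"""Pathway-pathway crosstalk analysis on a GIN.

Crosstalk between two pathways is measured as directed shortest paths in
the GIN between their member molecules (genes and compounds; intermediates
are construction artifacts, never endpoints).  Distances count the number
of nodes on the path, so two adjacent nodes are at distance 2.  Each
reachable ordered pair receives a display weight

    W = (2 / n_shortest) ** 2

which is 1 for a direct connection and decays quadratically, suppressing
long detours in bipartite connection plots.  Before the analysis, known
annotation artifacts (e.g. an extracellular ligand wired directly onto a
receptor inside a cell-interior map) can be removed by a curation list;
removing an edge pair also removes the signaling triplet built through
its intermediate.

Activation/inhibition signs never block traversal — an inhibitory edge is
still a path of information flow — but they are reported along retained
paths.
"""

from __future__ import annotations

import fnmatch
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from ginet.gin_assembler import GIN
from ginet.kgml_io import PathwayDoc
from ginet.metapath_builder import (
    DEFAULT_NODE_ENTRY_TYPES,
    intermediate_id,
    node_class,
    parse_intermediate,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurationRemoval:
    source: str  # exact node id or fnmatch-style wildcard
    target: str
    reason: str = ""


@dataclass
class CurationList:
    removals: tuple[CurationRemoval, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationList":
        with open(path, encoding="utf-8") as fh:
            entries = yaml.safe_load(fh) or []
        return cls(
            removals=tuple(
                CurationRemoval(
                    source=str(e["source"]),
                    target=str(e["target"]),
                    reason=str(e.get("reason", "")),
                )
                for e in entries
            )
        )


@dataclass(frozen=True)
class PairPath:
    node_a: str
    node_b: str
    direction: str  # "a_to_b" | "b_to_a"
    distance: float  # node count of the shortest path; math.inf if unreachable
    path: tuple[str, ...] | None

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.distance)

    @property
    def weight(self) -> float:
        if not self.reachable:
            return 0.0
        return edge_weight(int(self.distance))


@dataclass
class CrosstalkResult:
    pairs: list[PairPath]
    retained: dict[str, PairPath | None]
    shared_nodes: tuple[str, ...] = ()
    missing_nodes: tuple[str, ...] = field(default=())


def _matches(value: str, pattern: str) -> bool:
    if pattern == "*":
        return True
    if any(ch in pattern for ch in "*?"):
        return fnmatch.fnmatchcase(value, pattern)
    return value == pattern


def _edge_matches_removal(edge, removal: CurationRemoval) -> bool:
    if _matches(edge.source, removal.source) and _matches(edge.target, removal.target):
        return True
    # triplet form: the pair was expanded through ITM[target|source]
    for endpoint in (edge.source, edge.target):
        if node_class(endpoint) == "intermediate":
            substrates, enzyme = parse_intermediate(endpoint)
            if enzyme and _matches(enzyme, removal.source) and any(
                _matches(s, removal.target) for s in substrates
            ):
                return True
    return False


def apply_curation(gin: GIN, cur: CurationList) -> GIN:
    """Drop curated edges (and their intermediate triplets) from a GIN.

    A removal (S, T) deletes any direct edge S->T and every edge touching
    the intermediate ITM[T|S] that the signaling triplet for that pair
    created.  A removal matching nothing logs a warning; it is not an
    error, because curation lists are shared across KEGG releases.
    """
    kept = set(gin.edges)
    for removal in cur.removals:
        hit = {e for e in kept if _edge_matches_removal(e, removal)}
        if not hit:
            logger.warning(
                "curation removal (%s -> %s) matched no edges",
                removal.source,
                removal.target,
            )
            continue
        logger.info(
            "curation removal (%s -> %s): %d edge(s) removed (%s)",
            removal.source,
            removal.target,
            len(hit),
            removal.reason or "no reason given",
        )
        kept -= hit
    return GIN(species_code=gin.species_code, edges=frozenset(kept))


def pathway_members(
    doc: PathwayDoc, include_map_entries: bool = False
) -> set[str]:
    """Gene and compound node ids belonging to a pathway.

    Group (complex) entries contribute their constituent genes — a complex
    node itself is a GIN construction, not a pathway member, and
    intermediates never appear.
    """
    allowed = set(DEFAULT_NODE_ENTRY_TYPES)
    if include_map_entries:
        allowed |= {"map", "ortholog"}
    members: set[str] = set()

    def visit(entry_id: int, seen: frozenset[int]) -> None:
        if entry_id in seen or entry_id not in doc.entries:
            return
        entry = doc.entries[entry_id]
        if entry.entry_type not in allowed:
            return
        if entry.entry_type == "group":
            for cid in entry.component_refs:
                visit(cid, seen | {entry_id})
        else:
            members.update(entry.names)

    for eid in doc.entries:
        visit(eid, frozenset())
    return members


def _lexicographic_shortest_path(
    graph: nx.DiGraph,
    source: str,
    target: str,
    dist_from_source: Mapping[str, int],
    dist_to_target: Mapping[str, int],
) -> tuple[str, ...]:
    """Lexicographically smallest node sequence among all shortest paths.

    Greedy reconstruction: at every step take the smallest successor that
    still lies on some shortest path (its forward distance is one more and
    its remaining distance to the target one less).
    """
    total = dist_from_source[target]
    path = [source]
    current = source
    step = 0
    while current != target:
        remaining = total - step - 1
        candidates = [
            nxt
            for nxt in graph.successors(current)
            if dist_from_source.get(nxt) == step + 1
            and dist_to_target.get(nxt) == remaining
        ]
        current = min(candidates)
        path.append(current)
        step += 1
    return tuple(path)


def shortest_paths_between(
    gin: GIN, set_a: Iterable[str], set_b: Iterable[str]
) -> CrosstalkResult:
    """Directed shortest paths for every ordered node pair across pathways.

    Nodes belonging to both member sets are excluded from the endpoint
    sets (and reported); nodes absent from the GIN are reported and give
    unreachable pairs.  Unweighted BFS distances; ties between equal-length
    paths break to the lexicographically smallest node sequence so results
    are deterministic.  The single shortest pair path per direction is
    retained as the representative crosstalk route.
    """
    a_raw, b_raw = set(set_a), set(set_b)
    shared = a_raw & b_raw
    nodes_a = sorted(a_raw - shared)
    nodes_b = sorted(b_raw - shared)
    graph = gin.to_digraph()
    reverse = graph.reverse(copy=False)
    missing = tuple(
        sorted(n for n in (*nodes_a, *nodes_b) if n not in graph)
    )

    fwd: dict[str, dict[str, int]] = {}
    rev: dict[str, dict[str, int]] = {}
    for n in (*nodes_a, *nodes_b):
        if n in graph:
            fwd[n] = nx.single_source_shortest_path_length(graph, n)
            rev[n] = nx.single_source_shortest_path_length(reverse, n)

    pairs: list[PairPath] = []

    def record(src: str, dst: str, direction: str, a: str, b: str) -> None:
        d_edges = fwd.get(src, {}).get(dst)
        if d_edges is None:
            pairs.append(PairPath(a, b, direction, math.inf, None))
            return
        path = _lexicographic_shortest_path(graph, src, dst, fwd[src], rev[dst])
        pairs.append(PairPath(a, b, direction, float(len(path)), path))

    for a in nodes_a:
        for b in nodes_b:
            record(a, b, "a_to_b", a, b)
            record(b, a, "b_to_a", a, b)

    retained: dict[str, PairPath | None] = {}
    for direction in ("a_to_b", "b_to_a"):
        reachable = [
            p for p in pairs if p.direction == direction and p.reachable
        ]
        retained[direction] = (
            min(reachable, key=lambda p: (p.distance, p.path)) if reachable else None
        )
    return CrosstalkResult(
        pairs=pairs,
        retained=retained,
        shared_nodes=tuple(sorted(shared)),
        missing_nodes=missing,
    )


def edge_weight(n_shortest: int) -> float:
    """Display weight W = (2 / n_shortest)^2 of a path of n nodes.

    Adjacent nodes (n = 2) get the maximal weight 1; the quadratic decay
    de-emphasises long paths.  n below 2 is meaningless (a path has at
    least two distinct endpoints).
    """
    if n_shortest < 2:
        raise ValueError(f"a node pair path has >= 2 nodes, got {n_shortest}")
    return (2.0 / n_shortest) ** 2


def bipartite_table(result: CrosstalkResult) -> pd.DataFrame:
    """Weighted connection table of all reachable pairs.

    One row per reachable ordered pair: endpoints (never intermediates),
    direction, node-count distance, and the weight W used as line width in
    a bipartite layout.
    """
    rows = [
        {
            "node_a": p.node_a,
            "node_b": p.node_b,
            "direction": p.direction,
            "distance": int(p.distance),
            "weight": p.weight,
        }
        for p in result.pairs
        if p.reachable
        and node_class(p.node_a) != "intermediate"
        and node_class(p.node_b) != "intermediate"
    ]
    frame = pd.DataFrame(
        rows, columns=["node_a", "node_b", "direction", "distance", "weight"]
    )
    return frame.sort_values(
        ["direction", "distance", "node_a", "node_b"], ignore_index=True
    )


def write_crosstalk_table(result: CrosstalkResult, path: str | Path) -> None:
    bipartite_table(result).to_csv(path, sep="\t", index=False)


def relation_triplet_nodes(upstream: str, downstream: str) -> tuple[str, str, str]:
    """Nodes of the signaling triplet a relation (U, V) expands into."""
    itm = intermediate_id([downstream], upstream)
    return upstream, itm, downstream


__all__ = [
    "CurationRemoval",
    "CurationList",
    "PairPath",
    "CrosstalkResult",
    "apply_curation",
    "pathway_members",
    "shortest_paths_between",
    "edge_weight",
    "bipartite_table",
    "write_crosstalk_table",
    "relation_triplet_nodes",
]
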