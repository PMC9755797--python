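"""Shared fixtures: parsed synthetic pathways and random-graph builders."""

from __future__ import annotations

import random

import pytest

from ginet.gin_assembler import GIN, GinEdge, merge_metapathways
from ginet.kgml_io import parse_kgml
from ginet.metapath_builder import MetaEdge, MetaPathway, build_metapathway
from ginet.synthetic_kgml import (
    FixtureSpec,
    generate_crosstalk_pair,
    generate_fixture_set,
    generate_kgml,
)


@pytest.fixture(scope="session")
def fig1c_doc():
    """Minimal pathway with the signaling->metabolic crosstalk motif only."""
    spec = FixtureSpec(
        seed=7,
        n_genes=0,
        n_compounds=0,
        n_reactions=0,
        n_relations=0,
        planted_motifs=("fig1c",),
    )
    (text,) = generate_kgml(spec).values()
    return parse_kgml(text)


@pytest.fixture(scope="session")
def fixture_docs():
    """Three parsed random pathways sharing one molecule namespace."""
    return [parse_kgml(t) for t in generate_fixture_set(seed=11).values()]


@pytest.fixture(scope="session")
def fixture_gin(fixture_docs):
    return merge_metapathways([build_metapathway(d) for d in fixture_docs])


@pytest.fixture(scope="session")
def crosstalk_pair():
    """Planted two-pathway crosstalk fixture: (docs-by-id, manifest, gin)."""
    files, manifest = generate_crosstalk_pair(seed=5)
    docs = {name[:-4]: parse_kgml(text) for name, text in files.items()}
    gin = merge_metapathways([build_metapathway(d) for d in docs.values()])
    return docs, manifest, gin


def random_metapathway(
    rng: random.Random, pathway_id: str, n_nodes: int = 12, n_edges: int = 20
) -> MetaPathway:
    """Random edge set for merge-algebra tests (grammar not enforced)."""
    nodes = [f"syn:{i:04d}" for i in range(n_nodes)]
    edges = set()
    for _ in range(n_edges):
        s, t = rng.sample(nodes, 2)
        edges.add(
            MetaEdge(
                source=s,
                target=t,
                edge_type=rng.choice([1, 2, 3, 4]),
                sign=rng.choice(["neutral", "activation", "inhibition"]),
                pathway_id=pathway_id,
            )
        )
    return MetaPathway(pathway_id=pathway_id, edges=frozenset(edges))


def random_gin(
    rng: random.Random, n_nodes: int = 50, n_edges: int = 120, species: str = "syn"
) -> GIN:
    """Random directed GIN over gene-like nodes (for path/label oracles)."""
    nodes = [f"{species}:{i:04d}" for i in range(n_nodes)]
    edges = set()
    for _ in range(n_edges):
        s, t = rng.sample(nodes, 2)
        edges.add(GinEdge(source=s, target=t, edge_type=2, sign="neutral"))
    return GIN(species_code=species, edges=frozenset(edges))
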