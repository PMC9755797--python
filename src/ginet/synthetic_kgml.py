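"""Seeded generator of synthetic KGML fixtures.

The generator emits structurally faithful KGML — gene/compound/group/map
entries, reversible and irreversible reactions, multi-isoenzyme enzyme
entries, groups with alternative subunit slots, PPrel/PCrel relations with
activation/inhibition subtypes — so every pipeline stage is testable
without touching KEGG.  It targets structural coverage, not statistical
realism: degree distributions and pathway sizes are nothing like real
KEGG maps.

Identifier namespaces mimic KEGG's (``syn:0001`` genes, ``cpd:C9xxxx``
compounds) without colliding with real identifiers.  Output is a pure
function of the spec: the same spec yields byte-identical files.

Planted motifs give tests known ground truth, e.g. the signaling-cascade/
metabolic-reaction crosstalk motif (a chain A -> B -> C where kinase C
catalyses the reaction F -> G, so the meta-pathway must contain the
bridging edge C -> ITM[F|C]).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from ginet.kgml_io import (
    KgmlEntry,
    KgmlReaction,
    KgmlRelation,
    PathwayDoc,
    serialize_kgml,
)
from ginet.metapath_builder import intermediate_id

#: fixed identifiers of the signaling/metabolic crosstalk motif
FIG1C_MOTIF = {
    "a": "syn:9001",
    "b": "syn:9002",
    "c": "syn:9003",
    "f": "cpd:C99906",
    "g": "cpd:C99907",
    "reaction": "rn:R99901",
}

RELATION_SUBTYPES = (
    "activation",
    "inhibition",
    "binding/association",
    "phosphorylation",
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic pathway file.

    Probabilities steer structure draws (reaction reversibility, complex
    enzymes, isoenzyme entries); counts size the molecule pools.  Defaults
    give a small but feature-complete pathway touching every KGML
    construct the parser handles.
    """

    seed: int = 0
    pathway_number: int = 1
    species: str = "syn"
    n_genes: int = 12
    n_compounds: int = 8
    n_reactions: int = 6
    n_relations: int = 6
    p_reversible: float = 0.3
    p_group: float = 0.25
    p_isoenzyme: float = 0.25
    planted_motifs: tuple[str, ...] = ()
    include_map_entry: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_compounds", "n_reactions", "n_relations"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        for name in ("p_reversible", "p_group", "p_isoenzyme"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise FixtureError(f"{name}={p} outside [0, 1]")
        if self.n_reactions > 0 and self.n_compounds < 2:
            raise FixtureError("reactions require at least 2 compounds")
        if self.n_relations > 0 and self.n_genes < 2:
            raise FixtureError("relations require at least 2 genes")

    @property
    def pathway_id(self) -> str:
        return f"{self.species}{self.pathway_number:05d}"


class _DocBuilder:
    def __init__(self, pathway_id: str, species: str, title: str = "") -> None:
        self.pathway_id = pathway_id
        self.species = species
        self.title = title
        self.entries: dict[int, KgmlEntry] = {}
        self.reactions: list[KgmlReaction] = []
        self.relations: list[KgmlRelation] = []
        self._next = 1

    def entry(
        self,
        entry_type: str,
        names: tuple[str, ...] = (),
        reaction_ref: str | None = None,
        components: tuple[int, ...] = (),
    ) -> int:
        eid = self._next
        self._next += 1
        self.entries[eid] = KgmlEntry(
            entry_id=eid,
            entry_type=entry_type,
            names=names,
            reaction_ref=reaction_ref,
            component_refs=components,
        )
        return eid

    def reaction(
        self,
        name: str,
        substrates: tuple[int, ...],
        products: tuple[int, ...],
        reversible: bool = False,
    ) -> None:
        enzyme_ids = tuple(
            sorted(
                e.entry_id
                for e in self.entries.values()
                if name in e.reaction_names()
            )
        )
        self.reactions.append(
            KgmlReaction(
                reaction_id=name,
                direction="reversible" if reversible else "irreversible",
                substrate_ids=substrates,
                product_ids=products,
                enzyme_entry_ids=enzyme_ids,
            )
        )

    def relation(self, e1: int, e2: int, rel_type: str, subtype: str) -> None:
        self.relations.append(
            KgmlRelation(
                entry1=e1,
                entry2=e2,
                rel_type=rel_type,
                subtypes=(subtype,),
                raw_type=rel_type,
            )
        )

    def doc(self) -> PathwayDoc:
        return PathwayDoc(
            pathway_id=self.pathway_id,
            species_code=self.species,
            title=self.title,
            entries=dict(sorted(self.entries.items())),
            reactions=tuple(self.reactions),
            relations=tuple(self.relations),
        )


def _plant_fig1c(builder: _DocBuilder) -> None:
    m = FIG1C_MOTIF
    a = builder.entry("gene", (m["a"],))
    b = builder.entry("gene", (m["b"],))
    c = builder.entry("gene", (m["c"],), reaction_ref=m["reaction"])
    f = builder.entry("compound", (m["f"],))
    g = builder.entry("compound", (m["g"],))
    builder.relation(a, b, "PPrel", "activation")
    builder.relation(b, c, "PPrel", "activation")
    builder.reaction(m["reaction"], (f,), (g,))


def generate_pathway_doc(spec: FixtureSpec) -> PathwayDoc:
    """Build the in-memory PathwayDoc for one fixture spec."""
    rng = random.Random(spec.seed)
    builder = _DocBuilder(
        spec.pathway_id, spec.species, title=f"synthetic pathway {spec.pathway_id}"
    )

    gene_eids = [
        builder.entry("gene", (f"{spec.species}:{i:04d}",))
        for i in range(1, spec.n_genes + 1)
    ]
    compound_eids = [
        builder.entry("compound", (f"cpd:C9{i:04d}",))
        for i in range(1, spec.n_compounds + 1)
    ]
    if spec.include_map_entry:
        builder.entry("map", (f"path:{spec.species}00999",))

    iso_counter = 0
    for j in range(1, spec.n_reactions + 1):
        name = f"rn:R{spec.pathway_number:02d}{j:03d}"
        n_sub = 2 if (len(compound_eids) > 2 and rng.random() < 0.3) else 1
        substrates = tuple(sorted(rng.sample(compound_eids, n_sub)))
        remaining = [c for c in compound_eids if c not in substrates]
        products = (rng.choice(remaining),)
        if rng.random() < spec.p_group:
            # complex enzyme: group of two subunits; one slot may list
            # isoenzyme alternatives
            sub1_names: tuple[str, ...]
            if rng.random() < spec.p_isoenzyme:
                iso_counter += 1
                sub1_names = (
                    f"{spec.species}:4{j:03d}",
                    f"{spec.species}:5{iso_counter:03d}",
                )
            else:
                sub1_names = (f"{spec.species}:4{j:03d}",)
            sub1 = builder.entry("gene", sub1_names)
            sub2 = builder.entry("gene", (f"{spec.species}:6{j:03d}",))
            builder.entry(
                "group", (), reaction_ref=name, components=(sub1, sub2)
            )
        else:
            if rng.random() < spec.p_isoenzyme:
                iso_counter += 1
                enz_names = (
                    f"{spec.species}:1{j:03d}",
                    f"{spec.species}:5{iso_counter:03d}",
                )
            else:
                enz_names = (f"{spec.species}:1{j:03d}",)
            builder.entry("gene", enz_names, reaction_ref=name)
        builder.reaction(
            name, substrates, products, reversible=rng.random() < spec.p_reversible
        )

    for _ in range(spec.n_relations):
        if compound_eids and rng.random() < 0.3:
            e1 = rng.choice(compound_eids)
            e2 = rng.choice(gene_eids)
            rel_type = "PCrel"
        else:
            e1, e2 = rng.sample(gene_eids, 2)
            rel_type = "PPrel"
        builder.relation(e1, e2, rel_type, rng.choice(RELATION_SUBTYPES))

    for motif in spec.planted_motifs:
        if motif == "fig1c":
            _plant_fig1c(builder)
        else:
            raise FixtureError(f"unknown planted motif {motif!r}")

    return builder.doc()


def generate_kgml(spec: FixtureSpec) -> dict[str, str]:
    """Generate KGML file text(s) for a spec: {filename: xml_text}."""
    doc = generate_pathway_doc(spec)
    return {f"{doc.pathway_id}.xml": serialize_kgml(doc)}


def generate_fixture_set(
    seed: int,
    n_pathways: int = 3,
    species: str = "syn",
    planted_motifs: tuple[str, ...] = ("fig1c",),
    **spec_kwargs,
) -> dict[str, str]:
    """A small multi-pathway fixture set sharing one compound namespace.

    Pathways draw molecules from the same pools, so overlapping usage
    connects them in the merged GIN — the situation redundancy removal
    exists for.  The first pathway carries the planted motifs.
    """
    files: dict[str, str] = {}
    for k in range(n_pathways):
        spec = FixtureSpec(
            seed=seed * 1009 + k,
            pathway_number=k + 1,
            species=species,
            planted_motifs=planted_motifs if k == 0 else (),
            **spec_kwargs,
        )
        files.update(generate_kgml(spec))
    return files


# --- crosstalk pair fixture -------------------------------------------------

_XT = {
    "species": "syn",
    "pathway_a": "syn09101",
    "pathway_b": "syn09202",
    # pathway A: small metabolic chain
    "chain_compounds": ["cpd:C91001", "cpd:C91002", "cpd:C91003", "cpd:C91004"],
    "chain_enzymes": ["syn:1001", "syn:1002", "syn:1003"],
    # pathway B: signaling cascade
    "cascade": ["syn:2001", "syn:2002", "syn:2003", "syn:2004"],
    # bridge genes shared between the two files (interior path nodes)
    "h_out": "syn:5001",
    "h_in": "syn:5002",
    # artifact: a spurious ligand->receptor relation, curation target
    "artifact_compound": "cpd:C91000",
    "artifact_receptor": "syn:5003",
}


def _bridge_path(src: str, via: str, dst: str) -> list[str]:
    """Node sequence of a two-relation bridge src -> via -> dst in the GIN."""
    return [
        src,
        intermediate_id([via], src),
        via,
        intermediate_id([dst], via),
        dst,
    ]


def generate_crosstalk_pair(
    seed: int,
    with_bridges: bool = True,
    with_artifact: bool = True,
) -> tuple[dict[str, str], dict]:
    """Two disjoint pathways plus a manifest of their planted crosstalk.

    Pathway A is a four-compound metabolic chain, pathway B a four-gene
    signaling cascade; their member sets share no nodes.  When bridges are
    planted, exactly one out-bridge (compound of A activating a gene that
    in turn activates the cascade head) and one in-bridge (cascade tail
    inhibiting a gene that activates an enzyme of A) connect the two in
    the merged GIN, each a five-node path.  The optional artifact plants a
    second out-route through a spurious ligand-receptor relation — the
    kind of annotation error the curation list exists to remove.

    Returns ``(files, manifest)``: the KGML texts and the constructed
    ground truth (members, expected retained paths, weights, the curation
    removal that disconnects the artifact pair).  The manifest is built
    from the construction itself, not by running the analysis.
    """
    rng = random.Random(seed)
    x = _XT

    a = _DocBuilder(x["pathway_a"], x["species"], title="synthetic metabolic chain")
    cpd_ids = {c: a.entry("compound", (c,)) for c in x["chain_compounds"]}
    for i, enz in enumerate(x["chain_enzymes"]):
        rname = f"rn:R91{i + 1:03d}"
        a.entry("gene", (enz,), reaction_ref=rname)
        a.reaction(
            rname,
            (cpd_ids[x["chain_compounds"][i]],),
            (cpd_ids[x["chain_compounds"][i + 1]],),
            reversible=(i == 1),
        )
    # seeded decoys: extra compounds produced from the chain head
    n_decoys = rng.randint(1, 3)
    for d in range(1, n_decoys + 1):
        dec = a.entry("compound", (f"cpd:C918{d:02d}",))
        rname = f"rn:R918{d:02d}"
        a.entry("gene", (f"syn:18{d:02d}",), reaction_ref=rname)
        a.reaction(rname, (cpd_ids[x["chain_compounds"][0]],), (dec,))

    b = _DocBuilder(x["pathway_b"], x["species"], title="synthetic signaling cascade")
    casc_ids = {g: b.entry("gene", (g,)) for g in x["cascade"]}
    for up, down in zip(x["cascade"], x["cascade"][1:]):
        b.relation(casc_ids[up], casc_ids[down], "PPrel", "activation")

    manifest: dict = {
        "pathway_a": x["pathway_a"],
        "pathway_b": x["pathway_b"],
        "bridges": {},
        "artifact": None,
    }

    if with_bridges:
        # out-bridge: chain tail compound -> h_out (file A); h_out -> cascade
        # head (file B)
        h_out_a = a.entry("gene", (x["h_out"],))
        a.relation(cpd_ids[x["chain_compounds"][-1]], h_out_a, "PCrel", "activation")
        h_out_b = b.entry("gene", (x["h_out"],))
        b.relation(h_out_b, casc_ids[x["cascade"][0]], "PPrel", "activation")
        out_path = _bridge_path(
            x["chain_compounds"][-1], x["h_out"], x["cascade"][0]
        )
        # in-bridge: cascade tail -| h_in (file B); h_in -> first chain
        # enzyme (file A); the inhibitory edge must remain traversable
        h_in_b = b.entry("gene", (x["h_in"],))
        b.relation(casc_ids[x["cascade"][-1]], h_in_b, "PPrel", "inhibition")
        h_in_a = a.entry("gene", (x["h_in"],))
        a.relation(h_in_a, a_enzyme_eid(a, x["chain_enzymes"][0]), "PPrel", "activation")
        in_path = _bridge_path(x["cascade"][-1], x["h_in"], x["chain_enzymes"][0])
        manifest["bridges"] = {
            "a_to_b": _path_record(out_path),
            "b_to_a": _path_record(in_path),
        }

    if with_artifact:
        art_c = a.entry("compound", (x["artifact_compound"],))
        art_r_a = a.entry("gene", (x["artifact_receptor"],))
        a.relation(art_c, art_r_a, "PCrel", "activation")
        art_r_b = b.entry("gene", (x["artifact_receptor"],))
        b.relation(art_r_b, casc_ids[x["cascade"][1]], "PPrel", "activation")
        art_path = _bridge_path(
            x["artifact_compound"], x["artifact_receptor"], x["cascade"][1]
        )
        manifest["artifact"] = {
            "pair": [x["artifact_compound"], x["cascade"][1]],
            **_path_record(art_path),
            "removal": {
                "source": x["artifact_compound"],
                "target": x["artifact_receptor"],
                "reason": "spurious ligand-receptor link planted for curation",
            },
        }

    doc_a, doc_b = a.doc(), b.doc()
    from ginet.crosstalk import pathway_members  # local import, avoids cycle

    members_a = sorted(pathway_members(doc_a))
    members_b = sorted(pathway_members(doc_b))
    shared = sorted(set(members_a) & set(members_b))
    manifest["members_a"] = members_a
    manifest["members_b"] = members_b
    manifest["shared"] = shared

    # retained path per direction: the planted routes are the only
    # cross-pathway connections, so the minimum over them (distance first,
    # then lexicographic node sequence) is the expected analysis result.
    candidates = {"a_to_b": [], "b_to_a": []}
    if with_bridges:
        candidates["a_to_b"].append(manifest["bridges"]["a_to_b"])
        candidates["b_to_a"].append(manifest["bridges"]["b_to_a"])
    if with_artifact:
        candidates["a_to_b"].append(
            {k: manifest["artifact"][k] for k in ("path", "n_nodes", "weight")}
        )
    manifest["retained"] = {
        d: (
            min(cands, key=lambda r: (r["n_nodes"], r["path"]))
            if cands
            else None
        )
        for d, cands in candidates.items()
    }

    files = {
        f"{doc_a.pathway_id}.xml": serialize_kgml(doc_a),
        f"{doc_b.pathway_id}.xml": serialize_kgml(doc_b),
    }
    return files, manifest


def _path_record(path: list[str]) -> dict:
    n = len(path)
    return {"path": path, "n_nodes": n, "weight": (2.0 / n) ** 2}


def a_enzyme_eid(builder: _DocBuilder, gene: str) -> int:
    for e in builder.entries.values():
        if gene in e.names:
            return e.entry_id
    raise FixtureError(f"gene {gene} not present in builder")


def write_fixtures(files: dict[str, str], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in sorted(files.items()):
        p = outdir / name
        p.write_text(text, encoding="utf-8")
        written.append(p)
    return written


def expected_fig1c_edge() -> tuple[str, str]:
    """The bridging enzyme -> intermediate edge the crosstalk motif plants."""
    m = FIG1C_MOTIF
    return m["c"], intermediate_id([m["f"]], m["c"])
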