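"""Expansion of KGML group entries into concrete enzyme units.

KEGG stores a protein complex with alternative subunits as one group
entry: A + (B/C) + D is a group of three members where the middle slot
lists two candidate genes.  Downstream graph construction needs concrete
catalytic units, so each such group is split into every realisable
combination (ABD and ACD here).  Homo-oligomers collapse: a unit never
lists the same gene twice, so [{A},{A}] yields the single unit {A}.

A unit with more than one member becomes a distinct *complex* node and one
type-1 edge per member (subunit -> complex) records its composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # avoid an import cycle; MetaEdge only needed for typing
    from ginet.metapath_builder import MetaEdge

COMPLEX_PREFIX = "CPLX["
COMPLEX_SUFFIX = "]"
COMPLEX_JOIN = "+"


class GroupExpansionError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class EnzymeUnit:
    """A resolved catalytic unit: a single gene or an expanded complex.

    ``members`` is the sorted, duplicate-free tuple of gene identifiers.
    ``unit_id`` is a deterministic function of the members: the bare gene
    id for a monomer, else ``CPLX[m1+m2+...]`` over the sorted members.
    KEGG identifiers never contain ``+``, ``[`` or ``]``, so the scheme is
    collision-free.
    """

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise GroupExpansionError("enzyme unit needs at least one member")
        canonical = tuple(sorted(set(self.members)))
        if canonical != self.members:
            object.__setattr__(self, "members", canonical)

    @property
    def unit_id(self) -> str:
        if len(self.members) == 1:
            return self.members[0]
        return COMPLEX_PREFIX + COMPLEX_JOIN.join(self.members) + COMPLEX_SUFFIX

    @property
    def is_complex(self) -> bool:
        return len(self.members) > 1


def expand_group(
    member_alternatives: Sequence[Iterable[str]], group_name: str = "<group>"
) -> list[EnzymeUnit]:
    """Expand alternative-subunit slots into concrete enzyme units.

    Each element of ``member_alternatives`` is the set of candidate genes
    for one complex slot.  The result is one unit per element of the
    Cartesian product across slots, with duplicate members inside a unit
    collapsed (homodimer rule) and duplicate units removed.  Output sorted
    by ``unit_id`` and invariant under permutation of slots/alternatives.
    """
    slots = [sorted(set(alt)) for alt in member_alternatives]
    for i, slot in enumerate(slots):
        if not slot:
            raise GroupExpansionError(
                f"group {group_name}: alternative slot {i} is empty"
            )
    units = {EnzymeUnit(tuple(combo)) for combo in product(*slots)}
    return sorted(units, key=lambda u: u.unit_id)


def complex_edges(unit: EnzymeUnit, pathway_id: str = "") -> list["MetaEdge"]:
    """Type-1 subunit->complex edges for a multi-member unit.

    A monomer is not a complex: the empty list is returned.
    """
    from ginet.metapath_builder import MetaEdge  # deferred, cycle

    if not unit.is_complex:
        return []
    return [
        MetaEdge(
            source=member,
            target=unit.unit_id,
            edge_type=1,
            sign="neutral",
            pathway_id=pathway_id,
        )
        for member in unit.members
    ]


def write_complex_reference(units: Iterable[EnzymeUnit], path) -> None:
    """TSV export of a complex reference: unit_id <tab> comma-joined members."""
    lines = [
        f"{u.unit_id}\t{','.join(u.members)}"
        for u in sorted(set(units), key=lambda u: u.unit_id)
        if u.is_complex
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
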