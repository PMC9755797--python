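"""Cross-species comparison of GIN sub-networks via Jaccard scores.

Gene identifiers are species-specific, so sub-networks of two species are
compared after mapping genes to KEGG Orthology (KO) ids; compounds keep
their own ids (already species-neutral).  Intermediate and complex nodes
are construction artifacts and are excluded from the feature sets.  The
similarity of two sub-networks is the Jaccard score |A∩B| / |A∪B| over
those features; the giant component (subnet 1) can be excluded so that the
comparison focuses on the leftover fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from ginet.gin_assembler import GIN, SubnetLabeling
from ginet.metapath_builder import node_class


class KoMappingResult(NamedTuple):
    kos: frozenset[str]
    unmapped: frozenset[str]


@dataclass(frozen=True)
class FeatureSet:
    """KO ids (genes) plus compound ids of one labeled sub-network."""

    subnet_label: int
    features: frozenset[str]
    n_unmapped: int = 0


@dataclass
class JaccardMatrix:
    row_labels: tuple[int, ...]
    col_labels: tuple[int, ...]
    scores: np.ndarray  # shape (len(row_labels), len(col_labels)), in [0,1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=[f"subnet_{i}" for i in self.row_labels],
            columns=[f"subnet_{j}" for j in self.col_labels],
        )


def load_ko_mapping(path: str | Path) -> dict[str, str]:
    """Load a two-column gene-to-KO TSV (no header) into a dict."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "ko"], dtype=str, comment="#"
    )
    return dict(zip(frame["gene"], frame["ko"]))


def map_to_ko(genes: Iterable[str], mapping: Mapping[str, str]) -> KoMappingResult:
    """Image of a gene set under the KO mapping; unmapped genes reported.

    Orthologous genes of different species collapse onto shared KO ids,
    which is what makes the downstream Jaccard comparable across species.
    Genes absent from the mapping are dropped, not fatal.
    """
    genes = set(genes)
    kos = {mapping[g] for g in genes if g in mapping}
    return KoMappingResult(
        kos=frozenset(kos), unmapped=frozenset(g for g in genes if g not in mapping)
    )


def subnet_feature_sets(
    gin: GIN, labeling: SubnetLabeling, mapping: Mapping[str, str]
) -> dict[int, FeatureSet]:
    """Per-subnet feature sets: gene nodes KO-mapped, compound nodes as-is."""
    by_label: dict[int, FeatureSet] = {}
    for label in sorted(labeling.component_sizes):
        members = labeling.nodes_of(label)
        genes = {n for n in members if node_class(n) == "gene"}
        compounds = {n for n in members if node_class(n) == "compound"}
        mapped = map_to_ko(genes, mapping)
        by_label[label] = FeatureSet(
            subnet_label=label,
            features=frozenset(mapped.kos | compounds),
            n_unmapped=len(mapped.unmapped),
        )
    return by_label


def jaccard(a: FeatureSet | frozenset | set, b: FeatureSet | frozenset | set) -> float:
    """Jaccard score |A∩B| / |A∪B|; 0.0 when both sets are empty."""
    set_a = a.features if isinstance(a, FeatureSet) else frozenset(a)
    set_b = b.features if isinstance(b, FeatureSet) else frozenset(b)
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def jaccard_matrix(
    subnets_a: Mapping[int, FeatureSet],
    subnets_b: Mapping[int, FeatureSet],
    exclude_subnet1: bool = False,
) -> JaccardMatrix:
    """Pairwise Jaccard matrix over two species' sub-network feature sets.

    With ``exclude_subnet1`` the giant components (label 1 on both sides)
    are omitted, leaving only the fragment-versus-fragment comparison.
    """
    rows = tuple(sorted(l for l in subnets_a if not (exclude_subnet1 and l == 1)))
    cols = tuple(sorted(l for l in subnets_b if not (exclude_subnet1 and l == 1)))
    scores = np.zeros((len(rows), len(cols)))
    for i, la in enumerate(rows):
        for j, lb in enumerate(cols):
            scores[i, j] = jaccard(subnets_a[la], subnets_b[lb])
    return JaccardMatrix(row_labels=rows, col_labels=cols, scores=scores)


def matched_subnets(
    matrix: JaccardMatrix, threshold: float = 0.5
) -> list[tuple[int, int, float]]:
    """Subnet pairs whose Jaccard score reaches ``threshold``.

    KEGG leaves "matched" undefined numerically; 0.5 (a majority of the
    union shared) is the package default and is configurable.
    """
    hits = []
    for i, la in enumerate(matrix.row_labels):
        for j, lb in enumerate(matrix.col_labels):
            score = float(matrix.scores[i, j])
            if score >= threshold:
                hits.append((la, lb, score))
    return hits


def write_jaccard_matrix(matrix: JaccardMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")
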