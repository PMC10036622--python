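"""Edge-type (ET) catalogs, annotation handling and ET distributions.

An edge's type is the unordered pair of its endpoints' node-type labels.
With ``s`` node types there are ``s(s-1)/2 + s`` possible ETs (cross-type
pairs plus same-type pairs).  Multi-label nodes spread an edge's unit weight
equally over the distinct ETs formed by all label combinations, so every
typed edge always contributes total weight exactly 1 and the ET distribution
of a network is a weighted count per ET — a compact fingerprint of the
network's state that is insensitive to which individual edges moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "KEGG_METABOLISM_CLASSES",
    "NodeTypeScheme",
    "ETCatalog",
    "AnnotationTable",
    "build_catalog",
    "edge_types_of",
    "et_distribution",
    "response_distribution_per_et",
    "read_annotations",
]

# the 11 top-level metabolism classes of the KEGG PATHWAY hierarchy
KEGG_METABOLISM_CLASSES: tuple[str, ...] = (
    "Carbohydrate",
    "Energy",
    "Lipid",
    "Nucleotide",
    "Amino acid",
    "Other amino acids",
    "Glycan",
    "Cofactors and vitamins",
    "Terpenoids and polyketides",
    "Other secondary metabolites",
    "Xenobiotics",
)

FATES = ("PtoP", "AtoP", "PtoA", "AtoA")


@dataclass(frozen=True)
class NodeTypeScheme:
    """Ordered list of the s node-type labels."""

    labels: tuple[str, ...] = KEGG_METABOLISM_CLASSES

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("scheme needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if any(not lab for lab in self.labels):
            raise ValueError("labels must be nonempty")

    @property
    def s(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ETCatalog:
    """All unordered label pairs (including same-label pairs), in
    lexicographic order of label indices; exactly s(s-1)/2 + s entries."""

    scheme: NodeTypeScheme
    pairs: tuple[tuple[str, str], ...]

    @property
    def t(self) -> int:
        return len(self.pairs)

    def index(self, et: tuple[str, str]) -> int:
        return self.pairs.index(self.canonical(et))

    def canonical(self, et: tuple[str, str]) -> tuple[str, str]:
        a, b = et
        ia, ib = self.scheme.labels.index(a), self.scheme.labels.index(b)
        return (a, b) if ia <= ib else (b, a)


def build_catalog(scheme: NodeTypeScheme = NodeTypeScheme()) -> ETCatalog:
    labels = scheme.labels
    pairs = tuple(
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i, len(labels))
    )
    return ETCatalog(scheme=scheme, pairs=pairs)


class AnnotationTable(dict):
    """molecule ID -> nonempty frozenset of labels from one scheme."""

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]],
                     scheme: NodeTypeScheme) -> "AnnotationTable":
        table = cls()
        valid = set(scheme.labels)
        for mol, labels in mapping.items():
            labels = frozenset(labels)
            if not labels:
                raise ValueError(f"molecule {mol!r} has no labels")
            unknown = labels - valid
            if unknown:
                raise ValueError(f"molecule {mol!r} has labels outside the scheme: {unknown}")
            table[mol] = labels
        return table


def read_annotations(path: str | Path, scheme: NodeTypeScheme) -> AnnotationTable:
    """Read a two-column TSV: molecule_id <tab> pipe-separated labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = {row.iloc[0]: row.iloc[1].split("|") for _, row in df.iterrows()}
    return AnnotationTable.from_mapping(mapping, scheme)


def edge_types_of(
    pair: tuple[str, str],
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
) -> dict[tuple[str, str], float]:
    """The ETs of one edge with their fractional weights.

    All pairwise combinations of the two endpoints' labels are formed; the
    distinct resulting ETs share the edge's unit weight equally (weight
    1/#ETs each), so weights always sum to 1.  Raises KeyError if either
    endpoint is unannotated — callers report such edges as untyped.
    """
    a, b = pair
    ets = {catalog.canonical((la, lb)) for la in annotations[a] for lb in annotations[b]}
    w = 1.0 / len(ets)
    return {et: w for et in sorted(ets, key=catalog.index)}


@dataclass
class ETDistribution:
    """Weighted ET counts plus the count of edges that could not be typed."""

    weights: dict[tuple[str, str], float]
    n_typed_edges: int
    n_untyped_edges: int

    def as_vector(self, catalog: ETCatalog,
                  subset: Iterable[tuple[str, str]] | None = None) -> "pd.Series":
        ets = list(catalog.pairs) if subset is None else [catalog.canonical(e) for e in subset]
        return pd.Series([self.weights.get(et, 0.0) for et in ets],
                         index=[f"{a}--{b}" for a, b in ets])

    @property
    def total(self) -> float:
        return sum(self.weights.values())


def et_distribution(
    edges: Iterable[tuple[str, str]],
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
) -> ETDistribution:
    """Weighted count of each ET over an edge set.

    Each typed edge contributes total weight 1; edges with an unannotated
    endpoint are excluded and reported in ``n_untyped_edges``.
    """
    weights: dict[tuple[str, str], float] = {et: 0.0 for et in catalog.pairs}
    typed = untyped = 0
    for pair in edges:
        try:
            contrib = edge_types_of(pair, annotations, catalog)
        except KeyError:
            untyped += 1
            continue
        typed += 1
        for et, w in contrib.items():
            weights[et] += w
    return ETDistribution(weights=weights, n_typed_edges=typed, n_untyped_edges=untyped)


def response_distribution_per_et(
    response: "ResponseNetwork",
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
) -> dict[tuple[str, str], dict[str, float]]:
    """Per-ET histogram of pair fates (PtoP / AtoP / PtoA / AtoA).

    Every node pair (including absent AtoA pairs) is typed with the same
    fractional weighting used for edges, so per-ET totals over the four
    fates sum to that ET's weighted share of all N(N-1)/2 pairs.
    """
    hist: dict[tuple[str, str], dict[str, float]] = {
        et: {f: 0.0 for f in FATES} for et in catalog.pairs}
    for pair, fate in response.fate.items():
        try:
            contrib = edge_types_of(pair, annotations, catalog)
        except KeyError:
            continue
        for et, w in contrib.items():
            hist[et][fate] += w
    return hist
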