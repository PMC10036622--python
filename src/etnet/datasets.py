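"""Seeded synthetic cohorts with planted pairwise dependencies.

Emulates the shape of a glucose-challenge multi-omics study: two genotypes x
two timepoints, ~11-12 samples per condition, tens to hundreds of molecules,
multi-label annotations over the 11 metabolism classes, and a known
(planted) dependency structure that differs between conditions.  Values are
continuous and unit-free; downstream standardization removes scale anyway,
so no attempt is made to mimic metabolite concentration ranges or RNA count
distributions.

Three dependence kinds are planted:

``linear``
    y = r x + sqrt(1 - r^2) eps — correlation equal to the strength.
``quadratic``
    y proportional to (x^2 - 1) plus noise — strong dependence with
    near-zero linear correlation, the case where MI beats Pearson.
``xor``
    y = s x + noise with s a random sign per sample — zero correlation,
    dependence carried by |y| ~ |x|.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .edge_typing import KEGG_METABOLISM_CLASSES

__all__ = ["PlantedEdge", "CohortSpec", "Cohort", "generate_cohort",
           "demo_study_cohorts"]

DEPENDENCE_KINDS = ("linear", "quadratic", "xor")


@dataclass(frozen=True)
class PlantedEdge:
    """An unordered molecule pair with a planted dependence."""

    i: int
    j: int
    kind: str = "linear"
    strength: float = 0.9

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("planted pair must join distinct molecules")
        if self.kind not in DEPENDENCE_KINDS:
            raise ValueError(f"unknown dependence kind {self.kind!r}")
        if not 0 < self.strength <= 1:
            raise ValueError("strength must be in (0, 1]")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.i, self.j), max(self.i, self.j))


@dataclass
class CohortSpec:
    n_molecules: int = 40
    n_samples_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"OGTT0": 11, "OGTT4": 12})
    node_type_labels: Sequence[str] = KEGG_METABOLISM_CLASSES
    annotation_multiplicity: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.2})
    planted_edges: Mapping[str, Sequence[PlantedEdge]] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(k < 1 for k in self.annotation_multiplicity):
            raise ValueError("annotation multiplicity must give every molecule >= 1 label")
        if abs(sum(self.annotation_multiplicity.values()) - 1.0) > 1e-9:
            raise ValueError("annotation multiplicity must sum to 1")
        if len(set(self.node_type_labels)) != len(self.node_type_labels):
            raise ValueError("node type labels must be unique")
        for cond, edges in self.planted_edges.items():
            if cond not in self.n_samples_per_condition:
                raise ValueError(f"planted edges for unknown condition {cond!r}")
            seen: set[int] = set()
            for e in edges:
                for node in e.pair:
                    if not 0 <= node < self.n_molecules:
                        raise ValueError(f"planted node {node} out of range")
                    if node in seen:
                        raise ValueError(
                            f"molecule {node} appears in more than one planted pair "
                            f"in condition {cond!r}")
                    seen.add(node)

    def molecule_ids(self) -> list[str]:
        width = len(str(self.n_molecules - 1))
        return [f"mol{str(i).zfill(width)}" for i in range(self.n_molecules)]


@dataclass
class Cohort:
    """A generated study: one abundance matrix per condition plus truth."""

    matrices: dict[str, pd.DataFrame]
    annotations: dict[str, frozenset[str]]
    truth: dict[str, list[PlantedEdge]]
    spec: CohortSpec

    def truth_pairs(self, condition: str) -> set[tuple[str, str]]:
        ids = self.spec.molecule_ids()
        return {(ids[e.pair[0]], ids[e.pair[1]]) for e in self.truth.get(condition, [])}

    def write(self, outdir: str | Path) -> None:
        """Write matrices (TSV), annotations (TSV) and ground truth (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, df in self.matrices.items():
            df.to_csv(outdir / f"matrix_{cond}.tsv", sep="\t", index_label="molecule_id")
        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write("molecule_id\tlabels\n")
            for mol, labels in self.annotations.items():
                fh.write(f"{mol}\t{'|'.join(sorted(labels))}\n")
        truth = {
            cond: [{"i": e.pair[0], "j": e.pair[1], "kind": e.kind, "strength": e.strength}
                   for e in edges]
            for cond, edges in self.truth.items()
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def _dependent_sample(x: np.ndarray, kind: str, strength: float,
                      rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    eps = rng.standard_normal(n)
    if kind == "linear":
        return strength * x + np.sqrt(1 - strength**2) * eps
    if kind == "quadratic":
        # (x^2 - 1)/sqrt(2) is standardized for x ~ N(0,1) and uncorrelated with x
        base = (x**2 - 1) / np.sqrt(2)
        return strength * base + np.sqrt(1 - strength**2) * eps
    if kind == "xor":
        sign = rng.choice([-1.0, 1.0], size=n)
        return strength * sign * x + np.sqrt(1 - strength**2) * eps
    raise ValueError(kind)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate one matrix per condition with the planted structure.

    Deterministic given the spec's seed.  Non-planted molecules are i.i.d.
    standard normal; in each planted pair the second molecule is derived
    from the first with the stated dependence kind and strength, then all
    rows are scaled by ``noise_sd``.
    """
    spec.validate()
    ids = spec.molecule_ids()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule IDs")
    root = np.random.SeedSequence(spec.seed)
    anno_rng = np.random.default_rng(root.spawn(1)[0])

    matrices: dict[str, pd.DataFrame] = {}
    for cond in spec.n_samples_per_condition:
        n = spec.n_samples_per_condition[cond]
        digest = hashlib.blake2b(cond.encode(), digest_size=4).digest()
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, int.from_bytes(digest, "big")]))
        data = rng.standard_normal((spec.n_molecules, n))
        for edge in spec.planted_edges.get(cond, ()):
            i, j = edge.pair
            data[j] = _dependent_sample(data[i], edge.kind, edge.strength, rng)
        data *= spec.noise_sd
        matrices[cond] = pd.DataFrame(
            data, index=ids, columns=[f"{cond}_s{t:02d}" for t in range(n)])

    sizes = sorted(spec.annotation_multiplicity)
    probs = np.array([spec.annotation_multiplicity[s] for s in sizes], float)
    labels = list(spec.node_type_labels)
    annotations: dict[str, frozenset[str]] = {}
    for mol in ids:
        n_labels = int(anno_rng.choice(sizes, p=probs))
        chosen = anno_rng.choice(len(labels), size=min(n_labels, len(labels)), replace=False)
        annotations[mol] = frozenset(labels[c] for c in chosen)

    truth = {cond: list(edges) for cond, edges in spec.planted_edges.items()}
    return Cohort(matrices=matrices, annotations=annotations, truth=truth, spec=spec)


def demo_study_cohorts(
    seed: int = 0,
    n_molecules: int = 30,
    strength: float = 0.92,
) -> dict[str, Cohort]:
    """Two-genotype, two-timepoint study with overlapping planted structures.

    The "WT" cohort loses half of its baseline dependencies after the
    challenge and gains as many new ones; the "ob" cohort carries the
    time-reversed structure.  The overlap yields all three response-edge
    fates (stable, gained, lost) with known ground truth in each genotype.
    Annotations are shared across genotypes (drawn from the WT cohort).
    """
    kinds = ("linear", "quadratic", "xor")
    n_pairs = max(2, n_molecules // 4)  # planted pairs per condition
    base = [PlantedEdge(2 * i, 2 * i + 1, kinds[i % 3], strength)
            for i in range(n_pairs)]
    shifted = [PlantedEdge(2 * i, 2 * i + 1, kinds[i % 3], strength)
               for i in range(n_pairs // 2, n_pairs + n_pairs // 2)]
    wt_spec = CohortSpec(
        n_molecules=n_molecules,
        n_samples_per_condition={"OGTT0": 11, "OGTT4": 12},
        planted_edges={"OGTT0": base, "OGTT4": shifted},
        seed=seed)
    ob_spec = CohortSpec(
        n_molecules=n_molecules,
        n_samples_per_condition={"OGTT0": 12, "OGTT4": 12},
        planted_edges={"OGTT0": shifted, "OGTT4": base},
        seed=seed + 104729)
    wt = generate_cohort(wt_spec)
    ob = generate_cohort(ob_spec)
    ob.annotations = wt.annotations
    return {"WT": wt, "ob": ob}
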