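"""MI network inference and condition-difference (response) networks.

Every unordered molecule pair is tested for statistical independence; pairs
whose permutation p-value falls strictly below the threshold p0 become
edges.  Comparing the networks of two conditions assigns each node pair one
of four fates: present in both (PtoP), gained (AtoP), lost (PtoA), absent in
both (AtoA).  PtoP, AtoP and PtoA pairs together are the "response edges".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .mi import MIEstimatorConfig, permutation_test_independence, standardize

__all__ = [
    "MINetwork",
    "ResponseNetwork",
    "full_connection_count",
    "infer_network",
    "network_from_results",
    "response_network",
    "degree_distribution",
    "compare_degree_distributions",
]

FATES = ("PtoP", "AtoP", "PtoA", "AtoA")


def full_connection_count(N: int) -> int:
    """Maximum number of edges of a simple undirected network on N nodes,
    i.e. N choose 2."""
    if N < 1:
        raise ValueError("need N >= 1")
    return N * (N - 1) // 2


@dataclass
class MINetwork:
    """A thresholded MI network plus the full pairwise test results.

    ``results`` holds one row per tested pair (molecule_a, molecule_b,
    mi_nats, p_value, M_used); the edge set is exactly the rows with
    p_value < p0.  Molecules excluded before testing (constant rows) are
    kept in ``excluded`` so their pairs are reported untested, never as
    absent edges.
    """

    node_ids: tuple[str, ...]
    results: pd.DataFrame
    p0: float = 0.05
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.node_ids = tuple(self.node_ids)
        self.excluded = tuple(self.excluded)

    @property
    def N(self) -> int:
        return len(self.node_ids)

    def edge_set(self, p0: float | None = None) -> set[tuple[str, str]]:
        p0 = self.p0 if p0 is None else p0
        sub = self.results[self.results["p_value"] < p0]
        return {tuple(sorted((a, b))) for a, b in zip(sub["molecule_a"], sub["molecule_b"])}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return self.edge_set()

    @property
    def E(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        edges = self.edges
        for row in self.results.itertuples():
            pair = tuple(sorted((row.molecule_a, row.molecule_b)))
            if pair in edges:
                g.add_edge(*pair, mi=row.mi_nats, p=row.p_value)
        return g

    # ------------------------------------------------------------------ io
    def write_results(self, path: str | Path) -> None:
        self.results.to_csv(path, sep="\t", index=False)

    def write_edge_list(self, path: str | Path) -> None:
        sub = self.results[self.results["p_value"] < self.p0]
        sub.to_csv(path, sep="\t", index=False)

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\tmi\t{b}\n")

    def write_graphml(self, path: str | Path,
                      annotations: dict[str, frozenset[str]] | None = None) -> None:
        g = self.to_networkx()
        if annotations:
            for node in g.nodes:
                if node in annotations:
                    g.nodes[node]["node_types"] = "|".join(sorted(annotations[node]))
        nx.write_graphml(g, path)


def infer_network(
    matrix: pd.DataFrame,
    cfg: MIEstimatorConfig = MIEstimatorConfig(),
    p0: float = 0.05,
) -> MINetwork:
    """Test all N(N-1)/2 pairs of a molecule x sample matrix.

    The matrix is standardized first; constant rows are excluded and
    reported.  Per-pair permutation streams derive from the config seed and
    the sorted molecule IDs, so the result is independent of pair order.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    std, excluded = standardize(matrix)
    ids = list(std.index)
    rows = []
    data = std.to_numpy()
    for ia, ib in itertools.combinations(range(len(ids)), 2):
        a, b = ids[ia], ids[ib]
        res = permutation_test_independence(data[ia], data[ib], cfg, pair=(a, b))
        rows.append((a, b, res.mi, res.p_value, res.M_used))
    results = pd.DataFrame(rows, columns=["molecule_a", "molecule_b",
                                          "mi_nats", "p_value", "M_used"])
    return MINetwork(node_ids=tuple(ids), results=results, p0=p0,
                     excluded=tuple(excluded))


def network_from_results(results: pd.DataFrame, node_ids: Iterable[str],
                         p0: float) -> MINetwork:
    """Re-threshold stored pairwise results without re-running permutations."""
    return MINetwork(node_ids=tuple(node_ids), results=results, p0=p0)


@dataclass
class ResponseNetwork:
    """The difference of two condition networks: one fate per node pair."""

    node_ids: tuple[str, ...]
    fate: dict[tuple[str, str], str]

    def pairs_with_fate(self, *fates: str) -> set[tuple[str, str]]:
        want = set(fates)
        return {p for p, f in self.fate.items() if f in want}

    @property
    def response_edges(self) -> set[tuple[str, str]]:
        """PtoP, AtoP and PtoA pairs (all pairs that are an edge in at
        least one condition)."""
        return self.pairs_with_fate("PtoP", "AtoP", "PtoA")

    def counts(self) -> dict[str, int]:
        out = {f: 0 for f in FATES}
        for f in self.fate.values():
            out[f] += 1
        return out


def response_network(net0: MINetwork, net4: MINetwork) -> ResponseNetwork:
    """Classify every node pair by presence in the two condition networks."""
    if set(net0.node_ids) != set(net4.node_ids):
        raise ValueError("node sets differ between the two networks")
    e0, e4 = net0.edges, net4.edges
    fate: dict[tuple[str, str], str] = {}
    for a, b in itertools.combinations(sorted(net0.node_ids), 2):
        pair = (a, b)
        in0, in4 = pair in e0, pair in e4
        if in0 and in4:
            fate[pair] = "PtoP"
        elif in4:
            fate[pair] = "AtoP"
        elif in0:
            fate[pair] = "PtoA"
        else:
            fate[pair] = "AtoA"
    return ResponseNetwork(node_ids=tuple(sorted(net0.node_ids)), fate=fate)


def degree_distribution(net: MINetwork) -> pd.Series:
    """Node-degree histogram over degrees 0..N-1; total mass N and
    zero-degree nodes included."""
    g = net.to_networkx()
    degrees = [d for _, d in g.degree()]
    counts = np.bincount(degrees, minlength=net.N)
    return pd.Series(counts[:net.N], index=range(net.N), name="n_nodes")


def compare_degree_distributions(
    netA: MINetwork,
    netB: MINetwork,
    method: str = "cvm",
    bonferroni: int = 1,
) -> tuple[float, float]:
    """Two-sample test on the two per-node degree sequences.

    Default is the two-sample Cramér–von Mises test (consistent with the
    ET-distribution comparisons); ``method="ks"`` selects
    Kolmogorov–Smirnov.  ``bonferroni`` multiplies the p-value by the size
    of the comparison family, capped at 1.
    """
    from scipy import stats

    da = [d for _, d in netA.to_networkx().degree()]
    db = [d for _, d in netB.to_networkx().degree()]
    if method == "cvm":
        res = stats.cramervonmises_2samp(da, db)
    elif method == "ks":
        res = stats.ks_2samp(da, db)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), min(1.0, float(res.pvalue) * bonferroni)
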