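"""Graph density, ET graph density, conventional statistics and the
threshold-robustness scan.

Graph density is D = 2E / (N(N-1)).  The ET graph density restricts the
count to one edge type: E_ET is the (possibly fractional) weighted edge
count of that ET and N_ET the number of nodes whose label set intersects
the ET's label pair, so the denominator of D_ET includes all pairs among
those nodes.  The robustness scan perturbs the edge-existence threshold p0
around its reference value and asks how stable each network statistic's
per-node (or per-ET) profile is, measured as the absolute Spearman rank
correlation against the reference profile, normalized to 1 at the
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .edge_typing import ETCatalog, et_distribution
from .network import MINetwork, network_from_results

__all__ = [
    "graph_density",
    "et_graph_density",
    "DensityReport",
    "density_report",
    "conventional_stats",
    "robustness_scan",
    "condition_scan",
    "RobustnessScan",
]

CONVENTIONAL_STATS = (
    "path_length",
    "clustering",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
)


def graph_density(E: float, N: int) -> float:
    """D = 2E / (N(N-1))."""
    if N < 2:
        raise ValueError("graph density needs N >= 2")
    max_e = N * (N - 1) / 2
    if E < 0 or E > max_e:
        raise ValueError(f"edge count {E} outside [0, {max_e}]")
    return 2 * E / (N * (N - 1))


def et_graph_density(
    edges: Iterable[tuple[str, str]],
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
    et: tuple[str, str],
    node_ids: Iterable[str],
    bipartite: bool = False,
) -> float:
    """D_ET = 2 E_ET / (N_ET (N_ET - 1)) for one edge type.

    E_ET sums the fractional weights this ET receives over the edge set.
    N_ET counts nodes annotated with either label of the ET.  With
    ``bipartite=True`` a cross-type ET instead uses the tighter N_a * N_b
    denominator.  Returns NaN when the denominator is degenerate (fewer
    than 2 eligible nodes).
    """
    et = catalog.canonical(et)
    dist = et_distribution(edges, annotations, catalog)
    e_et = dist.weights[et]
    la, lb = et
    members_a = {n for n in node_ids if la in annotations.get(n, ())}
    members_b = {n for n in node_ids if lb in annotations.get(n, ())}
    if bipartite and la != lb:
        denom = len(members_a) * len(members_b)
    else:
        n_et = len(members_a | members_b)
        denom = n_et * (n_et - 1) / 2
    if denom < 1:
        return math.nan
    return e_et / denom


@dataclass
class DensityReport:
    D: float
    E: float
    N: int
    per_et: pd.DataFrame  # columns: et, E_ET, N_ET, D_ET

    def to_frame(self) -> pd.DataFrame:
        return self.per_et


def density_report(
    net: MINetwork,
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
) -> DensityReport:
    edges = net.edges
    dist = et_distribution(edges, annotations, catalog)
    rows = []
    for et in catalog.pairs:
        la, lb = et
        members = {n for n in net.node_ids
                   if annotations.get(n, frozenset()) & {la, lb}}
        n_et = len(members)
        e_et = dist.weights[et]
        d_et = 2 * e_et / (n_et * (n_et - 1)) if n_et >= 2 else math.nan
        rows.append((f"{la}--{lb}", e_et, n_et, d_et))
    per_et = pd.DataFrame(rows, columns=["et", "E_ET", "N_ET", "D_ET"])
    return DensityReport(D=graph_density(net.E, net.N), E=net.E, N=net.N,
                         per_et=per_et)


def conventional_stats(net: MINetwork | nx.Graph) -> pd.DataFrame:
    """Per-node vectors of the classical network statistics.

    path_length is the node's mean shortest-path distance to the nodes it
    can reach (NaN for isolated nodes); centralities use their standard
    normalized definitions.
    """
    g = net.to_networkx() if isinstance(net, MINetwork) else net
    nodes = sorted(g.nodes)
    clustering = nx.clustering(g)
    degree_c = nx.degree_centrality(g)
    closeness = {n: nx.closeness_centrality(g, n) for n in nodes}
    betweenness = nx.betweenness_centrality(g)
    path_mean: dict[str, float] = {}
    for n in nodes:
        lengths = nx.single_source_shortest_path_length(g, n)
        lengths.pop(n, None)
        path_mean[n] = float(np.mean(list(lengths.values()))) if lengths else math.nan
    return pd.DataFrame({
        "path_length": [path_mean[n] for n in nodes],
        "clustering": [clustering[n] for n in nodes],
        "degree_centrality": [degree_c[n] for n in nodes],
        "closeness_centrality": [closeness[n] for n in nodes],
        "betweenness_centrality": [betweenness[n] for n in nodes],
    }, index=nodes)


def _abs_spearman(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return math.nan
    rho = stats.spearmanr(a, b).statistic
    return abs(float(rho))


@dataclass
class RobustnessScan:
    """Absolute Spearman correlations of statistic profiles against the
    reference network, normalized so the reference value is 1."""

    reference: object  # threshold or condition label
    table: pd.DataFrame  # index: threshold/condition, columns: statistics

    def total_deviation(self, column: str) -> float:
        """Sum of |1 - value| over the scan; smaller = more robust."""
        col = self.table[column].dropna()
        return float(np.abs(1.0 - col).sum())


def _et_density_vector(net: MINetwork, annotations, catalog) -> np.ndarray:
    return density_report(net, annotations, catalog).per_et["D_ET"].to_numpy()


def _profiles(net: MINetwork, annotations, catalog) -> dict[str, np.ndarray]:
    conv = conventional_stats(net)
    out = {stat: conv[stat].to_numpy() for stat in CONVENTIONAL_STATS}
    out["et_density"] = _et_density_vector(net, annotations, catalog)
    return out


def robustness_scan(
    results: pd.DataFrame,
    node_ids: Iterable[str],
    thresholds: Iterable[float],
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
    reference: float = 0.05,
) -> RobustnessScan:
    """Stability of statistic profiles as p0 is perturbed around reference.

    Networks are rebuilt from the stored p-values at each threshold (no
    re-permutation); each statistic's per-node (per-ET for ET density)
    profile is rank-correlated against the profile at the reference
    threshold and the |Spearman rho| curve is normalized to 1 there.
    """
    thresholds = sorted(set(thresholds) | {reference})
    node_ids = tuple(node_ids)
    ref_net = network_from_results(results, node_ids, reference)
    ref_prof = _profiles(ref_net, annotations, catalog)
    rows = {}
    for p0 in thresholds:
        net = network_from_results(results, node_ids, p0)
        prof = _profiles(net, annotations, catalog)
        rows[p0] = {stat: _abs_spearman(prof[stat], ref_prof[stat])
                    for stat in prof}
    table = pd.DataFrame(rows).T
    # normalize each curve so its reference point is exactly 1
    ref_row = table.loc[reference]
    table = table / ref_row
    return RobustnessScan(reference=reference, table=table)


def condition_scan(
    networks: Mapping[str, MINetwork],
    annotations: Mapping[str, frozenset[str]],
    catalog: ETCatalog,
    reference: str,
) -> RobustnessScan:
    """Same statistic profiles compared across condition networks,
    normalized to 1 at the reference condition."""
    if reference not in networks:
        raise KeyError(f"reference condition {reference!r} not among networks")
    ref_prof = _profiles(networks[reference], annotations, catalog)
    rows = {}
    for cond, net in networks.items():
        if set(net.node_ids) != set(networks[reference].node_ids):
            raise ValueError("all condition networks must share a node set")
        prof = _profiles(net, annotations, catalog)
        rows[cond] = {stat: _abs_spearman(prof[stat], ref_prof[stat])
                      for stat in prof}
    table = pd.DataFrame(rows).T
    table = table / table.loc[reference]
    return RobustnessScan(reference=reference, table=table)
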