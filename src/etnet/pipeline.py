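"""Study-shaped orchestration: matrices in, comparison reports out.

A study has one or more omics layers (e.g. metabolome, transcriptome),
each measured under several conditions (typically genotype x timepoint).
For every layer the pipeline infers one MI network per condition, builds
the response network of each declared condition pair, types the edges,
and emits density reports, per-ET response distributions and rankings,
chi-squared distances, a CvM comparison table, MI-difference counts among
the stable (PtoP) edges, MDS embeddings and threshold-robustness scans.
All stages derive their randomness from the one root seed.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison import (CvMResult, compare_et_distributions, et_distance_matrix,
                         major_class_subset, net_change_ranking, torgerson_mds)
from .edge_typing import (AnnotationTable, ETCatalog, NodeTypeScheme, build_catalog,
                          et_distribution, response_distribution_per_et, FATES)
from .metrics import RobustnessScan, density_report, robustness_scan
from .mi import MIEstimatorConfig, permutation_test_mi_difference, standardize
from .network import MINetwork, infer_network, response_network

__all__ = ["StudyConfig", "StudyReport", "run_study"]

log = logging.getLogger("etnet")


@dataclass
class StudyConfig:
    """Everything needed to run a full study.

    ``layers`` maps layer name -> {condition -> matrix (DataFrame) or TSV
    path}.  ``response_pairs`` lists (label, condition_before,
    condition_after) triples; each produces one response network per
    layer.  The ET catalog is shared across layers so layer-vs-layer
    comparisons are well defined.
    """

    layers: Mapping[str, Mapping[str, object]]
    annotations: Mapping[str, frozenset] | str | Path
    response_pairs: Sequence[tuple[str, str, str]]
    scheme: NodeTypeScheme = field(default_factory=NodeTypeScheme)
    estimator: MIEstimatorConfig = field(default_factory=MIEstimatorConfig)
    p0: float = 0.05
    thresholds: Sequence[float] = (0.03, 0.04, 0.05, 0.06, 0.07)
    et_subset: Sequence[tuple[str, str]] | None = None  # default: 15 major-class ETs
    output_dir: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        for label, c0, c4 in self.response_pairs:
            for layer, conds in self.layers.items():
                if c0 not in conds or c4 not in conds:
                    raise ValueError(
                        f"response pair {label!r} references conditions missing "
                        f"from layer {layer!r}")


@dataclass
class StudyReport:
    catalog: ETCatalog
    networks: dict[tuple[str, str], MINetwork]               # (layer, condition)
    responses: dict[tuple[str, str], object]                 # (layer, pair label)
    densities: dict[tuple[str, str], object]
    et_distributions: dict[tuple[str, str], object]
    response_distributions: dict[tuple[str, str], dict]
    rankings: dict[tuple[str, str], pd.DataFrame]
    chi2_distances: dict[str, pd.DataFrame]
    mds: dict[str, pd.DataFrame]
    cvm_table: pd.DataFrame
    mi_difference: pd.DataFrame
    robustness: dict[tuple[str, str], RobustnessScan]


def _load_matrix(value) -> pd.DataFrame:
    if isinstance(value, pd.DataFrame):
        return value
    return pd.read_csv(value, sep="\t", index_col=0)


def _load_annotations(value, scheme: NodeTypeScheme):
    if isinstance(value, (str, Path)):
        from .edge_typing import read_annotations
        return read_annotations(value, scheme)
    return AnnotationTable.from_mapping(value, scheme)


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the full workflow and (optionally) write the report bundle.

    Deterministic given the config and root seed; per-pair permutation
    streams make results independent of evaluation order.
    """
    cfg.validate()
    catalog = build_catalog(cfg.scheme)
    annotations = _load_annotations(cfg.annotations, cfg.scheme)
    subset = (list(cfg.et_subset) if cfg.et_subset is not None
              else major_class_subset(catalog))
    subset = [catalog.canonical(et) for et in subset]

    networks: dict[tuple[str, str], MINetwork] = {}
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    densities = {}
    et_dists = {}
    robustness = {}
    for layer, conds in cfg.layers.items():
        for cond, value in conds.items():
            t0 = time.perf_counter()
            matrix = _load_matrix(value)
            est = MIEstimatorConfig(
                spline_order_k=cfg.estimator.spline_order_k,
                bin_rule=cfg.estimator.bin_rule,
                n_permutations_B=cfg.estimator.n_permutations_B,
                seed=cfg.seed,
                add_one_smoothing=cfg.estimator.add_one_smoothing)
            net = infer_network(matrix, est, cfg.p0)
            networks[(layer, cond)] = net
            matrices[(layer, cond)] = matrix
            densities[(layer, cond)] = density_report(net, annotations, catalog)
            et_dists[(layer, cond)] = et_distribution(net.edges, annotations, catalog)
            robustness[(layer, cond)] = robustness_scan(
                net.results, net.node_ids, cfg.thresholds, annotations, catalog,
                reference=cfg.p0)
            log.info("inferred %s/%s: N=%d E=%d (%.1fs)", layer, cond,
                     net.N, net.E, time.perf_counter() - t0)

    responses = {}
    resp_dists = {}
    rankings = {}
    mi_diff_rows = []
    for layer in cfg.layers:
        for label, c0, c4 in cfg.response_pairs:
            net0, net4 = networks[(layer, c0)], networks[(layer, c4)]
            resp = response_network(net0, net4)
            responses[(layer, label)] = resp
            dist = response_distribution_per_et(resp, annotations, catalog)
            resp_dists[(layer, label)] = dist
            rankings[(layer, label)] = net_change_ranking(
                {et: dist[et] for et in subset})
            n_sig, n_ptop = _mi_difference_counts(
                matrices[(layer, c0)], matrices[(layer, c4)], resp, cfg)
            mi_diff_rows.append((layer, label, n_ptop, n_sig,
                                 100 * n_sig / max(1, net0.N * (net0.N - 1) // 2),
                                 100 * n_sig / n_ptop if n_ptop else float("nan")))
    mi_difference = pd.DataFrame(
        mi_diff_rows, columns=["layer", "response", "n_PtoP", "n_significant",
                               "pct_full_connection", "pct_PtoP"])

    # chi-squared distances between response-edge fate histograms, per ET,
    # across response networks (and layers), plus their MDS embedding
    chi2_tables = {}
    mds_tables = {}
    resp_keys = list(resp_dists)
    for et_key, hist_source in (("response_fates", resp_dists),):
        for key_a, key_b in itertools.combinations(resp_keys, 2):
            name = f"{key_a[0]}:{key_a[1]}__vs__{key_b[0]}:{key_b[1]}"
            rows = []
            from .comparison import chi2_histogram_distance
            for et in subset:
                ha = np.array([hist_source[key_a][et][f] for f in FATES])
                hb = np.array([hist_source[key_b][et][f] for f in FATES])
                if ha.sum() == 0 or hb.sum() == 0:
                    rows.append((f"{et[0]}--{et[1]}", float("nan")))
                else:
                    rows.append((f"{et[0]}--{et[1]}",
                                 chi2_histogram_distance(ha, hb)))
            chi2_tables[name] = pd.DataFrame(rows, columns=["et", "chi2_distance"])
    # per-response-network ET x ET distance matrix over fate histograms + MDS
    for key in resp_keys:
        hists = {et: [resp_dists[key][et][f] for f in FATES] for et in subset}
        D = et_distance_matrix(hists, subset)
        name = f"{key[0]}:{key[1]}"
        chi2_tables[f"et_matrix__{name}"] = D
        if len(D) >= 2:
            mds_tables[name] = torgerson_mds(D, dim=2)

    # CvM comparison of ET fingerprints across conditions within each layer
    cvm_rows = []
    for layer, conds in cfg.layers.items():
        cond_list = list(conds)
        family = len(cond_list) * (len(cond_list) - 1) // 2
        for ca, cb in itertools.combinations(cond_list, 2):
            try:
                res = compare_et_distributions(
                    et_dists[(layer, ca)], et_dists[(layer, cb)], catalog,
                    bonferroni=max(1, family))
            except ValueError:
                res = CvMResult(float("nan"), float("nan"), family)
            cvm_rows.append((layer, ca, cb, res.statistic, res.p_value))
    cvm_table = pd.DataFrame(
        cvm_rows, columns=["layer", "condition_a", "condition_b",
                           "cvm_statistic", "p_bonferroni"])

    report = StudyReport(
        catalog=catalog, networks=networks, responses=responses,
        densities=densities, et_distributions=et_dists,
        response_distributions=resp_dists, rankings=rankings,
        chi2_distances=chi2_tables, mds=mds_tables, cvm_table=cvm_table,
        mi_difference=mi_difference, robustness=robustness)
    if cfg.output_dir is not None:
        _write_bundle(report, cfg)
    return report


def _mi_difference_counts(m0: pd.DataFrame, m4: pd.DataFrame, resp,
                          cfg: StudyConfig) -> tuple[int, int]:
    """Among PtoP edges, count pairs whose MI differs between conditions
    (permutation test, p < p0)."""
    s0, _ = standardize(m0)
    s4, _ = standardize(m4)
    ptop = sorted(resp.pairs_with_fate("PtoP"))
    n_sig = 0
    for a, b in ptop:
        p = permutation_test_mi_difference(
            s0.loc[a].to_numpy(), s0.loc[b].to_numpy(),
            s4.loc[a].to_numpy(), s4.loc[b].to_numpy(),
            MIEstimatorConfig(spline_order_k=cfg.estimator.spline_order_k,
                              bin_rule=cfg.estimator.bin_rule,
                              n_permutations_B=cfg.estimator.n_permutations_B,
                              seed=cfg.seed + 1,
                              add_one_smoothing=cfg.estimator.add_one_smoothing),
            pair=(a, b))
        if p < cfg.p0:
            n_sig += 1
    return n_sig, len(ptop)


def _write_bundle(report: StudyReport, cfg: StudyConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (layer, cond), net in report.networks.items():
        net.write_results(out / f"pairs_{layer}_{cond}.tsv")
        net.write_edge_list(out / f"edges_{layer}_{cond}.tsv")
        net.write_sif(out / f"network_{layer}_{cond}.sif")
    for (layer, cond), rep in report.densities.items():
        rep.per_et.to_csv(out / f"density_{layer}_{cond}.tsv", sep="\t", index=False)
    for (layer, label), resp in report.responses.items():
        rows = [(a, b, f) for (a, b), f in sorted(resp.fate.items())]
        pd.DataFrame(rows, columns=["molecule_a", "molecule_b", "fate"]).to_csv(
            out / f"response_{layer}_{label}.tsv", sep="\t", index=False)
    for (layer, label), rank in report.rankings.items():
        rank.to_csv(out / f"ranking_{layer}_{label}.tsv", sep="\t")
    for name, table in report.chi2_distances.items():
        table.to_csv(out / f"chi2_{name}.tsv", sep="\t",
                     index=isinstance(table.index, pd.Index) and table.index.name is None)
    for name, coords in report.mds.items():
        coords.to_csv(out / f"mds_{name}.tsv", sep="\t")
    report.cvm_table.to_csv(out / "cvm_table.tsv", sep="\t", index=False)
    report.mi_difference.to_csv(out / "mi_difference.tsv", sep="\t", index=False)
    for (layer, cond), scan in report.robustness.items():
        scan.table.to_csv(out / f"robustness_{layer}_{cond}.tsv", sep="\t")
    summary = {
        "densities": {f"{layer}/{cond}": rep.D
                      for (layer, cond), rep in report.densities.items()},
        "edge_counts": {f"{layer}/{cond}": net.E
                        for (layer, cond), net in report.networks.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
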