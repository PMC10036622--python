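"""Type edges by annotation classes and summarize a network as an ET
distribution.

Every edge's type (ET) is the unordered pair of its endpoints' annotation
labels; with 11 metabolism classes there are 66 possible ETs.  Multi-label
molecules split an edge's unit weight equally over the distinct ETs its
label combinations form.  The weighted count per ET is the network's
fingerprint; per-ET graph densities normalize it by each ET's possible
pair count.
"""

from etnet import (MIEstimatorConfig, build_catalog, density_report,
                   edge_types_of, et_distribution, infer_network)
from etnet.datasets import demo_study_cohorts

catalog = build_catalog()  # 11 labels -> 66 ETs
print(f"{catalog.scheme.s} node types -> {catalog.t} edge types")

wt = demo_study_cohorts(seed=0)["WT"]
mol = next(m for m, labels in wt.annotations.items() if len(labels) == 2)
partner = next(m for m in wt.annotations if m != mol)
print(f"\n{mol} has labels {set(wt.annotations[mol])}; its edge to "
      f"{partner} ({set(wt.annotations[partner])}) is typed as:")
for et, w in edge_types_of((mol, partner), wt.annotations, catalog).items():
    print(f"  {et[0]}--{et[1]}: weight {w:.3f}")

net = infer_network(wt.matrices["OGTT0"], MIEstimatorConfig(seed=0))
dist = et_distribution(net.edges, wt.annotations, catalog)
print(f"\n{dist.n_typed_edges} typed edges; top ETs by weighted count:")
print(dist.as_vector(catalog).sort_values(ascending=False).head(5).to_string())

rep = density_report(net, wt.annotations, catalog)
print(f"\noverall graph density D = {100 * rep.D:.2f}%")
print("per-ET densities (non-empty):")
print(rep.per_et.dropna().query("E_ET > 0").head(5).to_string(index=False))
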