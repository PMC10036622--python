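"""Estimate mutual information for linear and nonlinear dependencies.

Builds three planted molecule pairs — linear, symmetric quadratic and a
sign-flip ("xor") coupling — plus an independent pair, then prints each
pair's Pearson correlation, B-spline MI estimate and permutation p-value.
The two nonlinear pairs have near-zero correlation but clearly positive
MI, which is why the network inference uses MI rather than correlation.
"""

import numpy as np

from etnet import (CohortSpec, MIEstimatorConfig, PlantedEdge, generate_cohort,
                   permutation_test_independence)

spec = CohortSpec(
    n_molecules=8,
    n_samples_per_condition={"demo": 200},
    planted_edges={"demo": [PlantedEdge(0, 1, "linear", 0.9),
                            PlantedEdge(2, 3, "quadratic", 0.9),
                            PlantedEdge(4, 5, "xor", 0.9)]},
    seed=0)
data = generate_cohort(spec).matrices["demo"].to_numpy()
cfg = MIEstimatorConfig(seed=0)

print(f"{'pair':<12}{'pearson r':>10}{'MI (nats)':>11}{'perm p':>8}")
for name, i, j in [("linear", 0, 1), ("quadratic", 2, 3),
                   ("xor", 4, 5), ("independent", 6, 7)]:
    r = np.corrcoef(data[i], data[j])[0, 1]
    res = permutation_test_independence(data[i], data[j], cfg, pair=(str(i), str(j)))
    print(f"{name:<12}{r:>10.3f}{res.mi:>11.3f}{res.p_value:>8.3f}")

print("\nA permutation p below 0.05 links the pair in the network; the")
print("nonlinear pairs are detected although their correlation is ~0.")
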