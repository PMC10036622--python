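# etnet — edge-type network analysis for omics data

`etnet` is a Python library for comparing the *states* of molecular
interaction networks inferred from omics measurements. It addresses a
recurring problem in systems biology: two networks inferred from small
cohorts (say, a dozen mice before and after a glucose challenge) cannot be
compared edge by edge, because with n ≈ 12 samples individual edges are
unreliable. Instead, `etnet` reduces each network to its **edge-type (ET)
distribution** — the weighted count of edges per pair of biological
annotation classes — and compares those fingerprints. The fingerprint is
insensitive to which individual edges moved, much like a bag-of-words
summary of a document, and turns out to be markedly more robust to the
inference threshold than conventional graph statistics.

It is aimed at researchers with molecule × sample abundance matrices
(metabolomics, transcriptomics) measured under several conditions, plus a
node annotation table (e.g. KEGG metabolism classes).

## The method

**Network inference.** For molecules *i*, *j* with abundances
X<sub>i</sub>, X<sub>j</sub>, the mutual information

&nbsp;&nbsp;I(X;Y) = ∬ p(x,y) log [ p(x,y) / (p(x)p(y)) ] dx dy

is estimated by B-spline fractional binning: each standardized sample is
spread over M bins with the weights of the order-k B-spline basis (k = 3
by default; k = 1 recovers an ordinary histogram), and the joint
probability table is the mean outer product of the two weight vectors.
Statistical independence (I = 0) is tested by permuting X (B = 500
permutations); the p-value is the fraction of null MI values exceeding the
observed one, and the edge E<sub>ij</sub> = 1 iff p<sub>ij</sub> < p₀
(default 0.05).

**Response network.** Comparing two condition networks assigns each node
pair one of four fates: P→P (edge in both), A→P (gained), P→A (lost),
A→A (neither). A second permutation test (pooled re-splitting of the
paired samples) asks whether a stable edge's MI *value* changed.

**Edge types.** With s node-type labels there are t = s(s−1)/2 + s ETs
(66 for the 11 KEGG metabolism classes). A multi-label edge splits its
unit weight equally over the distinct ETs formed by its endpoints' label
combinations (weight 1/#E<sub>type,ij</sub> each). Network states are then
compared via the ET graph density D<sub>ET</sub> = 2E<sub>ET</sub> /
(N<sub>ET</sub>(N<sub>ET</sub>−1)), the chi-squared histogram distance
χ²(P,Q) = ½ Σᵢ (Pᵢ−Qᵢ)²/(Pᵢ+Qᵢ) ∈ [0,1], the two-sample
Cramér–von Mises test on ET fingerprints, and a Torgerson (classical) MDS
map of the ET-by-ET distance matrix.

## Worked example

`examples/01_mutual_information.py` plants three dependence kinds and an
independent pair (n = 200) and prints:

```
pair         pearson r  MI (nats)  perm p
linear           0.894      0.403   0.000
quadratic       -0.135      0.127   0.000
xor             -0.022      0.161   0.000
independent      0.029      0.016   0.964
```

The two nonlinear pairs have correlations near zero yet clearly positive
MI with permutation p = 0 — they become edges, which is the reason the
inference uses MI rather than Pearson correlation. The independent pair's
p = 0.964 leaves it unconnected.

`examples/05_robustness.py` perturbs the threshold p₀ across
0.03…0.07 and prints each statistic's total deviation from perfect rank
stability (smaller = more robust):

```
path_length             1.580
clustering              0.843
degree_centrality       0.951
closeness_centrality    1.648
betweenness_centrality  1.517
et_density              0.547
```

The ET graph-density profile is the most stable summary — the property
that justifies using the ET distribution as the network fingerprint.

The remaining examples cover inference + response fates (`02`), edge
typing and densities (`03`), and the full study comparison with rankings,
CvM tests and MDS (`04`). A thin CLI mirrors the library
(`etnet simulate|infer|respond|ettype|mds|run`).

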