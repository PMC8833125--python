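# Methods

## The model

`metabonet` analyzes **group-level metabolic brain networks**. The raw
datum is one standardized uptake value (SUV) per brain region per subject,
obtained from FDG-PET after spatial normalization to a 96-region rat brain
atlas (48 homotopic left/right pairs; the shipped atlas table lists them in
the conventional order — regions 1–48 right hemisphere, 49–96 left). Each
subject's regional values are globally normalized by that subject's
whole-brain mean uptake; at the region level the whole brain is taken to be
the union of the 96 atlas regions, the closest proxy available when the
pipeline runs from tables rather than images (image-driven runs can
normalize by a voxelwise brain-mask mean before extraction instead).

Metabolic connectivity is **inter-subject**: within one group of subjects,
the weight of the edge between regions *i* and *j* is the Pearson
correlation *r* of their normalized SUVs across that group's subjects.
There is therefore one network per group, not per subject, and group
comparison must treat the whole network construction as the statistic.

Each weighted network is binarized over a sparsity grid *S* =
0.05, 0.06, …, 0.50 (46 densities): at sparsity *S* exactly
round(*S*·4560) of the 4560 region pairs are kept, so both groups' graphs
have identical edge counts at every density. Edges are ranked by **signed**
correlation (most positive first); the field treats metabolic coupling as
positive co-variation, and binarized association networks conventionally
retain the strongest positive edges. Absolute-value ranking is available
(`ranking="absolute"`). Ties at a cut are broken by higher |r|, then
lexicographic region order — deterministic and logged. round() is
half-away-from-zero, fixed explicitly so edge counts are
platform-independent.

## Graph metrics

On each binary graph: characteristic path length Lp, clustering
coefficient Cp, global and local efficiency E_glob / E_loc, and the nodal
degree D, betweenness centrality BC and nodal efficiency E_nod. Exact
conventions (stated because they decide oracle agreement):

* **Lp** averages shortest-path length over *connected* pairs only.
  Thresholded connectomes are disconnected at low density; excluding
  infinite pairs (rather than restricting to the largest component or
  propagating infinity) keeps Lp defined across the whole grid and matches
  common practice for binarized connectomes. Alternative conventions would
  change Lp's absolute level but the permutation tests compare groups under
  the same convention.
* Efficiencies use 1/d with 1/∞ = 0, so they are defined on any graph.
* Nodes of degree < 2 contribute 0 (are not excluded) to the Cp and E_loc
  means over all nodes.
* **BC** is unnormalized, undirected (each unordered pair once). Group
  comparisons are invariant to the normalization constant.
* **Small-world indices**: γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ against an
  ensemble of degree-preserving randomized graphs
  (Maslov–Sneppen double-edge swapping, 10× edge-count swap attempts per
  graph), with σ = γ/λ exactly. The full protocol uses 5000 random networks
  per graph (the `small_world` default); inside permutation loops and
  attack trajectories the ensemble is reduced (configurable,
  `ensemble_size_in_perm`, default 20–100 depending on the entry point) —
  the normalization noise this adds is identical in distribution for both
  groups and enters the permutation null honestly.

Distances are computed by a vectorized boolean-matmul BFS closure
(cross-checked in the tests against `scipy.sparse.csgraph` and a
pure-Python BFS oracle); BC and rewiring use igraph's C routines
(cross-checked against an exhaustive shortest-path-enumeration oracle).

Metric curves over the grid are summarized by their **area under the curve
(AUC)**, computed by the trapezoid rule (the quadrature is not prescribed
by the protocol; trapezoid is the standard choice). Grid points where an
ensemble-normalized metric is undefined (zero ensemble clustering) are
dropped pairwise with a warning.

## Group comparison

All tests are **label permutations**: subjects are reassigned to two groups
of the original sizes and the full statistic pipeline — both correlation
matrices, both stacks, metric curves, AUCs — is recomputed per cycle
(defaults: 5000 cycles).

* Edge level: statistic r_A − r_B per pair; two-tailed p; significance at
  p < 0.001 uncorrected, split into increased/decreased by sign.
* Global level: statistic AUC_A − AUC_B per metric; α = 0.05.
* Nodal level: AUC difference per region for D, BC, E_nod;
  Benjamini–Hochberg FDR at q = 0.05 applied separately per metric across
  the 96 regions (the conservative default; joint correction across the
  3×96 family is a switch away).

p-values use the add-one form p = (1 + #{|null| ≥ |obs|})/(1 + P), which is
valid (never zero; minimum 1/(P+1)). Implementation detail with a
consequence: permutations shuffle the group-membership *mask* rather than
the data rows, so relabeling the groups exactly negates every observed and
null difference and leaves every p-value unchanged (asserted in the tests).
Permutations are sampled without enforcing uniqueness (P = 5000 ≪ C(47,23)).

## Robustness simulation

Nodes are deleted one at a time, in uniformly random order (40 independent
orderings, trajectories averaged) or in descending order of BC. The
targeted ordering is **static** — computed once on the intact network from
the AUC of each node's BC curve over the grid (consistent with how nodal
metrics are compared elsewhere); recomputing after each removal is a
configuration option, as is ranking at a single density. After each
removal:

* the surviving nodes' weighted submatrix is re-thresholded at the
  **minimum density with full connectivity** (edges added in descending
  correlation order until one component remains — a Kruskal-style
  construction whose retained edge count is provably minimal for the
  deterministic tie order), and the global metrics are computed on that
  connected graph, so Lp is always finite;
* the size of the largest connected component (LCC) is tracked on the
  *intact* network binarized at its own minimum connected density, with the
  removed nodes deleted. (On the re-thresholded remaining graph the LCC
  would be the whole graph by construction; tracking it on the fixed intact
  backbone is the reading that makes the two robustness outputs distinct.)

Group comparison per removal step reuses the permutation machinery:
targeted orderings are regenerated inside each permutation from the
permuted groups' own BC; random orderings are reused across permutations
(variance reduction — the orderings are ancillary). The repetition-averaged
statistic is tested. A projected-cost guard refuses budgets above a
configurable ceiling rather than silently running for hours.

## The synthetic cohort

No scan data are redistributable, so the package ships a generator that
emulates the study design: two groups (23 "aged", 24 "young") of 96-region
SUV vectors drawn as independent multivariate normals from group-specific
correlation matrices, then mapped to SUV scale (mean 1.0 after global
normalization, dispersion 0.15). Pearson correlation is location/scale
invariant, so the Gaussian marginal is immaterial to everything downstream;
no log-normal model is needed.

The base correlation structure is 4 communities of 24 regions
(within-community r = 0.5, between 0.1) — a coarse stand-in for the
modular covariance of regional metabolism. Group differences are planted by
overwriting individual entries: the default study spec plants eight
within-community edge differences at r = 0.8 vs 0.0 (four increased, four
decreased in the aged group) and one hub perturbation (region 12's
correlations to 20 community-2 partners raised from 0.1 to 0.45 in the
aged group only). Requested matrices are projected to the nearest
correlation matrix (alternating projections: eigenvalue clipping onto the
PSD cone with Dykstra correction, alternated with unit-diagonal
restoration); the realized-vs-requested distortion is reported, and a
request whose planted entries move by more than 0.1 is refused as
non-realizable. This matters in practice: a strong correlation between
members of two otherwise weakly-coupled communities is geometrically
infeasible, which bounds how large planted cross-community effects can be.

What the generator does **not** emulate: PET physics, scanner and
reconstruction noise, partial-volume effects, spatial smoothing-induced
neighborhood correlation, hemispheric symmetry, or any non-Gaussian tail
behavior. Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the design's sampling model, not
performance on real scans.

One master integer seed drives everything through named child streams
(`SeedSequence` keyed by stage name), so each stage is independently
reproducible and two runs of one config produce byte-identical reports.

## Statistical power at the study's sample sizes

Two honest findings from the package's own simulations, worth knowing
before interpreting edge-level or nodal results at n ≈ 23/group:

* A planted single-edge difference of r = 0.8 vs 0.0 is flagged at
  p < 0.001 in only ~25–30% of cohorts. The permutation null mixes the two
  populations (pooled r ≈ 0.4), so the null spread of the r-difference is
  ≈ 0.29, and an observed difference of ≈ 0.8 sits near 2.7σ — the
  uncorrected 0.001 threshold is simply a tall bar at these sample sizes.
* Nodal-degree FDR recovery of a planted hub is weaker still: every
  PSD-feasible hub perturbation we scanned yields permutation p-values for
  the hub's D-AUC in the 0.04–0.9 range, while BH-FDR across 96 regions
  needs p ≲ 5×10⁻⁴. Regions surviving FDR at these group sizes indicate
  effects substantially stronger than a correlation matrix can express as a
  single-hub perturbation of a modular background.

## Numerical and scaling choices

* Edge counts use half-away-from-zero rounding; all tie-breaks are
  deterministic; every stochastic entry point requires a seed.
* The acceptance script (`scripts/acceptance.py`) and the test suite scale
  simulation sizes (permutations per test, ensemble sizes inside
  permutation loops, attack-step subsampling, seed counts for calibration)
  to keep runs in the minutes range; the constants at the top of the script
  record the sizes used. Calibration assertions use binomial/Poisson bounds
  matched to those scaled sizes.
* Degenerate inputs: zero-variance regions are refused by name (r
  undefined); graphs with no connected pair return NaN Lp rather than
  raising; complete graphs are returned unchanged by the rewirer with a
  warning; empty node sets have LCC 0.

## Known limitations

* The sparsity range, edge ranking convention and disconnected-Lp handling
  are conventions, not identities; results at a single density can differ
  from AUC-based conclusions.
* The LCC-on-intact-backbone reading of the robustness output is one of
  two defensible readings of the procedure (see above); the other is
  trivial, which is why it was rejected.
* γ/λ/σ inside attack loops use reduced ensembles; their per-step values
  are noisier than the headline intact-network values.
* The generator's planted effects are block-plus-spike correlation
  structures; real aging effects are diffuse and correlated with the
  community structure itself.
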