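# Methods

This note records the model, the algorithmic choices, the defaults and the
limits of what the test battery demonstrates.

## Data model and curation

An input record is a SMILES string with an optional logS (log10 mol/L) and
source tag. Standardization is: parse → cleanup → keep the largest
covalently bonded organic fragment (counter-ions stripped; a structure
without carbon is rejected) → neutralize charges where chemically valid →
canonical SMILES → InChIKey. The InChIKey is the deduplication key, so
stereo variants with distinct InChI layers remain distinct molecules and
tautomer normalization is left to the InChI standard layer; tautomer
canonicalization beyond that is deliberately not applied. Failed records
are logged with a reason, never silently dropped.

Replicates of one structure are aggregated to the arithmetic mean and an
inter-source SD with the (n−1) denominator, defined as 0 for a single
measurement. The RELIABLE set — more than one measurement and
0 < SD < 1 log unit — is the yardstick for every downstream optimization;
the boundary cases (SD exactly 0 or exactly 1, single measurements) are
UNRELIABLE. Duplicate measurements with identical value and source are
kept: there is no defensible within-source collapsing rule, and the mean is
unaffected when values agree.

## The forest primitive

All regressors are bagged ensembles of CART trees
(`rrfsol.forest.RegressionForest`) with explicit bookkeeping of in-bag
membership, per-tree predictions and per-feature split counts, built on
scikit-learn's `DecisionTreeRegressor`. Defaults: 500 trees and
max_features = 1/3 for selection (the conventional regression-forest
sampling rate), and full-feature bagging-only forests for PV cleaning and
for the consensus sub-models (below).

## Variable selection

Occurrence importance counts internal split nodes per column over all
trees; it is conserved (counts sum to the total internal-node count).
Defaults that matter:

- **occurrence_threshold = 110 at n_trees = 500.** The pair is meaningful
  only together — halving the forest roughly halves every count — and both
  are configurable as a unit. At dataset sizes where trees carry thousands
  of nodes the marginal threshold is weak and the decoy comparison does the
  filtering.
- **min_samples_leaf = 5 for selection forests.** Fully grown leaf-size-1
  trees spend most of their splits memorizing residual noise, which inflates
  every column's count and dilutes the signal-to-decoy contrast; a leaf
  size of 5 (the classic regression-forest node size) keeps splits
  sample-supported and makes the counts discriminative. Cleaning forests
  use leaf size 1 instead — there the memorization is the point (below).
- **At least 8 candidate columns per split.** With a tiny candidate pool and
  fractional feature sampling a tree is *forced* to split on whatever single
  column it drew, so decoys accumulate counts they never earned and the
  parent-vs-decoy comparison degenerates to a coin flip. The forest
  therefore examines at least `min_features_per_split = 8` columns per node
  (or all of them when fewer exist).
- Decoys are fresh independent permutations each round (one shared
  permutation would preserve inter-column correlations among decoys), drawn
  from a round-derived seed so a lucky draw cannot persist.
- Correlation pruning is greedy by descending occurrence count on absolute
  Pearson correlation (threshold 0.51), ties broken lexicographically for
  determinism.
- Recursion restricts each round's pool to the previous selection, so the
  set shrinks monotonically and a fixed point exists; max_rounds = 10.

A known behaviour, not a bug: noise columns whose chance correlation with
the response is at the top of the null distribution can beat their fresh
decoys round after round, so final selections typically carry the planted
signal plus a few such columns. The decoy filter controls the *typical*
null column, not the maximum of a few hundred draws.

## Prediction-variance cleaning

PV(x) is the (n−1)-variance of the individual tree predictions at x. Its
meaning depends on where x stands relative to the forest:

- For a molecule **inside** the training set, bootstrap trees that sampled
  it (≈ 63 %) carry its reported label into their leaves (leaf size 1),
  while its out-of-bag trees predict what its descriptors imply. A label
  shifted by Δ raises the PV by roughly p(1−p)Δ² ≈ 0.23 Δ² — an anomaly
  score for the molecule's own measurement.
- For a **held-out** molecule the PV reflects only local model uncertainty,
  carries no information about the molecule's own label, and sits on a
  systematically larger scale (the full neighbour spread rather than 0.37
  of it).

The cleaning recursion is organized around that asymmetry:

1. **Split pass.** The UNRELIABLE set is split 50/50 (seeded); one forest is
   trained on half A; A is scored in-ensemble, B held-out; labels are
   CLEAN iff PV ≤ threshold (ties CLEAN — "within the threshold" read
   inclusively). No symmetric second model is trained.
2. **Rescoring pass.** A companion forest trained on the whole UNRELIABLE
   set gives every molecule an in-ensemble PV, and all labels are redrawn
   on this single comparable scale. Both directions of relabelling occur
   here: held-out-flagged innocents return, mislabelled molecules from
   either half are caught.
3. **Refinement passes.** A forest retrained on the current CLEAN set
   rescores CLEAN members in-ensemble; molecules beyond the threshold are
   expelled. Expulsion-only refinement makes CLEAN monotone non-increasing,
   so a fixed point is guaranteed; in practice 3–6 iterations. Cycle
   detection (hash of the label vector; on a cycle, the iteration with the
   fewest UNCLEAN is returned with a warning) is retained as a safeguard,
   and max_iterations = 20 caps the loop.

The design alternative — scoring UNCLEAN members held-out against the
CLEAN-trained forest at every iteration — was evaluated and rejected: a
held-out PV is blind to the molecule's own label, so flagged outliers whose
held-out PV is small are readmitted, re-flagged on the next pass, and the
labels oscillate instead of reaching the fixed point the procedure
requires; and the systematic scale gap between held-out and in-ensemble
PVs means no single threshold serves both.

Cleaning forests default to 300 trees, max_features = 1.0 (the anomaly
contrast relies on per-tree accuracy; randomization comes from the
bootstrap alone) and leaf size 1 (memorization is the signal carrier).

The threshold is fixed or optimized: each candidate runs the full
recursion, a forest is trained on the resulting CLEAN set, and the RMSE on
the RELIABLE set is the objective (argmin; ties favour the larger
threshold, keeping more data). The default grid is the split-pass PV
quantiles (0.3, 0.45, 0.6, 0.75, 0.9, 0.95) — scale-free and centred on
the in-ensemble range rather than the held-out-inflated upper tail.
RELIABLE molecules never enter cleaning; the final training set is CLEAN,
optionally plus RELIABLE (`include_reliable_in_training`, on by default
for production training, off in benchmarks where RELIABLE is the test
set).

## Consensus model

Class labels derive from the response at logS = −2 (boundary soluble). A
gradient-boosting classifier (scikit-learn defaults: 100 estimators, rate
0.1, depth 3) gates two class-specific regression forests next to one
global forest. Combination modes, all convex in the sub-predictions:
`mean3` (plain average of the three forests; classifier unused),
`hard_route` (default: classifier-routed class forest averaged with the
global forest) and `soft_route` (probability-weighted class forests
averaged with the global forest). `hard_route` is the default because under
`mean3` the classifier would be dead code. The sub-forests (300 trees)
randomize through the bootstrap alone: the consensus operates on the
post-selection space of a handful of descriptors, where fractional feature
sampling would leave one or two candidate columns per split and cripple
the trees. Model archives store the four
sub-models, a metadata JSON and a probe matrix whose stored predictions are
re-verified bit-exactly on load (probe floats are written with `%.17g` and
parsed with round-trip precision; the default CSV float path is 1 ulp
lossy).

## Synthetic benchmarks

Descriptors are simulated as i.i.d. standard-normal columns (plus jittered
duplicates, jitter SD 0.3, |r| ≈ 0.96 with the parent), not computed from
simulated structures: the algorithms under test consume numeric matrices,
and real-descriptor behaviour is covered by the 20-record SMILES fixture.
The response is intercept + X·β + ε.

- **SELECTION**: n = 500, 10 informative of 215 columns (200 noise, 5
  duplicates), β magnitudes 0.8–2.0 with alternating signs, residual SD
  0.5. Strong-to-moderate sparse signal typical of a curated QSPR table.
- **CLEANING**: n = 800, 3 informative (β = 1.0, −0.8, 0.6) of 35 columns,
  intercept −2.5, residual SD 0.5; 35 % of molecules carry 2–3 replicates
  with inter-source SD 0.3 (populating RELIABLE), the rest are
  single-source; 15 % of molecules receive a ±3 log label shift, injected
  among the single-source molecules only — a gross error is modelled as a
  one-off report, and a shift reproduced consistently by several sources
  is undetectable by any label-noise filter (and would land in RELIABLE).
- **CONSENSUS**: bimodal intercepts (−2 ± 1.5) straddling the class
  cut-off.

What passing these benchmarks does *not* show: real descriptor tables are
heavily correlated and heavy-tailed, real measurement error is not
Gaussian, and real unreliable measurements are not a clean ±3 log shift.
The benchmarks validate the machinery (recovery, recall, ordering), not
field performance on experimental databases.

## Problem sizes and numerical choices

Benchmark runs use the preset sizes above with the default forests
(10 seeds each for the selection and cleaning/consensus batteries — about
15 s and 45 s per seed respectively on one CPU). Stage seeds derive from a
base seed via CRC-32 of a stage label (always < 2³¹), so any stage can be
reproduced in isolation and reruns are bit-identical. Degenerate inputs are
errors, not silent behaviour: constant response (stump forests, zero
counts), a class side empty at the cut-off, single-tree PV, empty
threshold grids, all-dropped descriptor columns.

## Known limitations

- The occurrence threshold 110 is only meaningful at its paired forest
  size and tree granularity; at other sizes the decoy comparison carries
  the filtering.
- PV cleaning detects label anomalies only for molecules that enter a
  forest's training set; its first held-out pass is retained for fidelity
  to the workflow's structure, not for detection power.
- The paired model comparison assumes approximately normal per-pair
  differences; with 10 repeats the test is indicative, not exact.
- pH, ionization state, salt-form solubility and intrinsic-vs-aqueous
  corrections are out of scope; predictions are for the standardized
  neutral parent structure.
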