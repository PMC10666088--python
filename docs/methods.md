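# Methods

This note documents the model implemented by `gatetree`, the choices made
where the design was genuinely open, what the synthetic data emulate, and
the package's known limitations.

## Setting and assumptions

A mass-cytometry sample is a cells × markers matrix of ion counts. All
computation happens after the variance-stabilising transform
`arcsinh(x / cofactor)` with cofactor 5, the standard choice for mass
cytometry; a flag skips the transform for inputs that ship pre-transformed.
One *reference* sample carries per-cell type labels from manual gating, with
a reserved sentinel (default `"ungated"`, matched case-insensitively) for
cells the analyst left unassigned. The method assumes:

1. cells of one type form a single cluster in marker space (their expression
   patterns are essentially similar), so a type is describable by one
   conjunction of marker thresholds;
2. the *markers* that define a type are universal across biologically
   relevant samples, while the *threshold positions* may drift between
   batches (instrument, time, site);
3. ungated cells lack distinguishing characteristics and must not be forced
   into a type.

## Training: one-vs-rest gating trees

For each gated type, a binary decision tree separates Target (that type)
from Other (all *other gated* types; ungated reference cells take no part in
training, matching the Target/Other construction). Splits are exact: for
every marker, candidate thresholds are the midpoints between consecutive
distinct sorted values within the node, scored by base-2 information gain
ΔH; ties break to the lowest marker index, then the lowest threshold, so
training is deterministic. The tree always descends into the target-enriched
child — the other branch is an immediate rest-leaf — hence the classifier
collapses to the conjunction of conditions along one root-to-leaf path,
directly analogous to a manual gating hierarchy.

Growth stops when the best split's ΔH ≤ `min_entropy_gain` (0.1) or when
descending would keep ≤ `target_retention` (0.9) of **all** reference Target
cells on the path (the retention reading; a purity reading — stop once the
followed node's Target purity reaches the same bound — is available via
`HyperParams.stop_rule="purity"`). Consecutive conditions on the same marker
merge to the tightest bound. A valid leaf must test at least two distinct
markers and hold > 90% of Target cells; depth is capped at 6 (condition
counts in practice are small, typically < 5).

When growth stops before two distinct markers are on the path, the node is
usually already pure and any remaining within-node gain comes from isolated
stray cells, which would produce degenerate, overly loose conditions. The
required extra condition is therefore chosen by scoring candidate splits on
*unused* markers at the root (all gated cells) — recovering the type's
second defining marker with a manual-gating-like threshold — subject to the
retention constraint on the current node; within-node candidates are the
last resort, and a type separable on no marker at all fails loudly.

The trained `GateModel` stores one rule per type plus each type's centroid
(mean expression over **all** classification markers, not only tree markers:
the Euclidean reconciliation and drift test below operate in the full
space). Models serialise to human-readable JSON so a site can train once and
share the classifier.

## Tentative labeling

For each cell of a new sample, every rule's conjunction is evaluated. Zero
matches → tentatively ungated; several matches (types can share markers) →
the nearest-centroid member of the match set. The tree label *i* is then
reconciled with the nearest-centroid label *j* (Euclidean distance over all
classification markers):

* *i* gated, *i = j* → keep *i*;
* *i* gated, *i ≠ j* → switch to *j* only if Ed(cell, cᵢ) − Ed(cell, cⱼ) >
  `d1` (default 1 arcsinh unit);
* *i* ungated → rescue to *j* only if Ed(cell, cⱼ) < `d2` (default 0.05).

`d2` is deliberately strict: in an 8-to-39-dimensional marker space a 0.05
ball around a centroid is tiny, so the rescue fires essentially only for
cells sitting on a centroid. Both constants are exposed in `HyperParams`.

## Boundary tuning

Each rule's thresholds are re-derived on the new sample, one condition at a
time in root-to-leaf order, over the cells satisfying the rule's *other*
(current) conditions. The 1-D sweep starts at the tentative type centroid's
coordinate — the centroid is assumed to lie inside the boundaries — and
expands the admitted region stepwise, with step = (sample-wide marker
range) / `sweep_bins` (200). A step's newly admitted cells are *introduced
positives* (tentative label = the rule's type) or *introduced negatives*
(other types' labels); the boundary settles at the furthest step whose
introduced cells are (a) positive-dominated and (b) not negligible —
at least `density_stop_fraction` (1%) of the densest histogram bin inside
the current boundaries on the same 200-bin grid. Scanning to the furthest
acceptable step (rather than halting at the first unacceptable one) keeps
sparse interior lulls of a population's tail from pinning the boundary,
while dense opposing masses and empty space still bound the region. The
first step is always taken, so the tuned region strictly contains the
tentative centroid.

Tentatively *ungated* cells need care. Under a batch shift, the part of a
population that slipped outside the reference boundaries is tentatively
ungated and lies directly beyond the old threshold; counting those cells as
negatives would pin every boundary at its reference position and make
downward adaptation impossible. The sweep therefore classifies an ungated
cell as a positive when it falls inside the rule's *centroid-translated*
region — every threshold displaced by (tentative centroid − reference
centroid) on its marker, i.e. the reference gate carried to the frame the
tentative centroid defines — and as a negative otherwise. Background cells
far from the translated gate and all cells of other tentative types still
halt the expansion, which is what preserves ungated populations.

Only thresholds are tuned; markers and directions are frozen (assumption 2).
Thresholds may end on either side of their reference value, so boundaries
can contract as well as expand.

## Reclassification and drift iteration

All cells are re-tested against all tuned rules. No match → ungated; one
match → that type; several → the rule with the lowest *impurity* (fraction
of cells inside its tuned region whose tentative label differs from the
rule's type), ties broken by type-name order. Centroids of the reassigned
cells are then compared with the current model centroids: if a strict
majority of types moved more than `drift_threshold` (0.1 arcsinh units,
Euclidean), batch effects are assumed and the procedure repeats from
tentative labeling with the new centroids and tuned rules, up to
`max_iterations` (5; the cap guarantees termination and is logged if hit).
A type with no reassigned cells keeps its previous centroid (zero
displacement). The pipeline is fully deterministic: identical inputs give
bit-identical labelings, models and reports.

## Evaluation

Per-type precision, recall and F = 2PR/(P+R) (0 when degenerate), aggregated
population-weighted (Σ(|cᵢ|/N)·Fᵢ) or unweighted (macro mean). The evaluated
type set is the set of labels present in the truth; with
`include_ungated=False`, cells whose *truth* is ungated are dropped entirely
before any counting (evaluation on manually gated cells only), which also
removes the false positives they would contribute. A type absent from both
truth and prediction has no defined score and is excluded from aggregates
rather than counted as zero.

## Synthetic data

The generator draws each population from independent per-marker Gaussians in
arcsinh space — the space the classifier operates in, which keeps centroid
and threshold recovery analytically checkable — with exact ground-truth
labels. The stock layout emulates a multicenter-style design: 4 cell types
over 8 markers, each type elevated on its own marker pair (means 3.2 high /
0.8 low, spread 0.45 — separable by manual gating yet with touching tails),
and ~25% ungated background composed of a broad diffuse component
(mean 1.0, spread 0.6; 85%) plus low-density Gaussian "bridge" waypoints at
25/50/75% between every pair of type centroids (15%) — intermediate cells
with no distinguishing profile, the hard part of ungated preservation.

Batch effects are per-marker affine maps `scale·x + shift` applied in
arcsinh space. The standard suite pairs each target draw with a shifted copy
(so the two batches differ *only* by the effect) using shift magnitudes
drawn from U(0.35, 0.5) with alternating sign by marker index, so every type
has at least one down-shifted defining marker — real batch effects move
channels in both directions, and down-shifts are the harder direction for a
threshold classifier.

What the generator does **not** emulate: ion-count noise physics, zero
inflation, spillover, doublets, acquisition drift within a sample, or
correlated marker noise. Passing tests on these fixtures therefore
demonstrate the algorithmic contracts (split optimality, retention,
shift recovery, ungated preservation, determinism), not clinical-grade
performance on real CyTOF data.

## Parameter defaults

| Parameter | Default | Units / meaning |
| --- | --- | --- |
| `cofactor` | 5 | arcsinh cofactor for raw counts |
| `d1` | 1.0 | arcsinh distance margin for centroid override |
| `d2` | 0.05 | arcsinh distance cap for ungated rescue |
| `min_entropy_gain` | 0.1 | minimum ΔH (bits) to accept a split |
| `target_retention` | 0.9 | leaf must keep > this fraction of Target cells |
| `density_stop_fraction` | 0.01 | sweep-step floor vs densest bin |
| `drift_threshold` | 0.1 | arcsinh centroid displacement counting as drift |
| `max_iterations` | 5 | refinement rounds cap |
| `max_depth` | 6 | conditions per rule cap |
| `sweep_bins` | 200 | tuning grid resolution |
| `stop_rule` | retention | split-node stopping reading (or "purity") |

## Numerical choices

* Entropy uses base 2 with the 0·log 0 = 0 convention; an equally divided
  node has entropy exactly 1.
* The split search is exhaustive over midpoints and is verified against an
  independent brute-force enumeration in the tests; tie-breaks (lowest
  marker index, then lowest threshold; nearest-centroid ties to the
  lexicographically first type) make every stage deterministic.
* Tuned thresholds live on the 200-step grid, so threshold-recovery checks
  are quantised to one or two steps (1% of the marker range).
* Degenerate inputs: constant markers yield a no-split signal; a rule whose
  type is absent from a sample is returned untuned with a warning; an empty
  tuned region reports impurity 0.

## Problem sizes

The bundled suite uses 4,000-cell samples (750 per type + 1,000 background),
which exercise every pipeline stage in well under a minute; the scale check
trains and gates 100,000 cells × 30 markers in seconds on one CPU. Larger
studies scale linearly in cells and markers (sorting dominates training).

## Known limitations

* A cell type occupying several disjoint marker-space regions violates the
  one-conjunction assumption and cannot be captured by a single rule.
* Batch effects that permute marker *identities* (e.g. panel changes) break
  the frozen-marker assumption; only threshold drift is corrected.
* The `d2` rescue is nearly inert in high-dimensional marker spaces (by
  design fidelity); tree-ungated cells are recovered through boundary
  tuning, not through centroid rescue.
* Scores are hard assignments; no per-cell confidence is produced.
* Spillover compensation, bead normalisation and de-barcoding are upstream
  of this package and must be applied beforehand.
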