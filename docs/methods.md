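# Methods

## From time series to graphs

The connectome chain is sample Pearson correlation → Fisher z-transform
(artanh) → rectification (negatives to zero) → thresholding.  Three
numerical choices are deliberate:

* **Mean-centred correlation.**  The correlation is the standard sample
  Pearson coefficient; the Fisher transform presupposes it, and the
  uncentred inner-product variant would not lie in [−1, 1] for raw BOLD
  units.
* **Zero diagonal before the transform.**  artanh(1) diverges and
  self-loops carry no information for any of the graph measures, so the
  diagonal is zeroed at the Pearson stage.  Correlations of exactly ±1
  between distinct ROIs are capped at ±artanh(0.999) ≈ ±3.8002
  (configurable); synthetic data essentially never triggers the cap.
* **Strict threshold (edge iff W > τ).**  At τ = 0 this keeps exactly
  the positively correlated pairs, which is the reading under which the
  0.00 threshold is meaningful.  Rectifying before or after the
  transform is equivalent because artanh is odd and increasing.

Edge sets are nested across the 9-value grid (τ = 0.00 … 0.40, step
0.05), and the transform preserves weight order; both are enforced as
property tests.

## The 69-measure catalogue

The engine computes 36 global binary, 7 global weighted, 21 local binary
and 5 local weighted measures (enforced at load).  Every measure named in
the source material sits in its published category (degree assortativity,
maximal clique count, transitivity, shortest-path statistics, Stoer–Wagner
cut, Wiener index, conductance, the degree/betweenness/closeness/load
centralities, closeness vitality, effective size, weighted degree, page
rank, greedy coloring, local reaching centrality, …).  The remaining
slots are filled with standard, well-defined graph measures (spectral and
efficiency statistics, core numbers, community modularity of the greedy
partition, Burt constraint, articulation-point indicators, current-flow
closeness, and so on); the full ordered list is versioned in
`features.py` so any substitution is explicit.  Interpretation choices:
"number of cliques" means the number of *maximal* cliques
(Bron–Kerbosch); "Stoer–Wagner cuts" is the global minimum-cut weight;
weighted path measures use 1/weight as edge length; "conductance" is the
conductance of the weighted Fiedler bipartition.

Measures whose definition requires a connected graph (path lengths,
eccentricities, min cuts, closeness vitality, current-flow closeness)
return NaN with a per-subject disconnection flag rather than a
component-wise workaround; threshold comparison simply excludes
thresholds at which any subject disconnects.  In practice that limits the
comparison to τ ≤ 0.30.

Every binary measure is cross-checked against an independent brute-force
implementation (plain numpy: Floyd–Warshall, subset enumeration for
cliques and cuts, linear solves for PageRank/Katz, Laplacian
pseudoinverse for current flow) exhaustively over all 52 non-isomorphic
graphs with ≤ 5 nodes.  Algorithm-defined measures (greedy coloring,
greedy modularity communities) are checked for their defining properties
instead (properness, colour count bounds, modularity range).

## Synthetic cohorts

Subjects are drawn as T i.i.d. samples from a zero-mean multivariate
Gaussian whose correlation matrix encodes the group structure — the
pipeline only consumes second-order structure, so no hemodynamic model is
needed (and none is claimed).  Defaults: 8 blocks, within-block
correlation 0.45, between-block 0.10, T = 150, subject-level correlation
jitter with sd 0.02, counts 122 control / 50 patient.

The patient group differs by three mechanisms, all scaled by
`effect_strength`:

1. **Within-block demotion** (`rewire_frac = 0.50` of within-block pairs
   set to the between-block level).  Removing edges inside dense blocks
   simultaneously lowers the clustering coefficient, lengthens shortest
   paths, and fragments each block's near-clique into many overlapping
   maximal cliques — the three group contrasts, realized by a single
   mechanism.  A `promote_frac` option can additionally raise
   between-block pairs; it defaults to 0 because promoted cross-block
   edges act as shortcuts that can cancel the path-length contrast, and
   sampling noise at the between-block correlation level already supplies
   enough cross edges to keep graphs connected at τ = 0.20.
2. **Informative-ROI migration**: each designated ROI's ties to its home
   block are demoted and ties to the next block promoted, concentrating
   discriminative signal in that ROI's local measures (for RLF recovery
   tests).
3. **Differing-pair migration**: for a planted pair (i, j), ROI j migrates
   into i's block in patients only, so the pair co-clusters in patients
   but not controls (for SpeCo recovery tests).

After perturbation the matrix is repaired to the nearest positive-definite
correlation matrix (eigenvalue floor 1e−6, renormalized unit diagonal);
matrices that are already PD pass through bit-identically.  With
`effect_strength = 0` the two groups come from one distribution, so any
classifier must sit at chance — the exchangeability null used throughout
the tests.

The defaults (within 0.45 / between 0.10 / rewire 0.50) were fixed by
checking, across seeds, that graphs stay connected at the operating
threshold and that all three contrast directions hold on group means;
magnitudes (e.g. the ≈2× clique-count ratio) are emergent, not targets.
What the generator does *not* emulate: empirical BOLD marginals,
autocorrelated noise, scanner artefacts, site effects, or realistic
anatomical block structure.  Passing tests therefore demonstrate that the
pipeline recovers structure of this idealized kind, not clinical
performance.

Note that migration mechanisms (2) and (3) add cross-block links in
patients, which can offset the path-length contrast; the contrast
properties are therefore defined on cohorts with rewiring only, while
recovery properties use cohorts with planted markers.

## Threshold selection, augmentation, classification

Threshold comparison trains Random Forest, XGBoost and AdaBoost (10-fold
grid-search CV) on the 36 global binary measures per threshold; the
winner maximizes the grand mean of accuracy, specificity, sensitivity,
precision and F1 over the three models, ties resolved toward the denser
graph.  Hyperparameter grids are small, sensible defaults and
config-overridable.

Augmentation perturbs 5 unordered ROI pairs (both triangle copies, so 10
entries) with one U(0.0, 0.3) delta per pair; Fisher-z weights are
unbounded above so no clipping is applied.  The consensus labelers (RF +
XGBoost) consume the 36 global binary features at the selected threshold
— the same feature space as the threshold-selection stage they mirror.
Only minority-class synthetics are retained (the stated purpose is
imbalance repair), and augmented subjects join training folds only, never
test folds.

Evaluation models are standardized then min-max normalized inside the CV
pipeline (fit on training folds only); the labeler models are excluded
from evaluation by an allow-list.  Sensitivity is recall on the patient
class (label 1), specificity recall on controls.  Reported cells are
"mean ± std" over folds on the percent scale.

## GNNs

Both architectures are implemented in numpy with hand-derived
reverse-mode gradients (verified against finite differences to ~1e−10)
and Adam.  The GCN stacks three 64-channel convolutions
H′ = relu(D̂^{−1/2}(A+I)D̂^{−1/2} H W) with mean readout and a softmax
head.  The DGCNN stacks tanh convolutions with channels (32, 32, 32, 1),
concatenates all layer outputs, sorts nodes by the final single-channel
layer (ties broken by preceding channels right-to-left, then stable
original order), truncates/pads to k = 30 rows (~0.18·N), applies a 1-D
convolution with kernel and stride equal to the channel width (an
equivalent per-row linear map), max-pools pairs of rows, and classifies
with a dense softmax head.  Early stopping monitors a stratified 10%
validation split of each training fold; best-validation parameters are
returned.  Layer sizes are free parameters sized so that 10-fold CV on
~100 graphs of up to 164 nodes runs in minutes on one CPU; all are
config-overridable.  Node features (the 26 local measures) are
standardized with training-fold statistics; NaN columns from disconnected
graphs are zero-imputed after standardization.

## Biomarkers

RLF scores all N × 26 (ROI, measure) columns either by the two-class
ANOVA F statistic (perfect separators map to a large finite score) or by
mean |Shapley attribution| from a tree ensemble; both routes are exposed
and test-covered, the univariate route is the default for speed.  The top
100 pairs are kept (ties broken lexicographically) and ROIs ranked by
recurrence count, which conserves mass (counts sum to 100).

SpeCo clusters each subject's rectified weighted matrix by
normalized-Laplacian spectral embedding (k smallest eigenvectors of
I − D^{−1/2} W D^{−1/2}, rows normalized) followed by seeded k-means —
per subject, since co-occurrence is counted "for every subject".
Co-occurrence counts are thresholded at θ ∈ {0.90, 0.95} with an
*inclusive* ≥ rule (9/10 qualifies at θ = 0.90, which keeps the printed
90–95% range meaningful for small groups), and the informative set is the
symmetric difference of the two groups' majority sets, swept over
k ∈ {2, 3, 4, 5}.

## Explanations

Tree attributions use the polynomial-time path-dependent Shapley
algorithm over decision paths (conditional expectations follow
training-set cover down unsplit branches), summed over ensemble members;
it is exact — verified against brute-force subset enumeration — and
satisfies local accuracy (base value + attributions = predicted
probability).  Trees deeper than 10 fall back to a seeded
permutation-sampling approximation with interventional conditioning;
the two conventions agree only approximately by construction.
Aggregated importances are mean |attribution|, normalized to percent.

GNN masks are learned by Adam on a frozen model: sigmoid-parametrized
symmetric edge masks over the support of the normalized adjacency
(self-loops stay open) and per-channel feature masks, minimizing the
cross-entropy of the model's own prediction plus an ℓ1 size penalty
(default λ_size = 0.005) and an elementwise binary-entropy penalty
(default λ_entropy = 1.0) pushing masks toward 0/1.  Cohort-level
explanations average feature masks over correctly classified subjects
only, to avoid attributing the noise of errors.

## Problem sizes in tests and the acceptance script

Structural checks (catalogue, 4,264 nodal features, perturbation counts)
run at the full 164-ROI scale.  Classification, null-calibration and
recovery checks run on 30–40-ROI cohorts of 60–100 subjects — the
package's chosen desk-scale study conditions, stated here once: the
properties being checked (exchangeability, recovery of planted structure,
permutation symmetries) are size-invariant, and these sizes keep the full
suite within a few minutes.  The exchangeability check pools accuracy
over a 10-seed sweep and compares the pooled mean against the 95%
binomial interval at the per-cohort size (n = 60), a conservative band
given the variance reduction from pooling.

## Known limitations

* Weighted measures are cross-checked on hand-computed examples and
  degenerate cases, not exhaustively like the binary set.
* The DGCNN's 1-D convolution stage implements the single-stage variant
  (kernel = stride = channel width); deeper convolutional stacks over the
  sorted representation are not provided.
* The synthetic selected threshold need not equal 0.20 — where the
  planted signal lives in weight space decides the winner; the selection
  *procedure*, not its outcome on synthetic data, is the tested artifact.
* Spectral clustering uses seeded k-means; cluster labels are arbitrary
  (only co-membership is used downstream).
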