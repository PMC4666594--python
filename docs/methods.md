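# Methods

## The pipeline

`genomogram` classifies biomarker-gene mutation classes (one normal class
plus gene × mutation-type classes, 14 in the default configuration) from
raw DNA sequence, by turning each sequence into an image and classifying
image texture:

1. **Voss indicator encoding.** A sequence over {A, C, G, T} of length N
   becomes a 4×N binary matrix `u`, rows ordered (A, C, G, T), with
   `u[b, n] = 1` iff the base at position n is b. Columns are one-hot;
   ambiguity codes (N etc.) are rejected rather than imputed, because the
   encoding is defined only over the four unambiguous bases.

2. **Affine reduction to three channels.** Either the Z-curve map

       x_r[n] = u_A − u_C + u_G − u_T
       x_g[n] = u_A + u_C − u_G − u_T
       x_b[n] = u_A − u_C − u_G + u_T

   (each base → a corner of {−1,+1}³: purine/pyrimidine, amino/keto,
   strong/weak axes), or the tetrahedron map sending A→(0,0,1),
   T→(2√2/3, 0, −1/3), C→(−√2/3, √6/3, −1/3), G→(−√2/3, −√6/3, −1/3) —
   unit vectors from the centre of a regular tetrahedron to its vertices
   (pairwise dot products −1/3, vertices summing to zero). Both maps are
   applied **per position**, not cumulatively: the channels are
   piecewise-constant base indicators, which is what produces the
   salt-and-pepper image texture downstream. The classic cumulative
   Z-curve trajectory is available behind `cumulative=True` but is not the
   default. Both maps are injective on bases, so the encoded signal can be
   decoded back to the exact sequence (tested by round-trip).

3. **Windowed RGB genomic image.** The 3×N signal is sliced into
   overlapping windows — width W = 200 positions per image row, overlap
   O = 50, stride W − O = 150 — giving H = ⌊(N − W)/stride⌋ + 1 rows.
   Trailing positions that do not fill a window are discarded (zero
   padding available as a flag). Each H×W channel matrix is min-max
   scaled to [0, 255] independently (`g = round(255(m − min)/(max −
   min))`, half-away-from-zero, constant matrix → zeros) and the triple is
   composed as an RGB image. Grayscale uses BT.601 luma
   (0.2989 R + 0.5870 G + 0.1140 B, configurable), rounded
   half-away-from-zero. Rounding conventions are pinned because the 8-bit
   pixels feed the texture statistics and must be bit-reproducible.

4. **36-element HOG descriptor.** Gradients by centred [−1, 0, 1] filters
   with replicated borders; unsigned orientations θ ∈ [0°, 180°), 9 bins
   with centres at 0°, 20°, …, 160° and magnitude votes split linearly
   between the two nearest centres (wrapping 160°→0°); a floor-split 2×2
   grid of cells; the single block of all four cells (row-major, bins
   contiguous per cell) L2-normalised with ε = 10⁻⁶. The 2×2 geometry is
   the minimum that still works on the shortest genes, whose images have
   as few as two rows. The descriptor is invariant to adding a constant
   to all pixels and, after block normalisation, to positive intensity
   scaling; both properties are tested, and the whole computation is
   checked against an explicit-loop oracle to 10⁻¹².

5. **Haralick texture statistics** (for comparing the two renderings, not
   as classifier features): pixels are requantised to 8 uniform levels,
   co-occurrences counted at offset (0, +1) (horizontal neighbour,
   non-symmetric) and normalised to probabilities p(i,j);
   contrast = Σ p(i,j)(i−j)², homogeneity = Σ p(i,j)/(1+|i−j|). A constant
   image gives contrast 0, homogeneity 1; contrast is bounded by 49 at 8
   levels.

6. **Classifiers.** See below.

## The Gaussian RBF network

The main classifier is a single-hidden-layer network of Gaussian units
φ(x, c) = exp(−(b‖x − c‖)²) with a linear output layer (weights + bias)
and an argmax decision over the 14 class scores. The width comes from the
`spread` parameter as b = √(−ln 0.5)/spread ≈ 0.8326/spread, so a unit's
activation is exactly 0.5 at distance `spread` from its centre; the
default spread is 0.1 on the unit-norm HOG features.

Training is greedy and incremental: starting from an empty hidden layer,
the training input with the largest current squared output error becomes
the next centre (ties break to the lowest index; inputs exactly equal to
an existing centre are never selected, so duplicates cannot inflate the
hidden layer), the output layer is refit by least squares, and the loop
stops when the training MSE reaches `mse_goal` (default 0) or the hidden
layer reaches `max_neurons` (default: one per training instance). The
procedure is deterministic; the `seed` argument exists only for interface
uniformity.

**Output-layer conditioning.** The default output solve is plain least
squares, which interpolates exactly when the centres are distinct and
well separated (tested: training MSE ≤ 10⁻⁶ on distinct inputs). On the
mutation corpus, however, the Gaussian design matrix is numerically
singular *by construction*: the normal class duplicates every reference
sequence, and each single-mutation sample sits ~10⁻³ from its reference
in HOG space — far below the spread-0.1 kernel scale — so columns nearly
coincide and the unregularised solution has unbounded weights. The
trainer therefore accepts an optional validation set and then selects a
Tikhonov (ridge) level for the final output solve from a log grid —
including zero — by validation MSE, the standard global-ridge practice
for RBF output layers. The experiment runner passes the 15% validation
split; an explicit `ridge` level can also be fixed in `RbfConfig`.

## The MLP baseline

A 36 → h → h → 14 network with identity input units and hyperbolic
tangent activations in both hidden layers and the output layer, trained
by full-batch gradient descent on the MSE with momentum 0.9 and a
multiplicative adaptive learning rate: start 0.1, ×1.05 after an
improving epoch, ×0.7 with the step rejected and momentum cleared when
the loss regresses by more than 4%. Stops: 500 epochs, performance goal
0, gradient norm below 10⁻⁶, 120 s wall clock, or 500 consecutive epochs
without validation improvement. The two hidden layers must be equal; the
published sweep tried 100–500 units per layer, and the runner defaults to
400 (the best single-hidden-size trial for the Z-curve variant). Training
is deterministic given the seed; a non-finite loss raises instead of
being ignored.

## The synthetic mutation corpus

Real curated mutation records (COSMIC-style) and reference coding
sequences are not redistributable, so the package generates a corpus that
mirrors the published study design:

* ten reference genes with the real coding-sequence lengths (471 to
  16,614 nt) of the most frequently mutated lung-cancer biomarker genes;
* per-gene base-composition profiles with GC content spread over
  [0.3, 0.7] and alternating purine skew, making genes separable by
  texture the way real biomarker genes are separable by their power
  spectra;
* 14 classes with the published per-class unique-sample counts (total
  534): 100 normals as unmutated copies of the ten references (exact
  duplicates, mirroring the published corpus of 100 normal samples over
  ten genes), and each mutated sample being its reference carrying
  exactly one event — a single-base substitution, or a deletion of 1–20
  bp (small-indel range) — at a seeded-uniform position;
* a stratified 70/15/15 train/validation/test split with per-class
  flooring of the validation and test counts and the remainder in train.

Everything is bit-reproducible from the seed.

**What the generator does not emulate.** Bases are drawn i.i.d. from the
per-gene composition, so there is no local composition structure, no
codon periodicity, no repeats; real genomic images are more heterogeneous
row-to-row. Mutation positions are uniform, whereas real somatic
mutations cluster in hotspots. Passing tests on this corpus show that the
pipeline recovers composition-level signal through the image/HOG
representation and that the published method ordering (RBF above MLP)
holds under honest held-out evaluation; they do not certify accuracy on
real curated data.

## Evaluation conventions

Confusion matrices are oriented **rows = predicted, columns = actual**
(the orientation under which a published matrix's normal-class *column*
sums to its 100 instances). Accuracy is trace/total. Sensitivity and
specificity are one-vs-rest per class, macro-averaged without weights;
the single published sensitivity/specificity figures attributed to ROC
curves are not reproducible from the stated procedure (macro recall of
the best published matrix gives ≈ 0.9878, not 0.9960), so the package
reports macro values and per-class tables. ROC curves are one-vs-rest
threshold sweeps with trapezoidal AUC; a class with no positives reports
a missing AUC rather than 0. MSE is the mean squared difference between
one-hot targets and raw scores over all m×K entries.

The paired t-test on the two transforms' texture statistics uses
d = b − a, M = mean(d), SD with n−1 denominator, t = M/(SD/√n), two-tail
p from Student's t with n−1 df, and a 95% CI; a zero SD is handled
explicitly and flagged. Recomputing from the bundled texture table gives
|M| = 100.1 (contrast) and 9×10⁻⁵ (homogeneity); the published SD/t/p for
the contrast comparison are inconsistent with the published per-gene
values (the differences have SD ≈ 334) and are not reproduced. Ranks use
competition ranking (ties share the minimum rank); the published
homogeneity ranks for the tetrahedron column disagree with their own
printed values, so only contrast-rank agreement (2 of 10 genes differ) is
asserted.

Two gene-collapsed metrics accompany the 14-class accuracy, because the
normal class maps to no gene under the class→gene collapse:

* `gene_level_accuracy` — both labels collapsed to genes, with Normal as
  its own label. On the synthetic corpus this sits near 0.80 for *every*
  smooth classifier, by construction: a mutant's nearest neighbour in
  feature space is its own reference (one mutation separates mutant from
  reference, two separate mutant from mutant), the reference is
  duplicated in training as Normal, and no classifier smooth at the
  kernel scale can resolve the ~10⁻³ gap — so held-out normals are
  systematically confused with their gene's mutant classes.
* `mutant_gene_recovery` — over truly mutated samples only: the fraction
  whose predicted class names the correct mutated gene (a Normal
  prediction counts as a miss). This is the screening question the
  pipeline exists to answer — *which* biomarker gene carries the
  mutation — and is the metric the synthetic-recovery test binds
  (≥ 0.90; measured 0.98–1.00 across seeds).

The runner scores the held-out test split by default; `eval_on="full"`
scores the whole corpus (the convention under which published matrices'
column totals equal full class sizes).

## Numerical and degenerate-input choices

* Quantisation rounding: half away from zero, everywhere.
* Constant matrices normalise to all zeros; constant images give an
  all-zero HOG vector (ε prevents 0/0) and contrast 0/homogeneity 1.
* Greedy RBF ties break to the lowest training index; argmax decisions
  break to the lowest class index.
* Least-squares solves use SVD (`lstsq`, machine-precision cutoff) on
  the default path; the ridge path solves from the same SVD with the
  selected λ scaled by the largest squared singular value.
* Deletions must not overrun the sequence end; substitutions verify the
  reference allele and fail loudly on mismatch (stale coordinates).
* Splitting warns when a class is too small to appear in all three
  partitions and assigns the remainder to train.

## Problem sizes

The default test suite and the acceptance script use the full published
scale for the synthetic experiment — 534 samples, real gene lengths, the
70/15/15 split — which fits comfortably on one CPU (each pipeline variant
trains in seconds). The table-derived statistics involve no training at
all. Unit and property tests use scaled-down corpora (three genes of
400–600 nt) and small random images.

## Known limitations

* The published trained-model accuracies (Table-8-style values) are
  reproduced only as recomputations from the transcribed confusion
  matrices, not by retraining: the curated corpus is unavailable, and the
  published training protocol (hidden-layer cap equal to the *full*
  corpus size, whole-corpus column totals in the matrices) indicates
  whole-dataset scoring of a memorising network, which held-out
  evaluation deliberately does not emulate.
* i.i.d. composition profiles overstate how cleanly genes separate; real
  within-gene heterogeneity would lower all accuracies.
* The 14-class problem is intrinsically ill-posed at the Normal/mutant
  boundary under single-mutation sampling (see the gene-collapse
  discussion above); results on that boundary reflect the study design,
  not classifier quality.
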