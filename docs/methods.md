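# Methods

This note documents the models and procedures implemented in `top2track`,
the parameter choices that matter, what the synthetic world does and does
not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Coordinate and data model

All coordinates are 0-based half-open (BED native). One-based inputs
(e.g. methylation tables from bisulfite callers) are converted at the
reader boundary (`read_methylation(..., one_based=True)`). Strand is
ignored throughout: window scoring counts reads irrespective of strand and
sequence encodings use the forward genome strand. Read libraries store
single-end alignment intervals plus a declared mapped-read count
(`library_size`), which defaults to the number of stored reads and is the
denominator of all normalizations.

## Region construction

Candidate binding sites are ChIP-seq peaks kept when (i) their fold change
over the control is strictly greater than `min_fold` (default 5) and
(ii) at most `max_bad_frac` (default 20%) of their width lies on
blacklisted or non-mappable bases. When replicates exist, only peaks of
one replicate overlapping (>= 1 bp) a peak of the other are kept, retaining
the first replicate's coordinates. Peaks are then re-centered to a uniform
width (default 300 bp, the scoring window); a resized region that would
run past a chromosome end is dropped rather than truncated so that all
widths stay equal.

Backgrounds are built one region per peak, matching the per-chromosome
peak counts. *Random* backgrounds are seeded rejection samples that avoid
peaks, blacklisted/non-mappable bases, previously accepted regions, and —
optionally — windows whose binding-signal log-ratio exceeds a configurable
genome-wide quantile (default 0.95); this last exclusion guards against
sampling unannotated true sites as negatives. The quantile is a package
choice: "high signal" needs an operational definition, and the 95th
percentile removes the enriched tail without distorting the genomic
background.

*GC-matched* backgrounds use iterative greedy matching: each iteration
draws a fresh batch of candidate regions, and a candidate is retained iff
its G+C fraction is within `tolerance` of some still-unmatched peak on the
same chromosome; the matched peak (ties broken by smallest |dGC|, then
coordinate) leaves the pool. The default tolerance is 1/300 — one base
equivalent at the 300-bp width — with an iteration cap of 100 and a
candidate batch of max(20x remaining, 500) per iteration; failure to
converge raises with the unmatched peaks and their G+C values. G+C content
ignores N bases (undefined when a region is all N).

Open-chromatin (DNase) peaks are partitioned into five classes from their
H3K4me3/H3K4me1 fold ratio: ratio > 1.5 is a promoter, ratio < 0.67 an
enhancer. Remaining peaks split into low-signal (both marks below their
median over peaks; a zero H3K4me1 denominator also takes this path) and
roughly-equal-ratio groups. Low-signal peaks overlapping CTCF are
insulators and otherwise weak enhancers; roughly-equal peaks at a TSS are
weak promoters. The published scheme leaves two small groups unassigned
(roughly-equal peaks away from TSSs; low-signal non-CTCF peaks at TSSs);
both are classified weak enhancers here so that the partition is total.

## Window scoring

ChIP-seq enrichment of a window follows a fixed normalization order:
count reads overlapping the window (any >= 1 bp overlap; a midpoint rule is
available), scale each count by m/N where N is its library size and
m = min(N_test, N_input), add a pseudocount of 1, form the test/input
ratio, and take log2:

    score = log2( (c_test * m / N_test + 1) / (c_input * m / N_input + 1) )

Log base 2 is used so that scores compose with the log2 comparisons used
elsewhere (track correlation). The score is exactly 0 when test and input
agree and antisymmetric under swapping them. Accessibility-style assays
(DNase-seq, MNase-seq, RNA-seq) are scored as window count / library size,
and CpG methylation as the mean percent methylation of CpGs inside the
window (missing when the window has no CpG; missing values are imputed by
the column mean at matrix construction and the affected columns recorded
in the matrix metadata — imputation keeps the matrix rectangular instead
of discarding regions).

## Sequence and shape encodings

The positional k-mer encoding represents a length-L sequence as L−k+1
concatenated one-hot blocks of length 4^k (index order A < C < G < T), so
the vector length is 4^k(L−k+1): 1,200 / 4,784 / 19,072 columns for
k = 1/2/3 at L = 300. A window containing N produces an all-zero block.
Column names are `k{k}_pos{p}_{kmer}`.

DNA shape uses a pentamer lookup table over all 1024 5-mers for 13
structural features — 7 intra-base-pair (minor groove width, propeller
twist, shear, stretch, stagger, buckle, opening) and 6 base-pair-step
(helix twist, roll, shift, slide, rise, tilt). A 5-bp window slides over
the region: bp-resolution values land on the pentamer's central base
(L−4 real values), step values of adjacent pentamers are averaged onto the
L−5 interior steps, and terminal or N-containing positions carry the
per-feature table mean so every region yields equal-length vectors. The
padding convention is the package's own: published pipelines do not state
one, and the exact column count of a shape encoding is convention-
dependent, so the encoding is configured rather than asserted. No
reverse-complement averaging is applied. The shipped table generator
(`synthetic_shape_table`) is a synthetic stand-in — baseline plus a smooth
G+C dependence plus seeded noise — reproducing the lookup mechanics, not
the molecular-dynamics-derived values of the published tables, which are
consumed as TSV when available.

## Feature selection

Symmetrical Uncertainty, SU(X,Y) = 2·I(X;Y)/(H(X)+H(Y)) with entropies in
bits, is 0 for independent and 1 for bijectively related variables (and
defined as 0 when both are constant). Continuous features are discretized
for SU with supervised MDL partitioning (recursive entropy-minimizing
binary splits accepted under the MDL criterion), falling back to 10-bin
equal-frequency binning when no cut is accepted — the fallback keeps
uninformative features at non-trivial entropy instead of collapsing them
to constants. Bin edges are fitted on training folds only.

FCBF ranks features by SU with the class, keeps those above δ (default 0),
and walks the ranking removing any feature dominated by an already-kept
one (SU between them at least the feature's SU with the class); ties in
the ranking break by column index.

Subsets are scored by the CFS merit k·r̄_cf/√(k + k(k−1)·r̄_ff), which
rewards class relevance and penalizes within-subset redundancy; for k = 1
it reduces to the feature's class SU. Scatter Search maintains a
reference set of b1 = 5 best-merit and b2 = 5 maximally diverse (max-min
Hamming distance) solutions drawn from a seeded population of 100 subsets
(all singletons plus random subsets of uniform random size, capped at the
2^n − 1 distinct non-empty subsets). Every RefSet pair is combined —
intersection kept, each symmetric-difference member added with probability
1/2 — and each child is refined by best-improvement greedy add/remove
local search to a CFS local optimum; the RefSet is then statically
updated, stopping when it is unchanged or after 20 iterations. The initial
RefSet members are also refined by the local search (the classic
"improvement method"), which in practice makes the search reach the
exhaustive-search optimum on all tested instances of up to 12 features.
Hyperparameters (population 100, RefSet 5+5, 20 iterations) are package
defaults chosen for small-to-moderate feature counts; the search is
deterministic given its seed.

Selection stability is the mean pairwise Jaccard similarity of the
selected subsets across folds: 1 iff all folds select the same subset; a
pair involving an empty subset contributes 0. This index matches the
identity case exactly and handles unequal subset sizes.

## Classifiers and evaluation

Gaussian Naive Bayes is implemented natively: per-class, per-feature
means and variances with a variance floor of 1e-9 times the largest
feature variance (1e-12 when all variances vanish), log-sum posterior.
The linear-margin model (scikit-learn SVC, linear kernel, Platt-scaled
probabilities) standardizes features with train-fold statistics inside the
model; the tree ensemble is a 200-tree random forest. All three emit
class-1 probabilities behind one interface, and a fitted model carries a
feature-name manifest that prediction refuses to violate.

Evaluation is stratified k-fold (default 5) cross-validation with
imputation and scaling fitted on training folds only, reporting per-fold
accuracies (percent, mean ± SD), a pooled ROC over the out-of-fold scores
with its AUC (trapezoidal over tie-grouped points, equal to the
probability that a random positive outscores a random negative with ties
counting one half), and a confusion matrix summed over folds. Matrices
are built 1:1 sites:background so accuracy is meaningful; a warning fires
beyond 55:45 imbalance. Fold assignment is a seeded stratified shuffle.

## Genome-wide tracks

The mappable genome is tiled into windows of 300 bp every 50 bp (windows
with more than 20% non-mappable bases are dropped, the same rule as peak
filtering). Each window is scored for the model's features and assigned a
class-1 probability; the track serializes as a 4-column bedGraph with
6-decimal values. Windows with probability strictly above the threshold
(default 0.95) merge — overlapping or book-ended — into predicted peaks
whose score is the maximum constituent probability. Note that with
overlapping sliding windows, a sub-threshold window can be bridged by its
overlapping neighbours; raising the threshold never widens coverage but
can split peaks. Track-versus-experiment agreement is quantified per
region as Pearson correlation of log2(x+1)-transformed mean probability
and read count (the pseudocount avoids log of zero; correlation is
undefined under zero variance), plus overlap fractions and joint
membership counts between peak sets.

## The synthetic world

The generator emulates the statistical structure the pipeline exploits,
with every stage deterministic given the configuration seed:

- **Sites**: non-overlapping 300-bp sites placed away from chromosome
  ends, with margins so jittered feature placements never collide.
- **Colocalization**: per feature, an interval of site width is centered
  on each site (uniform ±50 bp jitter, since real enrichment profiles are
  centered but not perfectly aligned) with probability `p_at_site`;
  background feature intervals are scattered at the density that makes a
  random region overlap the feature with probability `p_at_background`.
  Defaults: (0.89, 0.11) for DNase — the mouse-liver colocalization
  frequencies — and (0.85, 0.05) for CTCF and RAD21.
- **Reads**: Poisson background (0.02 reads/bp of start positions) with
  the rate multiplied 8-fold inside feature sites; the paired input
  library has no enrichment. Reads are fixed-length (50 bp), uniform
  within their emitting region; `library_size` equals the emitted count.
- **Sequence**: bases drawn independently with position-specific G+C
  probability — 0.50 at sites versus a background whose level varies
  between 5-kb blocks (normal, mean 0.40, SD 0.10, clipped): an
  isochore-like heterogeneity that both resembles mammalian genomes and
  ensures GC-matched background sampling is feasible, as it is on real
  genomes. With a homogeneous background, candidates matching elevated
  site G+C within 1/300 would essentially never occur.
- **Methylation**: every genomic CpG gets a percent drawn around 25
  inside sites and 75 outside (SD 10, clamped to [0, 100]) —
  hypomethylated sites on a methylated background.

Deliberately not modeled: fragment-length distributions, GC amplification
bias, duplicate reads, diploid variation, chromatin-state spatial
autocorrelation beyond the isochore blocks, and motif structure. Passing
the recovery tests therefore demonstrates that the pipeline's inference
machinery is correct under its generative assumptions, not that the same
accuracies would be reached on real sequencing data, where noise is
heavier-tailed and features are correlated in ways the generator omits.

A second generator (`simulate_selection_matrix`) produces the
feature-selection benchmark: 800 balanced rows and 20 features, of which
3 are mutually independent class signals (Gaussian shifts of 2.6, 2.3 and
2.0 SD, giving each a class SU of about 0.3 or more after MDL
discretization), 4 are attenuated noisy copies of the signals (0.4x plus
N(0, 1.2) noise — they share signal with an informative feature but carry
little class information of their own), and 13 are standard-normal noise.
Under these conditions the CFS optimum is exactly the 3 signal features,
so Scatter Search across folds measures selection stability against a
known answer.

## Problem sizes

The default ("liver-like") world is 4 chromosomes x 500 kb with 400 sites
— large enough for stable colocalization frequencies, a 40k-window
genome-wide scan and a KS comparison of GC distributions on 400 matched
pairs, while a full pipeline run (simulation, GC matching, training,
genome scan, evaluation) completes in seconds. The chance-level
cross-validation benchmark uses n = 2000 balanced rows, at which the
sampling SD of mean CV accuracy is well under one percentage point.

## Pipeline and reproducibility

`run_training` executes simulate → background → matrix → (optional
selection) → cross-validation → final model → genome-wide track →
thresholded peaks → evaluation. One master seed derives per-stage seeds by
fixed offsets so stages are independently reproducible; a rerun with the
same config is bit-identical. When feature selection is enabled, the
final model uses features selected in a majority of folds. All artifacts
(config copy, matrix TSV, selection and CV reports, model blob with its
manifest, bedGraph, predicted-peak BED, evaluation JSON) are written to
the output directory.

## Known limitations

- The synthetic shape table is a stand-in; analyses of real shape
  preferences require the published pentamer tables as TSV input.
- GC matching assumes background G+C diversity covers the peak G+C range
  on every chromosome; it raises (listing unmatched peaks) otherwise
  rather than silently relaxing the tolerance.
- BAM ingestion is not built in; alignments are consumed as BED-dialect
  read intervals (one interval per mapped read).
- Scatter Search evaluates CFS merit exactly and is intended for feature
  counts up to a few hundred (e.g. after an SU prefilter), not for the
  full k-mer/shape parameter space.
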