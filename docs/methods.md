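# Methods

## Overview

`episig` implements episignature construction and evaluation for balanced
case/control DNA-methylation studies on Infinium-style arrays. Two feature
paradigms are built from the same training beta matrix:

- **DMC episignature** — individual CpG probes selected by a two-sided
  Mann–Whitney U test combined with an effect-size threshold on the group
  mean difference Δβ = mean(case) − mean(control);
- **DMR episignature** — differentially methylated regions found by a
  bump-hunting scan of the per-probe Δβ profile, scored by area and tested
  against a label-permutation null; the feature value of a region is the
  median methylation of its probes.

Classifiers (SVM, random forest, penalized logistic regression) are tuned by
leave-one-out cross-validation with the Matthews correlation coefficient
(MCC) as the selection score and a fixed decision threshold of 0.5. The
evaluation layer quantifies robustness to missing probes (whole-array probe
removal at 5–30%), cross-signature specificity, and unsupervised structure
(average-linkage Manhattan clustering, seeded UMAP embedding), plus a
genomic-partition annotation of signature CpGs.

## Statistical model and procedures

### Per-probe test (DMC branch)

For probe *j* with case values *x* and control values *y*, the U statistic
for the case group is the rank-sum form `U = R1 − n1(n1+1)/2` with average
ranks for ties, so `0 ≤ U ≤ n1·n2`. The exact two-sided p-value enumerates
all C(n1+n2, n1) assignments of the pooled sample to groups and counts
assignments whose |U − n1·n2/2| is at least the observed deviation; this
handles ties correctly. The asymptotic mode uses the tie- and
continuity-corrected normal approximation (scipy). `auto` switches from
exact to asymptotic at min(n1, n2) > 8 or in the presence of ties —
enumeration cost grows combinatorially and the approximation is already
accurate there (checked against enumeration to within 0.02 at n = 8/8).

P-values are Benjamini–Hochberg adjusted by default (configurable to raw p):
the region branch adjusts its empirical p-values, and applying the same
convention to probes keeps the two branches comparable. A probe enters the
signature iff adjusted p < 0.05 **and** |Δβ| ≥ 0.10 (both configurable);
rank tests alone will select biologically negligible shifts at large n, so
the conjunction is essential.

### Region caller (DMR branch)

1. **Clusters.** Probes are grouped into maximal runs of consecutive
   manifest probes on one chromosome with inter-probe gaps ≤ `max_gap`
   (default 1000 bp). Cluster ids are dense and increase along the genome.
2. **Coefficients.** The per-probe coefficient is the group mean difference
   computed over non-missing entries. For a balanced two-group design this
   equals the two-group linear-model coefficient a bumphunter-style caller
   fits, without the cost of per-probe regressions. An optional running-mean
   smoother (window in probes, shrinking at cluster edges) is off by
   default; the unsmoothed profile keeps planted-signal edges sharp and is
   the simpler null to permute.
3. **Cutoff.** With `cutoff="auto"`, the threshold is the nearest-rank
   0.99-quantile of the pooled |coefficients| over all label permutations —
   the analogue of letting the software choose the cutoff from the null
   spread of the statistic. A fixed numeric cutoff can be supplied instead.
4. **Candidates.** Within each cluster, maximal sign-homogeneous runs of
   probes with coefficient ≥ +cutoff or ≤ −cutoff become candidates; mixed
   signs never merge, so the per-region mean coefficient always satisfies
   |value| ≥ cutoff and area = Σ|coefficient| ≥ L·cutoff.
5. **Null.** Sample labels are permuted B times (default 1000; class sizes
   preserved because the label vector itself is permuted; permutation b is
   drawn from `default_rng(seed + b)`), the coefficient profile is
   recomputed, and candidates are re-scanned with the *same* cutoff and
   clustering. All null areas are pooled. Label permutation is used rather
   than a residual bootstrap: exchangeability holds exactly for the balanced
   two-group design and there are fewer moving parts.
6. **Inference.** Each candidate gets the add-one-smoothed empirical
   p = (1 + #{null ≥ area}) / (1 + N_null), guaranteeing p ∈ (0, 1], then BH
   adjustment across candidates. Retained regions need adjusted p < 0.05
   and at least `min_probes` probes (default 10).
7. **Training medians.** For every retained region the median of per-sample
   region medians is stored (overall and per class) so that test-time
   featurization has a defined fallback when an entire region is absent.

Coordinates are 1-based inclusive internally (Illumina manifest
convention); BED export converts to 0-based half-open.

### Featurization and missing data

The two paradigms deliberately differ in their missing-data policy:

- **DMC features** forward-carry impute over the whole array in genomic
  probe order per sample (a missing or absent probe takes the nearest
  preceding observed value; a missing leading run is back-filled), *then*
  extract the signature probes. Imputation before extraction matters: the
  value carried into a signature probe usually comes from a non-signature
  neighbour.
- **DMR features** never impute: a region's value is the median over its
  probes that are present and non-missing for that sample. Only when a
  region loses every probe is the stored training median substituted (and a
  warning logged).

Both outputs are sample × feature matrices in [0, 1] with no missing
entries.

### Classifiers

All kinds share the harness: for each hyperparameter grid point, LOOCV
produces one held-out prediction per training sample; pooled predictions are
scored with MCC; ties go to the first grid point in declared order; the
winner is refit on the full training set. Feature standardization is on by
default for SVM and PLR (margin and penalized models) and off for random
forests; scaling statistics are computed inside each LOOCV fold from that
fold's training part only, and the persisted statistics come from the full
training set.

- **PLR** is L2-penalized logistic regression, liblinear solver with the
  dual formulation (seeded — the dual coordinate-descent solver is
  randomized). Grid: C ∈ {10⁻³ … 10²}.
- **SVM** covers linear, RBF and polynomial (degree 2–3) kernels with a
  small C grid (11 points). Probabilities are obtained by Platt scaling — a
  sigmoid `P(case) = σ(a·f + b)` fitted to the held-out LOOCV decision
  values f at the chosen hyperparameters, i.e. calibrated strictly within
  the training data. This keeps probabilities an exact function of the
  persisted coefficients, unlike the libsvm-internal estimate whose
  pairwise-coupling iteration stops at a loose tolerance.
- **RF** grid: {100, 300} trees × depth {∞, 5, 10}, seeded.

MCC is computed from the confusion table with the convention that a zero
factor in the denominator yields 0. The decision threshold is fixed at 0.5;
a probability of exactly 0.5 maps to control.

Grids are intentionally small (≤ 24 points per kind) because LOOCV wraps
every point in n model fits; users can pass their own grids.

### Evaluation procedures

- **Missing-probe robustness** removes ⌊fraction·n_probes⌋ whole probe rows
  from the test array (probe-wise, emulating array-version changes and
  batch-wide probe failures, not per-cell dropout), at fractions
  {0, 5, 10, 20, 30}% with 10 repeats per nonzero fraction (repeat i seeded
  base_seed + i; the missing set is shared by all models within a repeat so
  paradigms are compared on identical degraded data). Fraction 0 is a single
  deterministic evaluation. Cells report mean ± sd of MCC.
- **Cross-specificity** featurizes a foreign cohort with one syndrome's
  signature and counts every sample there as a true negative;
  specificity = fraction predicted control at threshold 0.5.
- **Views.** Agglomerative clustering uses average linkage with Manhattan
  distance (preferred over Euclidean in high dimension); the 2-D embedding
  standardizes features (zero-variance features divide by 1) and runs UMAP
  with a fixed random state.
- **Genomic partition** assigns each CpG one category with precedence
  promoter (1–1000 bp upstream of the strand-aware TSS) → 1–5 kb upstream →
  gene body (within the gene interval) → intergenic, for the signature set
  and a background set; fractions per set sum to 1.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every claim in the test suite is made.

Per-probe baseline methylation is drawn once per `baseline_seed` from a
two-component beta mixture (60% unmethylated, Beta(3,17), mean 0.15; 40%
methylated, Beta(17,3), mean 0.85) mimicking the bimodal marginal
distribution of array betas. Planted probes draw their baseline from the
component that leaves room for their shift (unmethylated for Δβ > 0,
methylated for Δβ < 0), so the realised group difference matches the nominal
Δβ instead of being clipped at the boundary. Measurement noise is i.i.d.
Gaussian on the logit scale (default sd 0.30, a beta-scale spread of roughly
0.04–0.07 — typical of blood-derived array data); values are mapped back
through the logistic function, which keeps betas in (0, 1) without hard
clipping. The case-group expected value of a planted probe is
σ(logit(clip(baseline + Δβ))).

`baseline_seed` is separated from the sample-draw seed so a training and a
testing cohort of one study share probe-level baselines (biology is a
property of the probe, not of the sample draw). `null_regions` /
`null_dmcs` reserve the baseline component of *another* cohort's planted
sites without applying a shift there — this is what makes two
disjoint-signature cohorts mutually consistent for specificity experiments
(a probe that is unmethylated-at-rest in cohort A must also be so in
cohort B).

Detection p-values are drawn so that an expected `detection_fail_rate`
fraction of entries exceeds the 0.01 threshold. Missing-probe injection
removes whole rows, uniformly without replacement, reproducibly per seed.
The synthetic manifest places evenly spaced probes (default 500 bp) on one
or few chromosomes so the max-gap clustering is actually exercised.

**What the generator does not emulate:** two-channel intensities, dye bias,
probe-type (Infinium I/II) chemistry differences, batch/chip effects,
cell-composition heterogeneity, age/sex covariates, or spatially varying
noise. Consequently, passing tests demonstrate the correctness and internal
consistency of the algorithms under the declared generative model — not
that a particular clinical episignature will replicate; the normalization
stack needed for real IDAT-derived data (Noob, Funnorm, SWAN, BMIQ, dasen)
is deliberately out of scope and externally normalized matrices are
accepted as input.

## Preprocessing

Filtering removes, as the union, probes failing detection (p > 0.01 in
*any* sample — the conservative common practice; an "all-samples" policy is
available), cross-reactive probes, SNP-overlapping probes and
sex-chromosome probes, itemized in a report. Training and testing sets are
always filtered and normalized separately to avoid leaking test-set
distribution into training.

Normalization offers `raw` (identity), `quantile` (classical across-sample
quantile normalization: each sample's sorted values replaced by the mean of
sorted values across samples, mapped back by average rank with linear
interpolation at tied ranks), and `reference_scale` (per-sample affine
adjustment on the logit scale matching each sample's median and MAD to the
across-sample mean reference, inverse-mapped and clipped; a zero MAD
divides by 1).

## Numerical choices and degenerate inputs

- Betas are clipped to [10⁻³, 1−10⁻³] before any logit transform.
- Nearest-rank quantile (`ceil(q·n)`-th order statistic) for the auto
  cutoff — no interpolation, so the cutoff is always an observed magnitude.
- NaN coefficients (a probe missing in an entire group) break candidate
  runs and are excluded from scanning.
- Empty candidate lists are valid (empty signature with a logged warning),
  as are empty signatures downstream — models simply cannot be trained on
  zero features and say so.
- Fewer than 10 distinct label arrangements triggers a logged warning; the
  permutation null proceeds but is coarse.
- JSON artifacts are written with sorted keys so identical runs are
  byte-identical.

## Study conditions used by the test suite and acceptance script

Problem sizes were chosen once as desk-scale stand-ins for array-scale
cohorts: signature recovery and the null control run at 50,000 probes
(n = 20/20, B = 100 permutations, 20 planted 12-probe regions at Δβ = 0.3);
the separable-classification and specificity checks at 2,000 probes with
Δβ = 0.35; and the missing-probe ordering experiment in the low-effect
regime (Δβ = 0.1 — the regime where the paradigms actually diverge) over 10
cohorts of 8,000 probes with 16 planted regions, PLR for both paradigms,
10 removal repeats at 30%. B = 100–1000 permutations gives empirical
p-value resolution of 10⁻²–10⁻³ per candidate-rich profile, ample for the
0.05 retention threshold.

## Known limitations

- The permutation null pools areas across all permutations rather than
  using per-permutation maxima; this is anti-conservative for the single
  largest region in heavily signal-laden genomes but BH adjustment across
  candidates compensates in practice (the null control stays clean).
- The auto cutoff depends on the permutation pool and therefore on B and
  the seed; with very small B the 0.99 quantile is noisy.
- Exact Mann–Whitney enumeration is exponential; it is gated to
  min(n1, n2) ≤ 8 in auto mode.
- LOOCV-selected MCC is an optimistically biased estimate of generalization
  for the *selected* grid point (selection and scoring share the folds), as
  in the original procedure; test-set MCC is the honest figure.
- The genomic-partition annotator checks each probe against every gene
  interval of its chromosome; it is meant for signature-sized probe sets,
  not whole-array annotation.
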