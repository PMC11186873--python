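# Methods

This note documents the statistical model behind `episig`, the choices
made where the procedure left room for interpretation, and what the
synthetic-data generator does and does not emulate.

## Data model and scales

The pipeline's currency is the beta value: the methylation fraction of
a CpG probe, 0 (unmethylated) to 1 (fully methylated), with `NaN` for a
failed measurement. Inference runs on M-values,
`M = log2(b' / (1 - b'))` with `b' = clip(b, eps, 1 - eps)` and
`eps = 1e-3` — the standard base-2 logit convention. M-values have
approximately constant variance across the beta range, which makes the
per-probe Gaussian linear model defensible; effect sizes, however, are
reported as Δβ (case mean minus control mean **on the beta scale**),
because a "5 % methylation difference" is only meaningful there. This
mixed-scale convention — test on M, threshold on β — is deliberate and
used consistently: DMP calling combines a beta-scale effect bound with
an M-scale moderated test.

## Quality control

A sample is excluded when its fraction of missing probes is *strictly*
greater than `max_failure` (default 0.05); a probe is excluded when it
lies on chrX/chrY, overlaps a SNP, cross-reacts, is vendor-flagged, or
retains any missing value after sample exclusion. Sample QC runs before
probe QC, so a badly failed array does not drag down probes for
everyone else; each removed probe carries exactly one reason, assigned
in that priority order. Probes with residual missingness are dropped,
not imputed. The PCA screen flags samples more than `sd_threshold`
(default 3) standard deviations from the mean on any of the leading
`n_components` (default 2) principal components; it never removes them,
since outlier exclusion is a judgement call for the analyst.

## Control matching

Greedy nearest-neighbour matching without replacement: cases in sheet
order, each taking the `ratio` sex-identical pool members with the
smallest |age gap| (years), ties broken by control id so the result is
invariant to pool row order. No caliper is applied. The ratio is a
config value — 4:1 is the single-cohort default, 2:1 the pooled
multi-syndrome default — because the two study designs the package
reproduces used different ratios, and nothing in the procedure infers
one from the data.

## Cell-type deconvolution

Whole-blood methylation is a mixture over leukocyte types, and case
status must not be confounded with composition. Proportions are
estimated per sample by non-negative least squares against reference
cell-type profiles at discriminating probes, then normalised to the
simplex — the practical form of the Houseman reference-based approach.
The reference panel is an input (the generator emits a matched
synthetic panel); no real leukocyte reference is bundled. The first
K − 1 proportions enter the design matrix, dropping the last cell type
to avoid collinearity with the intercept.

## Moderated differential methylation

Per probe, ordinary least squares of M on (intercept, case indicator,
cell-proportion covariates). Residual variances are shrunk by empirical
Bayes: a scaled-F prior (`d0`, `s0²`) is fitted by matching the first
two moments of `log s²` — the mean and the excess of its variance over
`trigamma(df/2)`, inverted through a Newton solve of the trigamma
function — and the posterior variance
`s̃² = (d0·s0² + df·s²) / (d0 + df)` yields a moderated t on `d0 + df`
degrees of freedom. Moment matching was chosen over maximum likelihood
for determinism and closed-form testability; when the observed log
variances show no excess dispersion the prior degrees of freedom are
infinite and the prior variance is the pooled mean of `s²`. The
implementation agrees with the R `limma` reference to ~1e-10 on shared
fixtures (a cross-check in the test suite, not a dependency).
`d0 = 0` recovers the ordinary t exactly. All-zero covariate columns
are dropped (they carry no information and would make the design
singular), so the covariate-free model is an exact special case.

Benjamini–Hochberg adjustment is delegated to
`statsmodels.multipletests` and verified against a brute-force step-up
oracle. q-values are floored at 1e-300 before any logarithm. DMPs are
probes with |Δβ| > 0.05 **and** q < 0.01, both strict.

## Three-stage probe selection

1. **Product score.** `|Δβ| · (−ln q)`, descending; top `i = 1000`.
   The logarithm base is natural; since a base change rescales all
   scores by a constant, the ranking — the only thing used — is
   base-invariant. Ties break by smaller q, then probe id.
2. **AUROC.** Mann–Whitney AUROC per probe (ties count ½) on beta
   values of cases vs matched controls; ranked by
   `max(auroc, 1 − auroc)` so hypomethylated probes (AUROC near 0) and
   hypermethylated probes (near 1) compete on equal footing; top
   `j = 500`. AUROC and the stage-3 correlations use beta values by
   default (`value_scale` switches to M), matching the 0–1 scale on
   which signatures are visualised.
3. **Correlation pruning.** Greedy scan in stage-2 rank order; a probe
   is kept iff its |Pearson r| with every already-kept probe is ≤
   `k = 0.75` on the training samples. Rank order makes the scan
   deterministic and favours the strongest probes; zero-variance probes
   are excluded with a warning (their correlation is undefined).

A structural consequence worth knowing: stage 2 always returns exactly
`j` probes when stage 1 supplied at least `j`, so when the true signal
involves fewer than `j` probes the stage-2 set necessarily contains
`j − (true signal size)` noise probes, and — noise probes being mutually
near-uncorrelated — most of them survive pruning. The *purity* of the
final signature (fraction of truly differential probes) is therefore
bounded above by roughly `signal size / j` regardless of effect size;
with a 300-probe planted signature and `j = 500` the ceiling is 60 %.
On synthetic cohorts the selector approaches this ceiling (~40–55 %
purity) while recall of the planted set and all downstream
classification metrics remain high — the extra probes carry little
weight in the SVM. Purity improves only by shrinking `j` toward the
true signal size, which is unknown in practice.

## LOOCV

One iteration per case: the held-out case is removed, stages 1–3 are
re-run on the remaining cases plus all matched controls, and the
held-out sample is assigned to case or control by the nearer group
centroid (Euclidean distance, beta scale, the iteration's probes). The
centroid rule formalises the visual criterion of whether the test
sample clusters with the cases; it is deterministic and threshold-free.

## SVM classifier and MVP scores

Training set: cases (label 1) against matched controls, 75 % of every
other control cohort and 75 % of every other-disorder cohort (seeded
splits without replacement; cohorts smaller than 2 go wholly to test,
as do explicitly held-out cohorts such as same-syndrome validation
samples). The classifier is a linear-kernel SVM (C = 1, balanced class
weights) — the established choice for p ≫ n methylation panels, and the
only kernel whose model is auditable probe by probe. Decision values
are mapped to MVP scores in [0, 1] by a Platt-style sigmoid: a logistic
regression fitted to the training decision values. Fitting the sigmoid
ourselves (rather than using libsvm's internal cross-validated
calibration) keeps training fully deterministic without a random seed
and lets the whole model — probe ids, weights, bias, two sigmoid
coefficients — round-trip exactly through a human-readable JSON file.
The positivity cutoff defaults to 0.25 and is pure configuration; with
heavily imbalanced training sets the calibrated case probability is
conservative, which is why the operating cutoff sits well below 0.5.
Scores on separable training data saturate near the sigmoid's range
rather than at exactly 0/1.

## Unsupervised verification

Ward linkage is scipy's `method="ward"` on raw observations — the
ward.D2 convention (squared-Euclidean Lance–Williams update). MDS is
classical (Torgerson) scaling: double-centre the squared distance
matrix, eigendecompose, return the top-k coordinates; for distances
realisable in k dimensions the embedding reproduces them to numerical
precision, and tests assert on pairwise distances, never on raw
coordinates (which are only defined up to rotation/reflection).
Separation is reported as 2-cut cluster purity (majority-label
fraction) and mean silhouette per label group.

## Cohort comparison

The overlap matrix is asymmetric by construction:
entry (A, B) = 100·|DMP_A ∩ DMP_B| / |DMP_A|, diagonal 100, undefined
(missing) for a cohort with no DMPs. The relatedness tree takes, per
cohort, the `min(500, #DMPs)` DMPs with the lowest *adjusted* p-values
("lowest p" is interpreted as lowest q, consistent with the DMP
definition; `rank_by="p_raw"` switches), pools the chosen probes,
builds a probes × cohorts matrix of within-cohort median beta, and
clusters the cohort columns by Ward/Euclidean. Annotation uses the
categorical CGI class (island / shore / shelf / inter-CGI) and gene
class (promoter / exon / intron / intergenic / exon-intron boundary)
carried in the probe manifest rather than live interval intersection:
the contract — one class per probe — is what downstream proportions
need, and it keeps the package free of genome-track data. Restriction
to a probe whitelist (e.g. probes shared between array generations) is
available as an optional filter.

## The synthetic-cohort generator

`simulate_cohort` emulates, in order of importance to the analysis:

* **Bimodal probe baselines** (mixture of low-, high- and
  intermediate-methylation Beta distributions) — the marginal
  distribution real arrays show.
* **Cell-composition confounding**: K = 6 cell types with reference
  profiles deviating from the baseline (SD 0.15 at 500 designated
  discriminating probes, 0.02 elsewhere); per-sample mixing weights
  from a symmetric Dirichlet (α = 5, realistic blood-composition
  spread); cases and controls share the prior unless a confounding
  shift is explicitly requested.
* **A planted signature**: `signature_size` (default 300) probes with a
  beta-scale effect of ±`effect_delta_beta`, hypomethylated with
  probability `hypo_fraction` (default 0.8, matching the predominantly
  hypomethylated profiles seen for this disorder family). Effects are
  added on the beta scale and clipped to [0.01, 0.99] *before* noise;
  planted probes receive mid-range (0.2–0.8), cell-type-invariant
  baselines so the planted Δβ is exact in the noise-free limit.
* **Measurement noise**: Gaussian on the M scale (SD
  `noise_sd_logit = 0.3` in log2 units), back-transformed — beta stays
  in (0, 1) and the downstream linear model is correctly specified.
* **Metadata**: ages uniform on 2–47 years, both sexes, cohort labels;
  optional validation cases carrying the same signature; optional
  sister cohorts sharing `round(overlap_fraction × signature_size)`
  planted probes (same signed effects; remainders disjoint; the
  tertiary cohort's fraction can differ, e.g. 0 for an unrelated
  disorder); optional uniform probe failures for QC testing.

Not emulated: raw intensities and detection p-values (missingness *is*
probe failure here), batch and chip-position effects, allosome probes
(QC's allosome rule is tested through manifest fixtures), sex-linked
methylation, age-related drift, and probe-probe correlation beyond what
cell mixing and the planted case effect induce. Consequently, passing
recovery tests show the procedure is correct and well calibrated under
its own assumptions — they do not certify performance on real arrays,
where batch structure and annotation errors add failure modes this
generator cannot produce.

## Problem sizes and numerics

Tests and the acceptance script run at 20 000 probes (8 000 for the
10-seed null calibration) with the study's cohort sizes (13 cases/52
matched controls; 13 + 14 + 4 pooled/62 controls), which exercises every
code path at full cohort scale in seconds per run. Other numerical
choices: p-value floor 1e-300; trigamma inversion by Newton iteration
to relative 1e-10; NNLS via scipy's active-set solver (deterministic);
SVM via libsvm with fixed data order (deterministic); all simulation
randomness from `numpy.random.default_rng(seed)`, so regeneration under
the same seed is byte-identical.

## Known limitations

* Greedy matching is not globally optimal assignment; with thin control
  pools it can starve a later case that an optimal matcher would serve.
* The signature-purity ceiling discussed above: `j = 500` is a quota,
  not an adaptive cut, and admits noise probes whenever the true signal
  is smaller.
* Platt calibration on training decision values (rather than
  cross-validated ones) biases MVP scores toward confidence on
  separable training sets; the held-out behaviour, which is what the
  tests assert on, is unaffected.
* The deconvolution reference panel is synthetic; absolute proportion
  estimates on real data require a real panel supplied by the user.
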