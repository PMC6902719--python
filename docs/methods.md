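# Methods

## The analysis model

The pipeline targets paired mediator-panel studies: each subject is
measured before and after an intervention (and, in skin, at UVR-challenge
timepoints), so every contrast is within-subject. The statistical unit of
work is the *pairwise comparison* — one arm, one tissue, condition B vs
condition A, paired by subject. All per-species inference and all group
enrichment are computed per comparison, never pooled across tissues
(units differ: pg/mg protein in skin, pg/ml in plasma) or across arms.

## Missing values and the LOD

Targeted LC-MS/MS panels report "not detected" when a species falls below
its analytical limit of detection; the data are left-censored, not
missing at random. Two heuristics run per comparison, in order:

1. a species missing in **strictly more than half** of the comparison's
   samples is removed (missing in exactly half is retained);
2. every remaining missing cell is replaced by the species' LOD.

Zeros and blanks in input files are coerced to missing at load, since a
true zero is indistinguishable from below-LOD. The composition is
enforced: the LOD substitution refuses species lacking a positive LOD,
and downstream stages require a complete matrix.

## Variance-stabilizing glog normalization

Concentrations follow an additive-plus-multiplicative error model
(x = μ·e^η + ε), under which raw log transforms inflate the variance of
low-intensity species. The transform

    h_s(x) = arcsinh(a_s + b_s · x) / ln 2,   b_s > 0

is calibrated per sample s by profile maximum likelihood under the model
h_s(x_si) = μ_i + e, e ~ N(0, σ²): the objective is
(n·m/2)·log RSS − Σ log h′_s(x_si) with the species means μ_i and σ
profiled out, minimized by L-BFGS with analytic gradients over
(a_s, log b_s). Robustness comes from a least-trimmed step that
alternates parameter optimization with re-selecting the 90% of species
with the smallest residual sum of squares, until the kept set is stable
and either the parameter change falls below 1e-8 or the relative
objective change falls below 1e-10 (the likelihood has near-flat offset
directions along which the optimizer's restart jitter exceeds a pure
parameter tolerance), capped at 100 iterations. Initialization is moment
based: b₀ is the ratio of the median log-scale SD of high-intensity
species to the median raw SD of low-intensity species, a₀ = 0.

Degenerate inputs: a replicated (zero-residual) matrix is handled by a
floor on RSS; matrices smaller than 2×2 are rejected. If the fit does not
converge the pipeline falls back to the deterministic, monotone
log₂(x + LOD/2) transform and records that in the fit metadata and run
manifest.

Identifiability note: when the data carry no additive noise and all
species sit well above zero, the offsets a_s are identified only up to
the smallest arsinh argument b_s·x_min (the likelihood is flat below that
scale). The fitted transform is then log₂-like with agreement that is
asymptotic in b_s·x: tests evaluate the log₂-slope property in that
regime (20× the largest observed concentration) rather than at the data
median, where a residual offset of order b·x_min can shift the local
slope by a few 1e-4.

High-intensity interpretation: h(2x) − h(x) → 1, so the mean paired
difference on the h scale is reported as the log₂ fold change.

## Paired testing and FDR

Per species, d_j = h(B_j) − h(A_j) over subjects j; t = mean(d)/(sd(d)/√n)
with df = n−1, two-sided. Zero-variance conventions: all-zero differences
give p = 1; zero variance with nonzero mean gives p = 0 with a warning.
Subjects missing either side are excluded (logged); species with fewer
than two complete pairs are skipped (logged). Benjamini–Hochberg is
applied within the comparison's species set, significance at q < 0.05.

## iGA

Species are ranked by signed log₂ fold change (descending for "up",
ascending for "down"; ties break on smaller p, then name — the ranking
is fully deterministic). The ranking statistic is configurable (`t`
available by flag) and recorded in the output metadata. For a group with
members at ranks r₁ < … < r_G among N tested species, the PC score is the
minimum over x of the hypergeometric upper tail P(X ≥ x) with sample size
r_x, evaluated as a single big-integer ratio (exact to double precision;
no continuity or normal approximation). The minimum over x makes PC an
adaptive, cutoff-free enrichment score; it is *not* a uniform p-value
(it is anticonservative by up to a factor G under the null), which the
conventional 5×10⁻⁴ call threshold absorbs.

Correction: PC_corrected = min(1, PC_raw × n_tests) with n_tests =
(scored groups) × 2 directions — a Bonferroni rule, recorded in the
results metadata. Groups are always evaluated against the post-filter
species universe; groups with no surviving members are skipped and
logged.

## Default grouping scheme

Eight groups assembled by precursor × pathway rules, applied in order so
membership never overlaps: (1) AA-derived COX prostanoids/thromboxanes;
(2) AA-derived hydroxy acids and hepoxilins (HETEs, HX, LTB4);
(3) EPA-derived species (HEPEs, E-series prostanoids, LTB5);
(4) DHA-derived hydroxy acids (HDHAs); (5) octadecanoid/other-PUFA
hydroxy acids (HODEs, HOTrEs, HETrEs, oxo-ODEs, t-EKODE); (6) CYP450
epoxides; (7) CYP450 diols; (8) eCBs + NAEs. Species matching no rule
(e.g. the nonenzymatic isoprostane 8-iso-PGF2a) stay ungrouped with a
warning but remain in the tested universe. The scheme is data, not code:
any YAML mapping of label → species list can replace it.

## Synthetic studies

The generator emulates the paired two-arm design: defaults EPA n=12,
DHA n=9; epidermis, dermis, plasma; UVR timepoints unirradiated/24h/72h
in skin (plasma is sampled pre/post only); every subject has both phases
for every tissue × timepoint. Per species i and sample:

    c = med(i, tissue) · exp(u_subj,i) · effect · exp(η) + ε,  clipped at 0

with u ~ N(0, subject_sd²) drawn once per subject × species × tissue
(shared across phases, so pairing cancels it), η ~ N(0, mult_noise_sd²),
ε ~ N(0, add_noise_sd²). The LOD is the `lod_quantile` quantile of the
species' baseline log-normal marginal (σ² = subject_sd² + mult_noise_sd²);
values at or below it are recorded as missing.

Defaults, chosen once as plausible magnitudes for targeted mediator
panels: subject_sd 0.4 and mult_noise_sd 0.25 (log scale), add_noise_sd
2.0 concentration units, lod_quantile 0.2 (≈20% censoring). Baseline
medians are anchored to reported tissue magnitudes: epidermal EPA-derived
species sum to ~319 and DHA-derived to ~3136 pg/mg protein (the ~10×
EPA/DHA asymmetry), dermis at 0.3× epidermis, and in plasma CYP450
epoxides/diols are the most abundant classes, AEA exceeds 2-AG, and PEA
is the dominant NAE. Per-species variances and missingness rates are not
published for such panels at this granularity; these defaults are
plausible, not literal.

What the generator does **not** emulate: inter-batch drift, correlated
noise between species sharing a biosynthetic route, heavy-tailed or
skewed within-subject error, panel-wide contamination, or
subject-level covariates. Passing recovery/calibration tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every feature of real clinical data.

The RBC module generates paired fatty-acid weight-% profiles from
template means (pre n-3 index 4.86%; the default EPA-arm shift raises it
to 7.67%) with independent Gaussian within-subject noise (default sd 0.3
percentage points, clipped at 0).

## Summary quantities

- **n-3 index** = 20:5n-3% + 22:6n-3% of erythrocyte fatty acids.
- **Precursor totals** are per-subject sums of *raw* concentrations
  (unit fidelity; LOD-substituted cells contribute the LOD); percent
  change = 100·(mean post − mean pre)/mean pre on the raw scale, while
  any paired test on totals runs on log-transformed totals.
- **Skin–plasma Spearman screen** pairs samples by subject × phase on
  unchallenged samples; exact permutation p (all n! relabelings,
  two-sided on |ρ|) for n ≤ 9, the large-sample approximation otherwise;
  constant vectors are reported as missing with a note.
- RBC per-fatty-acid paired t tests are deliberately uncorrected
  (few, pre-specified composition endpoints).

## Problem sizes in tests and the acceptance script

Simulation-based checks use the study's own scale — n=12 subjects, the
89-species panel, single-tissue single-timepoint comparisons — with 500
replicates for null calibration, 200 for effect recovery, 10 000 for
paired-t calibration, and 10⁶ permutation draws per Monte-Carlo iGA
instance; these sizes give Monte-Carlo error comfortably below the
asserted margins. The acceptance script uses 200 null replicates.

## Known limitations

- PC values are exact, but their null distribution is not uniform; the
  Bonferroni correction bounds only the expected call rate.
- The VSN fallback (log₂(x + LOD/2)) differs from the ML calibration by a
  species-specific offset; fold changes from the two transforms are not
  interchangeable — the run manifest records which was used.
- Whether normalization should be fitted jointly across arms is an open
  design question in such studies; this package fits per comparison and
  says so in the manifest.
- Exact Spearman permutation p-values cost n!; above n = 9 the
  large-sample approximation is used.
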