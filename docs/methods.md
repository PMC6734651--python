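# Methods

## Overview

`boolmark` implements a biomarker-discovery pipeline for colorectal-cancer
(CRC) expression cohorts built around Boolean implication: the search for
genes *X* such that *X*-low expression implies high expression of vimentin
(*VIM*), the canonical mesenchymal / cancer-associated-fibroblast marker.
The pipeline has four computational stages — per-gene step-function
thresholding, the genome-wide implication search with permutation FDR,
candidate screening by support and differential expression, and survival /
baseline statistics for marker-defined patient subgroups — plus a seeded
synthetic-cohort generator that provides ground truth for every recovery
test. Real cohorts are consumed as already-normalized log2 genes × samples
TSV matrices; no cross-cohort renormalization is performed (the package
assumes upstream single-sample normalization made values comparable).

## Step-function thresholding

For each gene the expression values are sorted ascending and a one-step
function is fitted: every breakpoint `i ∈ 1..n-1` splits the sorted vector
into a left segment with mean μL and a right segment with mean μR, and the
breakpoint minimizing `SSE = Σ_left (x-μL)² + Σ_right (x-μR)²` is kept
(exhaustively, via prefix sums, O(n) after sorting). Ties in SSE break
toward the smallest breakpoint, making the fit deterministic and invariant
to input order. The high/low threshold is the midpoint `t = (μL+μR)/2` —
the placement is a package choice; only a single cutoff per gene is fitted
(no multi-step variants). An F-like statistic
`(SSE_flat − SSE_step) / (SSE_step/(n−2))` is reported for every fit but is
never used as a filter. Constant vectors are flagged degenerate and produce
only INTERMEDIATE calls. Fits require at least 4 non-missing values (two
per segment); genes below that are skipped and logged.

Sample calls use a margin `m` (log2 units) around the threshold: LOW below
`t−m`, HIGH above `t+m`, INTERMEDIATE inside the closed band. The default is
`m = 0.5` for the implication analysis (a noise buffer so borderline samples
do not contaminate the contingency table) and `m = 0` for patient-level
subgrouping, where every patient must receive a high/low label.

## Boolean implication statistic

For a pair (X, Y) the LOW/HIGH calls form a 2×2 contingency table
(intermediate and missing samples excluded). The relation "X-low ⇒ Y-high"
holds when the contradicting quadrant (X-low, Y-low) is sparse relative to
independence. With sparse count `o`, X-side margin `r`, Y-side margin `c`
and total `n`:

    e   = r·c / n
    S   = (e − o) / √e
    err = ½ (o/r + o/c)

A pair passes when `S > s_min` (default 3.0) and `err < err_max` (default
0.1); both are configurable, as is the minimum usable sample count
`min_n = 20` (stability of `e` and `err`). A zero margin makes the pair
not evaluable (never a pass). The statistic is a deficit in Poisson-scale
units; S scales as √k under k-fold replication of the table at fixed o/e,
and is symmetric under the contrapositive (X-low ⇒ Y-high vs Y-low ⇒
X-high). The genome-wide search tests every gene against a fixed target
over a sample population (typically the CRC arrays) and reports, per gene,
the quadrant counts, S, err, and the support fraction — the share of the
population contributing LOW/HIGH calls in both genes, which the screen
stage filters at 40%.

FDR of a threshold configuration is estimated by permutation: each round
independently shuffles every non-target gene's calls across samples
(destroying pairwise association while preserving per-gene call
composition) and recounts passing pairs;
`FDR = mean null passing count / observed passing count`, reported as 1
when nothing passes and capped at 1. The permutation stream is seeded and
bit-reproducible.

## Candidate screen

Implication hits are reduced by two conjunctive filters, both strict
inequalities: support fraction ≥ 0.40, and differential expression with
fold change > 2 at p < 0.001 against **both** normal mucosa and IBD tissue.
The DE test is a per-gene Welch two-sample t on log2 values (the
conservative unequal-variance default; configurable), with fold change
`2^|Δmean|`; genes with fewer than 3 non-missing values in a group are
skipped. No multiple-testing correction is applied inside the DE filter —
error control for the discovery step lives in the implication-stage FDR.
Every per-filter flag is retained in the output for audit, and the filters
are monotone in their thresholds.

## Survival analysis

Patients are grouped two ways from margin-0 calls: marker-low vs
marker-high, or the marker × VIM cross (marker-low/VIM-high,
marker-high/VIM-high, marker-high/VIM-low, with the rare low/low patients
as OTHER). Kaplan–Meier curves, the log-rank test and Cox
proportional-hazards fits are delegated to lifelines; Cox uses Efron tie
handling (the only method lifelines implements, and the less biased one).
Five-year rates are read from the step-function estimate at 60 months
(right-continuous). Covariate encodings: age dichotomized at 60, stage as
a numeric ordinal (per-stage increase), chemotherapy yes vs no with the
explicit "missing" category excluded complete-case, grade poor vs others,
location colon vs rectum.

The marker × chemotherapy 2×2 factorial analysis reports both scales:
multiplicative interaction as the Wald p of the Cox product term, and
additive interaction as RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1 estimated from a
joint-indicator Cox parameterization with a delta-method 95% CI (gradient
(−HR₁₀, −HR₀₁, HR₁₁) against the coefficient covariance). RERI is the
package's operationalization of "additive effect"; it is zero under hazard
additivity and (HR₁₀−1)(HR₀₁−1) under exact multiplicativity.

## Baseline-table statistics

The clinical baseline battery mirrors standard "Table 1" practice and the
variants were chosen to match published two-group tables computed with
SPSS-era conventions: Pearson χ² **without** continuity correction for
nominal variables (falling back to Fisher's exact test when any expected
cell count is below 5), the pooled-variance Student t from per-group
(mean, sd, n) summaries, and a tie-corrected asymptotic Mann–Whitney U on
ordinal category counts (midranks; variance
`n_a n_b/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`; no continuity correction).
Missing values are excluded from every test; the chemotherapy "missing"
category is displayed but never tested. The summary-level t and the
ordinal Mann–Whitney operate on printed tables directly, so published
baselines can be re-verified without patient-level data; agreement is
checked at printed precision (±0.001 on a 3-decimal p-value, since the
source tables were computed from unrounded summaries).

## Synthetic cohort generator

The generator emulates, at roughly 1/5 scale, a colorectal array
compendium — defaults 500 CRC, 20 polyp, 90 IBD, 80 normal samples and 500
genes — plus a discovery survival cohort of 889 patients and a validation
cohort of 691 (the scales of the two cohorts the pipeline is designed
for). Key structure and defaults:

- **Bimodal genes**: two-Gaussian mixtures with modes at 5 and 9 log2
  units and component σ = 0.5, so the mixture midpoint (7) is an
  unambiguous threshold at test scale. 50 independent bimodal background
  genes by default; remaining background genes are unimodal
  (mean ~ U(6,8), σ = 1).
- **Planted implication**: the marker (PPM1H) is low in a fraction
  π_low = 0.226 of CRC samples; the target (VIM) mixture component is
  sampled conditionally on the marker's — P(target low | marker low) = ε
  (default 0.02, the sparse-quadrant leak), P(target high | marker high)
  = 0.45. Conditional sampling keeps both marginals bimodal; no post-hoc
  editing of values.
- **Differential expression**: the marker and 10 further genes are shifted
  by 1.5 log2 units (≈2.8-fold) in normal/IBD relative to CRC, polyps
  halfway, so the planted marker passes the >2-fold screen.
- **Molecular labels**: MSI (base rate 0.15) and BRAF mutation (0.10) are
  enriched in marker-low CRC samples by an odds multiplier of 4; KRAS
  (0.40) and TP53 (0.50) are independent.
- **Survival**: exponential event times with hazard
  `h₀·exp(β·1[low] + β_stage·(stage−2) + β_age·1[age≥60])`,
  `h₀ = −ln(0.75)/60` per month (5-year DFS 75% in the reference group),
  β anchored at ln 1.37 (discovery) and ln 4.05 (validation), β_stage =
  ln 2.266, β_age = ln 1.181. Censoring is independent Uniform(0, τ) with
  τ solved numerically (Brent) so the expected censored fraction hits the
  target — default 0.70, i.e. a ~30% event rate; τ is capped by a
  120-month accrual horizon and an unreachable target raises an error.
  Disease-specific survival (validation cohort) uses hazard scale 0.4,
  β = ln 2.608 and censoring 0.88, reflecting the rarity of
  disease-specific death relative to relapse.
- **Reproducibility**: every gene and every patient draws from a
  sub-stream `SeedSequence([master_seed, stream, index])`, so generation
  is a pure function of (config, seed) and enlarging the study does not
  perturb existing entities.

What the generator does **not** emulate: platform/batch effects,
normalization artifacts, probe-level structure, correlated gene modules
beyond the planted pair, non-proportional hazards, informative censoring,
or covariate-marker confounding (covariates are drawn independently of
the marker group). Passing recovery tests therefore demonstrates
correctness of the machinery under the stated generative assumptions, not
robustness to the full messiness of real cohort data.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use the default 500-gene /
500-CRC-sample study for implication recovery (100 permutations for FDR),
50 replicates per planted β at the 889/691 cohort scales for Cox CI
coverage, 20 reduced studies (200 genes, 300 CRC samples) for the null
control, and exhaustive small-alphabet plus seeded random vectors (lengths
4–12) for the step-fit-versus-enumeration oracle. These sizes make the
whole battery run in well under a minute while leaving the planted effects
far from the decision boundaries.

## Known limitations

- The implication search is target-centred; all-pairs implication networks
  are out of scope.
- The support-fraction filter has a single interpretation (samples usable
  for the pair); per-gene platform coverage is reported alongside so the
  alternative reading can be filtered on by callers.
- Only Efron tie handling is available for Cox fits.
- CEA/CA19-9 appear as continuous covariates and summary rows only; no
  median/range tests on raw serum values.
- Gene identifiers are opaque keys: no alias resolution or multi-probe
  collapsing (matrices are expected to carry one row per gene).
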