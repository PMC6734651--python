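# boolmark

Boolean-implication biomarker discovery and survival analysis for
colorectal-cancer (CRC) expression cohorts.

A recurring observation in CRC transcriptomics is that poor-prognosis
tumours carry expanded mesenchymal components marked by high vimentin
(*VIM*) expression. `boolmark` implements the analysis that turns this into
a biomarker search: find genes *X* whose **low** expression *implies* high
*VIM* — an asymmetric, Boolean relationship in binarized expression data —
then test whether the *X*-low patient subgroup has worse survival.

The pipeline:

1. **Step-function thresholding** — each gene's sorted expression values get
   a one-step fit; the breakpoint minimizing the residual sum of squares
   defines a high/low cutoff `t = (μL + μR)/2`, and samples are called
   LOW/INTERMEDIATE/HIGH with a margin `m` around `t`.
2. **Implication search** — for every gene *X* vs the target *Y* = *VIM*,
   the LOW/HIGH calls form a 2×2 table; "X-low ⇒ Y-high" holds when the
   (X-low, Y-low) quadrant is sparse relative to independence:
   `S = (e − o)/√e` with `e = r·c/n`, and error rate
   `err = ½(o/r + o/c)`. A pair passes at `S > 3`, `err < 0.1`; the FDR of
   the configuration is estimated by within-gene permutation of calls.
3. **Candidate screen** — hits must be supported by ≥ 40% of the CRC arrays
   and differentially expressed (> 2-fold, p < 0.001, Welch t) versus both
   normal mucosa and IBD tissue.
4. **Survival & baseline statistics** — marker-defined subgroups are
   compared with Kaplan–Meier / log-rank, multivariate Cox (Efron ties),
   stage-restricted analyses, a marker × chemotherapy 2×2 factorial
   interaction (multiplicative Wald p and additive RERI with delta-method
   CI), and a clinical baseline-table battery (χ² without continuity
   correction / Fisher exact, pooled-summary Student t, tie-corrected
   Mann–Whitney U on ordinal tables).

A seeded synthetic-cohort generator (`boolmark.synthetic`) produces array
compendia and survival cohorts with planted truth — bimodal marker genes, a
sparse low–low quadrant with leak ε, a marker-low subgroup enriched for
MSI/BRAF labels, and proportional-hazards survival — so every stage is
covered by parameter-recovery tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort and write their tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1     # study TSVs + truth
python analysis/02_threshold.py             # per-gene cutoffs and calls
python analysis/03_implications.py --seed 1 # genome-wide search + FDR
python analysis/04_screen.py                # support + DE filters
python analysis/05_survival.py              # KM, Cox, interaction
python analysis/06_baseline.py              # baseline tables
```

With seed 1 the search stage prints:

```
tested 499 genes against VIM over 500 CRC arrays
  passing (S > 3, err < 0.1): 1
  top hit: PPM1H (S = 6.80, err = 0.013, support = 1.00)
  permutation FDR of the configuration: 0.0000 (100 permutations)
```

i.e. the planted partner gene is the only hit — its low–low quadrant with
VIM is ~6.8 Poisson-scale units sparser than independence predicts, with a
1.3% conditional leak — and 100 permutations produce no false hits. The
screen confirms it as the sole candidate (5.4-fold down vs normal,
5.3-fold vs IBD), and the survival stage recovers the planted prognostic
effect in both cohorts:

```
[discovery] multivariate Cox marker-low HR = 1.468 (1.116-1.932), p = 0.0061
[validation] multivariate Cox marker-low HR = 5.005 (3.617-6.926), p = 2.56e-22
```

both 95% CIs covering the planted hazard ratios (1.37 and 4.05).

## Layout

```
src/boolmark/      library: io, stepminer, implication, screen,
                   cohort_stats, survival, synthetic
analysis/          numbered narrative drivers (simulate ... baseline)
scripts/           acceptance.py
tests/             pytest suite with enumeration/simulation oracles
docs/methods.md    model assumptions, defaults, and design choices
```
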