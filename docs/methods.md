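# Methods

## Scope and model structure

This package simulates individual-specific serotonin (5-HT) dynamics in the
presynaptic terminal from five regulatory gene variants, reduces each
simulation to 30 summary features, and compares those features across
clinical groups with rank-based statistics. It is organised as a
statsmodels-style pair: `PresynapseCohortModel` (data + configuration) and
`CohortAnalysisResults` (fitted tables + `summary()`), with the underlying
machinery exposed as library modules (`variants`, `kinetics`, `features`,
`stats`, `cohort`, `pipeline`).

### Genotype → activity coefficients

Each individual carries calls at five variants: three *TPH2* SNPs
(rs111798998, rs4290270, rs7305115), the *SLC6A4* 5-HTTLPR length
polymorphism, and the X-linked *MAOA* promoter uVNTR. Each allele carries a
literature expression fold-change relative to its reference allele
(G → 3.0, A → 1.7, A → 1/1.4 for the TPH2 SNPs; L → 3.0 for 5-HTTLPR;
3.5R/4R → 5.5 for the uVNTR, the midpoint of the reported 5–6-fold range;
2R/3R/5R are treated as reference). Three modelling conventions are needed
where the literature is silent, and each is isolated so it can be swapped:

* **Within a variant**, the two allele multipliers combine by arithmetic
  mean (additive expression of two gene copies); hemizygous males use the
  single allele's multiplier. Implemented solely in `variant_coefficient`.
* **Across the three TPH2 SNPs**, coefficients multiply (independent
  regulatory effects; haplotype phase is unobserved).
* **X-inactivation** in MAOA-heterozygous females is ignored (plain mean);
  no mechanism would justify a specific skewing parameter.

The result is the activity triple (c_tph2, c_sert, c_maoa), bounded by the
per-gene multiplier products (c_tph2 ∈ [1/1.4, 5.1]); an all-reference
genotype maps to (1, 1, 1) for either sex. The triple takes at most
27 × 3 × 3 distinct values, which the cohort fitter exploits by caching one
simulation per distinct triple — an exact memoisation, not an approximation.

### Kinetic model

Eight ODEs track material through the terminal (all pools in μM, time in
minutes; every reaction is a 1:1 molar transformation):

    d(trp_ext)/dt = −k_up·trp_ext
    d(trp_in)/dt  = k_up·trp_ext − F_T          F_T = c_tph2·Vt·trp_in/(Kt+trp_in)
    d(5-HTP)/dt   = F_T − k_aadc·5-HTP
    d(fc5-HT)/dt  = k_aadc·5-HTP + F_S − F_V − F_M
    d(v5-HT)/dt   = F_V − k_rel·v5-HT           F_V = Vv·fc/(Kv+fc)
    d(e5-HT)/dt   = k_rel·v5-HT − F_S − k_eloss·e5-HT
                                                F_S = c_sert·Vs·e/(Ks+e)
    d(5-HIAA)/dt  = F_M − k_hiaa·5-HIAA         F_M = c_maoa·Vm·fc/(Km+fc)
    d(cleared)/dt = k_eloss·e5-HT + k_hiaa·5-HIAA

Genotype scales **Vmax only** (protein abundance tracks mRNA fold-change;
Km is a property of the enzyme). 5-HIAA removal `k_hiaa` is shared by every
individual in a run, so between-individual differences in the 5-HIAA time
course reflect synthesis and degradation capacity, never removal. The
eighth state (`cleared`) accumulates all removed material, making the state
total exactly conserved under the pulse input — the basis of the
mass-balance audit (`mass_balance` must stay ≤ 1e−6 relative; in practice
it is ~1e−13 at the default tolerances).

### Default parameters and their calibration

The kinetic constants are the package's own defaults (configurable in the
`kinetics` config section); they were chosen so that the model reproduces
the qualitative behaviour the analysis depends on, and are stated here with
that reasoning:

| parameter | default | unit | role |
|---|---|---|---|
| trp_ext0 | 100 | μM | dietary tryptophan pulse |
| k_up | 0.1 | 1/min | tryptophan uptake |
| vmax_tph2 / km_tph2 | 1.0 / 40 | μM/min, μM | synthesis (genotype-scaled) |
| k_aadc | 0.01 | 1/min | 5-HTP → fc5-HT conversion |
| vmax_vmat / km_vmat | 1.0 / 0.3 | μM/min, μM | vesicular packaging |
| k_rel | 0.2 | 1/min | vesicular release |
| vmax_sert / km_sert | 0.5 / 0.2 | μM/min, μM | reuptake (genotype-scaled) |
| k_eloss | 4.0 | 1/min | non-SERT extracellular clearance |
| vmax_maoa / km_maoa | 0.15 / 1.0 | μM/min, μM | degradation (genotype-scaled) |
| k_hiaa | 0.0005 | 1/min | 5-HIAA removal (shared) |
| t_end / dt_sample | 600 / 1 | min | simulation window and grid |

Three choices are deliberate and load-bearing:

* **AADC is the slow, genotype-independent bottleneck** (k_aadc = 0.01).
  TPH2 conversion of the pulse completes within the window for every
  genotype, so mean 5-HTP remains strictly increasing in c_tph2 through the
  residual 5-HTP pool at t_end (stronger synthesis finishes earlier and
  leaves a further-decayed pool — the margin is ~1.6e−4 μM, three orders
  above solver error), while downstream fluxes are paced by AADC rather
  than by c_tph2, keeping synthesis-genotype noise out of the metabolite
  features.
* **Extracellular clearance is fast** (k_eloss = 4/min, half-life ~10 s —
  extracellular 5-HT is in reality cleared on sub-minute timescales by
  diffusion and low-affinity transporters). This creates a genuine
  competition between the MAOA route (fc5-HT → 5-HIAA) and the
  non-recycled loss route, so MAOA genotype visibly moves the 5-HIAA
  totals instead of merely re-timing them.
* **5-HIAA removal is slow** (k_hiaa = 0.0005), so 5-HIAA accumulates
  concavely toward a late plateau. Its sampled series therefore has
  negative skewness (−0.69 to −1.2 across the full genotype enumeration):
  a more negative skew means later accumulation. This sign is a tested
  invariant for every reachable genotype.

Integration uses LSODA at rtol 1e−8 / atol 1e−10, sampled on the uniform
grid. Values more negative than −max(1e−12, 100·atol) μM abort the run;
smaller negatives are solver noise, clipped to zero and counted on the
trajectory. Identical inputs give bit-identical trajectories.

A constant-infusion variant (`input_mode="infusion"`) replaces the pulse by
a constant inflow R into the intracellular pool. Its steady state is solved
algebraically (`steady_state`, scipy root-finding started from the
closed-form flux-balance chain) and serves as an independent oracle: the
six dynamic concentration pools satisfy |derivative| < 1e−9 μM/min (the
cumulative `cleared` pool grows at exactly R by construction and is
excluded), long simulations converge to it within 1e−6 μM, and with
k_eloss = 0 the closed form hiaa* = R/k_hiaa holds exactly.

### Features

Each species' sampled series (601 points including t = 0) is reduced to
mean, median, maximum, standard deviation, skewness and kurtosis — 30
features per individual, in μM except the two unitless shape measures.
Moments are population (biased) moments with Pearson (non-excess) kurtosis:
sd = √m2, skew = m3/m2^1.5, kurt = m4/m2². Sample-corrected and
excess-kurtosis conventions are available behind a switch. A zero-variance
series reports skew = kurt = 0 with a degenerate flag rather than NaN, so
downstream rank tests stay total.

### Statistics

All group comparisons are rank-based (the feature distributions are
genotype-class mixtures, far from normal; `normality_screen` wraps
Shapiro–Wilk for the screening step):

* **Kruskal–Wallis** (mid-ranks, tie-corrected, chi-square approximation)
  compares each feature across attempters / non-attempters / unaffected.
* **Mann–Whitney U** for two-group comparisons: exact enumeration when both
  groups have ≤ 20 tie-free observations, otherwise the tie-corrected
  normal approximation.
* **Chi-square of independence** for categorical demographics, with Yates
  continuity correction on 2×2 tables.
* **Two-way ART ANOVA** within patients, diagnosis × attempt status as
  fixed between-subjects factors. For each effect the response is aligned
  (all other effects' cell-mean contributions subtracted, using unweighted
  cell means so unbalanced cells are handled in the least-squares-means
  sense), mid-ranked, and a full two-factor ANOVA is fitted to the ranks
  with Type-III sums of squares under effects coding; only the target
  effect's F and p are reported. Alignment diagnostics verify that
  stripped effects leave no trace (cell-mean spread ≤ 1e−10 on noiseless
  factorial data). Post hoc contrasts for a significant main effect are
  Tukey-HSD-adjusted pairwise comparisons on that effect's aligned ranks.
  Type-I error is calibrated: over 1,000 null datasets at the study's
  unbalanced cell sizes (46/55/76/72/53/90) each effect rejects at 3.5–6.5%
  at α = 0.05.

p < 0.05 is labelled significant and 0.05–0.10 a trend. Raw per-feature
p-values are reported by default; an optional Benjamini–Hochberg column can
be added and is clearly non-default.

### Synthetic cohorts

The study's genotype data are not public, so cohorts are synthesised:
Hardy–Weinberg sampling at configurable allele frequencies within each
diagnosis × attempt-status cell, one X allele for males and two for females
at the MAOA uVNTR, and exact per-cell sex counts. The default design mirrors
the published layout (BD 46/55, MDD 76/72, SCH 53/90 split SA/non-SA, 140
unaffected; 118/57 vs 140/77 female/male among SA vs non-SA patients), so
demographic summaries of a generated cohort reproduce the published shares
(SA 44.64%, BD 25.77%, MDD 37.76%) and the published sex chi-square
(χ² = 0.25, p = 0.619) exactly. Default allele frequencies
(G 0.35, A(rs4290270) 0.40, A(rs7305115) 0.45, L 0.55; uVNTR 3R 0.60,
4R 0.35, 3.5R 0.02, 2R/5R 0.03 combined) are documented placeholders — no
numerical comparison depends on them. The three TPH2 SNPs are drawn
independently (no linkage); per-cell substreams of the master seed make
cohorts reproducible and cells independent of each other's sizes. An
optional per-cell normal age model supports the demographic age tests; ages
are off by default.

`inject_effect` shifts one allele's frequency within one diagnosis group
(other alleles renormalised proportionally) to create detectable effects.
The end-to-end recovery experiment shifts the uVNTR 4R frequency by +0.3 in
the schizophrenia group of a 200-individual scaled cohort and tests the ART
diagnosis effect on the 5-HIAA mean: measured power is ~0.89–0.92 over 200
replicates, with the neutral pipeline rejecting at ~5–7%. The power ceiling
here is structural — the "noise" is mostly the within-group uVNTR genotype
mixture itself, which no kinetic setting can remove.

## What the synthetic data does and does not show

The generator reproduces the cohort's size structure, sex composition,
X-linked inheritance and Hardy–Weinberg genotype frequencies, and it can
embed group-specific allele-frequency differences. It does not reproduce
the real cohort's (undeposited) allele frequencies, linkage between TPH2
SNPs, population structure, relatedness, or any environmental contribution.
Passing tests therefore demonstrate that the pipeline is statistically
calibrated and can recover genotype-frequency effects of plausible size —
not that the real cohort contains such effects, and not the published
absolute concentration values, which additionally depend on unpublished
kinetic constants. Only sign and ordering properties of the published
feature table are treated as reproducible claims.

## Numerical conventions and degenerate inputs

* Ties: mid-ranks everywhere.
* Degenerate rank tests (all values identical) return statistic 0, p = 1,
  flagged rather than erroring.
* ART on all-tied ranks reports F = 0, p = 1 with a degenerate flag.
* Cohorts with fewer than two individuals skip the statistics stage with an
  explicit notice; incomplete factorial layouts skip the ART stage.
* The acceptance and replicate experiments use cohorts of n = 200 scaled
  proportionally from the study layout, and 200 replicates for power /
  1,000 for null calibration — sizes at which the Monte-Carlo error of the
  reported rates is ~1–2 percentage points.

## Known limitations

* The eight-equation scheme is a reconstruction: the published companion
  model's exact equations and constants are unavailable, so absolute
  concentrations (and hence the published μM feature values and F
  statistics) are out of reach by design.
* No receptor or postsynaptic signalling, no other neurotransmitter
  systems, no gene–environment interaction, no pharmacokinetics.
* No haplotype-aware sampling of the TPH2 SNPs; no genotype imputation.
* Mixed/repeated-measures ART and covariate adjustment are out of scope.
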