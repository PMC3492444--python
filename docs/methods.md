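# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the `adsig` pipeline.

## Study design being modelled

Post-mortem hippocampal expression is measured on a two-channel cDNA
platform (~4,608 probes) against a common reference RNA pool, with a
dye-swap replicate hybridization for every subject. Two contrasts are
first-class:

* **pathology** — subjects meeting AD neuropathology criteria (CP-AD and
  P-AD together, n = 13 in the reference design) versus pathology-free
  controls (N, n = 10);
* **manifestation** — demented versus non-demented subjects among the
  pathology carriers (CP-AD, n = 9, vs. P-AD, n = 4).

### Group assignment

AD pathology is defined as Braak ≥ IV **or** CERAD ∈ {B, C}; control
pathology as Braak ≤ II **and** CERAD ∈ {0, A}. The OR rule is the default
because it is the only rule consistent with the published 23-case summary
table, which contains demented cases at Braak ≥ IV with CERAD A; a strict
AND variant is exposed (`ad_pathology_rule="and"`) for sensitivity
analyses. CDR 0.5 ("questionable dementia") belongs to neither the CDR = 0
nor the CDR ≥ 1 stratum and maps to Unclassified.

## Preprocessing

1. **Spot filters.** A spot is removed when either channel's foreground
   reaches the scanner ceiling (default 63,000 ≈ 16 bits) or when either
   background-subtracted net signal is ≤ 0. Removals propagate as missing
   values; downstream tests are pairwise-complete and require at least 3
   observations per group per gene (configurable), else the gene's
   statistics are reported missing.
2. **Within-array normalization.** M = log₂(net₂/net₁) is centered by
   subtracting a lowess fit of M on A = ½log₂(net₁·net₂), span 0.4
   (config-exposed; the original protocol does not state one). The fit
   uses plain (non-robust) local regression: robustifying iterations
   degenerate when nearly all residuals are zero — the noise-free unit
   test case — and can swallow a lone true signal. A refit of lowess on
   the normalized data is *not* exactly zero (lowess is not a projection);
   the test suite asserts that it is an order of magnitude below the
   original dye-bias fit, and exactly zero in the noise-free case.
3. **Orientation.** Dye-swap arrays store physically exchanged channels,
   so the raw M of a swap array is sign-flipped relative to its partner.
   The dye bias lives in raw orientation, so lowess runs before the sign
   flip to the common test-over-reference orientation.
4. **Across-array scaling.** Each array's M is rescaled so its median
   absolute deviation equals the across-array median MAD ("inter-slide"
   spread matching; the original description names no statistic, and MAD
   is robust to the small DEG fraction). The step is skippable
   (`scale=False`), which degenerate noise-free inputs require.
5. **Replicate handling.** Default `arrays` mode keeps all hybridizations
   as columns (the 46-array design); `subject_mean` averages each
   subject's pair. Because a subject's two arrays share biological noise,
   array-level columns are pseudo-replicates: permutation inference is
   calibrated at the subject level, and all calibration tests use
   `subject_mean`. Array-level mode mirrors the original design and
   increases apparent power accordingly.

## Differential expression

Welch t per gene (pooled-variance optional; the permutation reference
makes the variant second-order), with a permutation p-value over
group-size-preserving relabelings of sample columns. When C(n, n_A) ≤
`n_perm` all assignments are enumerated (the p-value is exact and the
identity assignment is one of the enumerated terms); otherwise `n_perm`
relabelings are sampled uniformly and the plain exceedance frequency is
reported (a +1/+1 conservative option exists). Tie comparisons use a
relative tolerance of 1e−10 so that relabelings whose statistic equals the
observed one up to floating error (e.g. the complement assignment) count
as hits; genes constant to machine precision are degenerate by policy
(t = 0, p = 1). Thresholds are inclusive (P ≤ α). BH q-values are attached
and an FDR < 0.05 criterion is attempted before falling back to raw
P ≤ 0.01, with both outcomes recorded in the run report. Both permutation
and parametric p-values are reported, since either convention may stand
behind a published DEG count.

## Over-representation

One-sided Fisher's exact test (enrichment tail) of each category's 2×2
table against the full platform as reference. Raw p-values are reported by
default at the conventional P ≤ 0.05 operating point (BH optional);
no redundancy reduction across overlapping categories is applied.
Categories with no platform member are dropped with a log line.

## Clustering with bootstrap support

UPGMA on Euclidean distances between sample columns restricted to a
selected gene set (genes with any missing value are excluded from the
distance). Merge ties are resolved by scipy's deterministic
nearest-neighbor-chain order. Support resamples *genes* with replacement
(matching per-node support display on sample dendrograms); a node's
support is the fraction of replicates in which its exact leaf set recurs
as a clade. A sample-resampling variant is available, counting a clade as
recovered when its restriction to the drawn leaves recurs.

## Differential co-expression signature

Seeds (a DEG set) are expanded to first neighbors on a merged interactome
edge list, restricted to platform genes; isolated seeds are retained with
degree 0 but unscored. Per gene, `avg_abs_diff` is the mean over its
measured, non-constant interactors of |PCC_A − PCC_B|, Pearson
correlations computed per group across that group's columns
(pairwise-complete; groups need ≥ 3 samples per edge). The permutation
null redraws group labels (sizes preserved, exhaustive when feasible,
same tie tolerance as above); p = max(count ≥ observed, 1)/n_perm, so the
minimum reportable p is 1/n_perm. Significance is declared at P ≤ 0.05.

## Bolstered triplet classifier search

The small manifestation contrast (9 vs 4) makes cross-validated error
estimates too variable, so classifiers are ranked by the bolstered
resubstitution error: each training point is replaced by a spherical
Gaussian kernel with per-class width σ_c = d̄_c/α_D, where d̄_c is the
mean nearest-neighbor distance among class-c points and α_D = √(χ²_D
median) is the radius enclosing half the mass of a standard D-dimensional
Gaussian (α₃ ≈ 1.5382). For a linear rule sign(w·x + b) the error has the
closed form ε = (1/n) Σ Φ(−yᵢ(w·xᵢ+b)/(‖w‖σ_c(i))); a Monte-Carlo path
serves as an internal cross-check. Coincident same-class points would give
σ = 0 and are floored at 1e−8 times the data range, with a warning.

Candidate genes come from SVM-RFE: a linear SVM (C = 1, standardized
features) is fit and the feature set halved by |weight| until ≤ 200 genes
remain. The triplet search then screens *every* 3-combination with a
batched least-squares discriminant (closed-form 4×4 solves, vectorized
over ~20k triplets per chunk), ranks by (bolstered error ascending, margin
descending), re-fits a top pool (default 50) with a hard-margin SVM where
separable, and re-ranks before returning the top k. The least-squares
screen is the package's own design choice: it reproduces the ranking
behaviour of a per-triplet max-margin fit at a fraction of the cost, and
every *returned* candidate carries the max-margin fit when the data are
separable (least-squares otherwise). Classification ties (decision value
exactly 0) go to the positive class. A guard refuses searches beyond 10⁷
combinations unless overridden.

### Limitation: exact signature recovery

The bolstered estimate is dominated by the minimum point-to-surface
distance. At n = 13 with ~50 candidate genes, triplets holding two of
three planted signature genes plus one noise gene frequently achieve a
larger worst-case margin than the full planted triple (the noise dimension
lets the hyperplane tilt away from the nearest point), so the *exact*
planted triple lands in the top 5 in only about a third of simulated
cohorts — a rate that does not improve with planted effect size. What the
search does deliver reliably: planted signature genes appear in every
top-ranked triplet, preselection retains all three planted genes
essentially always, and the returned classifiers separate all samples.
Top-ranked gene *sets* should therefore be read as overlapping families of
candidates around the signature, not as a uniquely identified triple.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable:

* **Cohort.** Braak/CERAD/CDR are drawn from the value sets each group
  admits under the assignment rules (CP-AD/P-AD: Braak IV–VI, CERAD A/B/C
  with 20% A; N: Braak 0–II, CERAD 0/A); ages N(80, 10) clipped to
  [55, 100] years, post-mortem intervals uniform on [6, 19] h, 65% female
  — matching the autopsy-cohort ranges of the emulated design. Defaults:
  9/4/10 subjects, 4,608 genes, dye-swap on.
* **Expression.** Subject-level biological M is Gaussian with s.d.
  `noise_sd` (default 0.5 log₂ units). Planted DEGs add a fixed log₂
  offset to the pathology group; a planted 3-gene signature adds
  `triplet_offset` (default 1.5 = 3 × noise s.d.) to CP-AD subjects.
  Group-specific co-expression is planted via one latent factor per hub
  and group: loadings √|ρ| (hub) and sign(ρ)√|ρ| (interactors) give every
  hub–interactor pair correlation exactly ρ in expectation — closed-form
  control of the planted PCC.
* **Arrays.** Per array, M gains technical noise (s.d. 0.1) and an
  intensity-dependent dye bias `dye_bias·tanh(11 − A)` in raw orientation;
  A ~ N(11, 0.7). Channel signals are 2^(A∓M/2) plus log-normal background
  2^N(6, 0.5); configurable spot fractions are overwritten as saturated
  (≥ 63,000) or background-dominated to exercise the filters.
* **Interactome/annotation.** Erdős–Rényi G(n, p) with p = mean_degree/(n−1)
  (plus planted hub spokes); annotation seeds every category with one gene
  and adds Poisson(2) memberships per gene.
* **Determinism.** All randomness flows from one seed through fixed
  SeedSequence spawn keys per stage (cohort 0, biology 1, arrays 2,
  artifacts 3, interactome 4, annotation 5), so identical specs give
  byte-identical files.

What the generator does **not** model: probe sequence effects, print-tip
or spatial artifacts, image-level quantification, intensity-dependent
variance, and reference-pool composition (the reference channel is a
constant baseline, so only M carries information). Passing tests
demonstrate correctness of the statistical machinery under these idealized
conditions, not performance on real hybridizations.

## Problem sizes used in checks

The automated checks run the permutation test on 1,000 null genes at
1,000 permutations (13 vs 10), differential-correlation sensitivity over
50 synthetic cohorts (one hub, 4 interactors, |ΔPCC| = 1.0, noise 0.5,
1,000 permutations), bolstered closed-form vs Monte-Carlo on 20
configurations at 50,000 draws, UPGMA and Fisher oracles at n ≤ 8 and
N ≤ 20, bootstrap support at 500 replicates, and triplet-search recovery
over 30 cohorts of 50 candidates — sizes chosen so the whole battery
completes in well under a minute while keeping Monte-Carlo standard errors
far below the asserted margins.
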