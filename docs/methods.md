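# Methods

## Design

`protmr` implements a two-sample summary-statistic Mendelian
randomization screen: exposures are plasma protein levels instrumented
by pQTLs from one GWAS, outcomes are binary disease endpoints from a
second, non-overlapping GWAS. The causal parameter θ is the change in
log-odds of disease per SD increase in genetically predicted protein
abundance; results are reported as OR = e^θ with 95% CI
θ ± 1.96·se(θ).

The MR assumptions are the usual three: instruments are (1) robustly
associated with the protein, (2) independent of confounders, (3) affect
the outcome only through the protein. The QC cascade targets (1) and
(3); the sensitivity analyses probe violations of (3).

## Harmonization

Exposure and outcome records are joined on (chromosome, position,
order-free allele pair), with rsID as a fallback for positionally
discordant releases. Outcome effects are re-expressed on the exposure's
effect allele: a swapped allele pair negates the outcome beta and
complements its frequency; a reverse-strand complement is attempted
before declaring a mismatch (cross-cohort strand discordance is
common). Palindromic variants (A/T, C/G) cannot be resolved from
alleles: they are kept only when both allele frequencies are present,
both fall outside 0.5 ± 0.08, and the allele labels and minor-allele
side agree; anything ambiguous is dropped. The band (0.08) and the
drop-if-ambiguous policy are the conservative two-sample MR convention;
both are configurable, and no frequency-based allele inference is ever
performed on ambiguous variants. Harmonization is involutive: feeding in
pre-flipped outcome records yields identical harmonized betas.

## Instrument selection

Five filters run in the listed order, each tallied in a per-stage log so
that input count = output count + Σ removals:

1. **Significance** — keep p ≤ 5×10⁻⁸ (inclusive boundary).
2. **MHC exclusion** — drop chr6:26–34 Mb (GRCh37) or 29–33 Mb
   (GRCh38), both ends inclusive; the region's long-range LD makes
   instruments there untrustworthy.
3. **LD clumping** — greedy: rank by p (ties: chromosome, position,
   variant ID — fully deterministic), take the top record as an index,
   discard same-chromosome records within ±500 kb with r² > 0.001
   against it, repeat. Without an LD reference (none is bundled; the
   package computes no LD from genotypes), every same-chromosome pair
   inside the window is treated as linked — strictly more conservative,
   since it can only remove more.
4. **Cross-protein pleiotropy** — variants significantly associated
   with ≥ 5 proteins (count includes the variant's own protein) are
   removed as likely pleiotropic; absent variants default to count 1.
5. **Instrument strength** — per-variant explained variance defaults to
   2p(1−p)β² (SD-standardized exposure); the alternative convention
   β²/(β² + N·se²) is available via `IVConfig.r2_convention`. The joint
   F = R²(N−1−k)/((1−R²)k); sets with F < 10 are flagged weak and
   excluded from estimation rather than raised as errors.

## Estimators

* **Wald ratio** (k = 1): θ̂ = β̂_Y/β̂_X, se = se(β̂_Y)/|β̂_X|. The
  first-order delta SE deliberately ignores exposure-side error,
  matching the IVW weighting convention (the second-order term is
  negligible for instruments that survive the significance filter).
* **IVW** (k ≥ 2): ratio-weighted mean with w_j = β̂²_Xj/se²_Yj,
  identical to WLS of β̂_Y on β̂_X through the origin with weights
  1/se²_Yj (the test suite checks both routes agree to 1e-10 against an
  independent WLS oracle). Fixed-effect se = (Σw)^(−1/2); the
  random-effects variant multiplies it by max(1, √(Q/(k−1))) — a
  multiplicative overdispersion model floored at 1, so the
  random-effects SE never undercuts the fixed-effect SE. The floor
  makes the random-effects test slightly conservative under exact
  homogeneity (rejection a little below nominal); the fixed-effect test
  is the exactly calibrated one.
* **Method selection**: k = 1 → Wald; k = 2–3 → fixed IVW; k ≥ 4 →
  random-effects IVW. An override is available for users who want one
  estimator throughout.
* **MR-Egger** (k ≥ 3): WLS of β̂_Y on β̂_X with a free intercept,
  weights 1/se²_Yj, after re-signing each pair so β̂_X ≥ 0 (the standard
  exposure orientation; the slope is invariant to the joint flip).
  SEs carry the same multiplicative inflation, floored at 1; inference
  uses t with k−2 df. The intercept estimates the mean direct
  (pleiotropic) effect; intercept p < 0.05 is treated as evidence of
  directional pleiotropy.
* **Weighted median** (k ≥ 3): ratio estimates ordered ascending,
  normalized inverse-variance weights, estimate interpolated where the
  cumulative-weight midpoints cross 0.5 (clamped to the extreme ratio
  when one instrument carries over half the total weight on its side).
  SE by parametric bootstrap — 10,000 draws θ*_j ~ N(θ̂_j, se(θ̂_j)),
  weights held fixed — with a mandatory seed, so the SE is bit-identical
  across reruns.
* **Sensitivity**: Cochran's Q about the fixed-effect IVW estimate
  (df = k−1, upper-tail χ²), the Egger intercept test, and
  leave-one-out re-estimation (each reduced fit uses the method
  selected for k−1).

## Multiplicity and exclusion rules

One screen run forms a single BH-FDR family over all retained pairs'
primary p-values (the family is invariant to input ordering because
rows are sorted deterministically first). A Bonferroni flag at α/m is
reported alongside; m defaults to the retained-family size but is
configurable, since a proteome-wide screen's natural m (proteins ×
outcomes, e.g. 0.05/27,498 ≈ 1.8×10⁻⁶) exceeds the number of pairs that
survive QC in any given run. Pairs whose Egger intercept p < 0.05
(strict) are excluded with reason `egger_intercept_p<0.05` and carry no
estimates downstream. Colocalization runs only for pairs passing the
significance gate (Bonferroni by default, BH-q configurable), centered
on the pair's most significant instrument.

## Colocalization

Per shared variant, Wakefield's log approximate Bayes factor
0.5·[log(1−r) + r·z²] with r = W/(V+W), V = se², W the prior effect
variance — 0.15² for a quantitative (protein) trait, 0.2² on the
log-odds for a case-control trait, the method's conventional defaults.
Regional sums use log-sum-exp throughout (regional BFs overflow doubles
routinely); H3's Σ_{i≠j} term uses the identity
exp(S1+S2) − exp(S12) in log space, which is exactly zero for a
single-variant region. Priors p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵; decision rule
PP.H4 > 0.75. Only supplied betas/SEs are used — no MAF/sample-size
variance reconstruction — and orientation is irrelevant because only z²
enters.

## Synthetic data

The generator emulates the two-sample design at summary-statistic
level: true variant effects b_j ~ N(0, 0.15²) on the SD scale, standard
errors 1/√(2p(1−p)N) from the allele-frequency spectrum
(maf ~ U(0.05, 0.5)), observed betas = truth + analytically scaled
noise, p-values from Wald z-tests. Default sample sizes are
N_exp = 35,559 (a large plasma-proteome GWAS) and N_out = 84,000, the
effective case-control size 4/(1/cases + 1/controls) of a
22,426-case/330,377-control endpoint. The default effect SD of 0.15
reflects the strong cis signals that survive genome-wide-significance
instrument selection (per-set F statistics in the tens to hundreds).

Direct (pleiotropic) outcome effects α_j are planted on the
exposure-increasing allele frame — the outcome model is
θ·b_j + sign(b_j)·α_j + noise — so that a non-zero pleiotropy mean is
*directional* in the sense the Egger intercept estimates: under the
standard β̂_X ≥ 0 orientation an unsigned α would average to zero for
symmetric b, making "directional pleiotropy with mean 0.05" an
unreachable truth. With mean 0 the signed and unsigned constructions
are distributionally identical.

Coloc regions place equally spaced variants on one chromosome with
AR(1) LD (corr = ρ^|i−j|) and generate marginal z-scores from the
standard model z ~ N(R·z_true, R) via a Cholesky factor. Scenarios
plant a shared causal variant, two distinct ones (at the 1/4 and 3/4
points), or none. Instrument panels place variants ≥ 2 Mb apart across
chromosomes 1–22 (clear of the MHC), so they are LD-free by
construction.

A single integer seed drives everything; per-operation substreams are
spawned deterministically from it, so identical seeds give bit-identical
outputs.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: realistic LD beyond AR(1) (no
haplotype panels), winner's-curse inflation of selected exposure betas,
sample overlap between the two GWAS, population stratification,
imperfect genome-build alignment, and case-control effects generated by
actual logistic sampling (the normal approximation on the log-odds
scale is used instead, adequate at these sample sizes and effect
magnitudes but not for very rare outcomes).

## Problem sizes and numerical choices

Simulation-based checks use 200–2,000 replicates of 50-instrument
panels and 50-variant coloc regions — sizes at which the Monte-Carlo
error of each checked quantity is well below its tolerance band while
the full suite runs in well under a minute. The CI multiplier is fixed
at 1.96 (not a t quantile) for Wald/IVW/median so intervals match
reported 95% CIs exactly; Egger alone uses t(k−2). Degenerate inputs
follow a raise-early policy (zero exposure beta in a ratio, k below an
estimator's minimum, unknown genome build, absent coloc overlap are
hard errors), while data-quality failures (invariant-violating rows,
irreconcilable alleles, weak instrument sets, empty instrument sets)
are dropped/flagged and tallied, never raised — a screen must survive
bad pairs.

## Known limitations

No MR-PRESSO, mode-based, multivariable, or Steiger-filtered
estimators; no proxy-instrument lookup; no LD computation from
reference panels; no VCF parsing or build liftover; single-causal-variant
colocalization only (no SuSiE-style multi-signal decomposition). The
cross-protein pleiotropy count is an input map, not derived from a full
proteome scan inside the package.
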