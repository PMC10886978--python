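# Methods

This note documents the statistical model behind `cismr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Data model and conventions

All computation runs on GWAS summary statistics: per-variant marginal
effects (β, se), allele pair, effect-allele frequency, p-value and sample
size, restricted to a cis locus, with an optional signed LD correlation
matrix.  Coordinates are 1-based with inclusive interval endpoints; alleles
are single nucleotides (indels and multi-allelic records are rejected rather
than guessed at, since cis instruments in practice are SNVs).  Missing
p-values are recomputed as 2Φ(−|β/se|); supplied p-values inconsistent with
β/se by more than 10% on the −log₁₀ scale cause the row to be dropped and
counted.  Missing allele frequency is permitted, but any operation that
needs it (palindromic adjudication, F/PVE, z-score conversion) raises rather
than imputes.

## Instrument selection

Candidates are cis variants (gene ± 1 Mb, `cis_flank` configurable) with
*p* < 5×10⁻⁸.  Greedy clumping sorts candidates by ascending p (ties broken
by position, then variant id, so output is invariant to input row order),
takes the best remaining candidate as an index variant, and removes
remaining candidates with *r*² ≥ 0.01 against it **and** within 1 Mb of it.
Both conditions must hold: LD beyond the window does not prune, matching
standard clumping semantics.  The window is anchored at the index variant.
By default instruments are intersected with the outcome dataset *before*
clumping (so the index variants selected are those actually analysable); a
`clump_before_intersect` switch provides the alternative order.

Instrument strength: per-variant F = (β/se)²; PVE assumes a standardized
trait (var(y) = 1, appropriate for rank/log-transformed molecular traits);
the cumulative F uses the *minimum* instrument sample size, which is
conservative when sources differ.  F ≤ 20 flags the analysis as
weak-instrument but does not drop it by default (`drop_weak` enables a
strict mode that removes weak variants), because the F > 20 rule of thumb
marks acceptability, not an exclusion criterion.

## Harmonisation

Outcome records are aligned to the exposure's effect allele: allele swaps
negate β and reflect eaf; complementary-allele (strand) recoding is
attempted before declaring a mismatch.  Palindromic variants (A/T, C/G)
cannot be strand-resolved from labels; they are retained only when both
datasets' frequencies fall on the same side of 0.5 and both MAFs are below
`palindromic_maf_limit` = 0.42 (a common default in two-sample MR tooling);
with missing frequency on either side they are dropped.  Every attempted
pair receives exactly one status and drop counts are logged, so
retained + dropped always equals the input count.

## Estimators

* **Wald ratio** (one instrument): first-order delta-method SE
  (se_y/|β̂ₓ|).  The second-order term is negligible for strong instruments
  (F > 20) and first-order matches common tooling.
* **IVW**, multiplicative random effects: WLS of β̂ᵧ on β̂ₓ through the
  origin, weights 1/se²ᵧ; the fixed-effect SE is multiplied by
  max(1, √(Q/(k−1))).  The floor at 1 means heterogeneity can only widen the
  interval.  P-values are normal.
* **MR-Egger** (k ≥ 3): pairs are first oriented so every β̂ₓ > 0 (both
  betas negated together), as InSIDE-based interpretation of the intercept
  requires; WLS with intercept, SEs inflated by max(1, residual SE), t
  inference with k−2 df (a normal reference is anti-conservative at the
  small k typical of cis instruments).
* **Weighted median** (k ≥ 3): ratios θⱼ = β̂ᵧⱼ/β̂ₓⱼ weighted by
  β̂ₓⱼ²/se²ᵧⱼ (the first-order inverse variance of θⱼ), interpolated at
  cumulative weight 0.5.  The SE is a parametric bootstrap (default 1000
  draws of both β̂ₓ and β̂ᵧ from normal(β̂, se)); a seed is mandatory, and
  the pipeline derives one deterministically per analysis from the run seed
  and the (protein, tissue, outcome) labels.

A dispatcher routes one instrument to the Wald ratio, two to IVW, and three
or more to IVW plus the Egger and weighted-median sensitivity analyses.  For
binary outcomes (analysed on the log-odds scale) estimates and CI bounds are
additionally exponentiated to odds ratios.

## Multiple testing and follow-up

Benjamini–Hochberg adjustment is applied within families: the primary
CSF + brain scan forms one pooled family by default (`family_mode:
per_tissue` switches to per-tissue families — the choice is genuinely open
and both are supported), while plasma and brain-expression follow-ups each
form their own family.  Only primary pairs at pFDR < 0.05 enter follow-up.
eQTL datasets distributed as z-scores are converted assuming var(y) = 1:
β = z/√(2·eaf(1−eaf)(n+z²)), se = 1/√(2·eaf(1−eaf)(n+z²)), which recovers
β/se = z exactly.

## Colocalization

Per-variant log Wakefield ABFs, log ABF = ½(log(1−r) + r·z²) with
r = W/(V+W), V = se², are combined over the locus:

    L0 = 1,  L1 = p1·ΣB1,  L2 = p2·ΣB2,
    L3 = p1·p2·(ΣB1·ΣB2 − ΣB1B2),  L4 = p12·ΣB1B2,

normalized to posteriors PPH0..PPH4.  All sums use log-sum-exp, so |z| of
several hundred stays finite; the H3 cross-term excludes the diagonal, so a
single-variant locus yields PPH3 = 0 exactly.  Priors default to
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.  Effect priors W are 0.2² for quantitative and
0.15² (log-odds) for binary traits, the conventional beta/se-based ABF
defaults; both are configurable since the sample-size-based ABF variant is a
known alternative.  Loci with fewer than 25 shared variants trigger a
warning: the enumeration needs full locus summary statistics, not an
instrument list.  Eligibility for colocalization follows the study design:
pairs significant in both CSF and brain, plus pairs whose follow-up
association is itself significant, tested in every tissue where significant.

## Triangulation

Per protein–outcome pair, tissues with a significant association are
compared by the sign of the primary estimate: same sign in ≥ 2 tissues →
concordant; opposite signs → discordant; exactly one tissue → single-tissue;
none → null.

## Synthetic data

The generator simulates *summary statistics directly*: for a locus with LD
matrix R (AR(1), r[i][j] = ρ^|i−j|, positive definite for ρ < 1) and joint
effects b on standardized genotypes and trait, observed marginals are drawn
as β̂ ~ N(R·b, (1−pve)·R/n), se = √((1−pve)/n) — the exact sufficient
statistics a summary-level pipeline consumes, orders of magnitude cheaper
than individual-level genotypes.  Exposure and outcome are drawn in
independent samples (two-sample design).  Scenarios: H0 (nothing), H1/H2
(one trait only), H3 (distinct causal variants, index separation chosen so
r² < 0.01), H4_causal (β_out = θ·β_exp at the shared variant),
H4_shared_noncausal (shared variant, unrelated effect size), and
directional_pleiotropy (each instrument locus leaks a direct outcome effect
α_l ~ N(μ, 0.02), so the true Egger intercept is μ).

Defaults describe a realistic cis study: 200 variants per locus for
colocalization, ρ = 0.9, MAF uniform in (0.05, 0.5), causal PVE 1%,
θ = 0.3, n = 50,000 per sample (100,000 in the estimator-recovery
experiments), 10 instrument loci of 21 variants each for multi-instrument
catalogues.  Per-locus PVE is drawn uniform in ±50% of the target because
the Egger slope and intercept are only jointly identifiable when instrument
strengths vary.  10% of variants receive palindromic allele pairs to
exercise harmonisation; causal variants are kept non-palindromic so that
recovery experiments measure estimator error rather than harmonisation
attrition.  Binary outcomes are approximated on the log-odds scale with
effective n = 4/(1/n_cases + 1/n_controls).

What the generator does **not** emulate: realistic human LD panels (AR(1)
only), sample overlap between cohorts, winner's curse in the source QTL
studies, assay artefacts, or population structure.  Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
model, not robustness to those real-data complications.

## Reproducibility and numerics

Every stochastic experiment derives per-replicate seeds from one master seed
via spawned `SeedSequence` children (`cismr.simulate.rep_seeds`);
per-analysis bootstrap seeds come from a CRC of the analysis labels mixed
with the run seed.  Identical configuration + seed reproduce all output
tables byte-for-byte (fixed column order, `%.10g` float formatting,
lexicographic iteration over protein, tissue, outcome).  Posterior sums are
asserted to 10⁻¹⁰; LD matrices are symmetrized on read ((M+Mᵀ)/2, clipped,
unit diagonal); Cholesky factors of the AR(1) matrices are cached per
(m, ρ).  Experiment sizes in the test suite and acceptance script (200
oracle sets, 500 recovery replicates, 2000 calibration replicates, 100
colocalization replicates per scenario) keep the whole battery under a
minute on one CPU while holding Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Single-causal-variant colocalization only; no SuSiE-style multi-signal
  extension, conditional analysis or credible sets.
* No proxy-variant lookup for instruments missing from the outcome; absent
  variants are dropped and counted.
* No Steiger filtering, MR-PRESSO, mode-based or multivariable estimators.
* The Wald-ratio SE ignores exposure-side noise (first-order delta method);
  with weak instruments this understates uncertainty — weak sets are flagged
  via F ≤ 20.
* PVE and the z-score conversion assume standardized traits; effects on
  other scales must be standardized upstream.
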