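# Methods

This note documents the models implemented in `rcqge`, the assumptions
baked into its defaults, and the design choices made where the design was
genuinely open.

## Measurement model and titration fit

A competitive-PCR assay reports, at each titration point, the peak-area
frequency `f` of the target among all extension products of that assay;
within an assay the frequencies sum to one.  For a single-product assay
`f/(1-f)` estimates the cDNA:competitor molar ratio, so with
`x = log10(competitor concentration)` and `y = log10(f/(1-f))` the ideal
response is the line `y = t - x`, where `10**t` is the cDNA concentration.
The fitted model is a polynomial in `x` (degree 1 by default, matching a
least-squares linear fit; higher degrees are supported) shared between the
two treatment groups, with group-specific intercepts — treatment as an
additive covariate.  An independent per-group fit is available
(`shared_slope=False`) but the additive form is the default because it
stabilizes small ladders and matches how treatment enters the quoted
analysis.

The equivalence point x₀ solves the fitted curve's root (`-intercept/slope`
at degree 1; for higher degrees the real root inside the observed x range,
with an explicit extrapolation warning otherwise).  **Sign convention**:
larger x₀ = more competitor tolerated = more transcript.  The normalized
log fold change is the high-minus-low difference of x₀ minus the same
difference for the housekeeping assay; `FC = 10**log10FC` exactly, and
display rounding (1 d.p. for FC, 2 for log10FC, 4 for bias and p, 2 for SE)
is applied only in `format_qge_table`.

Cleaning follows three rules, in order: points with no signal for either
product are dropped; printing replicates are collapsed to their **median**
(not mean); frequencies of exactly 0 or 1 are excluded from fitting rather
than clamped, since the logit is undefined there and clamping would bias
the slope.  Ladders with fewer than `min_points = 3` usable points (two for
a line, one residual degree of freedom) are reported as unfit, never
crashed on.  Points where exactly one product is undetected appear as
boundary frequencies and are therefore excluded and counted in the QC
report.

## Bootstrap inference

Each bootstrap replicate resamples the cleaned observations with
replacement within each treatment group and recomputes the full normalized
log10FC, housekeeping refit included.  Reported per gene: bias
(mean of replicates minus the point estimate — *reported, not
subtracted*), SE (SD of replicates), the percentile CI, and a two-sided
tail-doubling p-value `2·min(#[r ≤ 0]+1, #[r ≥ 0]+1)/(B+1)`, floored at
1/B.  A normal-approximation p (`2·Φ(−|est/SE|)`) is available by flag.
Replicates with a non-negative slope or singular design are discarded;
more than 20% of them aborts inference for that gene with a diagnostic.

**Resampling unit.**  Two units are implemented:

- `"point"` (default): the pairs bootstrap of the regression — individual
  titration points are resampled within each group × product cell.  Under
  the generator's error model (independent logit-scale noise per point)
  this is well calibrated: measured type-I error 0.052 at α = 0.05 and
  95% CI coverage 0.95 in the simulation suites this package ships.
- `"animal"`: whole ladders are resampled, with the *same* resampled
  animals entering the gene and housekeeping refits.  This respects
  animal-level biological variance and is the right choice when such
  variance exists, but with very few animals per group it inherits the
  classic small-n bootstrap deflation — at 10 animals/group its measured
  type-I error is ≈ 0.10 at nominal 0.05.  It is therefore the non-default
  option, to be preferred on real designs with adequate group sizes or
  genuine between-animal heterogeneity.

No multiple-testing correction is applied across genes (per-gene P < 0.05,
as in the application the defaults mirror); a Benjamini-Hochberg pass can
be layered on the result table by the caller.

## Allele-specific expression

In a heterozygote a two-allele assay yields frequencies f₁, f₂ and a
competitor frequency summing to one.  The allele-1 ratio `r = f1/(f1+f2)`
cancels the competitor amount, is assumed constant across the titration
range, and is averaged unweighted over usable points (points with
f₁+f₂ = 0 carry no information).  Summing f₁+f₂ reconstructs a
total-expression ladder that feeds the titration model unchanged; in the
noise-free limit this reproduces a one-product assay of the same gene
exactly.  A second product that is never detected (e.g. an absent splice
isoform) is flagged rather than analysed.

The differential-ASE model's default response is the per-sample
`logit10(r)` with treatment as fixed effect: the grand-mean test is the
allele effect (allelic imbalance), the treatment term tests whether the
imbalance differs between groups.  The superficially natural alternative —
one observation per sample × allele with a treatment × allele
interaction — is also implemented (`response="per_allele"`), but the two
log-shares of one sample are complementary transforms of a single ratio,
so their residuals are perfectly anticorrelated within sample and the
interaction F-test is substantially anticonservative (≈ 0.17 at nominal
0.05, analytically).  The ratio response is the calibrated default; in
that mode the treatment and interaction columns coincide, because
treatment can act on a ratio only through the allele contrast.

## Association model

Androstenone (µg/g fat; treated as identical to ppm) is analysed as
`ln(androstenone) ~ sire + genotype + hys + bulbo`, ordinary least
squares, separately per breed: sire and the combined herd/year/season
factor `hys` are categorical fixed effects, and bulbo-urethral gland
length enters as a continuous covariate (it is a length measurement
proxying sexual maturity; a model treating it as a categorical bin is a
trivial variation the caller can apply by recoding the column).
Single-level factors and constant covariates are dropped automatically;
a genotype aliased with sire/hys structure raises an estimability error
naming the aliased columns.  The genotype effect is the nested-model
F test.  LS means use equal weights across the levels of the other
factors with the covariate at its mean; back-transformation is plain
`exp` — deliberately without a variance correction, so the estimates are
medians of the skewed original-scale distribution — and their SEs use the
delta method (`se·exp(m)`), an assumption since the reporting convention
being mirrored does not state one.  Hardy-Weinberg departure is the 1-df
chi-square against p², 2pq, q² expectations from observed allele
frequencies; monomorphic SNPs return NA.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not PCR kinetics: frequencies arise from the ideal titration line plus
i.i.d. Gaussian noise *on the logit scale* (keeping the fitted model
correctly specified), with optional dropout (missing-at-random no-signal
points) and an optional per-animal loading offset shared across assays,
which housekeeping normalization removes exactly.  Defaults mirror the
emulated study design:

| parameter | default | rationale |
|---|---|---|
| ladder | 11 points, 7-fold, from 4.04e-11 M | the fine titration scan |
| reaction volume | 5 µL | typical PCR volume; assumption, used only for molecule counts |
| replicates/point | 2 | "printed with 2 replicates"; whether parallel PCRs make it 4 is ambiguous, so the count is a parameter |
| animals/group | 48 | four extreme-androstenone groups of 48 |
| noise SD (logit10) | 0.15 | not stated anywhere; chosen so single-ladder EC50s scatter by ≈ 0.03–0.05 decades, a plausible precision for peak-area ratios; a package choice, not a measured value |
| true log10FC presets | published per-breed point estimates | realistic effect sizes for simulation |
| baseline concentrations | spread over −17…−13 log10 M | synthetic; keeps every EC50 inside the ladder |
| phenotype location/scale | ln(1.17), 0.79 | moment-matched to the Landrace mean 1.17, SD 1.10 µg/g |
| sire/hys effect SDs | 0.15 (ln scale) | modest batch/family structure; synthetic choice |
| extreme fraction/tail | 6% | the Landrace selection fraction (9% in Duroc) |
| assoc SNP allele freq, effect | 0.95, −0.30/copy | rare second allele; per-copy effect the size of the published heterozygote contrast |

What the generator does **not** emulate: PCR efficiency differences
between target and competitor, saturation at the ladder extremes,
spectral peak overlap, genotyping error, non-normal residuals, or
animal-level biological expression variance (beyond the loading offset).
Passing simulation suites therefore demonstrate the *statistical
machinery* is correct and calibrated under its stated model — not that
the biology of any real tissue is reproduced; the published biological
fold changes require the original samples, and only internal-consistency
checks against the printed tables are possible at desk scale.

## Numerical choices and problem sizes

All randomness flows from one integer seed; per-table and per-assay
substreams are derived deterministically, so identical configurations
reproduce byte-identical outputs.  Bootstrap replicates default to
B = 4000 for analyses; the shipped simulation suites use B = 500 with
200 null replications (type-I), 100 replications at a 2.6-fold effect
(coverage), and 200 association replications at n = 1000 animals — sizes
chosen to keep the whole suite in tens of seconds while leaving binomial
Monte-Carlo error well inside the bands being checked.  Degenerate cases
are resolved explicitly rather than left to floating-point accident:
noise-free fits give zero bias/SE, exactly-null effects give p = 1, and
boundary frequencies are excluded rather than clamped.

## Known limitations

- The degree-1 bootstrap path uses closed-form sufficient statistics and
  is fast; higher polynomial degrees fall back to a per-replicate refit
  loop and are noticeably slower.
- LS means use the equal-weight ("population marginal means") convention;
  observed-margin weighting is not implemented.
- The ASE model assumes the allele ratio is constant over the titration
  range; a precision-weighted average is available but the default is the
  unweighted mean of per-point ratios.
- Genotype input via VCF supports biallelic SNPs only.
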