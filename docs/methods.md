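# Methods

## Scope and model

`droughtsel` analyses multi-environment drought trials of a segregating
potato population. The observational unit is a replicate plot, pot or
big-bag with tuber fresh weight, starch content, tuber number, BBCH
stage and shoot height; trials carry timestamped microclimate logs. The
analysis proceeds in five steps: environment characterization, spatial
yield normalization, tolerance indexing, marker-based prediction, and
subpopulation selection with statistical comparison.

### Environment characterization

Daily thermal sum is `(Tmin + min(Tmax, 30 °C))/2 − 6 °C`, applied
literally, so cold days can contribute negative values; a
`floor_at_zero` flag gives the conventional growing-degree-day floor for
users who want it. Saturation vapor pressure uses the Buck-type form
`vpsat = 0.61365·exp(17.502·T/(240.97 + T))` kPa on hourly-averaged
temperature; VPD is `vpsat·(1 − RH/100)`. Midday VPD is the median over
the half-open window [10:00, 14:00) on the logger's local clock, and
cumulative curves run from planting to haulm destruction with missing
days contributing zero (gaps > 2 days are reported). Outlier control of
raw logs is a physical-range filter (T in [−30, 50] °C, RH in
[0, 100] %) plus mean-collapse of duplicate timestamps, both logged.
The per-trial stress index is `SI = 1 − mean(SY_stress)/mean(SY_control)`
clamped to [0, 1]; no formal definition exists for this quantity in the
trial literature we follow, so the yield-ratio form is a documented
choice. Trials with SI below 0.1 (configurable) are excluded from
tolerance scoring — a trial that barely reduced yield carries no
tolerance signal.

### Spatial normalization

Within each trial × treatment stratum, starch yield is corrected for
block, row and ridge by an additive least-squares model with categorical
factors; factors with a single level (pot trials have no rows or ridges)
are dropped rather than erroring. The stratum is trial × treatment
because blocks encode the irrigation regime in split-plot designs;
fitting across treatments would absorb the treatment effect the indices
need. The correction is

    SY_norm = (SY − fitted) − median(SY − fitted) + median(SY)

i.e. the fitted spatial component is removed and the stratum median is
restored **exactly**. The extra `− median(residuals)` term (beyond
adding back the raw median) is deliberate: the median of least-squares
residuals is not exactly zero, and without this term the correction
would neither preserve the stratum median nor be idempotent. With it,
normalizing already-normalized data is a no-op and the magnitude
guarantee holds to machine precision, which is what the procedure's
stated purpose — preserving the absolute magnitude of values — asks
for. On the log scale the model is fitted to `log10(SY + 1 g)` and
back-transformed, with the same median restoration applied after
back-transformation (the median commutes with monotone transforms only
for odd record counts). Singular designs fall back to pass-through with
a warning. One-way ANOVA per factor on `SY_norm` verifies that no
design factor remains significant.

### Tolerance indices

Replicate-level relative starch yield divides each stress replicate's
`SY_norm` by the genotype's mean control `SY_norm` in the same trial;
the analysis needs a per-replicate relative yield and a single replicate
has no natural control partner, so the genotype's control mean is the
divisor. Genotype relSY is the mean over replicates. DRYM subtracts the
trial-wide median over genotypes; DRYMp subtracts the median of the
three parent cultivars' genotype-level relSY (three values — the
reference names cultivars, not plots). The two indices differ per trial
by a constant, but DRYMp's parent anchor stays put when the population's
composition shifts during selection. Parents must be present in every
trial used for DRYMp; a missing parent is an error naming it.

### Marker prediction

Metabolite intensities are normalized per sample to the mean intensity
of all annotated analytes present in that sample and log10-transformed
(invariant to per-sample scaling); transcript Ct values become 2^−ΔCt
against the per-sample mean Ct of the reference genes (invariant to
per-sample shifts). Transcript values enter the model as 2^−ΔCt without
further log transform, matching how such data are deposited.

Missing cells (defaults mirror the study: 5.5 % metabolite, 2.2 %
transcript) are imputed by NIPALS PCA: components are extracted with
missing cells skipped in every inner product, the missing entries are
reconstructed from the rank-*k* model, and the extraction is repeated on
the completed matrix until the imputed values stabilize. This outer
refinement is needed because single-pass masked NIPALS centers columns
on observed-cell means only, which breaks exact recovery of low-rank
structure; the refinement converges linearly and is stopped when imputed
cells change by less than `tol × 10⁻³` relative (defaults: 5 components,
tol 10⁻⁶, 1000 inner iterations — none of these are externally
prescribed; 5 components comfortably exceeds the simulated latent rank).
Features missing in ≥ 50 % of samples are refused.

The predictive model is an L1-penalized (LASSO) linear regression of
genotype DRYM — broadcast to each of the genotype's samples, control and
stress pooled — on marker levels. Features are centered and scaled
inside each fit, the intercept is unpenalized, and coefficients are
returned on the original scale. The λ grid has 100 log-spaced values
from `λmax = max|X'y|/n` (standardized X, centered y) down to
`10⁻⁴·λmax`. Cross-validation uses 10 folds **grouped by genotype** so
no genotype contributes to both the training and validation side of a
fold (the response is a genotype-level quantity; ungrouped folds would
leak it). The chosen penalty is the largest λ whose mean CV error is
within one standard error (over folds) of the minimum — the sparser
"λmin + 1SE" model. Per-λ solutions come from coordinate descent at a
dual-gap tolerance of 10⁻¹⁰, with coefficients below 10⁻¹² clipped to
exactly zero (at the top of the grid w = 0 is optimal only on the
stationarity boundary and solvers leave O(10⁻¹⁶) residue, which would
otherwise masquerade as a selected predictor). Constant responses or
all-constant features yield an intercept-only model with a warning.
Predictions are averaged per genotype over all its samples; the
metabolite and transcript rankings (rank 1 = most tolerant, average
ranks for ties) are averaged into a combined score.

### Selection

Eligibility: genotypes with mean control tuber number < 5 in any scoring
trial (strict inequality), without control records, or flagged for
delayed emergence are excluded; the emergence flag is an input, as no
quantitative criterion is defined for it. Yield outliers are replicates
with `SY_norm` strictly outside mean ± 3 SD of their trial × treatment
stratum, flagged in a single pass over all genotypes' replicates
(per-genotype SDs are undefined at 1–5 replicates).

Phenotypic selection ranks eligible genotypes by DRYM within each
scoring trial; genotypes ranking ≤ 40 in at least two trials are
shortlisted. Genotypes whose qualification rests on outlier records are
removed by recomputing all per-trial DRYM values with flagged records
dropped and re-applying the shortlist rule; the surviving shortlist is
ordered by mean outlier-cleaned rank over qualifying trials and the top
k (default 20) form PPt. The source procedure reports both "20 lines
were selected" and a final PPt of 24 after merging with marker-selected
overlaps; k is therefore a parameter, and the Venn bookkeeping reports
the merged totals. Marker selection takes the best 24 (MPt) and worst
22 (MPs) of the combined predicted ranking, with ties broken by mean
predicted DRYM and then genotype id; MPt and MPs are drawn from opposite
ends of one deterministic ordering and cannot overlap.

### Evaluation

Overlap enrichment between two selections of sizes K and n from an
eligible pool N with observed overlap x reports the expectation `nK/N`,
the fold `x/expected`, and the upper-tail hypergeometric probability
P(X ≥ x), computed in log space; the upper tail is the enrichment
direction. ANCOVA fits `DRYMp ~ population + cum_VPD` by least squares
with sequential (Type I) sums of squares, population first — the
convention of the ANOVA routine this analysis style uses; model 2 drops
the parent records, and a single-population input degenerates to a
covariate-only fit. Superiority counts use either the 90th percentile
of parent replicate DRYMp or the upper bound of a normal-approximation
95 % CI of the parent mean (mean + 1.96·SE), counting lines strictly
above. Cross-system correlations are Pearson on pairwise-complete
genotype means with per-cell n. On synthetic data, truth metrics report
each subpopulation's precision against the top (bottom, for MPs)
tolerance quartile, its fold over the random expectation, and Spearman
correlations of selection scores with the latent tolerance.

## The synthetic study

The generator emulates the study design the pipeline was built for: two
crosses between a tolerant (At, latent tolerance +0.05 on the DRYM
scale) and two sensitive parents (Es −0.05, Rs −0.04), 100 offspring per
cross with tolerance Normal(mid-parent, 0.05) and yield potential
(240 ± 60 g starch/plant, field scale) drawn jointly at correlation
−0.3 (tolerant lines tend to yield less, as observed in such trials).
Default trials mirror the scoring phase: one big-bag (3 replicates,
stress severity 0.49), one pot and one field trial (~0.55), and one
wet-year field trial (0.05) that the SI filter must exclude; thermal-sum
and cumulative-VPD targets follow the published trial table, and the
weather generator reproduces them within 5 % / 10 % by construction
(sinusoidal diurnal cycle peaking at 14:00, humidity solved from the
midday VPD target, small Gaussian jitter).

Control starch yield per replicate is yield potential × test-system
scale (pot 0.25, big-bag 0.85, field 1.0 — matching the relative median
yields of the three systems) × multiplicative lognormal block/row/ridge
effects × lognormal noise with CV 0.12; yields are positive with
roughly scale-free dispersion, hence multiplicative errors. The stress
expectation multiplies the control expectation by
`clamp(1 − severity + tolerance, 0, 1)` — the simplest response making
DRYM identifiable, with the generator's closed form recoverable exactly
at zero noise. Marker features follow
`α_j + β_j·τ + γ_j·1[stress] + trial effect + Normal(0, 0.5)` on the
log10 (metabolite) or ΔCt (transcript) scale, with exactly 29 of 100
metabolite and 23 of 43 transcript features carrying β ≠ 0 (magnitudes
uniform in [0.3, 1.5] × 2.0, random signs, bounded away from zero);
matrices are emitted at measurement level (raw intensities with a
per-sample loading; Ct values for 43 targets + 4 reference genes) so
the normalization steps do real work. One pooled sample per genotype ×
trial × treatment over two marker trials gives ~810 training samples.
Missingness is completely at random at the configured rates; no
mechanism is documented for the real data, and MCAR is the assumption
under which NIPALS imputation is unbiased.

No variance components are published for yield or marker noise. The
noise defaults (tolerance SD 0.05, yield CV 0.12, marker noise SD 0.5)
were fixed once so that selection is informative but imperfect — DRYM
and marker predictions track the latent tolerance well below rank 1.0 —
and all downstream checks run against that regime. Consequences of the
simplifications: MCAR missingness cannot probe imputation bias under
informative missingness; the linear-in-τ marker model cannot probe
model misspecification; mid-parent genetics ignores segregation
distortion and epistasis. Passing tests therefore demonstrate that the
pipeline's machinery is correct and well-calibrated, not that the
marker model would attain the same accuracy on real populations — the
study this emulates found marker selection effective for tolerance but
not against sensitivity, a failure mode outside this generator's reach.

## Determinism and degenerate inputs

All randomness flows from a single integer seed through spawned
generator streams; rerunning any stage with the same seed reproduces
every artifact bit-identically (the manifest records SHA-256 digests).
Degenerate inputs have defined behavior throughout: empty climate
series, saturated air (VPD 0), constant yields (ANOVA F = 0, p = 1),
missing treatment arms (skipped and logged), absent parents (error
naming the cultivar), constant LASSO responses (intercept-only model),
fully tied marker scores (id-ordered deterministic selection), and
single-population ANCOVA (covariate-only fit).

## Limitations

- Spatial correction is additive categorical only; no spatially
  correlated field-trend models.
- No SSI/STI indices, no BLUP/mixed-model multi-environment analysis,
  no post-hoc letter displays.
- The stress-index definition cannot be validated against published
  trial tables without the original raw data; the file readers accept
  the published schemas so real data can be dropped in.
- PAR, soil-water balance and tuber size-class distributions are out of
  scope; the generator produces only a total tuber count.
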