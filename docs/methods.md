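# Methods

This note records the models, conventions and numerical choices behind
`noctura`, and what the synthetic-data generator does and does not emulate.

## Behavioural phenotyping

### Activity series and light annotation

All phenotypes operate on contiguous, fixed-width count series
(`ActivitySeries`). Monitor rows with a status code other than 1 are dropped
and logged; interior gaps (dropped or missing bins) are zero-filled with a
warning so the series stays contiguous. Zero-filled gaps are
indistinguishable from immobility, so sleep scored across a logged gap
should be treated with suspicion — the warnings exist to make that visible.

Day and night are clock-defined. Under LD, a bin is `L` when its Zeitgeber
time (hours after lights-on) is within the photoperiod, else `D`. After
`dd_start` the same schedule is projected forward at fixed clock times and
bins become `subjL`/`subjD`. Subjective night is deliberately *not* adjusted
for each fly's free-running period: the masking analysis compares fixed
clock-time windows, and re-anchoring them per fly would conflate period
differences with masking. Bins straddling a light transition are refused
(re-bin first).

### ND ratio

Per complete 24 h day, ND = (counts in night bins)/(counts in day bins);
the reported value is the mean of daily ratios (a pooled-counts variant is
available via `pool_days=True`; exact scale-invariance and L/D-swap
reciprocity hold per day and for the pooled form). A day with zero day
activity but nonzero night activity is infinite, flagged, and excluded from
the mean. Units: dimensionless; > 1 nocturnal, < 1 diurnal.

### Rhythmicity: Fisher's exact g

The periodogram is taken at the Fourier frequencies of the mean-centred
series (the even-n Nyquist ordinate is excluded, as its null distribution
differs). The exact null p-value of the maximum ordinate share is the
classical alternating series; terms are evaluated in log space. Flies are
called rhythmic at p < 0.05 on the 30-min-binned LD series; the threshold
and binning are configurable. No padding or detrending is applied: the
series are short (5 days) and mean-centring suffices for count data
without strong trends.

### Period: chi-square periodogram

Sokolove–Bushell Q against a χ²(K−1) threshold, candidate periods 18–30 h
in 0.1 h steps. Folding assigns bins to K = ⌊P/Δ⌋ phase columns by exact
phase, so candidate periods are not restricted to multiples of the bin
width. Because the scan covers ~120 highly correlated candidates, the
significance call is Bonferroni-corrected across the grid (family-wise
α = 0.05); uncorrected per-period thresholds flagged ~98% of white-noise
series as rhythmic in simulation. The corrected decision is conservative
(realized false-alarm rate well below 5%) and leaves recovery intact:
τ within ±0.25 h in ≥ 95% of noisy 5-day simulations. The reported
estimate is the candidate with the largest excess of Q over its threshold.
A scipy Lomb–Scargle scan over the same grid serves as a cross-check.

### Acrophase and circular statistics

Hours map to angles at 15°/h (ZT0 → 0°, ZT12 → 180°). The mean direction
and resultant length R are the count-weighted circular statistics of
bin-midpoint phase angles pooled over cycles, so a point mass gives R = 1
and phase-uniform activity R ≈ 0. The 95% CI of the mean direction uses
Fisher's large-sample formula applied to the per-cycle mean angles
(n = usable cycles); it is undefined when the pooled R < 0.1 (direction
meaningless) or when dispersion defeats the arcsine approximation.
Morning/evening peaks are window acrophases over ZT21–ZT3 and ZT9–ZT15 —
windows flanking lights-on and lights-off in a crepuscular species; both
are configurable.

Phase shifts are circular differences of post-pulse acrophases folded at
24 h, converted at 15°/h, with delays negative; a post-pulse series that
fails the chi-square rhythmicity test yields no value.

### Sleep

Sleep is the universal Drosophila convention: runs of ≥ 5 consecutive
zero-count minutes, scored only on 1-min bins (scoring re-binned data
inflates sleep and is refused). Output is minutes asleep per clock hour,
averaged across observed days.

### Masking

Per fly, ND is computed in LD and in DD (subjective flags), skipping the
first DD day as a transient. The cohort analysis is a two-way OLS ANOVA
(genotype × regime) on per-fly ND values with Tukey-adjusted post-hoc
pairwise contrasts. `delta = nd_dd − nd_ld`: a negative delta for a
nocturnal genotype means its nocturnality is partly a direct effect of
light (masking) rather than clock-driven.

## Quantitative genetics

### Model

Infinitesimal additive model: breeding values g ~ N(0, h²Vp), environmental
deviations e ~ N(0, (1−h²)Vp), offspring g = mid-parent g + a Mendelian-
sampling deviation of variance h²Vp/2 (the genic variance is held at its
base value; inbreeding and drift of the genic variance are not modelled).
The trait is the ND ratio itself, floored at 0.01 — selection acted on the
ratio scale, so the simulator does too. The environmental deviation is
taken to subsume assay noise: the configured h² is the heritability of the
measured phenotype. An optional Gaussian measurement layer
(`measurement_sd`) and the full Poisson-actogram measurement path are
available when measurement error should be explicit.

### Selection experiment and realized h²

Each cycle phenotypes `n_pop` males (default 300), selects the
`n_selected` most extreme (default 25) and mates each to an unselected
female; records carry S, R and their running sums. The selection
differential weights the sexes equally and charges the mates' *actual*
phenotypic deviation; realized h² is the slope of cum R on cum S through
the origin (zero cumulative selection must imply zero expected response).

**Mates and consistency.** By default the mates are modelled as unselected
females genetically exchangeable with the population. Under that design the
regression estimator is consistent: the male term contributes `½d` to S and
`½h²d` to R, and the mate's realized deviation contributes equally to S and
to expected R. The literal sib-mating design (`full_sib_mates=True`) makes
the mate a genetic full sister of the selected male; the offspring-on-
midparent regression then has slope `3h²/(2+h²)` (cov(o, p̄) = ¾Va,
var(p̄) = ½Vp + ¼Va), i.e. realized h² *overstates* h² whenever
0 < h² < 1 — at h² = 0.3 it converges to ≈ 0.39. Both behaviours are
covered by tests; recovery experiments use the consistent default.

**Variance erosion.** Truncation selection of 25/300 males
(k = i(i−x) ≈ 0.84 on the sire side) builds negative gametic-phase
disequilibrium, so additive variance — and with it the per-cycle response —
declines toward an equilibrium over the first few cycles. A ten-cycle
experiment at base h² = 0.371 therefore yields mean realized estimates of
≈ 34%, not 37.1%; at h² = 0.084 the erosion is negligible. This is genuine
infinitesimal-model behaviour, not estimator error.

**Drift variance.** Estimated by parametric bootstrap: the same design is
re-simulated at the estimated h² (500 replicates by default) and the
variance of the re-estimated slope is reported. This is assumption-light
and directly testable, at the price of simulation cost.

### Parent–offspring regression

OLS slope of offspring on the parental predictor; h² = b for mid-parent
pairs and 2b for single parents; the p-value is the two-sided zero-slope
test. Families in the generator have unrelated parents, so no assortative-
mating correction is applied.

### Base-population conditions

Defaults: ND mean 1.0 (crepuscular), Vp = 0.0225 (σ_P = 0.15), h² = 0.14.
The mean and variance were fixed so that a ten-cycle diurnal selection at
h² ≈ 0.37 traverses roughly 1.0 → 0.5 on the ratio scale — the range the
emulated experiment spans — while keeping the positivity floor inert
(< 0.1% of phenotypes clipped). Activity defaults: 1500 expected beam
breaks/day, two von-Mises bumps at ZT0 and ZT12 with concentration 2,
τ ~ N(24.0, 0.2²) h, masking coefficient 1.

### Masking in the generator

The expressed night/day ratio in LD equals the fly's `true_nd`; in DD the
log-excess over the template's intrinsic ratio is divided by
`1 + masking_m`. Thus `masking_m = 0` leaves the DD ratio equal to the LD
ratio in expectation, and large `masking_m` collapses DD behaviour toward
the crepuscular template — reproducing the qualitative signature of
nocturnality driven by light masking (nocturnal genotypes turning more
diurnal in constant darkness).

## Complementation test

Kruskal–Wallis across the three mutant-background crosses (df = 2) and
pairwise two-sample KS tests, exact for cells of ≤ 25 flies, asymptotic
otherwise; raw and Benjamini–Hochberg-adjusted KS p-values are both
reported, but the verdict uses raw p at α = 0.05, matching a convention of
reporting unadjusted pairwise outcomes. The verdict rule maps only the
full confirmation pattern (ordering D\* < C\* < N\*, significant
KS(N\* vs D\*), significant KW) to *complemented*; significance without
the ordering is *failed_to_complement*; all intermediate patterns are
*inconclusive* rather than forced into a binary call.

## What the simulator does not emulate

* Explicit loci, linkage, dominance or inbreeding depression — responses
  are symmetric by construction, so asymmetric selection responses must be
  imposed via direction-specific h² rather than emerging from allele
  frequencies (an explicit-locus variant would be the natural extension).
* Temperature, social effects, moonlight or any plasticity beyond the
  single masking coefficient.
* Mortality, fecundity or development time; every phenotyped fly survives.
* Within-day sleep architecture beyond what the two-bump Poisson template
  induces.

Passing recovery tests therefore show that the estimators are correct for
an idealised additive world of Poisson-observed actograms — not that real
recordings satisfy those assumptions.

## Problem sizes used in checks

Recovery experiments run 200 replicate selection experiments per direction
(10 cycles × 300 males, analytic phenotype path) and 500 replicate family
sets (105 or 85 families); property suites use 2000 white-noise replicates
for p-value uniformity, 200 for τ recovery and 1000 for the QCT null
verdict rate. These sizes put Monte-Carlo error comfortably inside the
stated tolerances while keeping the whole suite runnable on a laptop in
well under a minute per module.
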