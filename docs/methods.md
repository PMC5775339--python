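# Methods

This note documents the statistical procedures implemented in `dietshift`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical choices
that matter when results are compared across software.

## Sampling model and data semantics

The unit of observation is a regurgitate: one bird, one occasion, a set of
prey items each with a taxon label and (in the mass-based era) a wet mass in
grams. Two eras coexist in a typical long-term series: an early era carrying
only presence/absence per taxon (`mass_based = False`) and a later weighed
era. Occurrence-based statistics (FO, presence matrices, ordination input)
treat both identically; mass-based statistics (WW, MM, AP, permutation
comparisons) silently restrict their scope to weighed samples and raise if
none exist rather than imputing.

Taxa resolve to origin classes (arctic, atlantic, mesopelagic, intermediate)
through a catalog. The shipped default classifies polar cod and *Themisto
libellula* as Arctic; capelin, Atlantic herring, Atlantic cod and haddock as
Atlantic; glacier lanternfish, white barracudina and *Pasiphaea tarda* as
mesopelagic; every other identified taxon as intermediate. Unresolvable taxa
are "unidentified" and are *excluded from all origin aggregates* — they are
assumed randomly distributed among the named classes, so including them would
only add noise with unknown direction. The catalog is a CSV; users with a
different biogeographic reading override it without touching code.

Samples with missing colony/stage/sex metadata are retained under "unknown":
dropping them would bias every denominator. An empty regurgitate is still a
sample and counts in FO/WW/AP denominators.

## Diet indices

For category *c* in a scope of *n* samples, *N* containing *c*:

| index | definition | denominator | notes |
|---|---|---|---|
| FO | 100·N/n | all samples | no SEM (a single proportion, not a mean of a per-sample quantity) |
| WW | mean of per-sample mass of *c* | mass-based samples, zeros included | SEM = sd/√n |
| MM | mean of per-sample mass of *c* where present | occupied samples | undefined (error), not zero, when *c* is absent |
| AP | mean of 100·(mass of *c*)/(sample total) | mass-based samples with positive total | bounded, outlier-robust, equal weight per sample |

WW = MM·N/n holds exactly at full precision and is asserted as an invariant;
reported tables round to one decimal. SEMs use the sample standard deviation
(ddof = 1) and are reported missing for n < 2.

## Change-point regime models

Annual ecological indices rarely exceed ~20 points, which drives every choice
here.

- **Candidate forms.** constant (1 parameter), linear (2),
  constant_changepoint (2: a mean per regime), linear_changepoint (3: shared
  slope, intercept shift), linear_interaction_changepoint (4: separate
  intercept and slope per regime). One break at most: with ≤ ~20 points a
  second break is rarely identifiable, and the selection table lets users
  judge residual structure themselves.
- **Break scan.** Exhaustive over years leaving ≥ `min_segment = 3` points
  per regime (one residual degree of freedom per regime for linear pieces).
  Membership is year ≤ break vs year > break; the break is reported as the
  last year of the previous regime, and regime labels render as "start–y" /
  "(y+1)–end". For explanatory (environmental, demographic) series the scan
  window can be floored (default 1997 in the pipeline) so that breaks are
  only sought where the diet series has continuous support.
- **Selection.** AICc with k = parameters + 1 (residual variance):
  n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1). AICc rather than AIC because n/k is
  small throughout. Exact fits (RSS below 1e−12) score −∞; near-ties
  (ΔAICc < 0.01, including tied exact fits) resolve to the fewest-parameter
  form, which is what makes noiseless inputs recover exactly their generating
  form. Both per-term t/p values and the whole-model F against the grand mean
  are reported, since conventions differ between software.
- **Degeneracy.** On monotone trend data the break placement within the step
  forms is arbitrary; the guard is the selection step, which prefers the
  linear form there (penalty beats negligible RSS gain). This is a documented
  behavior, not an error.

## Permutation comparison

The two vectors for a year are *every* sample's summed Arctic mass and summed
Atlantic mass, zeros included, treated as two independent samples of length
n(year) each and tested by column permutation across the pooled 2n values
with statistic mean(a) − mean(b). Zeros stay in because a sample with no
Atlantic prey is evidence about Atlantic availability, not a missing value;
a config switch (`occupied_only`) restricts to occupied samples for
sensitivity analysis. Exact enumeration (all C(2n, n) regroupings) applies
when that count is ≤ 10,000; otherwise Monte Carlo with n_perm = 9,999
default and the +1 correction, so p is valid and never below 1/(n_perm+1).
Extremity comparisons use |T*| ≥ |T| − 1e−12 to keep ties deterministic in
floating point. Per-year tests are not multiplicity-corrected by default
(each year is reported on its own, as in per-year significance stars); a
Holm pass over the per-year p values is a one-liner for users who want it.
All per-year seeds spawn from one root seed, so results are bit-reproducible.

## Environmental series

- **Sea-ice index.** Daily block concentrations → block mean per day → daily
  mean per month → annual mean of the 12 monthly means. Month-first averaging
  is deliberate (short months weigh as much as long ones) and tested against
  the pooled-day alternative, which gives a different number. Years missing a
  month are dropped with a warning rather than silently rescaled.
- **Volume-weighted temperature.** Σ T(z)A(z)Δz / Σ A(z)Δz with Δz from the
  depth grid (np.gradient); areas must be non-negative and non-increasing
  with depth, since a fjord basin narrows downward — violating that almost
  always means swapped columns.
- **Trends and detrending.** OLS on years elapsed since the series' first
  observed year (interpretable intercepts; the centering convention is
  otherwise arbitrary). Detrending returns residuals (mean 0, idempotent).
  Constant series detrend to zero and report an undefined (NaN) trend F.
- **Correlation.** Pearson r on pairwise-complete overlapping years (gap
  years simply drop out), requiring ≥ 4 pairs. The 95% CI is Fisher-z:
  tanh(atanh r ± 1.96/√(n−3)). The significance flag is "CI excludes 0" —
  the decision rule used when correlations are displayed as CI bars — and the
  two-sided t-test p is also emitted. Detrended mode detrends *both* series
  first; comparing raw against detrended r is the package's device for
  separating genuine coupling from a shared long-term trend.

## Community structure

Input is the year × taxon FO matrix (percent), unstandardized — FO is
already bounded and comparable across taxa. Bray-Curtis
d = Σ|x−y|/Σ(x+y) is a bounded semimetric; the triangle inequality is
neither guaranteed nor asserted, which is precisely why the ordination is
non-metric. All-zero composition rows are an error naming the offending year.

Ward clustering follows the D2 convention: raw dissimilarities in, squaring
inside the Lance–Williams update (scipy's `linkage(..., 'ward')` on a
precomputed condensed matrix). An independent O(n³) Lance–Williams
implementation in the test suite cross-checks merge orders and heights.
Dendrograms export to Newick with branch lengths equal to merge-height
differences.

nMDS minimizes Kruskal stress-1 over monotone-regressed dissimilarities
(SMACOF iterations, k = 2 default, max 200 iterations, tolerance 1e−9).
Initialization is the classical PCoA configuration plus 20 random restarts.
Pure best-of-random-restarts selection is deliberately *not* used: on
strongly clustered matrices (exactly the two-regime structure this package
targets) unconstrained non-metric stress has degenerate optima that collapse
whole clusters onto coincident points with stress → 0. A restart only wins
if its stress is lower *and* it does not embed clearly dissimilar sites
(input dissimilarity above half the median) at effectively zero distance.
Only inter-point distances are identified, so tests and users should compare
stress and distance structure, never raw coordinates; coordinates are
mean-centered and orientation is arbitrary. Species scores are
FO-weighted averages of year coordinates; never-observed taxa are omitted
with a warning.

## Fish morphometrics

Otoliths are paired greedily, closest pair first, while the gap is within
0.3 mm (measurements are read to 0.1 mm; a pair from one fish should agree to
about that precision), always within one (sample, species) batch. Length is
intercept + slope·otolith, optionally scaled by a shrinkage factor in
[1.00, 1.04] to undo freezing shrinkage in the source regressions; estimates
outside the regression's valid otolith range are flagged as extrapolations,
not rejected. Age classes come from ordered length cutoffs (0+, 1, …, >4);
lengths below the first cutoff are 0+ by convention. For 0+ fish with a
capture date, the days elapsed since a configurable spawning window
(default Feb 15 – Apr 1) are reported as an (since-end, since-start)
envelope — the plausibility check for advection of young-of-the-year fish.
The bundled YAML carries synthetic placeholder coefficients of realistic
magnitude, clearly labelled; real analyses must substitute published,
region-appropriate regressions and cutoffs.

## Synthetic-data generator

The generator draws the study design the analysis assumes: 19 sampling years
(presence-only 1982–84 and 1987; weighed 1997–98 and 2004–2016), 46 samples
per year (~874 total), and per-taxon occurrence probabilities that switch
after the regime year (default 2006): polar cod 0.80 → 0.30, capelin
0.02 → 0.35, herring 0 → 0.10 from 2013, *T. inermis* 0.20 → 0.30,
*T. libellula* 0.15 → 0.05, *Nereis* 0.10 → 0.05, unidentified fish 0.15
throughout. Meal masses are lognormal with means matching typical
per-occurrence wet weights (fish ≈ 12–17 g, crustaceans ≈ 3–8 g) and shape
σ = 0.7–0.8 for right skew. Covariates are linear trends plus Gaussian
noise — sea-ice 19.9 − 0.5·t (sd 4), temperature 0.3 + 0.1·t (sd 0.5) — and
a population series that declines, steps up after 2006, then stays roughly
flat; clutch size and breeding success are trendless.

What it does **not** emulate, hence what passing tests do not show about real
data: taxon occurrences are independent within a sample (no prey-switching or
co-occurrence structure); per-year sample counts are constant rather than
opportunistic; masses are i.i.d. within taxon (no within-year schooling
correlation); covariates carry no autocorrelation; and the diet–environment
link is indirect (both driven by the regime/trend structure) rather than
mechanistic. Recovery results on this generator validate the estimation
machinery, not ecological conclusions.

## Validation sizes

The validation suite uses: 200 simulated series for change-point recovery
(success = step form selected at the true year; observed rate ≈ 85–90%),
1000 null replicates × 2000 Monte-Carlo permutations for type-I calibration,
400 replicates for CI-coverage checks, and 40 generator seeds for end-to-end
recovery of the regime year (±1), per-regime occurrence means (±5 points,
against the truth implied by the configured probabilities: 83.0% pre,
33.5% post for Arctic prey) and correlation signs. These sizes give
Monte-Carlo standard errors comfortably below the tolerances they are tested
against while keeping the whole suite fast.

## Known limitations

- Digestion bias (soft-bodied prey underrepresented) is not corrected;
  indices describe what survives to identification.
- The AICc selection assumes i.i.d. Gaussian residuals within regimes;
  annual autocorrelation would make breaks look sharper than they are.
- Bray-Curtis on FO ignores mass information entirely; years dominated by
  one heavy taxon but many rare ones can look similar to very different
  years.
- Exact permutation enumeration is O(C(2n, n)) and auto-switches to Monte
  Carlo; p values below 1/(n_perm+1) are unattainable by construction.
- The morphometrics placeholders are synthetic; lengths and ages from the
  bundled config are for pipeline exercise only.
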