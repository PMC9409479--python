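# Methods

## Scope and data model

The package models post-diapause development of the apricot seed wasp:
overwintered larvae resume development in spring, pupate, emerge as adults
inside the seed, and after a post-emergence interval chew an exit hole and
fly.  Two rearing designs are represented: cracked seeds (individual larvae
observed through pupation and adult emergence; records carry larva, pupa
and total durations) and intact seeds (only the date of adult exit is
observable; records carry a single total).  The two cohorts are kept
strictly separate — an "emergence" total and an "exit" total are different
stages with different thermal parameters — via the `kind` field on
`DurationRecord`, and the long-format CSV uses the stage labels
`larva`, `pupa`, `larva_to_emergence`, `larva_to_exit`.

Individuals with fate `prolonged` (alive but never pupated: prolonged
diapause) or `dead` have no completed duration and are excluded from all
rate computations.

## Rate models and thermal traits

Rates are reciprocal durations.  The ten candidate models are evaluated
unclamped: negative values outside the viable range are meaningful to root
finding and only consumers that need nonnegative rates clamp them.
Brière-1 is implemented in its canonical form a·T·(T−T_min)·(T_max−T)^1/2;
the variant without the square-root tail circulates in some secondary
sources (apparently a typesetting loss, since Brière-2 prints the exponent
1/d) and is available as `BRIERE1_LITERAL` for comparison.  "Longan-6",
a spelling that appears in parts of the literature, is accepted as an alias
of Logan-6.

Traits: the linear models have closed forms (LT = −b/a, DD = 1/a; Ikemoto's
slope/intercept are directly T_min and K).  A non-positive fitted slope has
no biological threshold and yields undefined traits.  For nonlinear models
T_opt is located by a 0.1 °C grid scan over a configurable search interval
(default 0–45 °C) refined by bounded scalar minimisation to 1e−6 °C; UT and
LT are zero crossings bracketed above and below T_opt and polished by Brent
root finding.  A trait whose bracket contains no sign change is reported as
`None`, never extrapolated.

## Fitting

Linear fits use the closed-form least-squares solution (`numpy.linalg.lstsq`
on the 2-column design).  Nonlinear fits minimise the residual sum of
squares by damped least squares (`scipy.optimize.least_squares`,
trust-region-reflective variant, xtol = ftol = 1e−10) restarted from 50
Latin-hypercube points inside each model's parameter box (seed 20220722 for
the start sample, so refitting is reproducible); the lowest-RSS converged
start wins, and a fit failure carries per-start diagnostics.  The parameter
boxes double as plausibility bounds and were chosen from the magnitudes
such curves take for insect development on the 0–45 °C range.

The temperature range entering a fit (all six viable temperatures vs
truncating at 27.0 °C) is an explicit caller decision, not automatic: for
the adult-exit stage the rate at 30.2 °C falls below the linear trend, and
the published thresholds for that stage come from the truncated range.
Fitting accepts per-individual rates or (temperature, mean) pairs; with
only printed group means available, mean-level refits reproduce the
published LT exactly to 1 decimal and DD to ~0.3%, the residual reflecting
per-individual vs mean-level weighting.

## Model selection

AIC is the least-squares form n·ln(RSS/n) + 2p; a perfect fit (RSS = 0)
yields −∞ with a warning, and in a ranking all weight then goes to the
exact fits.  AICc requires n > p + 1.  Akaike weights use exp(−Δ_i/2) on
AICc differences.  The plausibility screen is opt-in: given an observed
failure temperature (development ceased at 34.3 °C in rearing), any model
whose fitted UT exceeds it by more than a configurable margin (default
1 °C) is flagged and cannot be selected, so a Lactin-2-style fit with UT
near 39 °C loses to the best plausible runner-up.  Ties in AICc break
lexicographically by model name, making the ranking order-stable.

## Degree days and phenology

The single-day rule is the modified-average method on (T_max, T_min): zero
when T_max ≤ LT, otherwise mean(min(T_max, UT), max(T_min, LT)) − LT,
clamped to [0, UT − LT].  This reproduces the classic piecewise cases
(minimum below LT → substitute LT; maximum above UT → substitute UT) and
fills the two corner cases a four-branch statement leaves out — both bounds
exceeded gives (UT + LT)/2 − LT, and a whole day above UT gives UT − LT —
by continuity.  Boundary equalities land in the cooler branch, which keeps
the rule continuous in both temperatures.  Accumulation starts at a
1 January biofix by default and demands a gap-free daily series (the error
names the first missing date).  No sine-wave or hourly integration is
provided.

Weibull fitting initialises from the Weibull-plot linearisation
ln(−ln(1−F)) = b·ln x − b·ln a on interior points and refines by damped
least squares on the CDF itself; r² of the fit is reported.  Flight-date
prediction maps each cumulative point q to the first day whose accumulated
degree days satisfy F(x) ≥ q, with no within-day interpolation — forecasts
are integer Julian dates, matching how trap data are recorded.  Points the
season never reaches are flagged, not extrapolated.  Default thresholds for
the adult-exit forecast are LT = 7.3 °C and UT = 34.3 °C, both arguments.
In a temperate spring the UT branch is rarely active, so forecasts are
insensitive to UT.

## Validation statistics

Accuracy per site-year is the mean ± SE (sample SD/√n) of the absolute
day differences |observed − predicted| at the five cumulative-flight
points.  Absolute values are used deliberately: forecast rows mix early and
late errors and signed means would not reproduce the published summaries.
The t statistics test H0: mean difference = 3 (or 5) days against the
one-sided alternative "greater", upper-tail p on n−1 df; identical
differences (zero SD) make the statistic undefined and are flagged
not-computable rather than approximated.  The correlation column is the
Pearson coefficient r of the paired dates — the source table labels it r²,
but the printed values are numerically r, which is what the report stores.
The Grubbs screen is the standard two-sided single-outlier test
(G = max|x−x̄|/s against ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n)
t-quantile on n−2 df), one outlier per pass.

## Synthetic data

The generator emulates the study conditions: seven rearing temperatures
(14.5–34.3 °C) with 60 individuals per temperature per design, linear true
rate models per stage with the published thresholds (larva 8.1 °C/66.2 DD,
pupa 8.2 °C/180.8 DD, exit total 7.3 °C/336.7 DD; any registered rate model
may be substituted), lognormal multiplicative duration noise with mean 1
(durations stay positive and right-skewed, as biological timing data are;
default CV 8%, matching the SE/mean magnitudes of the published stage
means), 3% prolonged diapause, 5% mortality, even sex ratio.  At or above
the generator's upper threshold (34.3 °C), and wherever a true rate is
non-positive, all developing individuals become prolonged — the generator
never emits an infinite duration.  Larva and pupa durations get independent
noise draws; the emergence total is their sum.

Weather is a cosine annual cycle (mean 13 °C, half-amplitude 10.5 °C,
warmest day 196, diurnal half-range 4 °C, daily Gaussian noise SD 2 °C —
a southern-Korea-like seasonality in which ~337 DD above 7.3 °C accrue by
early May) with max/min swapped if noise inverts them.  Trap counts come
from inverse-CDF sampling each cohort member's exit degree-day requirement
from the true Weibull (scale 344.97 DD, shape 13.54) and binning by the
first day the cumulative series reaches it; individuals the season never
serves are reported as an unemerged count.  All draws flow from one
`numpy.random.default_rng` seed and are bit-reproducible.

What the generator does not emulate: correlation of siblings within a seed
batch, temperature-dependent variance or mortality, diapause-termination
physiology, two-year life cycles, and spatial weather error.  Passing
recovery tests therefore show the estimators are consistent under the
stated noise model, not that field data meet that model.

## Problem sizes and tolerances

Recovery tests use 60 individuals × 6 viable temperatures (the study's
cohort scale), 1–5% noise, and a 5 000-individual simulated trap cohort,
where the forecast and the simulated observation agree within one day at
every cumulative point.  Linear-trait recovery is asserted within 0.4 °C
(LT) and 5% (DD); Weibull recovery within 2% (scale) and 15% (shape) at 2%
proportion noise.  Optimiser tolerances are 1e−10 on step and cost; trait
root finding is polished to better than 1e−6 °C.

## Known limitations

Published nonlinear parameter estimates were released only in an appendix
not reproduced here, so nonlinear machinery is verified by self-consistency
(noiseless refits recover parameters to 1e−6; a dense-grid oracle bounds
the optimum on tiny problems) rather than against printed values.
Mean-level refits cannot match per-individual fits beyond the ~0.3%
discrepancy noted above.  The CLI reads single-station weather CSVs only.
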