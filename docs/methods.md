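# Methods

This note documents the models, conventions and numerical choices behind
`equiasym`, and what the synthetic-data generator does and does not
emulate.

## Signal model and stride parameters

Trot is a two-beat diagonal gait: head and pelvis each trace two vertical
oscillations per stride. The simulator builds each trace as a
piecewise-cosine curve through per-stride extremum knots placed at 1/8,
3/8, 5/8 and 7/8 of the stride (right max, right min, left max, left
min). Cosine arcs have zero slope at both ends, so the knots are the only
local extrema — every stride contains exactly two minima and two maxima
per trace by construction. Knot times are snapped to the sample grid;
in the noiseless case the sampled signal therefore attains each configured
extremum value exactly and extraction recovers injected asymmetries to
floating-point precision. This waveform is a modelling convenience: real
head/pelvic displacement is smoother and less stereotyped, but only the
extremum values enter the asymmetry parameters, so the arc shape between
extrema is immaterial to everything downstream.

Asymmetry is injected by splitting each configured trial-level difference
±half onto the right/left extremum of a kind. Optional per-stride
Gaussian jitter of the differences (`stride_asym_sd`, scalar or per
parameter) models biological stride-to-stride variability; white Gaussian
sensor noise (`noise_sd`, mm) is added per sample; sporadic outlier
strides add a large offset to one randomly chosen head extremum.

**Sign convention.** A stride starts at the right-forelimb reference
event (the pastern sensor's cycle start). Each parameter is the left-step
extremum value minus the right-step one, so a lower right-step minimum
gives a positive minimum-difference; positive values are right-associated.
Only the interpretation of the sign is fixed by the field's convention,
not the subtraction order; classification uses absolute values, so the
choice cannot affect prevalence results.

**Stride segmentation** finds upward zero crossings of the mean-centred
pastern reference with hysteresis (re-arm below −20% of the amplitude)
and linear interpolation of the crossing time. Fewer than two full
cycles, or cycle durations with CV > 0.5, raise a segmentation error.

**Extrema extraction** uses a 3-point comparison on the sampled grid,
plateaus credited to the earliest sample — deterministic and
oracle-checkable. For noisy data an optional zero-phase Butterworth
low-pass (default cutoff 15 Hz in the pipeline, against stride harmonics
of ~1.4 and ~2.9 Hz) and a turning-point prominence prune (smallest
adjacent max–min swing removed while below the threshold; `"auto"` =
quarter of the per-trace amplitude) suppress noise-induced extrema.
Strides without exactly two extrema of each kind per trace are flagged,
never silently dropped.

## Quality control

Outlier strides are removed iteratively: the head parameter pair
(HDmin, HDmax) is compared with the trial mean via the Mahalanobis
distance (sample covariance, ddof 1) and strides at distance ≥ 3 are
removed; statistics are recomputed and the loop repeats until no stride
is removed. "Three or more" is read as inclusive (≥ 3). With a singular
or near-singular covariance (condition number > 1e10) the rule falls back
to a per-parameter two-sided univariate criterion, |x − mean| ≥ 3 SD,
recorded in the QC report. Pelvic parameters are not auto-cleaned by
default (`parameters="all"` switches to the 4-D distance). The procedure
is idempotent and cannot remove the whole trial (that case flags the
trial instead). Manual stride-range exclusions (video-identified head
tossing etc.) are inclusive index pairs, validated against overlap and
trial bounds.

Trial inclusion: lunge trials need ≥ 25 strides; straight-line trials
≥ 20, or 16–19 with SD < |mean| for all four parameters (the 16–20
window is half-open at 20, which already passes the ordinary rule; the
dispersion comparison is strict).

## Classification and scores

Asymmetric iff any parameter has |mean| strictly above its threshold
(6 mm head / 3 mm pelvis) with SD strictly below |mean|. Above-threshold
parameters failing the SD condition set a high-variability flag and the
horse classifies symmetric. The double-threshold flag (strictly above
12 / 6 mm) inherits the SD condition by default, matching its use as a
count among asymmetric-classified horses; the unconditioned variant is
also reported. TAS halves the head terms so that the four parameters
contribute equally at threshold (the head thresholds are exactly double
the pelvic ones); an at-threshold trial scores 12 mm, which serves as the
formula's internal consistency check. `TAS_lunge` sums each parameter
signed across the two circle directions first, so a direction-symmetric
systematic lunge effect cancels; a missing direction propagates NaN
rather than a silent zero.

Cohort summaries report counts and one-decimal percentages that recompute
exactly from the integers; horses missing a trial drop out of that
summary's denominator. The "top quartile" of threshold-exceeding values
is the set strictly above the linearly interpolated 75th percentile;
when ties leave that set empty it falls back to the ceil(n/4) largest
(the counts printed in published tables are not consistent with any
single quantile convention, so the convention is exposed as an option).

## Cohort generator

`generate_population` draws, per horse: a discipline (default mix
0.50 / 0.38 / 0.12 show jumping / dressage / eventing), a latent
above-threshold status (default prevalence 0.70), a dominant parameter
(weights 0.265 / 0.190 / 0.293 / 0.252 favouring the minimum-difference
parameters), with each remaining parameter also exceeding its threshold
with probability 0.29 — matching the observed ~1.9 exceeding parameters
per asymmetric horse. Exceeding magnitudes are threshold + 0.5 mm +
exponential excess (scales 5.9 / 3.6 / 1.9 / 2.0 mm chosen so the
above-threshold |mean| averages sit near 12.4 / 10.1 / 5.4 / 5.5 mm);
signs are random. Stride-level SDs of exceeding parameters are uniform
0.3–0.8 of |mean| (1.1–2.0 for the high-inter-stride-variability horses,
default probability 0.09, who therefore classify symmetric). Hard and
soft surfaces share the horse's truth plus independent N(0, 1.2 mm)
surface perturbations; lunge trials add a ±4 mm systematic
direction-dependent offset to the pelvic minimum difference (inside-hind
drop), which cancels in the signed `TAS_lunge` sums. Stride counts per
trial are drawn near 33 ± 10 (straight) and 56 ± 20 (lunge) with the
inclusion-rule minima as floors; stride duration is ~0.70 ± 0.04 s.

Riders (default 51 for 71 horses, every rider assigned at least one
horse) contribute a N(0, 1 mm) shift to pelvic-minimum magnitude — the
random-intercept structure the association model estimates. Questionnaire
answers follow the study's observed frequencies (graded sidedness
0.085 / 0.662 / 0.225 / 0.028 for no/mild/moderate/severe; directional
questions per their published response tables) and are independent of
asymmetry under the null; `sidedness_association_effect` (mm per grade,
default 0) shifts pelvic-minimum magnitude per grade to create a true
association. `study_profile()` bundles the cohort configuration derived
from the published arithmetic (above-threshold prevalence 89/114,
high-variability fraction 10/89, missing-trial rates 9/123, 12/123,
2/123).

**What the generator does not emulate.** Real IMU accelerometry and its
double-integration artefacts (the pipeline starts at displacement);
gait-detection failures; circle geometry beyond the per-direction offset;
rider-on-horse dynamics; correlated left/right parameter structure within
a horse beyond the dominant/secondary draw. Surface discordance is
under-produced relative to real cohorts (real hard/soft classification
disagrees for ~25% of horses, the generator's borderline-crossing
mechanism yields ~15%), so concordance percentages from the emulation run
slightly high. Passing tests therefore demonstrate correctness of the
computational pipeline under a controlled data-generating process, not
the field validity of the thresholds.

## Association models

One observation per horse per model, listwise deletion of missing values.
The response is the absolute asymmetry magnitude (or TAS); the factor is
the binarized questionnaire answer (left/right → yes; the graded
sidedness question keeps no < mild < moderate with severe merged into
moderate); mean stride duration is the speed-proxy covariate (for lunge
responses, the mean of the two lunge trials' mean durations — one
response needs one covariate value); rider is a random intercept.

Fitting uses REML (statsmodels `MixedLM`, Powell optimizer, which proved
the most reliable when the rider variance sits near the boundary). When
every rider has a single horse, or the mixed fit fails, does not
converge, or returns a non-positive-definite fixed-effects covariance,
the model falls back to OLS and the result is flagged; with one horse per
rider the fallback reproduces OLS coefficients exactly, which is also the
model's correct limit. If the absolute skewness of the residuals exceeds
1.0 the response is Box-Cox transformed (offset +0.01 mm since absolute
asymmetries can be 0; lambda by maximum likelihood over a fixed grid
−2…2, step 0.05) and the model re-fitted.

Term tests are joint Wald F statistics on the fixed-effect covariance
with residual degrees of freedom (n − p). A Satterthwaite or
Kenward-Roger correction would be preferable in principle; statsmodels
does not expose the REML variance-parameter curvature needed to compute
it, and at these sizes (≈70 observations, 4 fixed parameters) the
residual-df F is close — the test suite verifies a null type-I error
within [0.03, 0.07] over 1000 simulator replicates and cross-checks the
fixed effects against R's lme4 on a reference dataset. Pairwise contrasts
of estimated marginal means (evaluated at the mean stride duration) use t
tests on the same df with Tukey studentized-range adjustment
(configurable to none). Degenerate inputs (constant response, a single
factor level, fewer than two riders) return a flagged result with NaN
p-values rather than an error.

Question reduction keeps, per declared overlap group, the member with the
fewest "na" answers (ties break to declared order, logged) and then drops
any question whose "no" fraction exceeds 50% — with near-universal "no"
answers there is no perceived sidedness to associate. The grouping itself
is user input, not an algorithmic step, since overlap between questions
is a judgement about their content.

## Problem sizes and reproducibility

The acceptance script uses a 123-horse trace-level cohort for the study
emulation, 1000 replicates at 71 horses / 51 riders for the null
calibration and 150 replicates at an 8 mm-per-grade shift for power — an
effect size chosen comfortably beyond the detection boundary (power
test suite verifies it at ≈1.0; at 5 mm per grade power is ≈0.9).
All randomness flows from a single integer seed; population tables are
byte-identical across runs with the same seed, and the pipeline writes a
manifest (package version, seed, config hash) alongside every report
bundle.
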