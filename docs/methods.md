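# Methods

## The measurement problem

A thigh-worn accelerometer (20 Hz, ±4 g, tri-axial) records free-living
movement for one to two weeks. The analysis asks a contextual question of
that stream: *was a given walk indoors or outdoors?* — and, once walks are
labeled, *how do the two contexts differ in duration, continuity, and
speed?* The package implements the whole chain and validates it on a
synthetic cohort whose ground truth is known exactly.

## Walking periods

Free-living walking is fragmented. Stepping bouts separated by standing
gaps of **strictly less than 60 s** are grouped into a *walking period*;
a gap of 60 s or more, or a gap spent on any activity other than standing
(when an ingested activity table says so), splits periods. Period
**continuity** is `(duration − standing)/duration × 100`. Periods whose
median stride frequency exceeds 1.4 Hz are treated as running and
excluded (a deliberately simple cadence rule; the threshold is
configurable). Periods with fewer than 4 detected strides are dropped
from the feature table, since an SD of stride frequency is meaningless
below that.

## Stride detection

Strides are found per bout by peak-picking on the dominant oscillation:
the tri-axial signal is band-passed (0.3–3 Hz, 4th-order zero-phase
Butterworth), projected on its axis of maximal variance (sign fixed by
skewness), and peaks are taken with minimum separation 0.55 s and
prominence 0.5× the segment SD, excluding 0.5 s at each bout edge
(filter transients). Intervals implying stride frequencies outside
[0.4, 1.6] Hz are implausible for walking and are discarded, not imputed.
Bout-level mean frequency is reported as (events − 1)/span, which is
immune to the upward Jensen bias that averaging reciprocal intervals
incurs under timing noise. On synthetic bouts spanning 0.6–1.2 Hz the
median absolute error of mean stride frequency is well below 1%.

## Bout detection

A moving RMS (1 s window) of the band-passed tri-axial power is
thresholded at 0.06 g; sub-second dropouts are closed, segments shorter
than 5 s dropped, and each segment's edges are refined to 0.6× its own
plateau RMS. The refinement level was set where the boundary bias against
generator ground truth crosses zero: a centred window holds half the
walking power at the true edge (RMS = plateau/√2 ≈ 0.71), but the
harmonic pulse train concentrates power mid-cycle, which moves the
unbiased crossing slightly lower. Resulting boundary errors are ≤ 0.5 s
and mean bout-overlap Jaccard ≈ 0.97.

## Speed model

Stride speed follows a power law in stride frequency,
`v = exp(ln(a·f)/(1−b)) = (a·f)^(1/(1−b))`, with per-participant
parameters a > 0, b < 1 supplied as inputs (their calibration from a
foot-worn sensor is outside this package's scope). Speeds and stride
frequencies are normalized by √(g·l₀) (l₀ = leg length, g = 9.81 m/s²)
before across-participant modelling. The generator inverts the law
exactly (f = v^(1−b)/a), so ground-truth speeds and frequencies agree to
1e-9 relative.

Class-conditional speed summaries average **per-period mean speeds**, one
walk one vote. Pooling raw strides would weight a period by its stride
count, which grows with both duration and cadence; since cadence rises
with speed, stride pooling inflates the class with the larger speed
spread (indoor, by ~0.1 m/s in our cohorts) and shrinks the
indoor–outdoor gap. The stride-level mixed model reaches the same
estimand through its period random intercepts.

## Classification protocol

Two ensemble learners with fixed hyperparameters: Random Forest
(40 trees, bootstrapped) and a bagging ensemble of 60 RBF-kernel SVMs
(each standardized internally; a bootstrap resample that happens to
contain one class yields a constant-voting member rather than an error).
Training uses only periods labeled purely indoor or outdoor. Validation
is leave-one-participant-out over the training pool (15 of 20
participants by default), so metrics measure generalization to unseen
people; the held-out participant of a fold contributes no training rows,
asserted structurally. The best *case* is chosen by the unweighted mean
of average accuracy, F1, and AUROC (ties: accuracy, F1, algorithm id);
its fold models are evaluated on the held-out test participants and the
single best (accuracy, then F1, AUROC, fold id) labels the mixed and
unlabeled periods. Indoor is the positive class for F1 — it is the
~80%-prevalent class, and the choice is configurable. AUROC scores come
from tree-vote fractions (RF) or the min-max-mapped mean decision
function (bagged SVM); a single-class validation fold has no AUROC and is
excluded from that average. Permutation importance is the mean ± SD
accuracy decrease over 20 shuffles of one feature column, evaluated on
the test set. A hyperparameter grid search utility is deliberately absent:
the fixed values are the tuned operating point, and the package treats
them as configuration.

## Mixed-effects models

Three models share the fixed effect of context (outdoor vs indoor):
duration and continuity at the period level with a participant random
intercept, and normalized stride speed at the stride level with periods
nested in participants (variance component per period). Estimation is
REML; candidate random-effect structures (independent residuals;
participant intercept; participant + period) are compared by **ML** AIC,
counting fixed effects plus all variance parameters, because ML
likelihoods are comparable across structures including the OLS baseline
while REML ones are not. The reported test is the Wald t with residual
degrees of freedom (n − 2) — an approximation adequate at these sample
sizes. statsmodels' default optimizer occasionally stalls at a zero
random-effect variance; such fits are retried with Powell and the better
finite-likelihood solution kept. For tractability the stride-level model
caps strides per period at 15 by seeded subsampling (balanced, so the
estimand is unchanged; the default cohort has ~500 k strides).
Simulation checks: 95% CI coverage ≥ 93/100, type-I error in
[0.02, 0.09] at α = 0.05, variance components recovered within 10%.

## Synthetic cohort generator

The generator is the test substrate and defines the study conditions.
Per participant: leg length ~ U(0.80, 0.95) m, speed parameters
a ~ U(1.2, 1.4), b ~ U(0.3, 0.5), indoor proportion ~ Beta(32, 8)
(mean 0.8), and a log-normal duration scale (σ = 0.05, mean 1) for mild
between-participant heterogeneity. The speed-parameter ranges were chosen
so that the frequencies implied by realistic speeds (0.5–2.6 m/s) stay
inside the detector's plausibility band [0.4, 1.6] Hz; wider ranges
(e.g. a up to 2.5 with b up to 0.6) put ordinary walks outside that band
or map 1.1 Hz to >10 m/s, which is not a usable operating point.

Class-conditional structure (defaults):

| parameter | indoor | outdoor |
|---|---|---|
| period duration (log-normal, CV 0.8) | mean 2.2 min | mean 11.4 min |
| continuity target | 61.6% | 81.7% |
| stride speed (truncated normal) | 1.10 ± 0.43 m/s | 1.38 ± 0.31 m/s |
| period mix | 80% | 20% |

Durations are log-normal (positive, right-skewed) truncated to
[0.4, 60] min with the parent location moment-matched so the class mean
is exact under the bound; multi-hour uninterrupted walking periods do not
occur in free-living data, and an unbounded CV-0.8 tail would let a
handful of tail draws dominate cohort means. Standing interruptions:
the configured rate (gaps/min, mean gap 30 s, uniform bounds [5, 55] s —
strictly under the grouping threshold so ground-truth periods survive
segmentation intact) fixes the mean standing fraction at
`rate × 30/60`; each period draws its fraction from a Beta with that
mean (concentration 8) and realizes it exactly as gaps with per-gap
length ≤ 55 s and every stepping bout ≥ 6 s. A direct compound-Poisson
draw cannot fit the target fraction into short indoor periods, which is
why the fraction is sampled first. The closed-form rates are 0.768/min
(indoor) and 0.366/min (outdoor). Stride speeds are moment-matched
truncated normals on [0.5, 2.6] m/s (the configured mean/SD are the
distribution's actual moments), constant per period up to a 0.03 m/s
per-stride jitter; absolute class means (1.10/1.38 m/s) are free choices
consistent with the 0.28 m/s gap and the class SDs.

Mixed periods (default 2%) concatenate a majority-context segment with a
shorter minority segment across a sub-threshold standing gap; 5% of pure
periods are published as unlabeled. The 80:20 mix refers to the pure
periods.

Waveforms: a fixed per-participant gravity orientation plus a
three-harmonic cosine pulse train (amplitudes 0.35/0.15/0.06 g) along a
swing axis, phase-locked to the scheduled stride events by piecewise
linear phase, with white noise (σ = 0.05 g), clipped to ±4 g. Idle time
between periods is shortened to 75–120 s of standing (the event tables
keep true offsets), keeping a 20-participant cohort to ~25 min of CPU
rather than simulated weeks.

**What the generator does not emulate:** sensor drift, detachment and
non-wear, posture transitions (sitting/lying), terrain- or fatigue-driven
within-period speed trends, GPS/self-report noise, and any systematic
overlap between the classes' feature distributions beyond what the
configured spread induces. Passing the end-to-end tests therefore shows
that the measurement chain is faithful when its assumptions hold — not
that the classifier's accuracy would transfer to real recordings.

## Problem sizes and numerical choices

The default cohort is 20 participants × 170 periods (~3 400 periods,
~3 000 of them after exclusions in any given run; ~500 k strides), the
scale at which the recovery analysis and acceptance numbers are
computed. Tests use smaller cohorts (5–12 participants) except the
end-to-end recovery, which runs the default scale once per session.
Determinism: every stochastic step draws from a seed-sequence substream
of one master seed (per-participant schedule and waveform streams, per-
fold classifier seeds, shuffle and subsample streams), so identical
config + seed reproduces cohorts, models, and reports bit for bit.
Degenerate inputs are contracts, not crashes: empty recordings yield
empty bout lists, constant signals yield empty stride sequences, a
constant outcome yields a zero effect with a degenerate-variance
warning, and a single-context model matrix raises.
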