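# Methods

## Signal model

All stages operate on the 3-D body-centroid trajectory extracted from
depth frames: per sample a time `t` (s) and world coordinates `x`
(lateral), `y` (height above floor), `z` (range), in millimetres. The
camera is an ideal pinhole with zero tilt at a configured height
(defaults: 512×424, f = 365 px, principal point at the image centre,
optical centre 1.0 m above the floor, 30 Hz). Back-projection of a
pixel (row, col, depth d) is `x = (col − cx)·d/fx`,
`y = sensor_height − (row − cy)·d/fy`, `z = d`. Invalid depth (0) is
always background, matching how time-of-flight sensors mark dropout.

Background subtraction is static: per-pixel median over person-free
frames, fixed tolerance (default 80 mm), largest 4-connected component
with a minimum size (default 50 px). An adaptive background was not
needed for a 15–40 s recording and would add state with no testable
benefit here.

## Activity HMM

The observation pair per sample is *(relative height, vertical
velocity)*. Height is smoothed with a centred moving average (0.25 s
window) and normalised by the standing height, calibrated as the 95th
percentile of the smoothed series (robust to noise spikes and to the
unknown absolute body size). Velocity is the finite-difference
derivative of the smoothed height, smoothed once more with the same
window; the double pass suppresses sensor noise to roughly ±17 mm/s at
10 mm depth noise, at the cost of blurring fast transitions by about a
quarter second (see Limitations).

The five states and their Gaussian emissions (mean ± SD; relative
height unitless, velocity mm/s):

| state            | rel. height | velocity   |
|------------------|-------------|------------|
| sitting          | 0.59 ± 0.05 | 0 ± 20     |
| transition-up    | 0.80 ± 0.09 | +280 ± 180 |
| standing         | 0.975 ± 0.02| 0 ± 15     |
| walking          | 0.99 ± 0.015| 0 ± 36     |
| transition-down  | 0.85 ± 0.15 | −240 ± 160 |

The parameters are hand-specified, not trained: they encode that a
seated centroid sits near 55–65% of standing height, that postural
transitions carry sustained vertical speed of a few hundred mm/s, and
that gait oscillates the centroid around a baseline just below the
calibrated standing height. The walking velocity SD (36 mm/s) is
deliberately *smaller* than the oscillation amplitude it observes
(±70–120 mm/s after smoothing): the transition topology, not the
emission, protects mid-walk swings — `transition-down` cannot return
to `walking`, so a Viterbi path can only enter it once at the end of
the walk, and a tighter walking velocity band moves that entry point
closer to the true end of the last step. The transition matrix allows
sitting→up→{standing, walking}, walking↔standing (this is how
hesitation stops are expressed), {walking, standing}→down→sitting,
with self-transition probabilities 0.90–0.99. Ties in Viterbi scores
are measure-zero under continuous emissions; the decoder's fixed state
order makes the outcome deterministic regardless.

Decoding uses `hmmlearn`'s Viterbi with these fixed parameters (no
fitting); a full-enumeration oracle over all 5¹⁰ paths of a 10-sample
instance verifies the decode in the test suite.

## Events

* start-move — first non-sitting sample after the initial sitting run;
* start-walk — first sample labelled walking;
* start-sit — first sample after the last walking run;
* end-sit — last sample before the final sitting run;
* stops — standing runs strictly inside the walking span, ≥ 0.5 s
  (shorter hesitations are not clinically reported), disjoint from the
  turn window;
* turn — from the horizontal distance to the chair (estimated as the
  mean horizontal centroid over the initial sitting run, overridable):
  the maximal contiguous interval containing the farthest point where
  the distance stays ≥ 95% of its maximum. Contiguity is imposed
  because a turn is a single manoeuvre; the window is clipped to the
  walking span if it spills over, with a log warning.

## Gait parameters

Steps are local maxima of the smoothed height inside the two walking
spans with stop intervals excised, requiring ≥ 5 mm prominence and
≥ 0.3 s separation (no plausible human cadence exceeds ~3 steps/s; the
separation floor prevents noise from splitting one peak into two).
Peaks within 0.12 s of a sub-span boundary are discarded as edge
artifacts; peaks are never paired across the turn or across a stop, so
a step spanning a stop does not enter the statistics.

Conventions, fixed for determinism:

* CV = population (1/n) SD divided by the mean, in percent.
* Median of an even count = mean of the two central values.
* Cadence = 1/step-duration, in steps/s. (Published tables sometimes
  label this quantity steps/min while printing values near 1.4–1.7,
  which are per-second magnitudes; this package labels it steps/s.)
* Gait speed = Σ step lengths / Σ step durations (cm/s), pooled over
  both walking spans.
* Vertical transition speeds are the extrema of the smoothed velocity
  inside [start-move, start-walk] and [start-sit, end-sit]; sit-down
  speed is negative by construction.
* Walking time = (start-turn − start-walk) + (start-sit − end-turn)
  − total stop time.
* Turn width = horizontal distance between the positions at start-turn
  and end-turn. Greatest walk width = directed Hausdorff (max-of-min)
  horizontal distance from the forward-walk path to the return-walk
  path — this captures path separation without pairing arbitrary
  far-apart points, which a plain maximum over all pairs would do.

## Agreement statistics

Differences are algorithm − expert. The SD of differences under
repeated trials comes from a one-way random-effects decomposition
(one-way ANOVA of the differences grouped by subject; between-subject
component `(MSB − MSW)/n₀` with the standard unbalanced `n₀`). Limits
of agreement use bias ± 2·SD (the factor 2, not 1.96, matching the
convention of the agreement literature this implements). Percentage
error = 100 · 2·SD / grand mean of the two methods, and is scale
invariant.

The repeated-measures CCC is a moment (balanced-EMS) variance-
components estimator for the model
`y = μ + subject + method + trial + subject×method + subject×trial + ε`
with `CCC = (σ²_subj + σ²_subj×trial) / (σ²_subj + σ²_subj×trial +
σ²_subj×method + σ²_ε + φ_method)`: trial-to-trial variation shared by
both methods is concordant and counts in the numerator, while method
offsets and subject×method disagreement penalise. With one trial per
subject it reduces to (and is computed as) Lin's classical formula.
Unbalanced trial counts use the mean count in the EMS algebra (an
approximation, logged). The ICC is ICC(2,1) — two-way random effects,
absolute agreement, single measure — computed by `pingouin` with each
(subject, trial) pair as the rated target. The Spearman CI is a BCa
bootstrap (default 2000 resamples, seeded) that resamples whole
subjects, preserving the repeated-measures structure; acceleration
comes from a leave-one-subject-out jackknife. Regression is ordinary
least squares of the algorithm on the expert.

## Fall-risk analysis

The threshold rule is strict: best-trial duration < cutoff (default
13.5 s) → low risk; the boundary value itself is high risk. Group
tests use Student's t only when both groups pass Shapiro–Wilk and a
median-centred Levene test at α = 0.05, otherwise the Wilcoxon
rank-sum; constant samples count as non-normal. The MANOVA reports
Pillai's trace with its F approximation (the most robust of the
standard multivariate statistics); with a single parameter it
degenerates to one-way ANOVA.

The subset search enumerates all feature subsets of size 1–3 × ten
standard classifiers (k-NN, linear SVM, RBF SVM, Gaussian process,
decision tree, random forest, multilayer perceptron, AdaBoost,
Gaussian naive Bayes, QDA), all at library defaults with a fixed seed,
scored by leave-one-subject-out cross-validation on one best-trial row
per subject. Scale-sensitive classifiers get a z-score standardizer
fit on training folds only. Two small default adjustments keep the
roster runnable on tiny classes: the MLP iteration cap is raised to
2000 (the default stops short of convergence on 30-odd samples) and
QDA gets a 10⁻³ covariance ridge (it otherwise hard-errors when a
class has barely more members than features, as a 5-member class with
3 features does). Equal scores rank smaller subsets first, then
alphabetical feature names. Per-class sensitivity/specificity are
one-vs-rest counts on the pooled held-out confusion matrix.

## Synthetic generator

The generator emulates the standard protocol geometry: chair 4 m from
the sensor, a 3 m lateral walk, a 180° turn past the floor mark, the
return on a parallel path 0.3 m away, modelled as a semicircular arc
bulging away from the chair. The vertical trace is piecewise: sitting
plateaus, cubic-smoothstep sit↔stand transitions, and a sinusoidal
per-step bob (default 15 mm at 1.6 Hz) superimposed on the walk.
Three structural choices make the ground truth exact and the joins
smooth:

* **Whole steps.** The walk length is rounded up to an integer number
  of steps (`N = ceil(3 m / step length)`; one turns after passing the
  mark), so every walking span starts and ends exactly at an
  oscillation trough — zero velocity, height `stand − amplitude` —
  and height peaks sit half a step period away from every boundary.
* **Stops snap to steps.** A hesitation stop begins at a completed
  step (an oscillation trough), so stop plateaus join the oscillation
  continuously and no peak sits near a stop edge.
* **Turn ground truth by the method's own definition.** The true turn
  events are the 95%-rule window computed in closed form on the
  noise-free path (the physical arc boundaries are retained
  separately). Any other definition would build a walk-speed-dependent
  systematic error into the oracle.

Sensor noise is i.i.d. Gaussian on all three coordinates (default
5 mm, scenario-settable); all randomness derives from the scenario
seed, so trajectories are pure functions of (scenario, seed). The
depth renderer draws a flat-depth upright box whose 3-D centroid
equals the trajectory sample, prepending person-free frames so the
background model can be built from the head of the sequence.

The randomized evaluation scenarios draw from frail-elderly ranges:
standing centroid height 0.9–1.1 m, sitting at 55–65% of standing,
gait speed 0.5–0.8 m/s, cadence 1.4–1.8 steps/s, oscillation 12–20 mm,
rise and sit-down times 1–2 s, turn 1.5–2.5 s, noise 2–10 mm, and one
mid-walk stop (0.8–1.8 s) in a quarter of trials.

What the generator does **not** emulate: arm/assistive-device motion,
multi-person scenes, occlusion and furniture, asymmetric or variable
step lengths (per-trial step geometry is constant, so CV ground truths
are zero and CV recovery is judged in absolute percentage points),
sensor-specific noise spectra, or very slow (> 2 s) postural
transitions. Passing tests therefore demonstrate correctness of the
algorithmic chain under clean protocol geometry, not clinical
performance on real recordings.

Cohort simulation draws subject-level parameter vectors from
class-conditional multivariate normals (uniform between-parameter
correlation, default 0.3), adds small within-subject trial jitter
(10% of the class SD), clips to physical bounds and rounds the count
parameters. The default two-class template uses published low-risk
(n = 11) vs at-risk (n = 26) summary statistics for all 21 parameters;
the three-class template (13/5/16) interpolates the intermediate
class midway.

## Numerical choices

* Smoothing window 0.25 s everywhere (heights, velocities, horizontal
  coordinates for turn and step geometry); shorter windows let sensor
  noise into the velocity channel, longer ones blur stop edges.
* Step-peak edge margin 0.12 s: with spans starting/ending at troughs
  the nearest true peak is ≥ 0.28 s from a boundary, so the margin
  rejects boundary artifacts without eating genuine peaks even under
  worst-case event jitter.
* Event timestamps are sample timestamps (no sub-frame interpolation),
  so each event carries a quantisation bias of up to one frame.
* Degenerate inputs raise informative errors rather than returning
  NaN: empty silhouettes, constant duration series, flat chair-distance
  profiles, groups smaller than three.

## Accuracy at the default study conditions

On the 100-seed randomized suite, 94 trajectories have every event
(including stop edges) within 0.2 s of ground truth; the exceptions
miss by ≤ 0.033 s, almost all at the walk→sit boundary of the slowest
sit-downs. The cause is structural: the centred smoothing erases the
zero-velocity trough between the last step and the descent, so the
observation pair defines that boundary only to about half a step
period, and a two-dimensional Gaussian emission cannot distinguish the
trough sample from mid-swing walking samples with identical values.
The same seeds push the derived phase times slightly past 0.3 s
absolute error (worst: 0.35 s on sit-down time; walking time, which
compounds two event errors, up to 0.65 s on a ~10 s phase, i.e. ~4%
relative). All step-geometry parameters recover well within 10–15%
everywhere; step counts within one step.

For two-group testing at the published summary statistics with
n = 11 vs 26, three parameters (turn width, greatest walk width, stop
count) have standardized effects near d ≈ 0.5, for which the two-sample
power at α = 0.05 is only ≈ 0.25–0.40; their group differences are
accordingly detected in well under 90% of simulation replicates. This
is a property of the effect sizes and sample sizes, not of the test
implementation; the remaining 18 parameters (d ≳ 1.2) are detected in
> 90% of replicates.

## Problem sizes used by the test suite

The suite analyses 100 synthetic trajectories (~530 samples each at
30 Hz), renders one full-resolution depth sequence (~540 frames of
512×424) for the end-to-end check, uses 200 null and 100 alternative
cohort replicates for test calibration, and restricts exhaustive
classifier searches to 5–6-feature pools with the fast half of the
classifier roster; the complete run takes about a minute on one CPU.
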