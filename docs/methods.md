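# Methods

This note documents the models, the synthetic-session generator, the
numerical choices, and the limitations of the `whiskloc` pipeline.

## Task and coordinate conventions

A session is a sequence of 4 s trials at 1 kHz. The pole is triggered at
500 ms, takes ~200 ms to rise into reach, and stays in reach until the end
of the answer period. The sampling period spans 0–750 ms and the answer
period 1250–2000 ms after pole onset. Go positions are posterior (0–5 mm),
no-go anterior (5–10 mm), contiguous, with the boundary at 5 mm; the pole
sits ~8 mm lateral to the follicle. Azimuthal angle is measured at the
whisker base from the mediolateral axis, increasing with protraction
(anterior); with the default geometry the pole subtends 0°–51° across the
10 mm range and the boundary sits at 32°. Outcomes follow the go/no-go
table: go+lick = hit, go+no-lick = miss, no-go+lick = false alarm,
no-go+no-lick = correct rejection.

Two task variants pivot about the boundary geometry: *angle* trials vary
azimuth at the boundary radial distance; *distance* trials vary radial
distance (go 8–10 mm, no-go 10–13 mm) at the boundary azimuth. Because the
generator's touch geometry is purely azimuthal, distance sessions carry no
azimuthal information and a kinematics-driven decision rule performs at
chance there — the signature the variant exists to reproduce.

## Synthetic session generator

The generator is a first-class, tested model of the study conditions, not a
fixture. Per trial:

1. **Cue-triggered whisking.** Whisking starts at pole trigger plus a
   latency ~ N(60, 16²) ms. Before the cue the whisker rests at −15° with a
   0.8° quiescent amplitude (below the 5° whisk threshold).
2. **Whisk schedule.** Whisk periods are 1/15 Hz with a 12% CV, reflecting
   the substantial cycle-to-cycle period variability of natural whisking;
   this is also what makes phase decorrelate across cycles while midpoint
   persists.
3. **Boundary targeting with noise.** Each whisk's peak protraction targets
   the boundary angle with total SD 10.9°. The noise is split into a slow
   AR(1) midpoint component (stationary SD 9°, per-whisk correlation 0.9 —
   timescale ≈ 10 whisks) and independent per-whisk amplitude noise
   (SD √(10.9² − 9²) ≈ 6.1° about a 20° mean, clipped to [5.5°, 40°]).
   Putting most of the noise on the midpoint makes it the slow,
   recoverable, decision-relevant component, consistent with midpoint
   being the most autocorrelated component across whisk cycles. Midpoint
   and amplitude envelopes interpolate the per-whisk values (lightly
   smoothed, σ = 8 ms); phase advances −π → π per cycle; the angle is
   midpoint + amplitude·cos(phase).
4. **Touch-adaptive bout.** Without touch the bout lasts ~2.5 whisks
   (1 + Poisson(1.5)) past the first in-reach whisk; after a (predicted)
   first touch it extends by a factor 2.6, reproducing the 2.5 → 6.5
   inflation of whisk counts after touch. The factor multiplies an
   independent draw, giving post-touch counts of mean ≈ 6.5, SD ≈ 3.
5. **Touch geometry.** The follicle translates affinely with angle (1.5 mm
   total excursion along a fixed direction, 1.3 AP : 0.7 ML). A contact
   opens at each upward crossing of the follicle-dependent pole angle while
   the pole is in reach (a protraction touch) and closes at the downward
   crossing (a retraction touch); if the pole rises under an
   already-protracted whisker the contact opens without a protraction
   onset, which is how retraction-only trials arise. During contact the
   angle is clipped at the pole — the pole physically blocks protraction,
   which is what pushes go-trial peak protraction posterior from the third
   whisk onward. Curvature is a linear function of protraction angle plus
   smoothed noise plus a contact increment proportional to the blocked
   protraction; the 1-ms-pre-touch sample serves as the roll-angle proxy.
6. **Choice.** Lick probability is sigmoid(w_m·m̃ + w_c·c̃ + b) where m̃ is
   the latent midpoint averaged over pre-answer touches, normalized by
   fixed reference statistics ((x − 12)/10), and c̃ the normalized touch
   count ((n − 2.5)/5). Zero-touch trials use m̃ = 0 — the reference mean —
   so they are decided by the count term and bias, matching the two-stage
   classifier's treatment. Defaults w = (−3.0, +2.5, −0.75) calibrate the
   session statistics to expert behavior: ~80% accuracy, ~94% lick on
   go-touch trials, ~47% on no-go-touch trials, rare licks without touch.
   The rule can alternatively be driven by angle-at-touch
   (``choice_feature="angle"``), used for the distance-variant control.
   Reference normalization (rather than session-empirical) is used because
   choices must be drawable per trial before the session exists.
7. **Licks.** Lick trials receive a decision lick at answer start plus a
   Gamma(2, 100 ms) delay and a ~7.7 Hz lick train; occasional pre-answer
   licks are generated (15% of lick trials, 5% of no-lick trials) to
   exercise the rule that licks before the answer period are ignored.

All randomness flows from the session seed through per-trial
`SeedSequence` spawns: sessions are bit-reproducible, trials independent.

What the generator does **not** emulate: whisker mechanics (no bending,
no forces — curvature is a statistical proxy), 3-D roll, multi-whisker
interactions, learning or motivational drift, choice-history effects, and
video-level measurement noise. Touch events are geometric crossings, so
every contact yields a protraction/retraction event pair rather than
curated contact episodes; absolute touch counts on posterior positions run
higher than in real sessions even though the position gradient and the
go/no-go ordering are preserved. Passing tests therefore demonstrate that
the pipeline recovers the structure this model encodes, not that it would
be robust to every artifact of real video-derived data.

## Kinematic decomposition

Band-pass: 6–60 Hz Butterworth, order 4, applied forward-backward
(`sosfiltfilt`) so touch- and peak-time samples are not phase shifted.
Amplitude and phase are the modulus and argument of the analytic signal of
the band-passed angle; phase uses the (−π, π] convention with −π mapped to
π. The recomposition identity bandpassed = amplitude·cos(phase) is exact by
construction and asserted in tests.

Midpoint: the obvious candidate "band-pass the difference between raw and
band-passed angle in 6–60 Hz" annihilates itself, so the midpoint is
defined as raw − band-passed, low-pass smoothed below 6 Hz (order 2,
zero-phase). This yields the slowly varying offset and preserves
angle ≈ midpoint + bandpassed + (small residual).

Edge handling: the first and last 100 ms of each trial are flagged as
filter transients and excluded from component statistics. Steady-state
accuracy claims (e.g. 5% tone recovery) are evaluated beyond the ~300 ms
warm-up of the order-4 band-pass; trial events of interest sit well inside
the trial.

Whisk segmentation: local maxima of the band-passed angle with minimum
separation of half the nominal whisk period, retained when instantaneous
amplitude ≥ 5°; plateau ties resolve to the earliest sample; peaks without
flanking troughs are dropped. Whisk counts are non-increasing in the
threshold by construction.

Autocorrelation: computed on mean-subtracted series, 1 at lag 0; a
zero-variance series is a delta at lag 0 with a warning. Session-level
component autocorrelations concatenate the whisking epochs and subtract one
global mean — per-bout estimates over a handful of whisks are dominated by
the short-window bias for slow components.

KL divergence: Σ p ln(p/q) in nats on a shared support; empty q bins facing
non-empty p bins receive 1/(10·n_bins) before renormalization. Both the
base and the zero handling are implementation choices (the reference
real-data values 0.04/1.12 are treated as a qualitative ordering, not as
targets).

## Feature extraction

The decision point is the first lick at or after the answer-period start
(closed left endpoint); on no-lick trials the session median of those
decision times is substituted (a session with no lick trials has no defined
median and errors). All touch-conditioned features average over touches
strictly before the decision; a touch at exactly the decision time is
excluded. Whisk latency references each touch to the nearest preceding
trough, taken from the decomposition's phase wraps through −π (whether the
original analysis used raw-angle or band-passed troughs is not determinable;
phase wraps are the self-consistent choice here). Curvature "1 ms before
touch" is exactly one sample at 1 kHz, the nearest sample at onset − 1 ms
otherwise. Touchless trials carry NaN missing markers — never imputed
zeros — so classifiers must branch on touch presence explicitly. For the
Hilbert decoders, phase/amplitude/midpoint means are recomputed over
protraction touches only and retraction-only trials are excluded; touch
count and the other features keep all touches.

Mean normalization is x′ = (x − mean)/(max − min): mean 0, range exactly 1,
affine-invariant; constant predictors raise rather than divide by zero.
Within cross-validation the statistics are computed on training folds only
and applied to the held-out fold (train-only was chosen where the original
convention is unknowable; a constant training-fold predictor falls back to
unit range).

## Classifier

Cost J(θ) = mean cross-entropy + λΣ_{j≥1}|θⱼ|, intercept unpenalized
(penalizing it would break the J(0) = ln 2 calibration on unbalanced data).
Probabilities are clipped at 1e−12 inside logs. The reported subgradient
uses sign(0) = 0, but the optimizer handles the kink properly: FISTA with
soft-thresholding on penalized coordinates, step 1/L with
L = ‖X‖₂²/(4m), convergence when the relative cost change falls below
tolerance (default 1e−9), non-convergence flagged on the model and warned.
λ path fits are warm-started in increasing λ; Σ|θ| is non-increasing along
the path (tolerance 1e−6).

Cross-validation: seeded stratified folds (remainders to the earliest
folds), default 20 iterations × 5 folds; held-out "error" is the
misclassification rate; the λ grid is 20 log-spaced points in [1e−4, 10]
(wide enough on range-1 features for the one-SEM rule to bite). The chosen
λ is the arithmetic mean of the minimum-error λ and the first larger λ
whose mean error exceeds minimum + SEM; per-fold MCC/accuracy/coefficients
are recorded at the chosen λ and the final model is refit on all data.

MCC uses the standard numerator TP·TN − FP·FN; any zero factor in the
denominator defines the score as 0 with a warning. Odds-ratio weights:
per fold, e^|θⱼ| is min-max normalized across predictors and multiplied by
sign(θⱼ), then averaged across folds — normalizing e^θ directly would send
strong negative predictors to zero weight, contradicting their use as
signed importances. Degenerate cases: a single predictor returns sign(θ)
with a warning; zero spread returns unit magnitudes.

Shuffle controls refit the full CV on label permutations with the fold
structure held fixed, so per-fold scores pair with the real fit; the paired
test is a Wilcoxon signed rank on the per-fold differences.

Two-stage choice model: trials with touch are scored by the kinematic
feature + count model; touch trials whose kinematic feature is missing
(retraction-only) fall back to the count-only model; trials without touch
are assigned "no lick" structurally — the count-only stage's invariant
outcome at zero touches, enforced exactly.

## Behavioral statistics

Psychometric curves use 1 mm bins aligned to the task range so the boundary
is a bin edge, with Clopper–Pearson binomial intervals. Boundary
discrimination compares cumulative windows [boundary − d, boundary) vs
[boundary, boundary + d] and reports the lick-probability difference with a
pooled-variance two-sample t statistic computed from its closed form on the
Bernoulli indicators (kept explicit so the statistic is auditable).
Whisk-count windows: pole onset → first touch (pre) and first touch →
decision lick (post); no-touch trials substitute the session median
first-touch time. Normalized touch counts subtract the mean count of the
trial's position bin. Resolution comparison sums per-bin absolute
deviations between classifier and subject psychometric curves.

## Problem sizes and reproducibility

Simulated analyses use 200-trial sessions, the size of the stable
high-performance block an expert animal contributes per session.
Parameter-recovery experiments run ten sessions (seeds 1–10) with 10 × 5
stratified CV — ten iterations estimate fold scores amply for ordering
models while keeping the recovery experiment's turnaround reasonable; the
library default remains 20. Multi-seed "majority" properties use fixed,
documented seed lists. Session HDF5 files are written with
`track_times=False` so identical sessions serialize to identical bytes, and
run manifests record SHA-256 hashes of every artifact; a rerun under the
same config reproduces the hashes exactly.

## Known limitations

- The midpoint/amplitude noise split and the amplitude-envelope dynamics
  are modeling choices; only the total per-whisk protraction noise and the
  qualitative component timescales are constrained by the study conditions.
- Geometric touch detection yields paired protraction/retraction events and
  no measurement gaps; real touch curation produces different event
  statistics (absolute counts here are inflated on posterior positions).
- The λ-selection "error" is misclassification rate; other losses would
  shift the chosen λ though rarely the model ordering.
- The phase feature enters the logistic models linearly; its circularity is
  mitigated only by the protraction-touch restriction, as in the original
  design.
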