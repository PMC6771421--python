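# whiskloc

Analysis pipeline for whisker-guided anteroposterior object localization in
head-fixed mice. A mouse with a single whisker sweeps it back and forth to
find a vertical pole presented somewhere along a contiguous 10 mm range
(posterior half rewarded: "go", lick; anterior half unrewarded: "no-go",
withhold). The scientific question is which sensorimotor features gathered
at the moment of touch drive the location decision. This package implements
the full statistical-learning analysis of that behavior — and a synthetic
session generator with complete ground truth, so every stage is testable as
parameter recovery without any behavioral data.

## What it computes

**Whisking kinematics.** The whisker azimuthal angle θ(t) (1 kHz, degrees)
is band-pass filtered (6–60 Hz Butterworth, zero-phase) and decomposed via
the Hilbert transform into

- amplitude A(t) = |𝓗[θ_bp](t)| — the envelope of the whisking oscillation,
- phase φ(t) = arg 𝓗[θ_bp](t) ∈ (−π, π] — position within the whisk cycle
  (−π/π at maximal retraction),
- midpoint M(t) — the slow offset the whisker oscillates about, the
  low-passed remainder θ − θ_bp,

so that θ(t) ≈ M(t) + A(t)·cos φ(t). Whisks are segmented as peaks of the
band-passed angle with instantaneous amplitude ≥ 5°.

**Trial features.** Each trial is reduced to 13 predictors (touch presence
and count, curvature 1 ms before touch as a roll-angle proxy, whisk and cue
latency, radial distance, and angle/phase/amplitude/midpoint at touch, plus
motor position and named combinations), computed strictly over pre-decision
touches — the decision point is the first lick of the answer period, with
the session median substituted on no-lick trials. Trials with exclusively
retraction touches are excluded from the Hilbert decoders.

**Classification.** A from-scratch L1-regularized logistic classifier:
mean cross-entropy J(θ) + λΣ|θⱼ| minimized by proximal gradient descent
(FISTA) with an unpenalized intercept; 20 iterations of 5-fold stratified
cross-validation over a log-spaced λ grid; λ chosen as the mean of the
minimum-error λ and the first λ one SEM above the minimum; performance
scored with the Matthews correlation coefficient

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

plus sign-carrying normalized odds-ratio weights, label-shuffle controls,
and the two-stage choice model: trials without touch are decided by touch
count alone (invariably "no lick"); trials with touch by a kinematic
feature (whisking midpoint at touch, or angle) plus touch count.

**Behavior.** Psychometric curves, boundary discrimination with closed-form
two-sample t statistics, pre/post-touch whisk-count distributions and their
KL divergence (touch-adaptive exploration), touch-count-conditioned lick
probabilities, protraction targeting by whisk index, and psychometric
resolution comparison between classifiers and subject.

## Worked example

```bash
python analysis/01_simulate_session.py --seed 1   # -> results/session.h5
python analysis/02_decompose_whisking.py
python analysis/03_extract_features.py
python analysis/04_fit_classifiers.py
python analysis/05_behavior_report.py
```

The simulation step prints

```
session: 200 trials (seed 1)
touch probability: go 0.960, no-go 0.550
touch count: most posterior bin 17.4, most anterior bin 0.7
lick rate: go 0.890, no-go 0.350
discrimination accuracy: 0.770
```

— noisy boundary-targeted whisking makes touch much more likely on go
(posterior) than no-go trials, with a steep posterior-to-anterior touch
count gradient. Decomposition (step 02) reports the component timescales at
a one-whisk-period (67 ms) lag:

```
autocorrelation at 67 ms (midpoint): 0.768   ... (phase): 0.372
```

midpoint is the most persistent component across whisk cycles and phase the
least. The classifier ranking (step 04) puts the two-stage models on top:

```
choice two-stage angle+count (all trials)                 MCC 0.745  acc 0.880
choice two-stage protraction_midpoint+count (all trials)  MCC 0.744  acc 0.880
choice two-stage protraction_amplitude+count (all trials) MCC 0.713
choice touch_count (touch trials)                         MCC 0.703
...
choice cue_latency (touch trials)                         MCC 0.000
midpoint+count touch-stage weights: bias +2.30, midpoint -4.37, count +7.20
```

Choices in these sessions are generated from midpoint-at-touch and touch
count, and the fitted two-stage model recovers exactly that structure: a
negative midpoint weight (more anterior midpoint → less likely to lick),
a positive count weight, and midpoint+count performing on par with the
angle+count model while timing features carry no information. The behavior
report (step 05) shows the adaptive-whisking signature: 2.6 whisks before
the first touch versus 7.0 after it, with whisk-count divergence between
touch and no-touch trials of 0.13 (pre-touch) versus 0.89 (post-touch).

The same pipeline runs end to end as `whiskloc run` (or stage-by-stage via
`whiskloc simulate|decompose|features|classify|behavior`), writing a
manifest with content hashes that reproduce exactly under a fixed seed.

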