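# Methods

## Problem and scope

Two systems record the 3D joint-centre positions of one hand over time: a
marker-based optical reference at a constant 150 Hz, and a markerless
tracker at a nominal ~120 Hz whose inter-frame intervals vary and whose
skeletal model introduces joint-dependent systematic error. The package
quantifies agreement between the two for finger joint angles and per-trial
range of motion (ROM), and ships a simulator that generates paired
recordings with known ground truth so every pipeline stage can be validated
without capture hardware.

## Hand model

The skeleton is five open chains rooted at the wrist. Non-thumb fingers
carry metacarpal base, MCP, PIP, DIP and tip landmarks (four segments); the
thumb has three bones and carries CMC, MCP, IP and tip (three segments).
Units are mm and degrees throughout.

Assumptions (deliberate simplifications):

- **Planar flexion.** Each finger flexes in the fixed plane spanned by its
  metacarpal direction and the palm normal, so every joint contributes one
  scalar angle; 0° means adjacent segments are collinear. No abduction for
  non-thumb fingers, no soft tissue, no anatomical joint axes.
- **Thumb abduction** is a rotation of the thumb chain within the palm
  plane about the CMC. It composes with CMC flexion: the three-point bend
  angle at the CMC satisfies `cos(theta) = cos(abduction) * cos(flexion)`,
  so the three-point angle equals the driven degree of freedom whenever the
  other is zero — which matches the task protocol (flexion tasks hold
  abduction at 0; the abduction task holds flexion at rest). The canonical
  inverse `angles_from_pose` disambiguates the two via the palm-plane
  azimuth and is exact for abduction in [0°, 90°) and cumulative flexion
  below 360°; it assumes the canonical palm frame (translation- but not
  rotation-invariant), unlike the three-point formula, which is invariant
  under rigid motion.
- The metacarpal fan (per-finger azimuths, wrist offsets) is fixed; its
  exact values do not enter any reported angle, because the MCP angle uses
  the wrist-to-MCP direction.

The default segment lengths use published marker-based group means for the
phalanges; non-thumb metacarpal lengths (65/63/58/53 mm, sd 5 mm in the
population model) are anatomically typical values chosen once, since no
marker-based reference exists for them.

## Task and sensor model (what the simulator emulates)

A trial is `n_cycles` (default 3) raised-cosine flexion/extension cycles
from a rest angle (default 5°) to a per-joint peak amplitude and back; the
trajectory starts and ends at rest and has exactly `n_cycles` maxima.
Movement speed is not fixed: each trial's cycle duration (default 2 s) is
scaled by a uniform draw from [0.8, 1.2]. The default protocol is 10
subjects x 2 trials x 6 dynamic tasks (flexion of each of the five fingers,
thumb abduction/adduction) plus one 3 s static trial per subject — 120
dynamic and 10 static recordings.

Each sensor is described by:

| parameter | reference default | test default | meaning |
|---|---|---|---|
| `nominal_rate` | 150 Hz | 120 Hz | mean frame rate |
| `interval_jitter_cv` | 0 | 0.1 | CV of inter-frame intervals |
| `positional_noise_sd` | 0.3 mm | 1.2 mm | isotropic Gaussian per landmark |
| `angular_bias` | none | +8° MCP, −10° PIP, −6° DIP (thumb +8/−6/−8) | additive per-joint offset |
| `dropout_prob` | 0 | 0.01 | per-frame independent drop |
| `trial_bias_sd` | 0 | 2° | per-trial random angular offset |

Inter-frame intervals are gamma-distributed with mean `1/rate` and the
stated CV (a simple strictly-positive interval law; constant when CV = 0).
Biased angles are clipped into their valid domain before rendering, which
is how the simulated tracker "flattens" full extension — and what produces
realistic magnitude-dependent (proportional) bias in ROM comparisons. The
test-system bias magnitudes are plausible placeholders expressing the
qualitative pattern reported for markerless trackers (distal joints
under-read, proximal joints over-read); they are not device measurements.
`trial_bias_sd` models pose-dependent repeatability error of the skeletal
model between attempts. Each bundle derives all randomness (geometry,
intervals, trial offsets, noise, dropout) from one seed via independent
spawned streams, so components are independently reproducible and the whole
study is bit-identical given a base seed.

Not emulated: infrared interference between systems, occlusion geometry,
true skeletal-model mechanics (the markerless tracker's joint-centre
estimation is represented only as configurable bias/noise), wrist/forearm
motion. Passing tests therefore demonstrate correctness of the *pipeline*
under a plausible error structure, not device performance on real hands.

## Stream synchronisation

The variable-rate stream's clock is rebuilt as the cumulative sum of
inter-frame intervals (leading 0). Raw timestamps are preferred when
present — they are strictly more informative — with a fallback to intervals
of `1/rate` from the device-reported rate; the path taken is recorded in
the output metadata. Resampling to the target rate (default 150 Hz) uses
linear interpolation on a grid `0, 1/rate, 2/rate, …` truncated at the
source span (never extrapolated). Linear interpolation was chosen over
splines because it is robust to jitter, exact on linear signals, and its
error is easy to bound (max error ~ h²·|x''|/8, ≈ 0.01° for these movement
speeds at 120 Hz). Gaps longer than 5x the nominal interval are logged;
dropped frames are simply absent before interpolation. Trials of different
speeds are compared on a 0–100 % duration grid with 101 points (the common
biomechanics convention).

## Kinematics and agreement

Joint angles use the three-point arccos formula with the argument clamped
to [−1, 1] against floating-point overshoot. Near 0° the arccos resolves
angles only to ~√machine-eps (≈ 1e-6°); everywhere away from 0° the
round-trip against the forward model is exact to < 1e-9°. Segment lengths
are per-frame Euclidean distances between consecutive landmarks; for the
reference system non-thumb metacarpal segments are excluded from reports,
mirroring marker-based practice.

Per-trial ROM is max − min of the angle trajectory. Study tables pool
per-trial ROM by the mean across trials and subjects (configurable to
median); the difference column is reference − test, the global sign
convention (configurable).

Bland–Altman: bias = mean difference, LoA = bias ± 1.96·sd (large-sample
multiplier), bias CI via Student t with n−1 df, proportional-bias trend via
Pearson r of (pair mean, pair difference) with a two-sided p (n−2 df);
`proportional_bias` is declared iff p < alpha strictly (default 0.05). With
constant differences r is undefined and reported as NaN with a flag, never
as 0. Each BA point is one trial's measurement; no repeated-measures LoA
correction and no multiple-testing adjustment are applied.

**Choice of per-trial measure.** A constant additive angular offset shifts
a trajectory's maximum and minimum equally, so per-trial ROM is invariant
to it. ROM is therefore the measure for study-style tables (where the
clipping-induced, magnitude-dependent error is what matters), while offset
recovery experiments use the per-trial mean angle evaluated on the two
streams' *common* resampled grid (`measure="mean"`), so that a slight span
mismatch between streams cannot masquerade as bias.

## Validation experiments

- **Null pipeline:** with positional noise, angular bias, trial offsets,
  jitter and dropout all zero — leaving only the 120 → 150 Hz rate mismatch
  — the full pipeline's BA bias stays below 0.05° and the LoA width below
  0.1° at every joint (observed ≈ 0.002° and 0.01°): the resampling stage
  itself introduces no material disagreement.
- **Offset recovery:** an additive offset b on one test-stream joint must
  be recovered as BA bias −b. This is a controlled experiment: both systems
  carry identical small positional noise (0.3 mm) so that the
  arccos-nonlinearity angle bias of noisy landmark estimation (≈ 0.15° at
  1 mm noise on ~40 mm segments, a property of the estimator rather than of
  the agreement pipeline) cancels between systems; between-trial
  variability comes from a 1° per-trial angular offset plus jitter. Over
  200 replicates of 60 trials per injected b ∈ {−20°, −10°, +10°}, the mean
  recovered bias lies within 0.05° of −b and the empirical coverage of the
  95 % bias CI is ≈ 94–95 %.
- Problem sizes were chosen as the package's own validation design:
  recovery trials are 2 cycles x 1.0 s, the null study is 4 subjects x 2
  trials x 6 tasks, and the published-table arithmetic checks run on the
  printed group values directly.

## Known limitations

- Headline per-joint biases and trend correlations of a real validation
  study cannot be reproduced from group-level printed tables: they require
  the deposited raw capture data and per-plot trial counts that are not
  recoverable; the package validates the method by construction instead.
- Positional noise induces a small upward angle bias (arccos nonlinearity)
  that grows with noise variance and differs between systems with unequal
  noise; at the default noise levels this is ≲ 0.2° and is dwarfed by the
  simulated systematic biases, but it is visible in ultra-precise settings.
- The simulator's bias model is additive in angle space; no mechanistic
  skeletal-model error, no occlusions, no cross-system interference.
- No lag alignment between streams is attempted (both streams are started
  and ended together, as in a software-synchronised capture); recordings
  with a genuine clock offset would need external alignment first.
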