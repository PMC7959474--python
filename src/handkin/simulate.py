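"""Synthetic paired hand-tracking recordings with known ground truth.

Emulates the study design this package analyses: a reference marker-based
stream at a constant 150 Hz with small isotropic positional noise, paired
with a markerless test stream at a nominal ~120 Hz whose inter-frame
intervals jitter, which may drop frames, and whose reported angles carry a
joint-dependent additive bias (the markerless tracker's skeletal model
tends to under-read distal joints and over-read proximal ones) plus a
per-trial random offset capturing pose-dependent repeatability error.

Movement tasks are flexion/extension of each finger (three smooth cycles
per trial) and thumb abduction/adduction; each cycle is a raised cosine
from the rest angle to the peak amplitude and back.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import hand
from .exceptions import ValidationError
from .hand import FINGERS, HandGeometry, NON_THUMB_FINGERS, THUMB_ABDUCTION, flexion_joints
from .recording import Recording

logger = logging.getLogger(__name__)

#: default rest angle (slightly bent, deg) for every joint
DEFAULT_REST_DEG = 5.0

#: default peak flexion amplitudes per joint role (deg)
DEFAULT_AMPLITUDES = {"mcp": 85.0, "pip": 95.0, "dip": 60.0,
                      "cmc": 45.0, "thumb_mcp": 55.0, "ip": 70.0,
                      "abduction": 50.0}

#: default additive angular bias (deg) of the test system: proximal joints
#: over-read, distal joints under-read; magnitudes are plausible placeholders,
#: not device measurements
DEFAULT_TEST_ANGULAR_BIAS: Dict[str, float] = {}
for _f in NON_THUMB_FINGERS:
    DEFAULT_TEST_ANGULAR_BIAS[f"{_f}_mcp"] = 8.0
    DEFAULT_TEST_ANGULAR_BIAS[f"{_f}_pip"] = -10.0
    DEFAULT_TEST_ANGULAR_BIAS[f"{_f}_dip"] = -6.0
DEFAULT_TEST_ANGULAR_BIAS.update({"thumb_cmc": 8.0, "thumb_mcp": -6.0, "thumb_ip": -8.0})

#: population of segment lengths (mean_mm, sd_mm) used to draw per-subject
#: skeletons; phalanges follow published marker-based group statistics,
#: non-thumb metacarpals are anatomically typical
DEFAULT_GEOMETRY_POPULATION: Dict[str, Dict[str, Tuple[float, float]]] = {
    "thumb": {"metacarpal": (38.12, 11.15), "proximal": (32.32, 11.65),
              "distal": (19.27, 10.52)},
    "index": {"metacarpal": (65.0, 5.0), "proximal": (44.89, 13.19),
              "intermediate": (25.73, 12.14), "distal": (17.08, 9.72)},
    "middle": {"metacarpal": (63.0, 5.0), "proximal": (50.59, 13.07),
               "intermediate": (30.21, 12.07), "distal": (17.71, 11.57)},
    "ring": {"metacarpal": (58.0, 5.0), "proximal": (44.90, 10.90),
             "intermediate": (28.95, 10.94), "distal": (17.40, 10.75)},
    "pinky": {"metacarpal": (53.0, 5.0), "proximal": (36.31, 3.58),
              "intermediate": (19.58, 7.96), "distal": (16.69, 8.65)},
}

_MIN_SEGMENT_MM = 5.0


@dataclass(frozen=True)
class TaskProfile:
    """One movement task: which joints move, how far, and how fast."""

    task: str
    amplitude: Mapping[str, float]        # joint -> peak angle (deg)
    rest_angle: Mapping[str, float] = field(default_factory=dict)  # joint -> rest (deg)
    n_cycles: int = 3
    cycle_duration: float = 2.0           # s per flexion/extension cycle
    target_joints: Tuple[str, ...] = ()   # joints reported for this task

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if not (self.cycle_duration > 0):
            raise ValidationError("cycle_duration must be positive")
        for joint, amp in self.amplitude.items():
            if joint not in hand.ANGLE_KEYS:
                raise ValidationError(f"unknown joint {joint!r}")
            if amp < self.rest(joint):
                raise ValidationError(f"amplitude below rest angle for {joint}")
        if not self.target_joints:
            object.__setattr__(self, "target_joints", tuple(self.amplitude))

    def rest(self, joint: str) -> float:
        return float(self.rest_angle.get(joint, DEFAULT_REST_DEG))

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    @property
    def is_static(self) -> bool:
        return all(amp == self.rest(j) for j, amp in self.amplitude.items()) or not self.amplitude

    # ---- protocol constructors -------------------------------------------------
    @classmethod
    def finger_flexion(cls, finger: str, **kw) -> "TaskProfile":
        if finger == "thumb":
            amp = {"thumb_cmc": DEFAULT_AMPLITUDES["cmc"],
                   "thumb_mcp": DEFAULT_AMPLITUDES["thumb_mcp"],
                   "thumb_ip": DEFAULT_AMPLITUDES["ip"]}
            return cls(task="thumb_flexion", amplitude=amp,
                       target_joints=flexion_joints("thumb"), **kw)
        amp = {f"{finger}_mcp": DEFAULT_AMPLITUDES["mcp"],
               f"{finger}_pip": DEFAULT_AMPLITUDES["pip"],
               f"{finger}_dip": DEFAULT_AMPLITUDES["dip"]}
        return cls(task=f"{finger}_flexion", amplitude=amp,
                   target_joints=flexion_joints(finger), **kw)

    @classmethod
    def thumb_abduction(cls, **kw) -> "TaskProfile":
        # abduction sweeps the thumb chain in the palm plane; the flexion
        # joints stay at rest, and the reported CMC bend angle tracks abduction
        return cls(task="thumb_abduction",
                   amplitude={THUMB_ABDUCTION: DEFAULT_AMPLITUDES["abduction"]},
                   rest_angle={THUMB_ABDUCTION: 0.0},
                   target_joints=flexion_joints("thumb"), **kw)

    @classmethod
    def static(cls, duration: float = 3.0) -> "TaskProfile":
        return cls(task="static", amplitude={}, n_cycles=1, cycle_duration=duration,
                   target_joints=())

    @classmethod
    def default_protocol(cls) -> Tuple["TaskProfile", ...]:
        """The six dynamic tasks: flexion of all five fingers + thumb abduction."""
        return tuple(cls.finger_flexion(f) for f in FINGERS) + (cls.thumb_abduction(),)


@dataclass(frozen=True)
class SensorModel:
    """Statistical model of one tracking system's measurement process."""

    nominal_rate: float                    # Hz
    interval_jitter_cv: float = 0.0        # CV of inter-frame intervals
    positional_noise_sd: float = 0.0       # mm, isotropic Gaussian per landmark
    angular_bias: Mapping[str, float] = field(default_factory=dict)  # deg per joint
    dropout_prob: float = 0.0              # per-frame
    trial_bias_sd: float = 0.0             # deg, per-trial random angular offset

    def __post_init__(self):
        if not (self.nominal_rate > 0):
            raise ValidationError("nominal_rate must be positive")
        if self.interval_jitter_cv < 0 or self.positional_noise_sd < 0 or self.trial_bias_sd < 0:
            raise ValidationError("jitter CV, noise sd and trial bias sd must be >= 0")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValidationError("dropout_prob must be in [0, 1)")

    @classmethod
    def reference_default(cls) -> "SensorModel":
        """Constant-rate marker-based system: 150 Hz, small positional noise."""
        return cls(nominal_rate=150.0, positional_noise_sd=0.3)

    @classmethod
    def test_default(cls) -> "SensorModel":
        """Variable-rate markerless tracker: ~120 Hz, jitter, dropouts, biased."""
        return cls(nominal_rate=120.0, interval_jitter_cv=0.1,
                   positional_noise_sd=1.2, angular_bias=dict(DEFAULT_TEST_ANGULAR_BIAS),
                   dropout_prob=0.01, trial_bias_sd=2.0)


class TruthTrajectories:
    """Noise-free ground-truth joint angles for one trial.

    Evaluates the raised-cosine task profile in closed form at arbitrary
    times, and carries a dense sampled grid for export/plotting.
    """

    def __init__(self, profile: TaskProfile, dt: float = 1.0 / 300.0,
                 cycle_duration: Optional[float] = None):
        if not (dt > 0):
            raise ValidationError("dt must be positive")
        self.profile = profile
        self.cycle_duration = float(cycle_duration or profile.cycle_duration)
        self.duration = profile.n_cycles * self.cycle_duration
        n = int(round(self.duration / dt))
        self.times = np.arange(n + 1) * dt
        if self.times[-1] > self.duration + 1e-12:
            self.times = self.times[self.times <= self.duration + 1e-12]
        self.angles = self.angles_at(self.times)

    def angles_at(self, t) -> Dict[str, np.ndarray]:
        """Closed-form joint angles (deg) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        out: Dict[str, np.ndarray] = {}
        phase = 2.0 * math.pi * t / self.cycle_duration
        bump = 0.5 * (1.0 - np.cos(phase))  # 0 at cycle boundaries, 1 mid-cycle
        for joint in hand.ANGLE_KEYS:
            rest = self.profile.rest(joint) if joint in self.profile.amplitude \
                else self.profile.rest_angle.get(joint, DEFAULT_REST_DEG)
            if joint == THUMB_ABDUCTION and joint not in self.profile.amplitude:
                rest = self.profile.rest_angle.get(joint, 0.0)
            amp = float(self.profile.amplitude.get(joint, rest))
            out[joint] = rest + (amp - rest) * bump
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for joint, values in self.angles.items():
            rows.append(pd.DataFrame({"joint": joint, "time_s": self.times,
                                      "angle_deg": values}))
        return pd.concat(rows, ignore_index=True)[["joint", "time_s", "angle_deg"]]


def generate_truth(profile: TaskProfile, geometry: Optional[HandGeometry] = None,
                   dt: float = 1.0 / 300.0,
                   cycle_duration: Optional[float] = None) -> TruthTrajectories:
    """Dense noise-free truth trajectories for one trial.

    ``geometry`` is accepted for interface symmetry (truth is purely angular).
    """
    return TruthTrajectories(profile, dt=dt, cycle_duration=cycle_duration)


def _draw_intervals(rng: np.random.Generator, rate: float, cv: float,
                    duration: float) -> np.ndarray:
    """Strictly positive inter-frame intervals with mean 1/rate and CV ``cv``.

    Gamma-distributed: shape 1/cv^2, scale cv^2/rate.
    """
    mean = 1.0 / rate
    if cv == 0.0:
        n = int(math.floor(duration / mean + 1e-9))
        return np.full(n, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    est = int(duration * rate * 1.5) + 20
    intervals = rng.gamma(shape, scale, size=est)
    while intervals.sum() < duration:
        intervals = np.concatenate([intervals, rng.gamma(shape, scale, size=est)])
    cum = np.cumsum(intervals)
    return intervals[: int(np.searchsorted(cum, duration))]


def render_stream(truth: TruthTrajectories, geometry: HandGeometry,
                  sensor: SensorModel, seed) -> Recording:
    """Render one sensor's recording of a trial.

    Frame times are cumulative sums of positive inter-frame intervals
    (constant when the jitter CV is 0); per-frame landmark positions are the
    forward kinematics of (truth angles + angular bias + per-trial offset),
    with biased angles clipped into their valid domain, plus isotropic
    Gaussian positional noise; frames are then dropped independently (first
    and last frames are always kept, so both streams span the trial).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_int, s_bias, s_noise, s_drop = [np.random.default_rng(c) for c in ss.spawn(4)]

    intervals = _draw_intervals(s_int, sensor.nominal_rate, sensor.interval_jitter_cv,
                                truth.duration)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    times = times[times <= truth.duration + 1e-12]

    trial_offset = {}
    if sensor.trial_bias_sd > 0:
        draws = s_bias.normal(0.0, sensor.trial_bias_sd, size=len(hand.ANGLE_KEYS))
        trial_offset = dict(zip(hand.ANGLE_KEYS, draws))

    angles = truth.angles_at(times)
    n_clipped = 0
    for joint in list(angles):
        a = angles[joint] + sensor.angular_bias.get(joint, 0.0) \
            + trial_offset.get(joint, 0.0)
        hi = 90.0 if joint == THUMB_ABDUCTION else 180.0
        clipped = np.clip(a, 0.0, hi - 1e-6)
        n_clipped += int(np.count_nonzero(clipped != a))
        angles[joint] = clipped
    if n_clipped:
        logger.warning("render_stream: clipped %d biased angle samples into domain",
                       n_clipped)

    positions = hand.pose_trajectory(geometry, angles, validate=False)
    if sensor.positional_noise_sd > 0:
        positions = positions + s_noise.normal(0.0, sensor.positional_noise_sd,
                                               size=positions.shape)

    if sensor.dropout_prob > 0 and times.size > 2:
        keep = s_drop.random(times.size) >= sensor.dropout_prob
        keep[0] = keep[-1] = True
    else:
        keep = slice(None)
    meta = {"sensor": {"nominal_rate": sensor.nominal_rate,
                       "interval_jitter_cv": sensor.interval_jitter_cv,
                       "positional_noise_sd": sensor.positional_noise_sd,
                       "dropout_prob": sensor.dropout_prob,
                       "trial_bias_sd": sensor.trial_bias_sd},
            "n_clipped_angles": n_clipped}
    return Recording(times[keep], hand.LANDMARKS, positions[keep],
                     nominal_rate=sensor.nominal_rate, metadata=meta)


@dataclass
class TrialBundle:
    """One trial's paired recordings plus retained ground truth."""

    reference_recording: Recording
    test_recording: Recording
    truth: TruthTrajectories
    seed: int
    metadata: Dict

    @property
    def subject(self):
        return self.metadata.get("subject")

    @property
    def task(self):
        return self.metadata.get("task")

    @property
    def trial(self):
        return self.metadata.get("trial")

    @property
    def is_static(self) -> bool:
        return self.metadata.get("task") == "static"


def draw_geometry(rng: np.random.Generator,
                  population: Optional[Mapping] = None) -> HandGeometry:
    """One subject's skeleton: independent normals truncated away from zero."""
    population = population or DEFAULT_GEOMETRY_POPULATION
    lengths: Dict[str, Dict[str, float]] = {}
    for finger in FINGERS:
        lengths[finger] = {}
        for segment in hand.finger_segments(finger):
            mean, sd = population[finger][segment]
            value = rng.normal(mean, sd)
            while value < _MIN_SEGMENT_MM:
                value = rng.normal(mean, sd)
            lengths[finger][segment] = float(value)
    return HandGeometry(lengths)


def generate_study(
    n_subjects: int = 10,
    trials_per_subject: int = 2,
    profiles: Optional[Sequence[TaskProfile]] = None,
    reference_sensor: Optional[SensorModel] = None,
    test_sensor: Optional[SensorModel] = None,
    base_seed: int = 0,
    geometry_population: Optional[Mapping] = None,
    speed_range: Tuple[float, float] = (0.8, 1.2),
    static_trials_per_subject: int = 1,
) -> List[TrialBundle]:
    """Simulate a full study: per-subject skeletons, dynamic trials of every
    task, plus static trials (hand at rest) for segment-length analysis.

    Movement speed is not fixed: each dynamic trial's cycle duration is the
    profile's value times a uniform draw from ``speed_range``.  Deterministic
    given ``base_seed``.
    """
    if n_subjects < 1 or trials_per_subject < 1 or static_trials_per_subject < 0:
        raise ValidationError("subject/trial counts must be >= 1 (static >= 0)")
    profiles = tuple(profiles if profiles is not None else TaskProfile.default_protocol())
    reference_sensor = reference_sensor or SensorModel.reference_default()
    test_sensor = test_sensor or SensorModel.test_default()

    root = np.random.SeedSequence(base_seed)
    bundles: List[TrialBundle] = []
    for subj_idx, subj_ss in enumerate(root.spawn(n_subjects), start=1):
        geom_ss, trial_root = subj_ss.spawn(2)
        geometry = draw_geometry(np.random.default_rng(geom_ss), geometry_population)
        static_profiles = tuple(TaskProfile.static()
                                for _ in range(static_trials_per_subject))
        task_list = [(p, t) for t in range(1, trials_per_subject + 1) for p in profiles]
        task_list += [(p, t) for t, p in enumerate(static_profiles, start=1)]
        trial_sss = trial_root.spawn(len(task_list))
        for (profile, trial_idx), trial_ss in zip(task_list, trial_sss):
            speed_ss, ref_ss, test_ss = trial_ss.spawn(3)
            rng = np.random.default_rng(speed_ss)
            if profile.is_static:
                cyc = profile.cycle_duration
            else:
                cyc = profile.cycle_duration * rng.uniform(*speed_range)
            truth = TruthTrajectories(profile, cycle_duration=cyc)
            ref = render_stream(truth, geometry, reference_sensor, ref_ss)
            test = render_stream(truth, geometry, test_sensor, test_ss)
            seed_int = int(trial_ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
            bundles.append(TrialBundle(
                reference_recording=ref, test_recording=test, truth=truth,
                seed=seed_int,
                metadata={"subject": subj_idx, "task": profile.task,
                          "trial": trial_idx,
                          "target_joints": list(profile.target_joints),
                          "cycle_duration_s": cyc},
            ))
    return bundles
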