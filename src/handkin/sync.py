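"""Timeline reconstruction, uniform resampling and time normalisation.

A variable-rate stream is put on a uniform clock in two steps: (1) rebuild a
time vector as the cumulative sum of inter-frame intervals (from raw
timestamps when present, else from the device-reported instantaneous rate),
then (2) linearly interpolate every coordinate onto a uniform grid at the
target rate (150 Hz by default, matching the reference system).  Trials of
different speeds are compared after resampling onto a 0-100% duration grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InsufficientDataError, NonMonotonicTimeError, ValidationError
from .kinematics import AngleTrajectory
from .recording import Recording

logger = logging.getLogger(__name__)

#: gaps longer than this multiple of the nominal interval are logged
GAP_WARN_FACTOR = 5.0


@dataclass
class SamplingTimeline:
    """A stream's rebuilt uniform-origin clock."""

    raw_times: Optional[np.ndarray]       # s, as recorded (None if absent)
    instantaneous_intervals: np.ndarray   # s, one per inter-frame step
    rebuilt_times: np.ndarray             # s, cumulative sum with leading 0
    source: str                           # "timestamps" | "reported_rate"

    @property
    def n_frames(self) -> int:
        return int(self.rebuilt_times.size)

    @property
    def mean_rate(self) -> float:
        return 1.0 / float(np.mean(self.instantaneous_intervals))

    @property
    def rate_cv(self) -> float:
        iv = self.instantaneous_intervals
        return float(np.std(iv) / np.mean(iv))


def build_time_vector(recording: Recording) -> SamplingTimeline:
    """Rebuild the stream clock as the aggregation of inter-frame intervals.

    Raw timestamps are preferred when present (strictly more informative);
    otherwise intervals fall back to 1/rate from the device-reported nominal
    rate.  The rebuilt vector starts at 0 and telescopes to the raw duration.
    """
    n = recording.n_frames
    if n < 2:
        raise InsufficientDataError(f"need >= 2 frames to build a time vector, got {n}")
    if recording.times.size == n and np.all(np.isfinite(recording.times)):
        intervals = np.diff(recording.times)
        bad = np.nonzero(intervals <= 0)[0]
        if bad.size:
            raise NonMonotonicTimeError(int(bad[0]) + 1)
        raw: Optional[np.ndarray] = recording.times
        source = "timestamps"
    else:
        if not recording.nominal_rate:
            raise ValidationError("no timestamps and no device-reported rate")
        intervals = np.full(n - 1, 1.0 / float(recording.nominal_rate))
        raw = None
        source = "reported_rate"
    rebuilt = np.concatenate([[0.0], np.cumsum(intervals)])
    if recording.nominal_rate:
        gap = GAP_WARN_FACTOR / float(recording.nominal_rate)
        n_gaps = int(np.count_nonzero(intervals > gap))
        if n_gaps:
            logger.warning("timeline: %d gaps exceed %.0fx the nominal interval",
                           n_gaps, GAP_WARN_FACTOR)
    return SamplingTimeline(raw_times=raw, instantaneous_intervals=intervals,
                            rebuilt_times=rebuilt, source=source)


def resample_uniform(recording: Recording, timeline: Optional[SamplingTimeline] = None,
                     target_rate: float = 150.0) -> Recording:
    """Resample every coordinate onto a uniform grid at ``target_rate`` Hz.

    The grid runs 0, 1/rate, 2/rate, ... up to the last rebuilt time; values
    are linearly interpolated between bracketing source frames and the grid
    never extends beyond the source span (truncation, not extrapolation).
    """
    if not (target_rate > 0):
        raise ValidationError("target_rate must be positive")
    if timeline is None:
        timeline = build_time_vector(recording)
    span = float(timeline.rebuilt_times[-1])
    step = 1.0 / float(target_rate)
    n_out = int(np.floor(span / step + 1e-9))
    new_times = np.arange(n_out + 1) * step
    flat = recording.positions.reshape(recording.n_frames, -1)
    out = np.empty((new_times.size, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(new_times, timeline.rebuilt_times, flat[:, j])
    meta = dict(recording.metadata)
    meta.update({
        "resampled_hz": float(target_rate),
        "timeline_source": timeline.source,
        "source_rate_mean": timeline.mean_rate,
        "source_rate_cv": timeline.rate_cv,
    })
    return Recording(new_times, recording.landmarks,
                     out.reshape(new_times.size, len(recording.landmarks), 3),
                     nominal_rate=float(target_rate), metadata=meta)


def time_normalize(trajectory: AngleTrajectory, n_points: int = 101) -> AngleTrajectory:
    """Resample a trajectory onto ``n_points`` equally spaced fractions of
    its duration (0-100%); endpoints are preserved exactly.

    The output's ``times`` field holds the percent grid.
    """
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if trajectory.times.size < 2:
        raise InsufficientDataError("need >= 2 samples to time-normalise")
    t0, t1 = float(trajectory.times[0]), float(trajectory.times[-1])
    frac = np.linspace(0.0, 1.0, n_points)
    sample_times = t0 + frac * (t1 - t0)
    values = np.interp(sample_times, trajectory.times, trajectory.angles)
    values[0] = trajectory.angles[0]
    values[-1] = trajectory.angles[-1]
    return AngleTrajectory(joint=trajectory.joint, times=frac * 100.0, angles=values,
                           meta={**trajectory.meta, "time_normalized": True})
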