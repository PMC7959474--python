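"""Joint angles, segment lengths and range of motion from landmark recordings.

The bend angle at a joint B between neighbouring landmarks A and C is

    theta = arccos( (B-A).(C-B) / (|B-A| |C-B|) )   in degrees,

i.e. the deviation of the distal segment from the proximal segment's line:
0 deg is a straight chain, and the value is taken as the flexion angle
directly (no 180-degree complement).  The MCP angle of a non-thumb finger
uses the wrist-to-MCP direction as its proximal segment; the thumb's CMC,
MCP and IP angles use its own three-bone chain.  Segment lengths are
per-frame Euclidean distances between consecutive landmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import hand
from .exceptions import DegenerateGeometryError, InsufficientDataError, ValidationError
from .recording import Recording

logger = logging.getLogger(__name__)


@dataclass
class AngleTrajectory:
    """Per-joint time series of angles (degrees)."""

    joint: str
    times: np.ndarray
    angles: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValidationError("times and angles must have equal length")


@dataclass
class RomRecord:
    """Range of motion of one joint over one trial."""

    joint: str
    rom: float
    angle_max: float
    angle_min: float
    subject: Optional[int] = None
    task: Optional[str] = None
    trial: Optional[int] = None


@dataclass
class SegmentLengthRecord:
    """Per-frame lengths (mm) of one finger segment, with summary statistics."""

    finger: str
    segment: str
    lengths: np.ndarray
    mean: float
    sd: float
    degenerate: bool = False


def joint_angle(a, b, c) -> float:
    """Bend angle (deg) at ``b`` formed by points ``a -> b -> c``.

    Vectorised over leading axes; the arccos argument is clamped to [-1, 1]
    to guard floating-point overshoot on near-collinear points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = b - a
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0.0) or np.any(nv == 0.0):
        scalar = nu.ndim == 0
        bad = 0 if scalar else int(np.nonzero((nu == 0.0) | (nv == 0.0))[0][0])
        raise DegenerateGeometryError("segment vector", frame=None if scalar else bad)
    cosang = np.clip(np.sum(u * v, axis=-1) / (nu * nv), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if ang.ndim == 0 else ang


def angle_trajectories(recording: Recording,
                       joints: Optional[Iterable[str]] = None,
                       ) -> Dict[str, AngleTrajectory]:
    """Per-joint bend-angle trajectories on the recording's own time base.

    Frames where any required landmark is non-finite are skipped for that
    joint (with a warning); a joint whose landmarks are entirely missing
    raises.
    """
    wanted = tuple(joints) if joints is not None else hand.FLEXION_JOINTS
    out: Dict[str, AngleTrajectory] = {}
    for joint in wanted:
        if joint not in hand.JOINT_TRIPLES:
            raise ValidationError(f"unknown joint {joint!r}")
        names = hand.JOINT_TRIPLES[joint]
        try:
            pts = [recording.position_of(n) for n in names]
        except KeyError as exc:
            raise ValidationError(f"joint {joint}: {exc}") from exc
        finite = np.all([np.all(np.isfinite(p), axis=1) for p in pts], axis=0)
        if not np.any(finite):
            raise InsufficientDataError(f"joint {joint}: no frames with all landmarks")
        if not np.all(finite):
            logger.warning("joint %s: skipping %d frames with missing landmarks",
                           joint, int(np.count_nonzero(~finite)))
        out[joint] = AngleTrajectory(
            joint=joint,
            times=recording.times[finite],
            angles=joint_angle(pts[0][finite], pts[1][finite], pts[2][finite]),
        )
    return out


def segment_lengths(recording: Recording,
                    metacarpals: str = "all") -> List[SegmentLengthRecord]:
    """Per-frame Euclidean segment lengths with mean and sample sd.

    ``metacarpals='thumb_only'`` reproduces the marker-based reporting rule
    where non-thumb metacarpal segments are not considered.
    """
    if metacarpals not in ("all", "thumb_only"):
        raise ValidationError("metacarpals must be 'all' or 'thumb_only'")
    records: List[SegmentLengthRecord] = []
    for finger in hand.FINGERS:
        chain = (hand.WRIST,) + hand.finger_landmarks(finger)
        pairs = list(zip(chain[1:-1], chain[2:]))  # base->...->tip
        for segment, (p, q) in zip(hand.finger_segments(finger), pairs):
            if segment == "metacarpal" and metacarpals == "thumb_only" and finger != "thumb":
                continue
            d = recording.position_of(q) - recording.position_of(p)
            lengths = np.linalg.norm(d, axis=1)
            finite = np.isfinite(lengths)
            lengths = lengths[finite]
            degenerate = bool(np.any(lengths == 0.0))
            if degenerate:
                logger.warning("segment %s/%s: zero length in %d frames",
                               finger, segment, int(np.count_nonzero(lengths == 0.0)))
            sd = float(np.std(lengths, ddof=1)) if lengths.size > 1 else 0.0
            records.append(SegmentLengthRecord(
                finger=finger, segment=segment, lengths=lengths,
                mean=float(np.mean(lengths)), sd=sd, degenerate=degenerate))
    return records


def rom(trajectory: AngleTrajectory, subject=None, task=None, trial=None) -> RomRecord:
    """Range of motion: max minus min angle over the trial."""
    if trajectory.angles.size < 2:
        raise InsufficientDataError("ROM needs >= 2 samples")
    amax = float(np.max(trajectory.angles))
    amin = float(np.min(trajectory.angles))
    return RomRecord(joint=trajectory.joint, rom=amax - amin,
                     angle_max=amax, angle_min=amin,
                     subject=subject, task=task, trial=trial)


def rom_difference(rom_reference: float, rom_test: float) -> float:
    """Reference-minus-test ROM difference (deg), the study's sign convention."""
    if rom_reference < 0 or rom_test < 0:
        raise ValidationError("ROM values must be non-negative")
    return float(rom_reference) - float(rom_test)


def segment_table(records: Sequence[SegmentLengthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"finger": r.finger, "segment": r.segment, "mean_mm": r.mean,
          "sd_mm": r.sd, "n_frames": r.lengths.size, "degenerate": r.degenerate}
         for r in records]
    )
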