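"""Hand landmark topology, skeletal geometry and forward kinematics.

The hand is modelled as five open kinematic chains rooted at the wrist.
Coordinate frame (right hand, palm down over the sensor): the palm lies in
the X-Z plane, +Z points from the wrist towards the middle-finger metacarpal,
+X from the ulnar to the radial side, and +Y is the palm normal.  Each
non-thumb finger carries five landmarks (metacarpal base, MCP, PIP, DIP,
tip); the thumb has only three bones (metacarpal, proximal and distal
phalanx) and therefore four landmarks (CMC, MCP, IP, tip).

Flexion is planar: every finger flexes in the fixed plane spanned by its
metacarpal direction and the palm normal, so each joint contributes a single
scalar flexion angle (0 deg = adjacent segments collinear, i.e. a straight
finger).  Thumb abduction is an additional rotation of the thumb chain
within the palm plane about the CMC.  Units are millimetres and degrees
throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

from .exceptions import AngleRangeError, ValidationError

FINGERS: Tuple[str, ...] = ("thumb", "index", "middle", "ring", "pinky")
NON_THUMB_FINGERS: Tuple[str, ...] = FINGERS[1:]

THUMB_SEGMENTS: Tuple[str, ...] = ("metacarpal", "proximal", "distal")
FINGER_SEGMENTS: Tuple[str, ...] = ("metacarpal", "proximal", "intermediate", "distal")

WRIST = "wrist"


def finger_landmarks(finger: str) -> Tuple[str, ...]:
    """Ordered landmark chain of one finger, wrist excluded, base to tip."""
    if finger == "thumb":
        return ("thumb_cmc", "thumb_mcp", "thumb_ip", "thumb_tip")
    return (f"{finger}_base", f"{finger}_mcp", f"{finger}_pip",
            f"{finger}_dip", f"{finger}_tip")


LANDMARKS: Tuple[str, ...] = (WRIST,) + tuple(
    name for f in FINGERS for name in finger_landmarks(f)
)
LANDMARK_INDEX: Dict[str, int] = {name: i for i, name in enumerate(LANDMARKS)}


def finger_segments(finger: str) -> Tuple[str, ...]:
    return THUMB_SEGMENTS if finger == "thumb" else FINGER_SEGMENTS


def flexion_joints(finger: str) -> Tuple[str, ...]:
    """Flexion joint labels of one finger, proximal to distal."""
    if finger == "thumb":
        return ("thumb_cmc", "thumb_mcp", "thumb_ip")
    return (f"{finger}_mcp", f"{finger}_pip", f"{finger}_dip")


FLEXION_JOINTS: Tuple[str, ...] = tuple(j for f in FINGERS for j in flexion_joints(f))
THUMB_ABDUCTION = "thumb_abduction"
ANGLE_KEYS: Tuple[str, ...] = FLEXION_JOINTS + (THUMB_ABDUCTION,)

#: landmark triple (a, b, c) whose bend angle at b defines each flexion joint
JOINT_TRIPLES: Dict[str, Tuple[str, str, str]] = {}
for _f in FINGERS:
    _chain = (WRIST,) + finger_landmarks(_f)
    # skip the metacarpal base of non-thumb fingers: the MCP angle is defined
    # from the wrist-to-MCP direction, not from the base marker
    _angle_chain = _chain if _f == "thumb" else (_chain[0],) + _chain[2:]
    for _j, _name in enumerate(flexion_joints(_f)):
        JOINT_TRIPLES[_name] = (_angle_chain[_j], _angle_chain[_j + 1], _angle_chain[_j + 2])

#: palm-plane azimuth of each finger's metacarpal direction, degrees from +Z
#: towards +X (radial); the exact fan placement does not enter the joint angles
AZIMUTH_DEG: Dict[str, float] = {
    "thumb": 55.0, "index": 15.0, "middle": 0.0, "ring": -12.0, "pinky": -25.0,
}
#: wrist-to-(metacarpal base | CMC) offset along the fan direction, mm
BASE_OFFSET_MM: Dict[str, float] = {
    "thumb": 25.0, "index": 15.0, "middle": 15.0, "ring": 15.0, "pinky": 15.0,
}

_PALM_NORMAL = np.array([0.0, 1.0, 0.0])

#: typical adult segment lengths (mm) used as the default skeleton; phalanx
#: values follow published marker-based group means, non-thumb metacarpals are
#: anatomically typical values (no marker-based reference is available)
DEFAULT_SEGMENT_LENGTHS_MM: Dict[str, Dict[str, float]] = {
    "thumb": {"metacarpal": 38.12, "proximal": 32.32, "distal": 19.27},
    "index": {"metacarpal": 65.0, "proximal": 44.89, "intermediate": 25.73, "distal": 17.08},
    "middle": {"metacarpal": 63.0, "proximal": 50.59, "intermediate": 30.21, "distal": 17.71},
    "ring": {"metacarpal": 58.0, "proximal": 44.90, "intermediate": 28.95, "distal": 17.40},
    "pinky": {"metacarpal": 53.0, "proximal": 36.31, "intermediate": 19.58, "distal": 16.69},
}


@dataclass(frozen=True)
class HandGeometry:
    """Per-finger segment lengths (mm) defining a rigid hand skeleton."""

    segment_lengths: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        for finger in FINGERS:
            if finger not in self.segment_lengths:
                raise ValidationError(f"missing finger {finger!r} in geometry")
            segs = self.segment_lengths[finger]
            expected = finger_segments(finger)
            if set(segs) != set(expected):
                raise ValidationError(
                    f"finger {finger!r} must define segments {expected}, got {tuple(segs)}"
                )
            for seg, length in segs.items():
                if not (float(length) > 0.0):
                    raise ValidationError(
                        f"segment length must be strictly positive: {finger}/{seg} = {length}"
                    )

    @classmethod
    def default(cls) -> "HandGeometry":
        return cls({f: dict(s) for f, s in DEFAULT_SEGMENT_LENGTHS_MM.items()})

    def length(self, finger: str, segment: str) -> float:
        return float(self.segment_lengths[finger][segment])

    def to_json(self, path=None) -> str:
        payload = json.dumps({f: dict(s) for f, s in self.segment_lengths.items()},
                             indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "HandGeometry":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (ValueError, TypeError):
                with open(source, "r", encoding="utf-8") as fh:
                    data = json.load(fh)
        return cls(data)


@dataclass(frozen=True)
class JointAngleSet:
    """A full set of joint angles (degrees).

    Keys are the 15 flexion joints plus ``thumb_abduction``; missing joints
    default to 0 deg.  Flexion angles live in [0, 180): 0 means the adjacent
    segments are collinear.  Thumb abduction lives in [0, 90).
    """

    angles: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for key, value in self.angles.items():
            if key not in ANGLE_KEYS:
                raise ValidationError(f"unknown joint {key!r}")
            v = float(value)
            hi = 90.0 if key == THUMB_ABDUCTION else 180.0
            if not (0.0 <= v < hi):
                raise AngleRangeError(f"{key} = {v} deg outside [0, {hi:g})")

    def __getitem__(self, joint: str) -> float:
        return float(self.angles.get(joint, 0.0))

    def as_dict(self) -> Dict[str, float]:
        return {k: self[k] for k in ANGLE_KEYS}


def _fan_direction(azimuth_rad):
    """Unit palm-plane direction(s) at the given azimuth(s) from +Z towards +X."""
    az = np.asarray(azimuth_rad, dtype=float)
    return np.stack([np.sin(az), np.zeros_like(az), np.cos(az)], axis=-1)


def _flexed_direction(base_dir: np.ndarray, cum_flexion_rad: np.ndarray) -> np.ndarray:
    """Rotate the palm-plane direction towards -Y (palmar) by the cumulative flexion."""
    c = np.cos(cum_flexion_rad)[..., None]
    s = np.sin(cum_flexion_rad)[..., None]
    return c * base_dir - s * _PALM_NORMAL


def pose_trajectory(
    geometry: HandGeometry,
    angles: Mapping[str, np.ndarray],
    wrist_origin: Sequence[float] = (0.0, 0.0, 0.0),
    validate: bool = True,
) -> np.ndarray:
    """Vectorised forward kinematics over a sequence of poses.

    Parameters
    ----------
    angles
        Mapping joint label -> array of angles in degrees, one value per
        frame (missing joints are held at 0 deg).  All arrays must share one
        length ``n``.

    Returns
    -------
    ndarray of shape (n, len(LANDMARKS), 3), positions in mm ordered as
    :data:`LANDMARKS`.
    """
    lengths = {}
    for key, arr in angles.items():
        if key not in ANGLE_KEYS:
            raise ValidationError(f"unknown joint {key!r}")
        lengths[key] = np.size(arr)
    n = max(lengths.values(), default=1)
    if any(m not in (1, n) for m in lengths.values()):
        raise ValidationError("angle arrays must share a common length")

    def ang(joint):
        a = np.asarray(angles.get(joint, 0.0), dtype=float)
        a = np.broadcast_to(np.atleast_1d(a), (n,))
        if validate:
            hi = 90.0 if joint == THUMB_ABDUCTION else 180.0
            if np.any(a < 0.0) or np.any(a >= hi):
                raise AngleRangeError(f"{joint} outside [0, {hi:g}) deg")
        return np.radians(a)

    origin = np.asarray(wrist_origin, dtype=float).reshape(1, 3)
    out = np.empty((n, len(LANDMARKS), 3), dtype=float)
    out[:, LANDMARK_INDEX[WRIST]] = origin

    for finger in FINGERS:
        az0 = math.radians(AZIMUTH_DEG[finger])
        d0 = _fan_direction(az0)  # fixed wrist->base direction
        chain = finger_landmarks(finger)
        if finger == "thumb":
            az = az0 + ang(THUMB_ABDUCTION)
            d = _fan_direction(az)  # abducted flexion-plane direction, (n, 3)
            base = origin + BASE_OFFSET_MM[finger] * d0
            out[:, LANDMARK_INDEX[chain[0]]] = base
            prev = np.broadcast_to(base, (n, 3)).copy()
            cum = np.zeros(n)
            for joint, segment, landmark in zip(
                flexion_joints(finger), THUMB_SEGMENTS, chain[1:]
            ):
                cum = cum + ang(joint)
                prev = prev + geometry.length(finger, segment) * _flexed_direction(d, cum)
                out[:, LANDMARK_INDEX[landmark]] = prev
        else:
            base = origin + BASE_OFFSET_MM[finger] * d0
            out[:, LANDMARK_INDEX[chain[0]]] = base
            mcp = base + geometry.length(finger, "metacarpal") * d0
            out[:, LANDMARK_INDEX[chain[1]]] = mcp
            prev = np.broadcast_to(mcp, (n, 3)).copy()
            cum = np.zeros(n)
            for joint, segment, landmark in zip(
                flexion_joints(finger), FINGER_SEGMENTS[1:], chain[2:]
            ):
                cum = cum + ang(joint)
                prev = prev + geometry.length(finger, segment) * _flexed_direction(d0, cum)
                out[:, LANDMARK_INDEX[landmark]] = prev
    return out


def forward_pose(
    geometry: HandGeometry,
    angles: "JointAngleSet | Mapping[str, float]",
    wrist_origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Dict[str, np.ndarray]:
    """Landmark positions (mm) of a single posed hand.

    Consecutive-landmark distances equal the configured segment lengths, and
    re-deriving angles from the returned positions reproduces the input
    angles (see :func:`angles_from_pose`).
    """
    if isinstance(angles, JointAngleSet):
        mapping = angles.as_dict()
    else:
        mapping = JointAngleSet(dict(angles)).as_dict()  # validates
    pos = pose_trajectory(geometry, {k: np.array([v]) for k, v in mapping.items()},
                          wrist_origin)
    return {name: pos[0, i] for i, name in enumerate(LANDMARKS)}


def _planar_flexion(v: np.ndarray, plane_dir: np.ndarray) -> np.ndarray:
    """Flexion angle (rad) of segment direction ``v`` relative to ``plane_dir``.

    Assumes ``v`` lies in the plane spanned by ``plane_dir`` and the palm
    normal; atan2 keeps the recovery well conditioned near 0 deg.
    """
    return np.arctan2(-v[..., 1], np.sum(v * plane_dir, axis=-1))


def angles_from_pose(pose: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Exact inverse of :func:`forward_pose` in the canonical palm frame.

    Recovers all 15 flexion angles plus thumb abduction.  Translation
    invariant; unlike the three-point joint-angle formula it is *not*
    rotation invariant, because it decomposes the thumb's composite
    CMC rotation into abduction (palm-plane azimuth) and flexion.
    """
    def vec(a, b):
        return np.asarray(pose[b], dtype=float) - np.asarray(pose[a], dtype=float)

    out: Dict[str, float] = {}
    for finger in FINGERS:
        chain = finger_landmarks(finger)
        if finger == "thumb":
            # the palm-plane projection of the metacarpal flips sign once CMC
            # flexion passes 90 deg, so pick the azimuth candidate that puts
            # abduction into its admissible [0, 90) range (unique there)
            v_meta = vec(chain[0], chain[1])
            azimuth = math.degrees(math.atan2(v_meta[0], v_meta[2]))
            abduction = azimuth - AZIMUTH_DEG["thumb"]
            for shift in (0.0, 360.0, -360.0, 180.0, -180.0):
                if -1e-9 <= abduction + shift < 90.0:
                    abduction += shift
                    break
            out[THUMB_ABDUCTION] = abduction
            d = _fan_direction(math.radians(AZIMUTH_DEG["thumb"] + abduction))
            segs = [vec(a, b) for a, b in zip(chain[:-1], chain[1:])]
        else:
            d = _fan_direction(math.radians(AZIMUTH_DEG[finger]))
            segs = [vec(a, b) for a, b in zip(chain[1:-1], chain[2:])]
        cum_prev = 0.0
        for joint, v in zip(flexion_joints(finger), segs):
            u = v / np.linalg.norm(v)
            cum = math.degrees(_planar_flexion(u, d))
            if cum < -1e-9:
                cum += 360.0
            out[joint] = cum - cum_prev
            cum_prev = cum
    return out
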