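"""The :class:`Recording` container and its CSV dialect.

A recording is an ordered sequence of time-stamped landmark frames from one
tracking system.  The interchange format is a wide CSV: column 1 ``time_s``,
then ``<landmark>_x_mm``, ``<landmark>_y_mm``, ``<landmark>_z_mm`` per
landmark; a missing (dropped) frame is simply an absent row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class Recording:
    times: np.ndarray                   # (n,) seconds
    landmarks: Tuple[str, ...]          # length L
    positions: np.ndarray               # (n, L, 3) mm
    nominal_rate: Optional[float] = None  # Hz as reported by the device
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.landmarks = tuple(self.landmarks)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.positions.shape != (self.times.size, len(self.landmarks), 3):
            raise ValidationError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{self.times.size} frames x {len(self.landmarks)} landmarks"
            )

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames else 0.0

    def landmark_index(self, name: str) -> int:
        try:
            return self.landmarks.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not in recording") from None

    def position_of(self, name: str) -> np.ndarray:
        """(n, 3) trajectory of one landmark."""
        return self.positions[:, self.landmark_index(name), :]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        for i, name in enumerate(self.landmarks):
            for j, axis in enumerate("xyz"):
                data[f"{name}_{axis}_mm"] = self.positions[:, i, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, nominal_rate: Optional[float] = None,
                   metadata: Optional[dict] = None) -> "Recording":
        if "time_s" not in df.columns:
            raise ValidationError("recording table must have a 'time_s' column")
        names = []
        for col in df.columns:
            if col.endswith("_x_mm"):
                names.append(col[: -len("_x_mm")])
        if not names:
            raise ValidationError("no landmark columns (*_x_mm) found")
        pos = np.empty((len(df), len(names), 3))
        for i, name in enumerate(names):
            for j, axis in enumerate("xyz"):
                col = f"{name}_{axis}_mm"
                if col not in df.columns:
                    raise ValidationError(f"missing coordinate column {col!r}")
                pos[:, i, j] = df[col].to_numpy(dtype=float)
        return cls(df["time_s"].to_numpy(dtype=float), tuple(names), pos,
                   nominal_rate=nominal_rate, metadata=dict(metadata or {}))

    @classmethod
    def from_csv(cls, path, nominal_rate: Optional[float] = None,
                 metadata: Optional[dict] = None) -> "Recording":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # surface the offending file
            raise ValidationError(f"cannot parse recording CSV {path}: {exc}") from exc
        return cls.from_frame(df, nominal_rate=nominal_rate, metadata=metadata)

    def with_frames(self, mask_or_index) -> "Recording":
        """New recording restricted to the selected frames (metadata shared)."""
        return Recording(self.times[mask_or_index], self.landmarks,
                         self.positions[mask_or_index], nominal_rate=self.nominal_rate,
                         metadata=dict(self.metadata))
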