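"""Exception hierarchy."""


class HandkinError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HandkinError, ValueError):
    """Invalid configuration or construction input (e.g. non-positive segment length)."""


class AngleRangeError(HandkinError, ValueError):
    """A joint angle lies outside its admissible domain."""


class InsufficientDataError(HandkinError, ValueError):
    """Too few frames/samples for the requested operation."""


class NonMonotonicTimeError(HandkinError, ValueError):
    """Timestamps are not strictly increasing; carries the offending index."""

    def __init__(self, index: int, message: str | None = None):
        self.index = index
        super().__init__(message or f"timestamps not strictly increasing at index {index}")


class DegenerateGeometryError(HandkinError, ValueError):
    """Zero-length segment vector; carries the frame index and joint/segment label."""

    def __init__(self, label: str, frame: int | None = None, message: str | None = None):
        self.label = label
        self.frame = frame
        where = f" at frame {frame}" if frame is not None else ""
        super().__init__(message or f"degenerate geometry for {label}{where}")
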