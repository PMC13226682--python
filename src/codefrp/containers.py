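"""Core data containers shared across the pipeline.

Conventions: time is milliseconds from trial (snippet) onset unless a
field says otherwise; gaze coordinates are screen pixels with the origin
at the top-left corner and y increasing downward; EEG amplitudes are
microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# --------------------------------------------------------------------------
# stimulus layout


@dataclass(frozen=True)
class LineBox:
    """Bounding box of one code line, with an informativeness flag.

    Lines holding no execution-relevant content (e.g. a lone brace) are
    marked uninformative; the informative-only correction variants drop
    them from the candidate set.
    """

    x0: float
    y0: float
    x1: float
    y1: float
    informative: bool = True

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate line box")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2)

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate rectangle")

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive point membership."""
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class StimulusLayout:
    """One snippet's on-screen geometry: ordered line boxes plus one AOI."""

    snippet_id: str
    lines: tuple[LineBox, ...]
    aoi: Rect
    screen: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if len(self.lines) < 1:
            raise ValueError("layout needs at least one line")
        for a, b in zip(self.lines, self.lines[1:]):
            if b.y0 < a.y1:
                raise ValueError("line boxes must be vertically ordered, non-overlapping")
        if not any(ln.informative for ln in self.lines):
            raise ValueError("layout needs at least one informative line")
        aoi_cx = (self.aoi.x0 + self.aoi.x1) / 2
        aoi_cy = (self.aoi.y0 + self.aoi.y1) / 2
        on_informative = any(
            ln.informative and ln.contains(aoi_cx, aoi_cy) for ln in self.lines
        )
        if not on_informative:
            raise ValueError("AOI must sit on an informative line")

    @property
    def line_height(self) -> float:
        return float(np.median([ln.height for ln in self.lines]))

    def line_centers_y(self, informative_only: bool = False) -> np.ndarray:
        return np.array(
            [ln.center[1] for ln in self.lines if ln.informative or not informative_only]
        )

    def candidate_line_indices(self, informative_only: bool = False) -> list[int]:
        return [
            i for i, ln in enumerate(self.lines) if ln.informative or not informative_only
        ]


# --------------------------------------------------------------------------
# gaze


@dataclass
class GazeStream:
    """Uniformly sampled gaze positions for one trial.

    Invalid samples (tracking loss) keep their slot with NaN coordinates;
    they are never silently dropped.
    """

    trial_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("gaze arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            step = 1000.0 / self.rate_hz
            if not np.allclose(dt, step, rtol=1e-6, atol=1e-6):
                raise ValueError("timestamps must be uniform at rate_hz")
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return len(self) * 1000.0 / self.rate_hz


@dataclass(frozen=True)
class QCResult:
    retained: bool
    missing_fraction: float
    longest_gap_ms: float
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.retained != (len(self.reasons) == 0):
            raise ValueError("retained must mirror empty reasons")


@dataclass(frozen=True)
class Fixation:
    """One fixation: a stationary gaze interval with a spatial centroid."""

    onset_ms: float
    offset_ms: float
    x: float
    y: float
    line_index: int | None = None
    in_aoi: bool = False

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class FixationSequence:
    """Ordered, disjoint fixations of one trial, plus correction metadata."""

    trial_id: str
    fixations: tuple[Fixation, ...]
    correction_method: str = "none"
    offset_applied: tuple[float, float] = (0.0, 0.0)
    all_invalid: bool = False  # warning flag: detection saw no valid data

    def __post_init__(self) -> None:
        for a, b in zip(self.fixations, self.fixations[1:]):
            if b.onset_ms < a.offset_ms:
                raise ValueError("fixations must be time-ordered and disjoint")

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    def with_fixations(self, fixations, method: str | None = None) -> "FixationSequence":
        return replace(
            self,
            fixations=tuple(fixations),
            correction_method=self.correction_method if method is None else method,
        )


# --------------------------------------------------------------------------
# EEG


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts with event markers.

    data is channels x samples; events are (label, sample_index) pairs.
    reference is the current reference scheme of the data.
    """

    channels: tuple[str, ...]
    rate_hz: float
    data: np.ndarray
    events: tuple[tuple[str, int], ...] = ()
    reference: str = "left_mastoid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data rows must match channel count")
        for label, s in self.events:
            if not 0 <= s < self.data.shape[1]:
                raise ValueError(f"event {label!r} at sample {s} out of range")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in recording") from None

    def get(self, channel: str) -> np.ndarray:
        return self.data[self.index(channel)]


@dataclass
class Epoch:
    """One fixation- (or stimulus-) locked EEG segment.

    times_ms spans window_ms inclusive on both ends; verdict is "accepted"
    or "rejected"; reasons lists the violated artifact criteria.
    """

    trial_id: str
    condition: str
    channels: tuple[str, ...]
    times_ms: np.ndarray
    data: np.ndarray
    window_ms: tuple[float, float] = (-300.0, 1000.0)
    baseline_window_ms: tuple[float, float] = (-300.0, 0.0)
    verdict: str = "accepted"
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (len(self.channels), len(self.times_ms)):
            raise ValueError("epoch data must be channels x times")


@dataclass
class ParticipantAverage:
    participant: object
    condition: str
    channels: tuple[str, ...]
    times_ms: np.ndarray
    data: np.ndarray
    n_epochs: int

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("average needs at least one epoch")


@dataclass
class DifferenceWaveSet:
    """Per-participant (confusing - clean) averages on a common grid.

    data is participants x channels x times.
    """

    participants: tuple[object, ...]
    channels: tuple[str, ...]
    times_ms: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (
            len(self.participants),
            len(self.channels),
            len(self.times_ms),
        ):
            raise ValueError("difference data must be participants x channels x times")

    @property
    def n(self) -> int:
        return len(self.participants)
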