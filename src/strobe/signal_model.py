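"""Shared domain types and trace utilities.

The capacitance signal produced by a fly-feeding arena is a uniformly
sampled stream of integer sensor counts (one channel per food source).
Everything downstream — the closed-loop detector, the simulator and the
feeding analytics — works on :class:`CapacitanceTrace` objects and the
whole-sample time arithmetic defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError, SessionMismatchError

__all__ = [
    "Channel",
    "CapacitanceTrace",
    "DetectorParams",
    "InteractionEvent",
    "LedTimeline",
    "to_samples",
    "validate_session",
]


class Channel(str, enum.Enum):
    """The two food channels of a two-choice arena."""

    FOOD1 = "food1"
    FOOD2 = "food2"


def to_samples(duration: float, sample_period: float) -> int:
    """Convert a duration in seconds to a whole number of samples.

    Uses round-half-even so that durations landing exactly between two
    sample counts are resolved deterministically (0.095 s at 10 ms/sample
    gives 10 samples). All time parameters meeting a sampled trace go
    through this single conversion.

    Parameters
    ----------
    duration : float
        Non-negative duration in seconds.
    sample_period : float
        Seconds per sample; must be positive.

    Returns
    -------
    int
        ``round(duration / sample_period)`` with banker's rounding.
    """
    if sample_period <= 0:
        raise InvalidParameterError(f"sample_period must be > 0, got {sample_period}")
    if duration < 0:
        raise InvalidParameterError(f"duration must be >= 0, got {duration}")
    # guard against ratios like 9.499999999999998 that are 9.5 in exact
    # arithmetic: snap to 9 decimals before the half-even round
    return int(round(round(duration / sample_period, 9)))


@dataclass(frozen=True)
class CapacitanceTrace:
    """Uniformly sampled capacitance signal for one channel.

    Parameters
    ----------
    values : array-like of int
        Raw capacitance-to-digital counts, one per sample.
    sample_period : float
        Seconds per sample (> 0).
    channel : Channel
        Which food source this electrode monitors.
    t0 : float
        Session-relative time of the first sample, seconds.
    """

    values: np.ndarray
    sample_period: float = 0.010
    channel: Channel = Channel.FOOD1
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 1 or values.size < 1:
            raise InvalidParameterError("trace must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values.astype(np.float64))):
            raise InvalidParameterError("trace values must all be finite")
        if values.dtype.kind == "f":
            rounded = np.rint(values)
            if not np.array_equal(rounded, values):
                raise InvalidParameterError(
                    "trace values are sensor counts and must be whole numbers"
                )
            values = rounded
        object.__setattr__(self, "values", values.astype(np.int64))
        if self.sample_period <= 0:
            raise InvalidParameterError(
                f"sample_period must be > 0, got {self.sample_period}"
            )
        object.__setattr__(self, "channel", Channel(self.channel))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (number of samples x sample period)."""
        return len(self) * self.sample_period

    @property
    def times(self) -> np.ndarray:
        """Session-relative sample times in seconds."""
        return self.t0 + np.arange(len(self)) * self.sample_period


@dataclass(frozen=True)
class DetectorParams:
    """Behavioural contract of the closed-loop sip detector.

    Defaults reproduce the published hardware configuration: a 100 ms
    running-minimum window and a 100-count rising-edge threshold chosen to
    exceed sensor noise. The sampling rate of the capacitance front end is
    configurable; 100 Hz is the package default, making the window exactly
    10 samples.
    """

    window: float = 0.100
    threshold: int = 100
    sample_period: float = 0.010

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise InvalidParameterError(f"window must be > 0, got {self.window}")
        if self.threshold <= 0:
            raise InvalidParameterError(f"threshold must be > 0, got {self.threshold}")
        if self.sample_period <= 0:
            raise InvalidParameterError(
                f"sample_period must be > 0, got {self.sample_period}"
            )
        if self.window_samples < 1:
            raise InvalidParameterError(
                "window must span at least one sample at the given rate"
            )

    @property
    def window_samples(self) -> int:
        """The running-minimum window expressed in whole samples."""
        return to_samples(self.window, self.sample_period)


@dataclass(frozen=True, order=True)
class InteractionEvent:
    """A detected feeding interaction: a maximal LED-on run.

    ``onset_index`` is the first LED-on sample, ``offset_index`` the last
    (inclusive).
    """

    onset_index: int
    offset_index: int
    channel: Channel = field(default=Channel.FOOD1, compare=False)

    def __post_init__(self) -> None:
        if self.onset_index < 0 or self.offset_index < self.onset_index:
            raise InvalidParameterError(
                f"need 0 <= onset <= offset, got ({self.onset_index}, {self.offset_index})"
            )
        object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def duration_samples(self) -> int:
        return self.offset_index - self.onset_index + 1

    def duration_s(self, sample_period: float) -> float:
        """Event duration in seconds at the given sampling period."""
        return self.duration_samples * sample_period


@dataclass(frozen=True)
class LedTimeline:
    """Per-sample LED command aligned to a capacitance trace."""

    states: np.ndarray
    sample_period: float = 0.010
    channel: Channel = Channel.FOOD1

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=bool)
        object.__setattr__(self, "states", states)
        if self.sample_period <= 0:
            raise InvalidParameterError(
                f"sample_period must be > 0, got {self.sample_period}"
            )
        object.__setattr__(self, "channel", Channel(self.channel))

    def __len__(self) -> int:
        return int(self.states.size)

    def events(self) -> list[InteractionEvent]:
        """Maximal LED-on runs as interaction events, sorted and disjoint."""
        if len(self) == 0:
            return []
        padded = np.concatenate(([0], self.states.astype(np.int8), [0]))
        diff = np.diff(padded)
        onsets = np.flatnonzero(diff == 1)
        offsets = np.flatnonzero(diff == -1) - 1
        return [
            InteractionEvent(int(a), int(b), self.channel)
            for a, b in zip(onsets, offsets)
        ]


def validate_session(
    trace1: CapacitanceTrace, trace2: CapacitanceTrace
) -> tuple[CapacitanceTrace, CapacitanceTrace]:
    """Check that two traces form a coherent two-channel session.

    Both traces must have the same length and sampling period and carry
    distinct channel labels. The pair is returned unchanged, so the check
    is idempotent.
    """
    if len(trace1) != len(trace2):
        raise SessionMismatchError(
            f"trace lengths differ: {len(trace1)} vs {len(trace2)}"
        )
    if trace1.sample_period != trace2.sample_period:
        raise SessionMismatchError(
            f"sample periods differ: {trace1.sample_period} vs {trace2.sample_period}"
        )
    if trace1.channel == trace2.channel:
        raise ConfigurationError(
            f"both traces labelled {trace1.channel.value!r}; channels must be distinct"
        )
    return trace1, trace2
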