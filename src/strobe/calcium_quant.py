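"""ΔF/F quantification of calcium-indicator fluorescence traces.

The acquisition protocol records 5 s of baseline, 1 s of tastant
stimulation and 9 s post-stimulus. The response amplitude is
ΔF/F = (peak - baseline) / baseline, where the baseline is the mean of
the 10 frames immediately preceding stimulus onset and the peak is the
maximum 3-frame rolling mean over the stimulus-and-post window. Window
placement (rolling mean vs top-k, immediately-pre-stimulus baseline) is
configurable since conventions vary between labs; the defaults here are
the rolling-mean / pre-stimulus reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .signal_model import to_samples

__all__ = [
    "FluorescenceTrace",
    "DffResult",
    "baseline_mean",
    "peak_mean",
    "delta_f_over_f",
    "timecourse_summary",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """A single-ROI fluorescence time series with stimulus timing.

    Parameters
    ----------
    values : array-like of float
        Fluorescence per frame, arbitrary units.
    frame_period : float
        Seconds per frame.
    stim_onset : float
        Stimulus onset time from trace start, seconds (default 5.0).
    stim_duration : float
        Stimulus duration, seconds (default 1.0).
    """

    values: np.ndarray
    frame_period: float
    stim_onset: float = 5.0
    stim_duration: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size < 1:
            raise InvalidParameterError("trace must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("fluorescence values must all be finite")
        object.__setattr__(self, "values", values)
        if self.frame_period <= 0:
            raise InvalidParameterError(
                f"frame_period must be > 0, got {self.frame_period}"
            )
        onset = self.stim_onset_index
        if not 0 <= onset < values.size:
            raise InvalidParameterError(
                f"stimulus onset at {self.stim_onset}s lies outside the trace"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def stim_onset_index(self) -> int:
        """Frame index of the first stimulus frame."""
        return to_samples(self.stim_onset, self.frame_period)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_period


@dataclass(frozen=True)
class DffResult:
    """ΔF/F summary of one trace."""

    dff: float
    peak_index: int
    baseline_mean: float
    peak_mean: float


def baseline_mean(trace: FluorescenceTrace, n_points: int = 10) -> float:
    """Mean of the ``n_points`` frames immediately before stimulus onset."""
    if n_points < 1:
        raise InvalidParameterError(f"n_points must be >= 1, got {n_points}")
    onset = trace.stim_onset_index
    if onset < n_points:
        raise InvalidInputError(
            f"need {n_points} pre-stimulus frames, trace has {onset}"
        )
    return float(np.mean(trace.values[onset - n_points : onset]))


def peak_mean(trace: FluorescenceTrace, n_points: int = 3) -> tuple[float, int]:
    """Peak of the centred rolling mean over the stimulus-and-post window.

    Rolling windows of ``n_points`` consecutive frames are taken entirely
    within [stimulus onset, trace end]; the maximum window mean and the
    frame index of that window's centre are returned. Ties between equal
    window means are broken toward the earliest window.
    """
    if n_points < 1:
        raise InvalidParameterError(f"n_points must be >= 1, got {n_points}")
    onset = trace.stim_onset_index
    segment = trace.values[onset:]
    if segment.size < n_points:
        raise InvalidInputError(
            f"need {n_points} frames at/after stimulus onset, trace has {segment.size}"
        )
    kernel = np.full(n_points, 1.0 / n_points)
    means = np.convolve(segment, kernel, mode="valid")
    best = int(np.argmax(means))
    center = onset + best + n_points // 2
    return float(means[best]), center


def delta_f_over_f(
    trace: FluorescenceTrace, baseline_points: int = 10, peak_points: int = 3
) -> DffResult:
    """Maximum fractional fluorescence change of a trace.

    ΔF/F = (peak - baseline) / baseline with the window conventions of
    :func:`baseline_mean` and :func:`peak_mean`. Invariant to positive
    rescaling of the trace; additive offsets change it (the ratio is not
    shift-invariant), which is why raw, un-offset fluorescence must be
    supplied.
    """
    f0 = baseline_mean(trace, baseline_points)
    if f0 <= 0:
        raise InvalidInputError(f"baseline mean must be positive, got {f0}")
    peak, idx = peak_mean(trace, peak_points)
    return DffResult(
        dff=(peak - f0) / f0, peak_index=idx, baseline_mean=f0, peak_mean=peak
    )


def timecourse_summary(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    """Frame-wise mean and SEM across equal-length traces.

    Returns a DataFrame with ``time_s``, ``mean`` and ``sem`` columns; SEM
    is NaN for a single trace.
    """
    if not traces:
        raise InvalidParameterError("timecourse_summary needs at least one trace")
    n = len(traces[0])
    period = traces[0].frame_period
    for tr in traces[1:]:
        if len(tr) != n or tr.frame_period != period:
            raise InvalidInputError(
                "all traces must share length and frame period"
            )
    stack = np.vstack([tr.values for tr in traces])
    mean = stack.mean(axis=0)
    if stack.shape[0] >= 2:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        sem = np.full(n, np.nan)
    return pd.DataFrame(
        {"time_s": traces[0].times, "mean": mean, "sem": sem}
    )
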