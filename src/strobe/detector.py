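"""The closed-loop sip-detection algorithm.

The hardware evaluates, at every sample, the minimum of the capacitance
signal over the most recent 100 ms and compares the current sample against
it. A rise of more than a noise threshold (100 counts by default) above
that running minimum is a rising edge and switches the stimulation LED on
(or keeps it on). The LED command is simply the truth value of that
condition at each sample, so two turn-off behaviours emerge without any
extra machinery:

* falling edge — the signal drops back to within the threshold of the
  window minimum, and the condition fails immediately;
* plateau — once the signal has been flat for a full window, the minimum
  has caught up with the current value and the condition fails.

Whichever happens sooner wins, matching the closed-loop contract of the
apparatus. Two interchangeable code paths are provided: a streaming
per-sample state machine (:class:`SipDetector`) with memory bounded by the
window, and a vectorised batch path (:func:`detect`). Tests assert they
are bitwise identical.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError
from .signal_model import (
    CapacitanceTrace,
    DetectorParams,
    InteractionEvent,
    LedTimeline,
)

__all__ = [
    "running_min",
    "rising_condition",
    "DetectorState",
    "SipDetector",
    "detect",
    "event_durations",
]


def running_min(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing-window running minimum of a signal.

    ``out[t] = min(values[max(0, t - window + 1) : t + 1])`` — the minimum
    of the ``window`` most recent samples including the current one. For
    the leading ``window - 1`` samples the window is truncated at the start
    of the trace.

    Implemented with the block prefix/suffix-minima decomposition: the
    trace is cut into blocks of ``window`` samples; cumulative minima
    within blocks, taken left-to-right and right-to-left, combine into any
    trailing window minimum with O(1) work per sample. The whole pass is a
    single sweep with memory bounded by the block size, matching the
    streaming contract of the hardware filter.

    Parameters
    ----------
    values : array-like of int
        The signal.
    window : int
        Window length in samples; must be >= 1.
    """
    if window < 1:
        raise InvalidParameterError(f"window must be >= 1 sample, got {window}")
    v = np.asarray(values)
    n = v.size
    if n == 0:
        return v.copy()
    if window == 1:
        return v.copy()
    w = int(window)
    n_blocks = -(-n // w)
    pad = n_blocks * w - n
    # pad with +inf-like sentinel (max of dtype) so it never wins a minimum
    sentinel = np.iinfo(v.dtype).max if v.dtype.kind in "iu" else np.inf
    blocks = np.concatenate([v, np.full(pad, sentinel, dtype=v.dtype)]).reshape(
        n_blocks, w
    )
    prefix = np.minimum.accumulate(blocks, axis=1).reshape(-1)[:n]
    suffix = np.minimum.accumulate(blocks[:, ::-1], axis=1)[:, ::-1].reshape(-1)
    out = prefix.copy()
    t = np.arange(w - 1, n)
    start = t - w + 1
    np.minimum(suffix[start], prefix[t], out=out[w - 1 :])
    return out


def rising_condition(current: int, window_min: int, threshold: int) -> bool:
    """The rising-edge test: current sample exceeds the window minimum by
    strictly more than the threshold."""
    return current - window_min > threshold


@dataclass
class DetectorState:
    """Streaming detector state; memory bounded by the window length.

    ``window_buffer`` holds the raw samples of the current window;
    ``min_queue`` is a monotonic deque of (index, value) pairs whose front
    is the window minimum. Both never exceed the window length. The LED
    command at any step is a pure function of the buffered window and the
    threshold — there is no hidden history.
    """

    window: int
    window_buffer: deque = field(default_factory=deque)
    min_queue: deque = field(default_factory=deque)
    led_on: bool = False
    samples_seen: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise InvalidParameterError(f"window must be >= 1 sample, got {self.window}")
        self.window_buffer = deque(self.window_buffer, maxlen=self.window)

    @property
    def window_min(self) -> int:
        """Minimum of the buffered window (undefined before the first sample)."""
        return self.min_queue[0][1]

    @property
    def memory_samples(self) -> int:
        """Number of samples the state currently retains (for auditing the
        bounded-memory contract)."""
        return max(len(self.window_buffer), len(self.min_queue))


class SipDetector:
    """Per-sample closed-loop detector.

    Feed samples one at a time with :meth:`step`; each call returns the LED
    command for that sample before the next one is consumed (the per-sample
    latency contract). Amortised O(1) per step via a monotonic deque.
    """

    def __init__(self, params: DetectorParams | None = None):
        self.params = params or DetectorParams()
        self.state = DetectorState(window=self.params.window_samples)

    def reset(self) -> None:
        self.state = DetectorState(window=self.params.window_samples)

    def step(self, sample: int) -> bool:
        """Consume one sample; return the LED command for it."""
        st = self.state
        i = st.samples_seen
        sample = int(sample)
        st.window_buffer.append(sample)
        q = st.min_queue
        while q and q[-1][1] >= sample:
            q.pop()
        q.append((i, sample))
        while q[0][0] <= i - st.window:
            q.popleft()
        st.samples_seen = i + 1
        st.led_on = rising_condition(sample, q[0][1], self.params.threshold)
        return st.led_on

    def run(self, values) -> np.ndarray:
        """Stream a whole signal through :meth:`step`; returns the LED
        command sequence."""
        return np.fromiter(
            (self.step(s) for s in np.asarray(values)), dtype=bool,
            count=len(np.asarray(values)),
        )


def detect(
    trace: CapacitanceTrace, params: DetectorParams | None = None
) -> tuple[LedTimeline, list[InteractionEvent]]:
    """Batch detection over a full trace.

    Computes the per-sample LED command ``values - running_min > threshold``
    and segments its maximal true-runs into interaction events. Bitwise
    identical to streaming the trace through :class:`SipDetector`.

    Parameters
    ----------
    trace : CapacitanceTrace
        The capacitance signal of one channel.
    params : DetectorParams, optional
        Detection parameters; defaults reproduce the published hardware
        configuration. The trace's own sampling period takes precedence
        over ``params.sample_period`` when converting the window.
    """
    params = params or DetectorParams()
    window = DetectorParams(
        window=params.window,
        threshold=params.threshold,
        sample_period=trace.sample_period,
    ).window_samples
    values = trace.values
    if values.size == 0:
        timeline = LedTimeline(
            np.zeros(0, dtype=bool), trace.sample_period, trace.channel
        )
        return timeline, []
    minima = running_min(values, window)
    led = (values - minima) > params.threshold
    timeline = LedTimeline(led, trace.sample_period, trace.channel)
    return timeline, timeline.events()


def event_durations(
    events: list[InteractionEvent], sample_period: float
) -> list[float]:
    """Durations in seconds of a list of events (inclusive sample spans)."""
    if sample_period <= 0:
        raise InvalidParameterError(f"sample_period must be > 0, got {sample_period}")
    return [e.duration_s(sample_period) for e in events]
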