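"""From detected events to per-fly preference and cohort summaries.

A fly's preference between the two food channels is the normalised sip
count difference, PI = (sips1 - sips2)/(sips1 + sips2), computed per fly
over a session. Flies with fewer than 15 total sips are excluded from
cohort statistics (but retained in the table with the reason logged).
Detected interaction events are classified as sips by duration bounds,
since the full sip-vs-other-interaction classifier of the capacitance
monitor is outside this package's scope; the bounds are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .signal_model import Channel, InteractionEvent

__all__ = [
    "FeedingSession",
    "CohortSummary",
    "count_sips",
    "strobe_preference",
    "apply_inclusion",
    "summarize_cohort",
    "MIN_SIPS_DEFAULT",
    "SIP_DURATION_BOUNDS",
]

logger = logging.getLogger(__name__)

#: Inclusion rule: a fly must log at least this many sips in total.
MIN_SIPS_DEFAULT = 15

#: Default duration bounds (s) for classifying a detected event as a sip.
SIP_DURATION_BOUNDS = (0.02, 5.0)


@dataclass(frozen=True)
class FeedingSession:
    """One fly's session: events, sip counts, preference, inclusion."""

    fly_id: str
    sips_food1: int
    sips_food2: int
    preference: float = math.nan
    included: bool | None = None
    condition: str = ""
    events_food1: tuple[InteractionEvent, ...] = field(default=(), repr=False)
    events_food2: tuple[InteractionEvent, ...] = field(default=(), repr=False)
    exclusion_reason: str | None = None
    #: planted ground-truth events (simulated sessions only; empty for real data)
    ground_truth: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.sips_food1 < 0 or self.sips_food2 < 0:
            raise InvalidParameterError("sip counts must be non-negative")

    @property
    def total_sips(self) -> int:
        return self.sips_food1 + self.sips_food2


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of a cohort of single-fly sessions."""

    n_included: int
    n_excluded: int
    mean_preference: float
    sem_preference: float
    table: pd.DataFrame = field(repr=False)

    @property
    def n_total(self) -> int:
        return self.n_included + self.n_excluded


def count_sips(
    events: list[InteractionEvent],
    sample_period: float,
    min_duration: float = SIP_DURATION_BOUNDS[0],
    max_duration: float = SIP_DURATION_BOUNDS[1],
) -> dict[Channel, int]:
    """Count events classified as sips, per channel.

    An event counts as a sip when its duration lies in
    ``[min_duration, max_duration]`` (inclusive). Returns counts for both
    channels (zero when a channel has no qualifying events).
    """
    if min_duration > max_duration:
        raise InvalidParameterError(
            f"min_duration {min_duration} exceeds max_duration {max_duration}"
        )
    if sample_period <= 0:
        raise InvalidParameterError(f"sample_period must be > 0, got {sample_period}")
    counts = {Channel.FOOD1: 0, Channel.FOOD2: 0}
    for ev in events:
        if min_duration <= ev.duration_s(sample_period) <= max_duration:
            counts[ev.channel] += 1
    return counts


def strobe_preference(sips1: int, sips2: int) -> float:
    """Preference index (sips1 - sips2) / (sips1 + sips2).

    Returns NaN (undefined, not zero) when both counts are zero: a fly
    that never fed expresses no preference.
    """
    if sips1 < 0 or sips2 < 0:
        raise InvalidParameterError(
            f"sip counts must be non-negative, got ({sips1}, {sips2})"
        )
    total = sips1 + sips2
    if total == 0:
        return math.nan
    return (sips1 - sips2) / total


def apply_inclusion(
    session: FeedingSession, min_sips: int = MIN_SIPS_DEFAULT
) -> FeedingSession:
    """Flag a session included iff its total sips reach the minimum.

    The threshold applies to the summed sips of both channels; a session
    with exactly ``min_sips`` total sips is included. Excluded flies keep
    their data and record the reason.
    """
    total = session.total_sips
    if total >= min_sips:
        return replace(session, included=True, exclusion_reason=None)
    reason = f"total sips {total} < minimum {min_sips}"
    logger.info("fly %s excluded: %s", session.fly_id, reason)
    return replace(session, included=False, exclusion_reason=reason)


def summarize_cohort(sessions: list[FeedingSession]) -> CohortSummary:
    """Mean +/- SEM preference over included flies.

    SEM is the sample standard deviation over the square root of n; it is
    NaN for fewer than two included flies, and the mean is NaN when no fly
    is included (non-fatal). Excluded flies appear in the per-fly table
    with ``included = False``.
    """
    if not sessions:
        raise InvalidParameterError("summarize_cohort needs at least one session")
    table = pd.DataFrame(
        {
            "fly_id": [s.fly_id for s in sessions],
            "condition": [s.condition for s in sessions],
            "sips_food1": [s.sips_food1 for s in sessions],
            "sips_food2": [s.sips_food2 for s in sessions],
            "preference": [s.preference for s in sessions],
            "included": [bool(s.included) for s in sessions],
        }
    )
    prefs = table.loc[table["included"], "preference"].to_numpy(dtype=float)
    n_inc = int(prefs.size)
    mean = float(np.mean(prefs)) if n_inc >= 1 else math.nan
    sem = float(np.std(prefs, ddof=1) / np.sqrt(n_inc)) if n_inc >= 2 else math.nan
    return CohortSummary(
        n_included=n_inc,
        n_excluded=len(sessions) - n_inc,
        mean_preference=mean,
        sem_preference=sem,
        table=table,
    )
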