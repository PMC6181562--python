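"""Binary-choice dye preference and proboscis-extension scoring.

Two classic fly behavioural readouts that complement the closed-loop
arena: the dye two-choice assay, where groups of flies feed overnight on
two dyed foods and are scored by abdomen colour, and the proboscis
extension reflex (PER), where each fly is stimulated a fixed number of
times per tastant and the fraction of extensions is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidParameterError

__all__ = [
    "DyeChoiceResult",
    "PerRecord",
    "dye_preference",
    "pool_dye_swaps",
    "per_fraction",
    "summarize_per",
]


@dataclass(frozen=True)
class DyeChoiceResult:
    """Abdomen-colour counts for one group of flies in a two-choice test.

    ``dye_orientation`` records which dye marked Food 1 ("standard" or
    "swapped"); half the replicates are run with dyes swapped to control
    for intrinsic dye preference.
    """

    n_food1_color: int
    n_food2_color: int
    n_both_colors: int = 0
    n_unfed: int = 0
    group_id: str = ""
    dye_orientation: str | None = None

    def __post_init__(self) -> None:
        counts = (self.n_food1_color, self.n_food2_color, self.n_both_colors, self.n_unfed)
        if any(c < 0 for c in counts):
            raise InvalidParameterError(f"fly counts must be non-negative, got {counts}")

    @property
    def n_fed(self) -> int:
        return self.n_food1_color + self.n_food2_color + self.n_both_colors


@dataclass(frozen=True)
class PerRecord:
    """Proboscis extension responses of one fly to one stimulus."""

    fly_id: str
    stimulus: str
    n_extensions: int
    n_presentations: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.n_extensions <= self.n_presentations:
            raise InvalidParameterError(
                f"need 0 <= extensions <= presentations, got "
                f"{self.n_extensions}/{self.n_presentations}"
            )


def dye_preference(result: DyeChoiceResult) -> float:
    """Group preference index from abdomen-colour counts.

    PI = (n Food-1-coloured - n Food-2-coloured) / n fed, where flies
    labelled with both colours count as fed (denominator) but favour
    neither food (numerator). NaN when no fly fed.
    """
    if result.n_fed == 0:
        return math.nan
    return (result.n_food1_color - result.n_food2_color) / result.n_fed


def pool_dye_swaps(groups: list[DyeChoiceResult]) -> pd.DataFrame:
    """Per-group preference indices with dye-orientation metadata.

    Counts are already expressed in Food 1 / Food 2 space whichever dye
    marked each food, so the index is computed identically for both
    orientations; the orientation column is retained for diagnostics
    (e.g. checking that pooled swapped halves cancel any dye bias).
    """
    for g in groups:
        if g.dye_orientation is None:
            raise ConfigurationError(
                f"group {g.group_id!r} is missing its dye_orientation flag"
            )
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "dye_orientation": [g.dye_orientation for g in groups],
            "n_fed": [g.n_fed for g in groups],
            "preference": [dye_preference(g) for g in groups],
        }
    )


def per_fraction(record: PerRecord) -> float:
    """Fraction of presentations answered with a proboscis extension."""
    return record.n_extensions / record.n_presentations


def summarize_per(records: list[PerRecord]) -> pd.DataFrame:
    """Mean +/- SEM extension fraction per stimulus across flies."""
    if not records:
        raise InvalidParameterError("summarize_per needs at least one record")
    df = pd.DataFrame(
        {
            "stimulus": [r.stimulus for r in records],
            "fly_id": [r.fly_id for r in records],
            "fraction": [per_fraction(r) for r in records],
        }
    )
    def _sem(x: pd.Series) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) >= 2 else math.nan

    out = df.groupby("stimulus", sort=False)["fraction"].agg(
        n="size", mean="mean", sem=_sem
    )
    return out.reset_index()
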