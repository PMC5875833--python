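"""Reproducibility statistics and report-table helpers for routine QA."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import OffsetVector


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (report convention; banker's rounding is not)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class ReproSeries:
    """Repeated focal-spot measurements on one linac/energy."""

    repeats: Sequence[OffsetVector]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.repeats) < 2:
            raise ValueError("need at least 2 repeats for a reproducibility SD")


@dataclass(frozen=True)
class ReproStats:
    """Per-direction mean and sample (n-1) SD, full precision, mm."""

    mean_crossplane: float
    sd_crossplane: float
    mean_inplane: float
    sd_inplane: float
    n: int
    label: str = ""

    def rounded(self, ndigits: int = 3) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean_crossplane": round_half_away(self.mean_crossplane, ndigits),
            "sd_crossplane": round_half_away(self.sd_crossplane, ndigits),
            "mean_inplane": round_half_away(self.mean_inplane, ndigits),
            "sd_inplane": round_half_away(self.sd_inplane, ndigits),
        }


def repro_stats(series: ReproSeries) -> ReproStats:
    """Mean and sample SD of repeated offsets, per reported direction."""
    cross = np.array([o.crossplane for o in series.repeats], dtype=float)
    inpl = np.array([o.inplane for o in series.repeats], dtype=float)
    return ReproStats(
        mean_crossplane=float(np.mean(cross)),
        sd_crossplane=float(np.std(cross, ddof=1)),
        mean_inplane=float(np.mean(inpl)),
        sd_inplane=float(np.std(inpl, ddof=1)),
        n=len(series.repeats),
        label=series.label,
    )


def repro_table(series_list: Sequence[ReproSeries], ndigits: int = 3) -> pd.DataFrame:
    """One row per series: rounded means and SDs, ready for CSV export."""
    return pd.DataFrame([repro_stats(s).rounded(ndigits) for s in series_list])
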