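"""Diurnal-course summaries: peaks, midday depression, water-use efficiency.

Clock times are "H:MM" 24-hour strings with no date arithmetic.  The
midday window defaults to 11:00–15:00 (inclusive); the morning peak is
the maximum rate strictly before the window, the evening peak the
maximum strictly after it, and the depression index is
1 − midday_min/morning_peak.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DiurnalRecord",
    "DiurnalSummary",
    "parse_clock",
    "format_clock",
    "summarize_diurnal",
    "wue",
]

log = logging.getLogger(__name__)

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


def parse_clock(text: str) -> int:
    """Parse "H:MM" into minutes since midnight."""
    m = _CLOCK_RE.match(str(text).strip())
    if not m:
        raise ValueError(f"cannot parse clock time {text!r} (expected H:MM)")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 23 or mm > 59:
        raise ValueError(f"clock time out of range: {text!r}")
    return 60 * hh + mm


def format_clock(minutes: int) -> str:
    return f"{minutes // 60}:{minutes % 60:02d}"


@dataclass(frozen=True)
class DiurnalRecord:
    """One gas-exchange record in a diurnal course."""

    clock_time: str
    photo: float
    pari: Optional[float] = None
    tleaf: Optional[float] = None
    co2s: Optional[float] = None
    trmmol: Optional[float] = None
    cond: Optional[float] = None
    ci: Optional[float] = None
    repeat_id: str = ""

    def __post_init__(self) -> None:
        parse_clock(self.clock_time)  # validates format
        if self.photo < -0.5:
            # photo may dip slightly below zero from instrument noise;
            # large negatives indicate a unit or parse problem
            warnings.warn(
                f"photo={self.photo} at {self.clock_time} is strongly negative",
                stacklevel=2,
            )

    @property
    def minutes(self) -> int:
        return parse_clock(self.clock_time)


@dataclass(frozen=True)
class DiurnalSummary:
    morning_peak: Optional[tuple[str, float]]
    evening_peak: Optional[tuple[str, float]]
    midday_min: Optional[tuple[str, float]]
    depression_index: float
    daily_mean_rate: float
    mean_wue: float


def wue(photo: float, trmmol: float) -> float:
    """Instantaneous water-use efficiency, µmol CO₂ per mmol H₂O."""
    if trmmol <= 0:
        raise ValueError(f"trmmol must be > 0 for WUE, got {trmmol}")
    return photo / trmmol


def summarize_diurnal(
    records: Sequence[DiurnalRecord],
    midday_window: tuple[str, str] = ("11:00", "15:00"),
) -> DiurnalSummary:
    """Summarize one repeat's diurnal course.

    Peaks and the midday minimum are elements of the input (no
    interpolation).  Records with non-positive transpiration are skipped
    in the WUE mean with a warning.
    """
    if len(records) < 3:
        raise ValueError(f"need >= 3 records, got {len(records)}")
    recs = sorted(records, key=lambda r: r.minutes)
    mins = [r.minutes for r in recs]
    if len(set(mins)) != len(mins):
        raise ValueError("clock times must be strictly increasing within a repeat")
    w_lo, w_hi = parse_clock(midday_window[0]), parse_clock(midday_window[1])

    before = [r for r in recs if r.minutes < w_lo]
    inside = [r for r in recs if w_lo <= r.minutes <= w_hi]
    after = [r for r in recs if r.minutes > w_hi]

    def peak(rs, fn):
        if not rs:
            return None
        r = fn(rs, key=lambda r: r.photo)
        return (r.clock_time, r.photo)

    morning = peak(before, max)
    evening = peak(after, max)
    midday = peak(inside, min)

    depression = math.nan
    if midday is None:
        warnings.warn(
            "no records inside the midday window; depression fields absent",
            stacklevel=2,
        )
        log.info("midday window [%s, %s] empty", *midday_window)
    elif morning is not None and morning[1] > 0:
        depression = 1.0 - midday[1] / morning[1]

    wues = []
    for r in recs:
        if r.trmmol is None:
            continue
        if r.trmmol <= 0:
            warnings.warn(
                f"record at {r.clock_time} skipped in WUE mean (trmmol={r.trmmol})",
                stacklevel=2,
            )
            continue
        wues.append(wue(r.photo, r.trmmol))

    return DiurnalSummary(
        morning_peak=morning,
        evening_peak=evening,
        midday_min=midday,
        depression_index=depression,
        daily_mean_rate=float(np.mean([r.photo for r in recs])),
        mean_wue=float(np.mean(wues)) if wues else math.nan,
    )
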