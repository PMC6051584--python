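"""Recording schedules, sub-sampling, and detection histories.

The field protocol records five minutes at the top of each hour from 02:00
to 19:00 (the diel survey) plus one continuous six-hour block from 20:00 to
02:00 (the night survey).  Candidate sub-sampling schedules select minutes
within the night block; a night is "detected" for a schedule if at least one
bellow falls in its windows.  Detection histories are site x night binary
matrices with per-cell validity (outage nights carry no information).

Conventions: windows are half-open ``[start, start+duration)``; a night is
keyed by the calendar date on which its 20:00 block starts, so the 00:00 to
02:00 tail belongs to the previous date; the local clock is assumed
continuous (no DST arithmetic).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import BellowEvent, OutageCalendar

__all__ = [
    "RecordingWindow",
    "Subschedule",
    "SUBSCHEDULES",
    "WindowCounts",
    "DetectionHistory",
    "build_recording_windows",
    "count_events_in_windows",
    "apply_subschedule",
    "build_detection_history",
    "night_block_minutes",
    "events_to_frame",
]

NIGHT_BLOCK_START = dt.time(20, 0)
NIGHT_BLOCK_MINUTES = 360
HOURLY_SAMPLE_HOURS = range(2, 20)  # 02:00 .. 19:00 inclusive start hours


@dataclasses.dataclass(frozen=True)
class RecordingWindow:
    """One scheduled recording interval at a site."""

    site_id: str
    start: dt.datetime
    duration_min: int
    kind: str  # "hourly_5min" | "night_block"

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ValueError("window duration must be positive")
        if self.kind == "night_block" and (
            self.start.time() != NIGHT_BLOCK_START or self.duration_min != NIGHT_BLOCK_MINUTES
        ):
            raise ValueError("night_block windows start 20:00 and last 360 minutes")

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(minutes=self.duration_min)


@dataclasses.dataclass(frozen=True)
class Subschedule:
    """Minutes of the 360-minute night block counted toward detection.

    ``windows`` are (offset-from-20:00, duration) pairs in minutes, disjoint
    and inside [0, 360].
    """

    name: str
    windows: tuple[tuple[int, int], ...]

    def __post_init__(self):
        spans = []
        for off, dur in self.windows:
            if off < 0 or dur <= 0 or off + dur > NIGHT_BLOCK_MINUTES:
                raise ValueError(f"sub-schedule window ({off},{dur}) outside [0,360]")
            spans.append((off, off + dur))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("sub-schedule windows must be disjoint")

    @property
    def total_minutes(self) -> int:
        return sum(dur for _, dur in self.windows)

    def minute_mask(self) -> np.ndarray:
        mask = np.zeros(NIGHT_BLOCK_MINUTES, dtype=bool)
        for off, dur in self.windows:
            mask[off : off + dur] = True
        return mask


# The peak-bellowing sub-windows are centred on 23:00-00:00 (about four hours
# after a typical 19:00 sunset); "30 minutes per hour" takes the first half
# of each block hour.
SUBSCHEDULES: dict[str, Subschedule] = {
    "six_hours": Subschedule("six_hours", ((0, 360),)),
    "six_by_30min": Subschedule(
        "six_by_30min", tuple((h * 60, 30) for h in range(6))
    ),
    "three_hours": Subschedule("three_hours", ((120, 180),)),  # 22:00-01:00
    "two_hours": Subschedule("two_hours", ((150, 120),)),  # 22:30-00:30
    "one_hour": Subschedule("one_hour", ((180, 60),)),  # 23:00-00:00
}


@dataclasses.dataclass(frozen=True)
class WindowCounts:
    window: RecordingWindow
    n_bellows: int
    female_present: bool


@dataclasses.dataclass(frozen=True)
class DetectionHistory:
    """Site x night binary detection matrix with per-cell validity."""

    site_ids: tuple[str, ...]
    nights: tuple[dt.date, ...]
    detected: np.ndarray  # int {0,1}, shape (n_sites, n_nights)
    valid: np.ndarray  # bool, same shape

    def __post_init__(self):
        if self.detected.shape != (len(self.site_ids), len(self.nights)):
            raise ValueError("detected matrix shape inconsistent with labels")
        if self.valid.shape != self.detected.shape:
            raise ValueError("valid matrix shape inconsistent")

    def subset(
        self,
        site_ids: Sequence[str] | None = None,
        nights: Sequence[dt.date] | None = None,
    ) -> "DetectionHistory":
        rows = (
            [self.site_ids.index(s) for s in site_ids]
            if site_ids is not None
            else list(range(len(self.site_ids)))
        )
        night_set = set(nights) if nights is not None else None
        cols = [
            j for j, n in enumerate(self.nights) if night_set is None or n in night_set
        ]
        return DetectionHistory(
            site_ids=tuple(self.site_ids[i] for i in rows),
            nights=tuple(self.nights[j] for j in cols),
            detected=self.detected[np.ix_(rows, cols)].copy(),
            valid=self.valid[np.ix_(rows, cols)].copy(),
        )


def build_recording_windows(
    site_ids: Sequence[str], start_date: dt.date, end_date: dt.date
) -> list[RecordingWindow]:
    """The full field schedule: 18 hourly 5-min samples + one night block per day."""
    windows: list[RecordingWindow] = []
    for site in site_ids:
        day = start_date
        while day <= end_date:
            for h in HOURLY_SAMPLE_HOURS:
                windows.append(
                    RecordingWindow(site, dt.datetime.combine(day, dt.time(h, 0)), 5, "hourly_5min")
                )
            windows.append(
                RecordingWindow(
                    site,
                    dt.datetime.combine(day, NIGHT_BLOCK_START),
                    NIGHT_BLOCK_MINUTES,
                    "night_block",
                )
            )
            day += dt.timedelta(days=1)
    return windows


def events_to_frame(events: Sequence[BellowEvent]) -> pd.DataFrame:
    """Events as a tidy frame with columns site_id, timestamp, sex."""
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in events],
            "timestamp": pd.to_datetime([e.timestamp for e in events]),
            "sex": [e.sex for e in events],
        }
    )


def count_events_in_windows(
    events: Sequence[BellowEvent] | pd.DataFrame, windows: Sequence[RecordingWindow]
) -> list[WindowCounts]:
    """Count male bellows (and flag female presence) in each window.

    Events are binned with the half-open convention: an event at the exact
    window start counts, one at the exact end does not.  Events falling in no
    window are dropped.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    by_site: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for site, grp in df.groupby("site_id"):
        ts = grp["timestamp"].to_numpy(dtype="datetime64[ns]")
        order = np.argsort(ts, kind="stable")
        by_site[site] = (ts[order], (grp["sex"].to_numpy() == "female")[order])
    out: list[WindowCounts] = []
    for w in windows:
        ts_f = by_site.get(w.site_id)
        if ts_f is None:
            out.append(WindowCounts(w, 0, False))
            continue
        ts, female = ts_f
        lo = np.searchsorted(ts, np.datetime64(w.start), side="left")
        hi = np.searchsorted(ts, np.datetime64(w.end), side="left")
        fem = bool(female[lo:hi].any())
        out.append(WindowCounts(w, int(hi - lo - female[lo:hi].sum()), fem))
    return out


def apply_subschedule(
    night_counts_per_minute: Sequence[int], sub: Subschedule
) -> int:
    """1 if any bellow falls in the sub-schedule's minutes of the night block."""
    counts = np.asarray(night_counts_per_minute)
    if counts.shape != (NIGHT_BLOCK_MINUTES,):
        raise ValueError("expected per-minute counts covering the 360-minute block")
    return int(counts[sub.minute_mask()].sum() > 0)


def night_block_minutes(timestamps: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Map timestamps to (night date, minute offset into the 20:00 block).

    Returns parallel arrays; timestamps outside any night block get offset -1.
    A timestamp between midnight and 02:00 belongs to the previous date's
    block.
    """
    ts = pd.to_datetime(timestamps)
    minutes = ts.dt.hour * 60 + ts.dt.minute
    dates = ts.dt.normalize()
    in_evening = minutes >= 1200
    in_morning = minutes < 120
    offset = np.full(len(ts), -1, dtype=int)
    offset[in_evening] = minutes[in_evening] - 1200
    offset[in_morning] = minutes[in_morning] + 240
    night = dates.where(~in_morning, dates - pd.Timedelta(days=1))
    return night.dt.date.to_numpy(), offset


def build_detection_history(
    events: Sequence[BellowEvent] | pd.DataFrame,
    site_ids: Sequence[str],
    start_date: dt.date,
    end_date: dt.date,
    sub: Subschedule,
    outages: Mapping[str, OutageCalendar] | None = None,
    males_only: bool = True,
) -> DetectionHistory:
    """Binary site x night detection history under a sub-sampling schedule.

    One column per night from ``start_date`` to ``end_date`` (the night of
    ``end_date`` runs into the following morning).  Cells on a site's outage
    dates are invalid; all others are 0/1 by whether any bellow falls inside
    the sub-schedule's windows.  Duplicate events cannot change the result.
    """
    site_ids = tuple(site_ids)
    nights = tuple(
        start_date + dt.timedelta(days=i)
        for i in range((end_date - start_date).days + 1)
    )
    detected = np.zeros((len(site_ids), len(nights)), dtype=int)
    valid = np.ones_like(detected, dtype=bool)

    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if males_only and len(df):
        df = df[df["sex"] == "male"]
    if len(df):
        night_dates, offsets = night_block_minutes(df["timestamp"])
        mask = sub.minute_mask()
        in_sub = (offsets >= 0) & mask[np.clip(offsets, 0, NIGHT_BLOCK_MINUTES - 1)]
        night_pos = {n: j for j, n in enumerate(nights)}
        site_pos = {s: i for i, s in enumerate(site_ids)}
        for s, n in zip(df["site_id"].to_numpy()[in_sub], night_dates[in_sub]):
            i = site_pos.get(s)
            j = night_pos.get(n)
            if i is not None and j is not None:
                detected[i, j] = 1

    if outages:
        for i, s in enumerate(site_ids):
            cal = outages.get(s)
            if cal is None:
                continue
            for j, n in enumerate(nights):
                if n in cal.dates:
                    valid[i, j] = False
                    detected[i, j] = 0
    return DetectionHistory(site_ids, nights, detected, valid)
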