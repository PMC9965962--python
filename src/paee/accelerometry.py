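"""Accelerometer count processing: epochs -> minutes -> CPM.

The device records triaxial activity counts in short fixed epochs.  The
processing chain re-integrates epochs to one-minute totals, combines the
axes into a vector magnitude, detects non-wear time (long runs of zero
counts with a small interruption allowance), applies the valid-day and
wear-protocol rules, and finally reports counts per minute (CPM) as total
vector-magnitude counts over valid wear time divided by valid wear
minutes.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochStream",
    "MinuteSeries",
    "CpmResult",
    "reintegrate",
    "vector_magnitude",
    "to_minute_series",
    "detect_nonwear",
    "daily_wear_summary",
    "compute_cpm",
    "process_stream",
]


@dataclass
class EpochStream:
    """Contiguous triaxial counts at a fixed epoch length.

    ``counts`` has shape (n_epochs, 3) with non-negative integers;
    timestamps are implicit: ``start + i * epoch_s``.
    """

    start: dt.datetime
    epoch_s: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n, 3)")
        if len(self.counts) == 0:
            raise ValueError("empty epoch stream")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def __len__(self) -> int:
        return len(self.counts)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=len(self), freq=pd.Timedelta(seconds=self.epoch_s)
        )


@dataclass
class MinuteSeries:
    """Per-minute vector-magnitude counts with an optional wear mask."""

    start: dt.datetime
    vm: np.ndarray
    wear: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.vm)

    def minutes(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self), freq="min")

    def to_frame(self) -> pd.DataFrame:
        idx = self.minutes()
        frame = pd.DataFrame(
            {
                "vm_counts": self.vm,
                "date": idx.date,
                "is_weekend": idx.dayofweek >= 5,
            },
            index=idx,
        )
        if self.wear is not None:
            frame["wear"] = self.wear
        return frame


@dataclass
class CpmResult:
    participant_id: str
    total_vm_counts: float
    valid_wear_minutes: float
    cpm: float
    n_valid_weekdays: int
    n_valid_weekend_days: int
    protocol_valid: bool


def reintegrate(stream: EpochStream, target_epoch_s: int) -> EpochStream:
    """Sum counts into longer epochs; a trailing partial window is dropped.

    ``target_epoch_s`` must be an integer multiple of the stream's epoch
    length.  Total counts are conserved apart from any dropped tail,
    which is reported with a warning rather than zero-padded (padding
    would deflate CPM).
    """
    if target_epoch_s % stream.epoch_s != 0:
        raise ValueError(
            f"target epoch {target_epoch_s}s is not a multiple of {stream.epoch_s}s"
        )
    ratio = target_epoch_s // stream.epoch_s
    if ratio == 1:
        return replace(stream, counts=stream.counts.copy())
    n_full = len(stream) // ratio
    tail = len(stream) - n_full * ratio
    if tail:
        warnings.warn(
            f"dropping trailing partial window of {tail} epochs", stacklevel=2
        )
    if n_full == 0:
        raise ValueError("stream shorter than one target epoch")
    summed = (
        stream.counts[: n_full * ratio].reshape(n_full, ratio, 3).sum(axis=1)
    )
    return EpochStream(start=stream.start, epoch_s=target_epoch_s, counts=summed)


def vector_magnitude(axis1, axis2, axis3):
    """Euclidean norm of the three axis counts (not rounded)."""
    a1 = np.asarray(axis1, dtype=float)
    a2 = np.asarray(axis2, dtype=float)
    a3 = np.asarray(axis3, dtype=float)
    if (a1 < 0).any() or (a2 < 0).any() or (a3 < 0).any():
        raise ValueError("counts must be non-negative")
    return np.sqrt(a1 * a1 + a2 * a2 + a3 * a3)


def to_minute_series(stream: EpochStream) -> MinuteSeries:
    """Re-integrate to 60 s per-axis totals, then take the vector magnitude.

    Summing axes first and combining afterwards keeps minute counts
    well-defined for the minute-based non-wear rule; the stream must be
    aligned to a minute boundary.
    """
    if stream.epoch_s > 60:
        raise ValueError("epoch length exceeds one minute")
    if stream.start.second != 0 or stream.start.microsecond != 0:
        raise ValueError("stream not aligned to a minute boundary")
    per_minute = reintegrate(stream, 60)
    vm = vector_magnitude(
        per_minute.counts[:, 0], per_minute.counts[:, 1], per_minute.counts[:, 2]
    )
    return MinuteSeries(start=stream.start, vm=vm)


def _rle(categories: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode to (category, start, length) triples."""
    n = len(categories)
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(categories)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [
        (int(categories[s]), int(s), int(e - s)) for s, e in zip(starts, ends)
    ]


def detect_nonwear(
    series: MinuteSeries,
    min_bout_min: int = 60,
    max_interruption_min: int = 2,
    spike_tolerance: float = 100.0,
) -> MinuteSeries:
    """Mark non-wear minutes: long zero runs with a small interruption budget.

    Scanning left to right, a candidate bout starts at a zero-count
    minute and extends through further zeros, spending the interruption
    budget (default 2 minutes) on minutes with ``0 < vm <
    spike_tolerance``.  A minute at or above the tolerance, or an
    interruption beyond the budget, terminates the candidate, which is
    then trimmed back to its last zero minute.  Candidates whose total
    span (interruptions included) reaches ``min_bout_min`` are non-wear;
    scanning resumes at the next zero minute after the terminator.

    Implemented over a run-length encoding of the minute categories; an
    independent minute-by-minute reference lives in the test suite.
    """
    vm = series.vm
    cat = np.where(vm == 0, 0, np.where(vm < spike_tolerance, 1, 2))
    runs = _rle(cat)
    wear = np.ones(len(vm), dtype=bool)

    i = 0
    while i < len(runs):
        c, start, length = runs[i]
        if c != 0:
            i += 1
            continue
        last_zero_end = start + length - 1
        budget = max_interruption_min
        j = i + 1
        while j < len(runs):
            cj, sj, lj = runs[j]
            if cj == 0:
                last_zero_end = sj + lj - 1
            elif cj == 1 and lj <= budget:
                budget -= lj
            else:
                break
            j += 1
        if last_zero_end - start + 1 >= min_bout_min:
            wear[start : last_zero_end + 1] = False
        i = j + 1  # resume after the terminating run
    return MinuteSeries(start=series.start, vm=vm, wear=wear)


def daily_wear_summary(
    series: MinuteSeries, valid_day_min: int = 600
) -> pd.DataFrame:
    """Per-calendar-day wear minutes, wear-time counts and validity.

    A day is valid when it holds at least ``valid_day_min`` minutes of
    wear; vector-magnitude counts are summed over wear minutes only.
    """
    if series.wear is None:
        raise ValueError("wear flags not set; run detect_nonwear first")
    frame = series.to_frame()
    grouped = frame.groupby("date", sort=True)
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "wear_min": float(g["wear"].sum()),
                "vm_counts_during_wear": float(g.loc[g["wear"], "vm_counts"].sum()),
                "is_weekend": bool(g["is_weekend"].iloc[0]),
            }
        ),
        include_groups=False,
    )
    out["is_valid"] = out["wear_min"] >= valid_day_min
    return out.reset_index()


def compute_cpm(
    daily: pd.DataFrame,
    participant_id: str = "",
    min_valid_weekdays: int = 3,
    min_valid_weekend_days: int = 1,
) -> CpmResult:
    """CPM over valid days and the wear-protocol verdict.

    ``cpm = sum(wear-time counts) / sum(wear minutes)`` over valid days
    only; the protocol requires at least three valid weekdays and one
    valid weekend day.  With no valid wear time the CPM is undefined
    (NaN) and the participant fails the protocol.
    """
    if len(daily) == 0:
        raise ValueError("no daily summaries")
    valid = daily[daily["is_valid"]]
    total = float(valid["vm_counts_during_wear"].sum())
    minutes = float(valid["wear_min"].sum())
    n_weekday = int((~valid["is_weekend"]).sum())
    n_weekend = int(valid["is_weekend"].sum())
    cpm = total / minutes if minutes > 0 else float("nan")
    protocol_valid = (
        n_weekday >= min_valid_weekdays
        and n_weekend >= min_valid_weekend_days
        and minutes > 0
    )
    return CpmResult(
        participant_id=participant_id,
        total_vm_counts=total,
        valid_wear_minutes=minutes,
        cpm=cpm,
        n_valid_weekdays=n_weekday,
        n_valid_weekend_days=n_weekend,
        protocol_valid=protocol_valid,
    )


def process_stream(
    stream: EpochStream,
    participant_id: str = "",
    min_bout_min: int = 60,
    max_interruption_min: int = 2,
    spike_tolerance: float = 100.0,
    valid_day_min: int = 600,
    min_valid_weekdays: int = 3,
    min_valid_weekend_days: int = 1,
) -> tuple[CpmResult, pd.DataFrame]:
    """Full chain: epochs -> minutes -> non-wear -> daily summary -> CPM."""
    series = detect_nonwear(
        to_minute_series(stream),
        min_bout_min=min_bout_min,
        max_interruption_min=max_interruption_min,
        spike_tolerance=spike_tolerance,
    )
    daily = daily_wear_summary(series, valid_day_min=valid_day_min)
    result = compute_cpm(
        daily,
        participant_id=participant_id,
        min_valid_weekdays=min_valid_weekdays,
        min_valid_weekend_days=min_valid_weekend_days,
    )
    return result, daily
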