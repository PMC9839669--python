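"""Time-domain HRV metrics over protocol windows.

Four measures are computed per window: mean heart rate (HR, bpm), mean
inter-beat interval (RRmean, s), the root mean square of successive
interval differences (RMSSD, s) and the standard deviation of intervals
(SDNN, s).  Reactivity is the stress2-minus-baseline change in HR and
RRmean.

Conventions (all configurable where noted):

* HR is the mean of instantaneous rates 60/RRi (default).  The
  alternative 60/RRmean is always <= the default (Jensen); the default
  matches the convention of common HRV software where group-mean HR
  exceeds 60/RRmean.
* SDNN uses the sample standard deviation (n-1 divisor) by default.
* Intervals belong to a half-open window [start, start+dur) by their
  *end* time, so no interval is double-counted at a boundary.
* RMSSD differences are taken only between consecutive *accepted*
  intervals; a rejected interval breaks the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import HRVSummary, RRSeries
from .schedule import PhaseSchedule


def window_rr(rr: RRSeries, start_s: float, dur_s: float) -> RRSeries:
    """Accepted intervals whose end time lies in ``[start_s, start_s+dur_s)``."""
    if dur_s <= 0:
        raise ValueError("window duration must be positive")
    t = rr.interval_end_times_s
    keep = (t >= start_s) & (t < start_s + dur_s) & rr.accepted
    return RRSeries(
        rr.intervals_s[keep], t[keep], np.zeros(int(keep.sum()), dtype=int)
    )


def rr_mean(rr: RRSeries) -> float | None:
    x = rr.accepted_intervals()
    if x.size < 1:
        return None
    return float(np.mean(x))


def mean_hr(rr: RRSeries, convention: str = "instantaneous") -> float | None:
    """Mean heart rate in bpm.

    ``instantaneous`` (default): mean of 60/RRi over accepted intervals.
    ``from_mean``: 60 / mean(RRi).
    """
    x = rr.accepted_intervals()
    if x.size < 1:
        return None
    if convention == "instantaneous":
        return float(np.mean(60.0 / x))
    if convention == "from_mean":
        return float(60.0 / np.mean(x))
    raise ValueError(f"unknown HR convention {convention!r}")


def rmssd(rr: RRSeries) -> float | None:
    """Root mean square of successive differences of accepted intervals.

    Differences are formed only across consecutive accepted pairs: a
    rejected interval between two accepted ones removes both differences
    it would participate in.
    """
    ok = rr.accepted
    if int(ok.sum()) < 2:
        return None
    x = rr.intervals_s
    pair = ok[:-1] & ok[1:]
    if not pair.any():
        return None
    d = np.diff(x)[pair]
    return float(math.sqrt(np.mean(d * d)))


def sdnn(rr: RRSeries, ddof: int = 1) -> float | None:
    """Sample standard deviation of accepted intervals (n-1 by default)."""
    x = rr.accepted_intervals()
    if x.size < 2:
        return None
    return float(np.std(x, ddof=ddof))


def summarize_window(
    rr: RRSeries,
    subject_id: str,
    window: str,
    hr_convention: str = "instantaneous",
) -> HRVSummary:
    """HRV summary of an already-windowed RR series.

    Windows with fewer than 3 beats (2 intervals) yield missing metrics.
    """
    n_intervals = int(rr.accepted.sum())
    n_beats = n_intervals + 1 if n_intervals else 0
    if n_beats < 3:
        return HRVSummary(subject_id, window, None, None, None, None, n_beats)
    return HRVSummary(
        subject_id=subject_id,
        window=window,
        hr_bpm=mean_hr(rr, hr_convention),
        rr_mean_s=rr_mean(rr),
        rmssd_s=rmssd(rr),
        sdnn_s=sdnn(rr),
        n_beats=n_beats,
    )


def phase_summaries(
    rr: RRSeries,
    schedule: PhaseSchedule,
    subject_id: str,
    hr_convention: str = "instantaneous",
) -> list[HRVSummary]:
    """One HRVSummary per analysis window (baseline + each phase)."""
    out = []
    for label in schedule.window_labels:
        start, dur = schedule.window(label)
        out.append(
            summarize_window(
                window_rr(rr, start, dur), subject_id, label, hr_convention
            )
        )
    return out


@dataclass(frozen=True)
class ReactivityRecord:
    """Stress2-minus-baseline reactivity of HR and RRmean."""

    subject_id: str
    delta_hr_bpm: float | None
    delta_rr_mean_s: float | None
    reason_missing: str | None = None

    @property
    def complete(self) -> bool:
        return self.delta_hr_bpm is not None and self.delta_rr_mean_s is not None


def reactivity(
    summaries: list[HRVSummary],
    baseline_window: str = "baseline",
    stress_window: str = "stress2",
) -> ReactivityRecord:
    """dHR = HR_stress2 - HR_baseline; dRRmean likewise."""
    by_window = {s.window: s for s in summaries}
    sid = summaries[0].subject_id if summaries else ""
    for w in (baseline_window, stress_window):
        if w not in by_window:
            return ReactivityRecord(sid, None, None, f"no {w} summary")
        s = by_window[w]
        if s.hr_bpm is None or s.rr_mean_s is None:
            return ReactivityRecord(sid, None, None, f"{w} metrics missing")
    b, s2 = by_window[baseline_window], by_window[stress_window]
    return ReactivityRecord(
        sid, s2.hr_bpm - b.hr_bpm, s2.rr_mean_s - b.rr_mean_s
    )
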