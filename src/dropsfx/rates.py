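"""Run-level and time-binned hit and indexing statistics.

Definitions, matching how such beamtimes are reported:

* hit rate — percentage of hits among all collected patterns;
* crystal-level indexing rate — indexed crystals of the *correct* (own)
  unit cell divided by the number of hits; a multi-crystal pattern
  contributes each of its indexed crystals, so the rate may exceed 100%;
* event-level indexing rate — percentage of hits with at least one indexed
  crystal of any cell, multi-crystal hits counted once (the time-binned
  quantity);
* run summary — hits, rates, average peak count over hits, average Bragg
  peak intensity over all found peaks, average diffraction limit over
  indexed events.

Displayed rates are rounded to one decimal, half away from zero; full
precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd


class UndefinedRateError(ValueError):
    """Rate requested over an empty denominator."""


class Rate(NamedTuple):
    """A percentage plus a validity flag (False when the denominator was 0)."""

    value: float
    defined: bool = True


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (971/2 -> 92.0-style table presentation)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class EventRecord:
    """Per-event analysis outcome: the unit of all rate statistics."""

    event_id: int
    time_s: float
    n_peaks: int
    is_hit: bool
    mean_peak_intensity: float = float("nan")
    indexed_crystals_per_cell: dict = field(default_factory=dict)
    resolution_limit: float | None = None   # Å; None if unindexed

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if any(v < 0 for v in self.indexed_crystals_per_cell.values()):
            raise ValueError("indexed counts must be >= 0")

    @property
    def n_indexed_total(self) -> int:
        return sum(self.indexed_crystals_per_cell.values())


@dataclass
class RunTable:
    """Ordered events of one run, with absolute wall-clock event times."""

    run_id: int
    sample_label: str
    events: list[EventRecord]
    duration_s: float

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if times and self.duration_s < times[-1] - times[0]:
            raise ValueError("duration shorter than the event time span")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_hits(self) -> int:
        return sum(e.is_hit for e in self.events)

    @property
    def start_time(self) -> float:
        return self.events[0].time_s if self.events else 0.0

    @property
    def end_time(self) -> float:
        return self.events[-1].time_s if self.events else 0.0


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

def hit_rate(n_hits: int, n_events: int) -> float:
    """Percentage of hits among all collected patterns."""
    if n_events <= 0:
        raise UndefinedRateError("hit rate undefined for zero events")
    return 100.0 * n_hits / n_events


def crystal_indexing_rate(n_indexed_correct_cell: int, n_hits: int) -> Rate:
    """Indexed crystals (correct cell) per hit, as a percentage.

    Zero hits yields ``Rate(0.0, defined=False)`` — summary tables print 0
    for such runs while the flag keeps the value machine-distinguishable.
    """
    if n_hits < 0 or n_indexed_correct_cell < 0:
        raise ValueError("counts must be >= 0")
    if n_hits == 0:
        return Rate(0.0, defined=False)
    return Rate(100.0 * n_indexed_correct_cell / n_hits, defined=True)


def event_indexing_rate(events: list[EventRecord]) -> Rate:
    """Percentage of hits with ≥1 indexed crystal of any cell.

    Multi-crystal hits count once. Undefined (flagged) when the bin holds
    no hits.
    """
    hits = [e for e in events if e.is_hit]
    if not hits:
        return Rate(0.0, defined=False)
    n_indexed_events = sum(1 for e in hits if e.n_indexed_total >= 1)
    return Rate(100.0 * n_indexed_events / len(hits), defined=True)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def run_summary(run: RunTable, correct_cell: str) -> dict:
    """One summary row per run, mirroring a beamtime results table.

    Averages over an empty set (a run of blanks) are reported as None.
    Rates carry both the full-precision value and the one-decimal display
    rounding.
    """
    events = run.events
    n_events = run.n_events
    n_hits = run.n_hits
    hits = [e for e in events if e.is_hit]

    cells = sorted({c for e in events for c in e.indexed_crystals_per_cell})
    indexed_per_cell = {c: sum(e.indexed_crystals_per_cell.get(c, 0)
                               for e in events) for c in cells}
    n_indexed_correct = indexed_per_cell.get(correct_cell, 0)
    idx_rate = crystal_indexing_rate(n_indexed_correct, n_hits)

    total_peaks = sum(e.n_peaks for e in events)
    intensity_mass = sum(e.mean_peak_intensity * e.n_peaks for e in events
                         if e.n_peaks > 0 and not math.isnan(e.mean_peak_intensity))
    dlims = [e.resolution_limit for e in events
             if e.resolution_limit is not None]

    return {
        "run": run.run_id,
        "sample": run.sample_label,
        "duration_s": run.duration_s,
        "n_events": n_events,
        "n_hits": n_hits,
        "hit_rate_pct": round_half_away(hit_rate(n_hits, n_events))
        if n_events > 0 else None,
        "indexed_per_cell": indexed_per_cell,
        "indexing_rate_pct": round_half_away(idx_rate.value),
        "indexing_rate_defined": idx_rate.defined,
        "avg_n_peaks": (sum(e.n_peaks for e in hits) / n_hits)
        if n_hits > 0 else None,
        "avg_peak_intensity_adu": (intensity_mass / total_peaks)
        if total_peaks > 0 else None,
        "avg_resolution_limit_A": (sum(dlims) / len(dlims)) if dlims else None,
    }


# ---------------------------------------------------------------------------
# time-binned series
# ---------------------------------------------------------------------------

@dataclass
class BinnedSeries:
    """Hit and event-indexing rates on a uniform wall-clock binning.

    Bins with no events are flagged empty (NaN rates), never zero-filled;
    gaps between runs therefore appear as stretches of empty bins.
    """

    bin_width_s: float
    bin_edges: np.ndarray            # (n_bins + 1,)
    n_events: np.ndarray
    n_hits: np.ndarray
    hit_rate_pct: np.ndarray         # NaN where no events
    event_indexing_rate_pct: np.ndarray  # NaN where no hits
    valid: np.ndarray                # bool: bin contains >= 1 event

    @property
    def n_bins(self) -> int:
        return len(self.n_events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_s": self.bin_edges[:-1],
            "bin_end_s": self.bin_edges[1:],
            "n_events": self.n_events,
            "n_hits": self.n_hits,
            "hit_rate_pct": self.hit_rate_pct,
            "event_indexing_rate_pct": self.event_indexing_rate_pct,
            "valid_flag": self.valid,
        })


def binned_series(runs: list[RunTable], bin_width_s: float) -> BinnedSeries:
    """Bin the concatenated wall-clock timeline of several runs.

    Event times are absolute, so wash/reload intervals between runs show up
    as empty bins. Bin edges are anchored at the first run's first event
    time. Overlapping run intervals are rejected.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    populated = [r for r in runs if r.events]
    if not populated:
        raise ValueError("no events to bin")
    ordered = sorted(populated, key=lambda r: r.start_time)
    for r0, r1 in zip(ordered, ordered[1:]):
        if r1.start_time <= r0.end_time:
            raise ValueError(
                f"run intervals overlap (run {r0.run_id} vs {r1.run_id})")

    t0 = ordered[0].start_time
    t_end = max(r.end_time for r in ordered)
    n_bins = max(1, int(math.floor((t_end - t0) / bin_width_s)) + 1)
    edges = t0 + bin_width_s * np.arange(n_bins + 1)

    events = [e for r in ordered for e in r.events]
    idx = np.clip(((np.array([e.time_s for e in events]) - t0)
                   // bin_width_s).astype(int), 0, n_bins - 1)
    n_events = np.bincount(idx, minlength=n_bins)
    n_hits = np.bincount(idx, weights=[float(e.is_hit) for e in events],
                         minlength=n_bins).astype(int)

    hit_pct = np.full(n_bins, np.nan)
    eidx_pct = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if n_events[b] > 0:
            hit_pct[b] = hit_rate(int(n_hits[b]), int(n_events[b]))
        bin_events = [e for e, i in zip(events, idx) if i == b]
        r = event_indexing_rate(bin_events)
        if r.defined:
            eidx_pct[b] = r.value
    return BinnedSeries(bin_width_s=bin_width_s, bin_edges=edges,
                        n_events=n_events, n_hits=n_hits,
                        hit_rate_pct=hit_pct,
                        event_indexing_rate_pct=eidx_pct,
                        valid=n_events > 0)


# ---------------------------------------------------------------------------
# building runs from analysis output
# ---------------------------------------------------------------------------

def events_from_peak_analysis(peak_lists: dict[int, "object"],
                              times: dict[int, float],
                              min_peaks_per_hit: int = 15) -> list[EventRecord]:
    """Turn per-event peak lists into :class:`EventRecord` objects."""
    records = []
    for event_id in sorted(peak_lists):
        pl = peak_lists[event_id]
        n = len(pl)
        mean_int = float(np.mean(pl.intensities())) if n else float("nan")
        records.append(EventRecord(
            event_id=event_id, time_s=times[event_id], n_peaks=n,
            is_hit=n >= min_peaks_per_hit,
            mean_peak_intensity=mean_int))
    return records
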