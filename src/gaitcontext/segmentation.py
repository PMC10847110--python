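"""Stepping-bout detection and walking-period segmentation.

Free-living walking is start-and-stop: a walk to the shops contains brief
halts at doors and crossings. Stepping bouts separated by standing gaps
shorter than one minute are therefore grouped into a single *walking
period*, the unit of context classification. Gaps of exactly one minute or
longer split periods (strict less-than rule), and gaps spent on activities
other than standing always split, whatever their length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GAP_MAX_S, SegmentationConfig
from .signals import (
    AccelerometerRecording,
    StrideSequence,
    bandpass,
    detect_strides,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SteppingBout:
    start_s: float
    end_s: float
    source: str = "detected"  # detected | ingested

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout end must come after its start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class WalkingPeriod:
    """A group of stepping bouts whose inter-bout standing gaps are all
    below the grouping threshold."""

    participant_id: str
    bouts: list[SteppingBout]
    strides: StrideSequence | None = None
    period_id: str = ""

    @property
    def start_s(self) -> float:
        return self.bouts[0].start_s

    @property
    def end_s(self) -> float:
        return self.bouts[-1].end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def standing_time_s(self) -> float:
        return self.duration_s - sum(b.duration_s for b in self.bouts)


def detect_bouts(recording: AccelerometerRecording,
                 config: SegmentationConfig | None = None
                 ) -> list[SteppingBout]:
    """Detect stepping bouts from the raw waveform.

    A moving-RMS of the band-passed tri-axial acceleration (power summed
    over axes) is thresholded; sub-second dropouts are closed and segments
    shorter than the minimum bout length discarded. An empty recording
    yields an empty list.
    """
    cfg = config or SegmentationConfig()
    if recording.n_samples == 0:
        return []
    fs = recording.sampling_rate
    if recording.n_samples < int(4 * fs):
        return []
    dyn = bandpass(recording.samples.astype(float), fs)
    win = max(1, int(round(cfg.bout_window_s * fs)))
    kernel = np.ones(win) / win
    power = np.convolve((dyn * dyn).sum(axis=1), kernel, mode="same")
    active = np.sqrt(power) > cfg.bout_rms_threshold_g

    # close gaps shorter than bout_close_gap_s
    close = int(round(cfg.bout_close_gap_s * fs))
    bounds = _runs(active)
    if close > 0 and len(bounds) > 1:
        merged = [bounds[0]]
        for s, e in bounds[1:]:
            if s - merged[-1][1] <= close:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        bounds = merged

    # refine edges against the bout's own plateau RMS: the fixed threshold
    # is low enough to catch weak gaits, which widens edges by roughly half
    # the smoothing window. A centred window holds half the walking power
    # at the true edge; the refinement level (fraction of the plateau
    # median) is set where boundary bias against generator ground truth
    # crosses zero, slightly below 1/sqrt(2) because the harmonic pulse
    # train concentrates power mid-cycle.
    rms = np.sqrt(power)
    refined = []
    for s, e in bounds:
        level = cfg.bout_refine_level * float(np.median(rms[s:e]))
        above = rms[s:e] >= max(level, cfg.bout_rms_threshold_g)
        idx = np.flatnonzero(above)
        if idx.size:
            refined.append((s + int(idx[0]), s + int(idx[-1]) + 1))
    bounds = refined

    min_len = int(round(cfg.bout_min_s * fs))
    t0 = recording.start_s
    return [
        SteppingBout(t0 + s / fs, t0 + e / fs, source="detected")
        for s, e in bounds
        if e - s >= min_len
    ]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of True runs; end is exclusive."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def ingest_bouts(table: pd.DataFrame) -> tuple[list[SteppingBout],
                                               list[tuple[float, float]]]:
    """Read a ground-truth activity table (columns start_s, end_s,
    activity); returns stepping bouts verbatim plus the standing intervals,
    which :func:`group_bouts` uses to decide which gaps may merge."""
    stepping = table[table["activity"] == "stepping"]
    standing = table[table["activity"] == "standing"]
    bouts = [
        SteppingBout(float(r.start_s), float(r.end_s), source="ingested")
        for r in stepping.itertuples()
    ]
    intervals = [(float(r.start_s), float(r.end_s))
                 for r in standing.itertuples()]
    return bouts, intervals


def group_bouts(bouts: list[SteppingBout], gap_max_s: float = GAP_MAX_S,
                standing_intervals: list[tuple[float, float]] | None = None,
                participant_id: str = "") -> list[WalkingPeriod]:
    """Group consecutive bouts into walking periods.

    Bouts merge iff their gap is strictly below ``gap_max_s`` *and*, when
    ``standing_intervals`` is provided, the gap is fully covered by
    standing (a sitting or other-activity gap splits regardless of
    length). Input must be sorted and non-overlapping.

    Raises
    ------
    ValueError
        On unsorted or overlapping bouts.
    """
    if not bouts:
        return []
    for prev, cur in zip(bouts, bouts[1:]):
        if cur.start_s < prev.end_s:
            raise ValueError(
                f"bouts overlap or are unsorted: [{prev.start_s}, {prev.end_s}] "
                f"followed by [{cur.start_s}, {cur.end_s}]"
            )

    periods: list[list[SteppingBout]] = [[bouts[0]]]
    for cur in bouts[1:]:
        prev = periods[-1][-1]
        gap = cur.start_s - prev.end_s
        merge = gap < gap_max_s
        if merge and standing_intervals is not None and gap > 0:
            merge = _covered(prev.end_s, cur.start_s, standing_intervals)
        if merge:
            periods[-1].append(cur)
        else:
            periods.append([cur])
    return [
        WalkingPeriod(participant_id, group, period_id=f"{participant_id}_{i:04d}")
        for i, group in enumerate(periods)
    ]


def _covered(start: float, end: float,
             intervals: list[tuple[float, float]], tol: float = 1e-6) -> bool:
    """True if [start, end] is fully covered by the union of intervals."""
    cursor = start
    for s, e in sorted(intervals):
        if e <= cursor + tol:
            continue
        if s > cursor + tol:
            break
        cursor = max(cursor, e)
        if cursor >= end - tol:
            return True
    return cursor >= end - tol


def attach_strides(periods: list[WalkingPeriod],
                   recording: AccelerometerRecording,
                   min_bout_s: float = 2.0) -> None:
    """Detect and attach the concatenated per-bout stride sequence of each
    period (in place)."""
    for period in periods:
        events = []
        discarded = 0
        for bout in period.bouts:
            if bout.duration_s < min_bout_s:
                continue
            seq = detect_strides(recording, (bout.start_s, bout.end_s))
            discarded += seq.n_discarded
            if len(seq) >= 2:
                events.append(seq.events)
        if events:
            period.strides = StrideSequence(np.concatenate(events),
                                            n_discarded=discarded)
        else:
            period.strides = StrideSequence(np.empty(0), n_discarded=discarded)


def period_frequencies(period: WalkingPeriod) -> np.ndarray:
    """Stride frequencies of a period, computed within bouts only (the
    interval spanning a standing gap is not a stride)."""
    if period.strides is None or period.strides.is_empty:
        return np.empty(0)
    events = period.strides.events
    freqs = []
    for bout in period.bouts:
        sel = events[(events >= bout.start_s - 1e-9)
                     & (events <= bout.end_s + 1e-9)]
        if sel.size >= 2:
            freqs.append(1.0 / np.diff(sel))
    return np.concatenate(freqs) if freqs else np.empty(0)


def exclude_running(periods: list[WalkingPeriod],
                    cadence_max_hz: float = 1.4
                    ) -> tuple[list[WalkingPeriod], int]:
    """Drop periods whose median stride frequency exceeds the walking
    cadence ceiling (a running episode); returns (kept, n_removed)."""
    kept = []
    removed = 0
    for period in periods:
        freqs = period_frequencies(period)
        if freqs.size and float(np.median(freqs)) > cadence_max_hz:
            removed += 1
        else:
            kept.append(period)
    if removed:
        logger.info("excluded %d running-like periods", removed)
    return kept, removed
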