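"""Replication-timing quintiles and mutation-density profiles.

A timing track partitions the genome into intervals carrying either a
continuous replication-timing value (smaller = earlier replication) or a
pre-assigned quintile label 1-5 (1 = earliest).  Mutations are assigned to
quintiles, per-quintile counts are normalized to the largest quintile of
each group, and the per-quintile TC-to-TT percentage is reported — the
classic view of how a mutational process tracks replication timing.

BED intervals are 0-based half-open; mutation positions are 1-based and
converted at the boundary.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .spectrum import tc_to_tt_fraction
from .variants import MutationRecord

logger = logging.getLogger(__name__)

QUINTILES = (1, 2, 3, 4, 5)


class TimingInterval(NamedTuple):
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    value: float  # timing value, or quintile label when track is labeled


@dataclass
class TimingTrack:
    """Non-overlapping genomic intervals with timing values or labels."""

    intervals: list[TimingInterval]
    labeled: bool = False

    def __post_init__(self) -> None:
        by_contig: dict[str, list[TimingInterval]] = {}
        for iv in self.intervals:
            if iv.end <= iv.start:
                raise ValueError(f"empty interval {iv}")
            by_contig.setdefault(iv.contig, []).append(iv)
        for contig, ivs in by_contig.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping intervals on {contig}: {a}, {b}")
        if self.labeled:
            labels = {iv.value for iv in self.intervals}
            if not labels <= {1.0, 2.0, 3.0, 4.0, 5.0}:
                raise ValueError(f"quintile labels must be 1..5, got {sorted(labels)}")
        self._by_contig = {
            contig: (
                [iv.start for iv in ivs],
                ivs,
            )
            for contig, ivs in by_contig.items()
        }

    @property
    def total_length(self) -> int:
        return sum(iv.end - iv.start for iv in self.intervals)

    def lookup(self, contig: str, position: int) -> TimingInterval | None:
        """Interval containing a 1-based position, or None."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, ivs = entry
        pos0 = position - 1  # to 0-based
        i = bisect_right(starts, pos0) - 1
        if i >= 0 and ivs[i].start <= pos0 < ivs[i].end:
            return ivs[i]
        return None


def quintilize(track: TimingTrack) -> TimingTrack:
    """Label intervals 1-5 by length-weighted quantile cut of timing values.

    Smaller timing values map to earlier quintiles; each quintile covers
    about 20% of tracked bases.  Ties in value are broken toward the
    earlier quintile.  Requires at least 5 distinct values.
    """
    if track.labeled:
        return track
    values = {iv.value for iv in track.intervals}
    if len(values) < 5:
        raise ValueError(f"need >= 5 distinct timing values, got {len(values)}")
    order = sorted(
        range(len(track.intervals)), key=lambda i: track.intervals[i].value
    )
    total = track.total_length
    labels = [0] * len(track.intervals)
    cum = 0
    for i in order:
        length = track.intervals[i].end - track.intervals[i].start
        mid = cum + length / 2
        labels[i] = min(5, int(mid / (total / 5)) + 1)
        cum += length
    labeled = [
        TimingInterval(iv.contig, iv.start, iv.end, float(labels[i]))
        for i, iv in enumerate(track.intervals)
    ]
    return TimingTrack(labeled, labeled=True)


def assign_quintiles(
    records: Iterable[MutationRecord], track: TimingTrack
) -> dict[int | str, list[MutationRecord]]:
    """Map each record to its interval's quintile.

    Records outside every interval land in the ``"untracked"`` bin, which
    profiles ignore (count logged).
    """
    if not track.labeled:
        raise ValueError("track must be labeled; run quintilize first")
    bins: dict[int | str, list[MutationRecord]] = {q: [] for q in QUINTILES}
    bins["untracked"] = []
    for rec in records:
        iv = track.lookup(rec.contig, rec.position)
        if iv is None:
            bins["untracked"].append(rec)
        else:
            bins[int(iv.value)].append(rec)
    if bins["untracked"]:
        logger.info("%d records outside the timing track", len(bins["untracked"]))
    return bins


@dataclass
class QuintileProfile:
    """Per-quintile mutation counts, largest-quintile-normalized densities,
    and TC-to-TT percentages for one group of samples."""

    group_id: str
    counts: list[int]
    normalized: list[float]
    tc_tt_percent: list[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quintile": list(QUINTILES),
                "count": self.counts,
                "normalized": self.normalized,
                "tc_tt_percent": self.tc_tt_percent,
            }
        )


def quintile_profile(
    assignment: dict[int | str, list[MutationRecord]],
    genome: GenomeSequence,
    group_id: str,
) -> QuintileProfile:
    """Profile from a quintile assignment (pooled over a group's samples)."""
    counts = [len(assignment.get(q, [])) for q in QUINTILES]
    peak = max(counts)
    if peak == 0:
        raise ValueError(f"group {group_id}: no mutations in tracked regions")
    normalized = [c / peak for c in counts]
    tc_tt = [
        100.0 * tc_to_tt_fraction(assignment.get(q, []), genome) for q in QUINTILES
    ]
    return QuintileProfile(group_id, counts, normalized, tc_tt)


def read_timing_bed(path: str) -> TimingTrack:
    """Read a BED4/BED5 timing track.

    The timing value is taken from the 4th column when numeric, else the
    5th (score) column.  If every value is an integer in 1..5 the track is
    treated as pre-labeled quintiles.
    """
    intervals = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: need >= 4 BED columns")
            value = None
            try:
                value = float(parts[3])
            except ValueError:
                if len(parts) >= 5:
                    value = float(parts[4])
            if value is None:
                raise ValueError(f"{path}:{line_no}: no numeric timing value")
            intervals.append(
                TimingInterval(parts[0], int(parts[1]), int(parts[2]), value)
            )
    values = [iv.value for iv in intervals]
    labeled = all(v == int(v) and 1 <= v <= 5 for v in values)
    return TimingTrack(intervals, labeled=labeled)


def write_timing_bed(track: TimingTrack, path: str) -> None:
    with open(path, "w") as handle:
        for iv in track.intervals:
            value = int(iv.value) if track.labeled else iv.value
            handle.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{value}\n")
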