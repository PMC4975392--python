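"""Sliding-window CpG-island searcher.

Implements the classic Takai–Jones search shape: a 200 bp seed window
stepped 1 bp until both ratio criteria (GC% and observed/expected CpG)
are met, extension by 200 bp jumps while they hold, 1 bp trimming of the
candidate until the whole region satisfies the criteria, merging of
candidates separated by small gaps when the merged region still
qualifies, and a minimum-length filter.  The pipeline defaults are
GC >= 55%, ObsCpG/ExpCpG >= 0.65 and length >= 500 bp.

ObsCpG counts "CG" dinucleotides; ExpCpG = (#C * #G) / length, so the
O/E ratio is ObsCpG * length / (#C * #G).  N bases count toward window
length but never toward C, G or CpG; runs of N at least one scan window
long split the sequence into independently scanned segments.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .io_formats import SequenceRecord

__all__ = ["IslandParams", "CpGIsland", "gc_content", "obs_exp_cpg", "find_islands"]


@dataclass(frozen=True)
class IslandParams:
    """Search thresholds; defaults are the pipeline's standard values."""

    gc_min: float = 55.0
    oe_min: float = 0.65
    len_min: int = 500
    scan_window: int = 200
    merge_gap: int = 100
    merge: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.gc_min <= 100):
            raise ValueError(f"gc_min out of range: {self.gc_min}")
        if self.oe_min <= 0:
            raise ValueError(f"oe_min must be positive: {self.oe_min}")
        if self.len_min < self.scan_window:
            raise ValueError("len_min must be >= scan_window")


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_percent: float
    obs_exp: float
    obs_cpg: int

    @property
    def length(self) -> int:
        return self.interval.length


def gc_content(seq: str) -> float:
    """GC percentage: 100 * (#C + #G) / length, N in the denominator only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("C") + s.count("G")) / len(s)


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG ratio; 0 when the sequence lacks C or G."""
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 bp")
    s = seq.upper()
    c, g = s.count("C"), s.count("G")
    if c == 0 or g == 0:
        return 0.0
    obs = s.count("CG")
    return obs * len(s) / (c * g)


class _SegmentStats:
    """O(1) criteria checks over arbitrary spans via prefix sums."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        self.n = len(arr)
        self.pc = np.concatenate(([0], np.cumsum(is_c)))
        self.pg = np.concatenate(([0], np.cumsum(is_g)))
        cg = is_c[:-1] & is_g[1:] if len(arr) > 1 else np.zeros(0, dtype=bool)
        self.pcg = np.concatenate(([0], np.cumsum(cg)))

    def counts(self, start: int, end: int) -> tuple[int, int, int]:
        c = int(self.pc[end] - self.pc[start])
        g = int(self.pg[end] - self.pg[start])
        # CG pairs fully inside [start, end)
        obs = int(self.pcg[max(start, end - 1)] - self.pcg[start]) if end - start >= 2 else 0
        return c, g, obs

    def gc_percent(self, start: int, end: int) -> float:
        c, g, _ = self.counts(start, end)
        return 100.0 * (c + g) / (end - start)

    def obs_exp(self, start: int, end: int) -> float:
        c, g, obs = self.counts(start, end)
        if c == 0 or g == 0:
            return 0.0
        return obs * (end - start) / (c * g)

    def meets(self, start: int, end: int, params: IslandParams) -> bool:
        c, g, obs = self.counts(start, end)
        if c == 0 or g == 0:
            return False
        length = end - start
        if 100.0 * (c + g) < params.gc_min * length:
            return False
        return obs * length >= params.oe_min * c * g

    def window_meets_array(self, w: int, params: IslandParams) -> np.ndarray:
        """Boolean array over all window start positions [0, n-w]."""
        if self.n < w:
            return np.zeros(0, dtype=bool)
        c = self.pc[w:] - self.pc[:-w]
        g = self.pg[w:] - self.pg[:-w]
        obs = self.pcg[w - 1 :] - self.pcg[: self.n - w + 1]
        ok = (c > 0) & (g > 0)
        ok &= 100.0 * (c + g) >= params.gc_min * w
        ok &= obs * w >= params.oe_min * c * g
        return ok


def _shrink(stats: _SegmentStats, start: int, end: int, params: IslandParams) -> tuple[int, int] | None:
    """Trim 1 bp at a time until the whole span meets both criteria.

    When either end could be trimmed, the base whose removal raises GC%
    more goes first; on a tie the right end is trimmed, which keeps the
    output deterministic.
    """
    while end - start >= 2:
        if stats.meets(start, end, params):
            return start, end
        gc_left = stats.gc_percent(start + 1, end)
        gc_right = stats.gc_percent(start, end - 1)
        if gc_left > gc_right:
            start += 1
        else:
            end -= 1
    return None


def _scan_segment(stats: _SegmentStats, params: IslandParams) -> list[tuple[int, int]]:
    w = params.scan_window
    meets = stats.window_meets_array(w, params)
    hits = np.flatnonzero(meets)
    n = stats.n
    candidates: list[tuple[int, int]] = []
    pos = 0
    while True:
        j = np.searchsorted(hits, pos)
        if j >= len(hits):
            break
        start = int(hits[j])
        end = start + w
        while end + w <= n and meets[end]:
            end += w
        # fine extension: push the end 1 bp at a time while the trailing
        # scan window still qualifies, so island tails shorter than a
        # full jump are not dropped
        while end < n and stats.meets(end + 1 - w, end + 1, params):
            end += 1
        shrunk = _shrink(stats, start, end, params)
        if shrunk is not None:
            candidates.append(shrunk)
            pos = max(shrunk[1], start + 1)
        else:
            pos = start + 1
    return candidates


def _merge_candidates(
    stats: _SegmentStats, candidates: list[tuple[int, int]], params: IslandParams
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in candidates:
        if out and s - out[-1][1] < params.merge_gap and stats.meets(out[-1][0], e, params):
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def find_islands(record: SequenceRecord, params: IslandParams = IslandParams()) -> list[CpGIsland]:
    """Locate CpG islands on one sequence.

    Every reported island satisfies all three criteria (GC%, O/E,
    minimum length) over its full extent; islands are disjoint and
    sorted.  A sequence shorter than the scan window yields no islands.
    """
    seq = record.sequence.upper()
    islands: list[CpGIsland] = []
    # split on N-runs >= scan_window; shorter N runs are scanned through
    pattern = re.compile("N{%d,}" % params.scan_window)
    seg_start = 0
    segments: list[tuple[int, str]] = []
    for m in pattern.finditer(seq):
        if m.start() > seg_start:
            segments.append((seg_start, seq[seg_start : m.start()]))
        seg_start = m.end()
    if seg_start < len(seq):
        segments.append((seg_start, seq[seg_start:]))

    for offset, segseq in segments:
        if len(segseq) < params.scan_window:
            continue
        stats = _SegmentStats(segseq)
        candidates = _scan_segment(stats, params)
        if params.merge:
            candidates = _merge_candidates(stats, candidates, params)
        for s, e in candidates:
            if e - s < params.len_min:
                continue
            c, g, obs = stats.counts(s, e)
            islands.append(
                CpGIsland(
                    interval=GenomicInterval(record.name, offset + s, offset + e),
                    gc_percent=stats.gc_percent(s, e),
                    obs_exp=stats.obs_exp(s, e),
                    obs_cpg=obs,
                )
            )
    return islands


def islands_to_bed(islands: list[CpGIsland]) -> list[GenomicInterval]:
    """BED4 representation with name ``CpG:<ObsCpG count>``."""
    return [
        GenomicInterval(
            isl.interval.chrom,
            isl.interval.start,
            isl.interval.end,
            attrs=(f"CpG:{isl.obs_cpg}",),
        )
        for isl in islands
    ]
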