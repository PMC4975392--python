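"""Interval algebra underlying the pipeline.

All coordinates are 0-based half-open (BED convention) on exact-string
chromosome names.  This module builds the reference peak set (REF) by
merging per-sample peak calls at >= 1 bp overlap, derives the genomic
feature windows used for peak annotation and region-level quantification
(3 kb upstream promoter, 5 kb downstream, +/- 1 kb TSS, UTRs, exon,
intron, whole gene, repeat classes), and assigns each REF peak a single
feature label by a fixed precedence.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import AnnotationTable

__all__ = [
    "GenomicInterval",
    "RefPeak",
    "RefPeakSet",
    "Window",
    "FeatureWindows",
    "merge_peak_sets",
    "derive_feature_windows",
    "annotate_peaks",
    "intersect_counts",
    "merge_interval_arrays",
    "ANNOTATION_PRECEDENCE",
]

#: single-label annotation precedence; anything overlapping none is intergenic
ANNOTATION_PRECEDENCE = ("promoter", "exon", "intron", "downstream")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).  Extra BED columns survive a
    round trip through :mod:`coldmeth.io_formats` in ``attrs``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    attrs: tuple = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValueError(f"non-integer coordinates: {self.start!r}, {self.end!r}")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class RefPeak:
    """One merged reference peak and the samples whose calls built it."""

    peak_id: str
    interval: GenomicInterval
    source_samples: frozenset

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class RefPeakSet:
    """Sorted, disjoint reference peak set — the common coordinate system.

    Peaks are sorted by (chrom, start), pairwise disjoint within each
    chromosome, and carry stable ids ``peak_00001`` ... assigned in
    sorted order.
    """

    def __init__(self, peaks: Sequence[RefPeak]):
        self.peaks = list(peaks)
        self._validate()
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        for chrom, group in itertools.groupby(
            range(len(self.peaks)), key=lambda i: self.peaks[i].chrom
        ):
            idx = list(group)
            starts = np.array([self.peaks[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.peaks[i].end for i in idx], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, idx)

    def _validate(self) -> None:
        seen = set()
        prev = None
        for p in self.peaks:
            if p.peak_id in seen:
                raise ValueError(f"duplicate peak_id {p.peak_id}")
            seen.add(p.peak_id)
            if prev is not None and prev.chrom == p.chrom:
                if p.start < prev.start:
                    raise ValueError("peaks not sorted by (chrom, start)")
                if p.start < prev.end:
                    raise ValueError(
                        f"overlapping peaks {prev.peak_id} and {p.peak_id}"
                    )
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[RefPeak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> RefPeak:
        return self.peaks[i]

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def chrom_arrays(self, chrom: str):
        """(starts, ends, global indices) for one chromosome, or empty."""
        if chrom not in self._by_chrom:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, []
        return self._by_chrom[chrom]

    def total_bases(self) -> int:
        return sum(p.interval.length for p in self.peaks)


def merge_peak_sets(
    peak_sets: Mapping[str, Sequence[GenomicInterval]]
) -> RefPeakSet:
    """Merge per-sample peak calls into the reference peak set (REF).

    Peaks sharing at least 1 bp (transitively) collapse into a single
    reference peak; half-open intervals that merely touch
    (``end == start``) do not merge.  ``source_samples`` records every
    sample whose call contributed to a merged peak.  The result is
    sorted, disjoint and idempotent under re-merging.
    """
    if not peak_sets:
        raise ValueError("at least one peak set required")
    events = []
    for sample in sorted(peak_sets):
        for iv in peak_sets[sample]:
            events.append((iv.chrom, iv.start, iv.end, sample))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    merged: list[tuple[str, int, int, set]] = []
    for chrom, start, end, sample in events:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] | {sample})
        else:
            merged.append((chrom, start, end, {sample}))
    width = max(5, len(str(len(merged))))
    peaks = [
        RefPeak(
            peak_id=f"peak_{i + 1:0{width}d}",
            interval=GenomicInterval(chrom, start, end),
            source_samples=frozenset(samples),
        )
        for i, (chrom, start, end, samples) in enumerate(merged)
    ]
    return RefPeakSet(peaks)


@dataclass(frozen=True)
class Window:
    """A feature window with the transcript/gene/repeat that owns it."""

    chrom: str
    start: int
    end: int
    strand: str
    owner: str  # transcript_id, gene_id or repeat instance id


@dataclass
class FeatureWindows:
    """Derived feature windows, grouped by window class.

    Classes: ``promoter_up3k``, ``downstream5k``, ``tss1k``, ``utr5``,
    ``utr3``, ``exon``, ``intron``, ``whole_gene`` and one
    ``repeat:<class>`` entry per repeat class present in the annotation.
    """

    windows: dict[str, list[Window]]
    chrom_sizes: dict[str, int]
    _merged_cache: dict = field(default_factory=dict, repr=False)

    def classes(self) -> list[str]:
        return sorted(self.windows)

    def merged(self, cls: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Disjoint, sorted (starts, ends) arrays per chromosome for a class."""
        if cls not in self._merged_cache:
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for w in self.windows.get(cls, []):
                per_chrom.setdefault(w.chrom, []).append((w.start, w.end))
            self._merged_cache[cls] = {
                chrom: merge_interval_arrays(ivs) for chrom, ivs in per_chrom.items()
            }
        return self._merged_cache[cls]


def merge_interval_arrays(
    intervals: Iterable[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse (start, end) pairs into sorted disjoint numpy arrays."""
    ivs = sorted(intervals)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _clip(start: int, end: int, size: int) -> tuple[int, int] | None:
    s, e = max(0, start), min(size, end)
    return (s, e) if s < e else None


def derive_feature_windows(
    annotation: "AnnotationTable",
    chrom_sizes: Mapping[str, int],
    promoter_bp: int = 3000,
    downstream_bp: int = 5000,
    tss_half: int = 1000,
) -> FeatureWindows:
    """Derive per-transcript feature windows from gene models.

    For a + strand transcript [s, e): promoter = [s - promoter_bp, s),
    downstream = [e, e + downstream_bp), tss1k = [s - tss_half,
    s + tss_half); the - strand mirrors all three around the transcript.
    All windows are clipped to [0, chrom_size).  Exon windows are
    unioned across the transcripts of a gene (so isoform-shared exons
    are not double counted); introns are the per-transcript complement
    of that transcript's exons within its span.
    """
    wins: dict[str, list[Window]] = {
        k: []
        for k in (
            "promoter_up3k",
            "downstream5k",
            "tss1k",
            "utr5",
            "utr3",
            "exon",
            "intron",
            "whole_gene",
        )
    }
    tx = annotation.transcripts
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    for row in annotation.exons.itertuples(index=False):
        exons_by_tx.setdefault(row.transcript_id, []).append((row.start, row.end))

    gene_exons: dict[str, list[tuple[str, str, int, int]]] = {}
    gene_span: dict[str, tuple[str, str, int, int]] = {}

    for row in tx.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"transcript {row.transcript_id} has no strand")
        size = chrom_sizes[row.chrom]
        if row.strand == "+":
            tss, tes = row.start, row.end
            prom = _clip(tss - promoter_bp, tss, size)
            down = _clip(tes, tes + downstream_bp, size)
        else:
            tss, tes = row.end, row.start
            prom = _clip(tss, tss + promoter_bp, size)
            down = _clip(tes - downstream_bp, tes, size)
        tss1k = _clip(tss - tss_half, tss + tss_half, size)
        for cls, span in (("promoter_up3k", prom), ("downstream5k", down), ("tss1k", tss1k)):
            if span is not None:
                wins[cls].append(Window(row.chrom, span[0], span[1], row.strand, row.transcript_id))

        ex = sorted(exons_by_tx.get(row.transcript_id, []))
        for s, e in ex:
            gene_exons.setdefault(row.gene_id, []).append((row.chrom, row.strand, s, e))
        # intron = transcript span minus its exons
        cursor = row.start
        for s, e in ex:
            if cursor < s:
                wins["intron"].append(Window(row.chrom, cursor, s, row.strand, row.transcript_id))
            cursor = max(cursor, e)
        if cursor < row.end:
            wins["intron"].append(Window(row.chrom, cursor, row.end, row.strand, row.transcript_id))

        g = gene_span.get(row.gene_id)
        if g is None:
            gene_span[row.gene_id] = (row.chrom, row.strand, row.start, row.end)
        else:
            gene_span[row.gene_id] = (g[0], g[1], min(g[2], row.start), max(g[3], row.end))

    for gene_id, exlist in gene_exons.items():
        chrom, strand = exlist[0][0], exlist[0][1]
        starts, ends = merge_interval_arrays((s, e) for _, _, s, e in exlist)
        for s, e in zip(starts, ends):
            wins["exon"].append(Window(chrom, int(s), int(e), strand, gene_id))
    for gene_id, (chrom, strand, s, e) in gene_span.items():
        wins["whole_gene"].append(Window(chrom, s, e, strand, gene_id))

    for table, cls in ((annotation.utr5, "utr5"), (annotation.utr3, "utr3")):
        for row in table.itertuples(index=False):
            strand = annotation.transcript_strand(row.transcript_id)
            wins[cls].append(Window(row.chrom, row.start, row.end, strand, row.transcript_id))

    for row in annotation.repeats.itertuples(index=False):
        cls = f"repeat:{row.repeat_class}"
        wins.setdefault(cls, []).append(
            Window(row.chrom, row.start, row.end, ".", f"{row.repeat_class}:{row.chrom}:{row.start}")
        )
    return FeatureWindows(windows=wins, chrom_sizes=dict(chrom_sizes))


def _overlaps_any(
    merged: Mapping[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    start: int,
    end: int,
) -> bool:
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    # first window with end > start; it overlaps iff its start < end
    i = int(np.searchsorted(ends, start, side="right"))
    return i < len(starts) and starts[i] < end

_LABEL_SOURCES = {
    "promoter": "promoter_up3k",
    "exon": "exon",
    "intron": "intron",
    "downstream": "downstream5k",
}


def annotate_peaks(ref: RefPeakSet, windows: FeatureWindows) -> dict[str, str]:
    """Assign each REF peak a single feature label.

    A peak qualifies for a class by >= 1 bp overlap with any window of
    that class; precedence promoter > exon > intron > downstream
    resolves multi-class peaks, and a peak overlapping none is
    ``intergenic``.  UTR and repeat windows participate in region-level
    quantification but not in this 5-way annotation.
    """
    merged_by_label = {
        label: windows.merged(cls) for label, cls in _LABEL_SOURCES.items()
    }
    out: dict[str, str] = {}
    for peak in ref:
        label = "intergenic"
        for cand in ANNOTATION_PRECEDENCE:
            if _overlaps_any(merged_by_label[cand], peak.chrom, peak.start, peak.end):
                label = cand
                break
        out[peak.peak_id] = label
    return out


def intersect_counts(ref: RefPeakSet, regions: Sequence[GenomicInterval]) -> int:
    """Number of REF peaks overlapping >= 1 bp of any region (count once)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {chrom: merge_interval_arrays(ivs) for chrom, ivs in per_chrom.items()}
    return sum(
        1 for p in ref if _overlaps_any(merged, p.chrom, p.start, p.end)
    )
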