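"""Read counting and normalization over reference peaks and region classes.

A read (supplied as an aligned interval) is assigned to the unique REF
peak sharing the largest overlap with it; because REF peaks are
disjoint, only boundary-spanning reads are ambiguous, and those break
ties to the leftmost peak.  Library size is the total number of supplied
read intervals, so RPM is reads-per-million *mapped* reads whether or
not a read landed in a peak.

Region-class quantification applies the same largest-overlap rule
within each class independently: a read may count toward several
overlapping classes (exon and whole-gene, say) but only once per class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .intervals import GenomicInterval, RefPeakSet

__all__ = [
    "PeakMatrix",
    "RegionInstance",
    "Dendrogram",
    "count_reads",
    "compute_rpm",
    "compute_rpkm",
    "build_peak_matrix",
    "build_region_matrix",
    "cluster_peaks",
    "dendrogram_to_newick",
]


def compute_rpm(count: float, lib_size: int) -> float:
    """Reads per million mapped reads: count / lib_size * 1e6."""
    if lib_size < 1:
        raise ValueError("lib_size must be >= 1")
    if count < 0:
        raise ValueError("negative count")
    return count / lib_size * 1e6


def compute_rpkm(count: float, length: int, lib_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if length < 1:
        raise ValueError("region length must be >= 1 bp")
    if lib_size < 1:
        raise ValueError("lib_size must be >= 1")
    if count < 0:
        raise ValueError("negative count")
    return count / (length / 1000.0) / (lib_size / 1e6)


def _reads_to_arrays(reads: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out = {}
    for chrom, ivs in per_chrom.items():
        arr = np.array(ivs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def count_reads(
    ref: RefPeakSet, reads: Sequence[GenomicInterval]
) -> tuple[np.ndarray, int]:
    """Assign reads to REF peaks by largest overlap; ties go leftmost.

    Returns (per-peak counts aligned with ``ref`` order, lib_size).
    lib_size counts every supplied read, assigned or not, and
    assigned + unassigned = lib_size always.
    """
    counts = np.zeros(len(ref), dtype=np.int64)
    lib_size = len(reads)
    for chrom, (rs, re_) in _reads_to_arrays(reads).items():
        pstarts, pends, idx = ref.chrom_arrays(chrom)
        if len(pstarts) == 0:
            continue
        gidx = np.array(idx, dtype=np.int64)
        npk = len(pstarts)
        # first peak whose end > read start
        i0 = np.searchsorted(pends, rs, side="right")

        def overlap_at(j: np.ndarray) -> np.ndarray:
            valid = j < npk
            jj = np.minimum(j, npk - 1)
            ov = np.minimum(pends[jj], re_) - np.maximum(pstarts[jj], rs)
            return np.where(valid, np.maximum(ov, 0), 0)

        ov0 = overlap_at(i0)
        ov1 = overlap_at(i0 + 1)
        best = np.where(ov1 > ov0, i0 + 1, i0)  # tie -> leftmost (i0)
        best_ov = np.maximum(ov0, ov1)
        # reads spanning >= 3 peaks are rare; resolve them exactly
        third = i0 + 2
        spans3 = (third < npk) & (pstarts[np.minimum(third, npk - 1)] < re_)
        for k in np.flatnonzero(spans3):
            j = int(i0[k])
            b_ov, b_j = 0, -1
            while j < npk and pstarts[j] < re_[k]:
                ov = min(pends[j], re_[k]) - max(pstarts[j], rs[k])
                if ov > b_ov:
                    b_ov, b_j = ov, j
                j += 1
            best[k], best_ov[k] = b_j, b_ov
        hit = best_ov > 0
        np.add.at(counts, gidx[np.minimum(best[hit], npk - 1)], 1)
    return counts, lib_size


@dataclass
class PeakMatrix:
    """Per-peak, per-sample read counts with RPM and log2(RPM+1) views."""

    ref: RefPeakSet
    samples: list[str]
    counts: pd.DataFrame  # index = peak_id, columns = samples
    lib_sizes: pd.Series  # index = samples

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples):
            raise ValueError("counts columns must match sample order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for s in self.samples:
            if self.counts[s].sum() > self.lib_sizes[s]:
                raise ValueError(f"sample {s}: peak counts exceed lib_size")

    @property
    def rpm(self) -> pd.DataFrame:
        return self.counts / self.lib_sizes * 1e6

    @property
    def log_rpm(self) -> pd.DataFrame:
        return np.log2(self.rpm + 1.0)


def build_peak_matrix(
    ref: RefPeakSet, reads_by_sample: Mapping[str, Sequence[GenomicInterval]]
) -> PeakMatrix:
    samples = list(reads_by_sample)
    data = {}
    libs = {}
    for s in samples:
        cnt, lib = count_reads(ref, reads_by_sample[s])
        data[s] = cnt
        libs[s] = lib
    counts = pd.DataFrame(data, index=ref.peak_ids)
    return PeakMatrix(ref=ref, samples=samples, counts=counts, lib_sizes=pd.Series(libs))


@dataclass(frozen=True)
class RegionInstance:
    """One region instance of a class, possibly spliced (multi-interval)."""

    instance_id: str
    chrom: str
    blocks: tuple  # ((start, end), ...)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.blocks)


def _count_region_class(
    instances: Sequence[RegionInstance], reads: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-instance read counts with the largest-overlap / leftmost rule."""
    import pyranges as pr

    rows = []
    order = {
        inst.instance_id: rank
        for rank, inst in enumerate(
            sorted(instances, key=lambda x: (x.chrom, x.start, x.instance_id))
        )
    }
    for i, inst in enumerate(instances):
        for s, e in inst.blocks:
            rows.append((inst.chrom, s, e, i))
    blocks = pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "inst"])
    reads_df = pd.DataFrame(
        {
            "Chromosome": [r.chrom for r in reads],
            "Start": [r.start for r in reads],
            "End": [r.end for r in reads],
            "rid": np.arange(len(reads)),
        }
    )
    counts = np.zeros(len(instances), dtype=np.int64)
    if blocks.empty or reads_df.empty:
        return counts
    joined = pr.PyRanges(reads_df).join(pr.PyRanges(blocks)).df
    if joined.empty:
        return counts
    joined["ov"] = (
        np.minimum(joined["End"], joined["End_b"])
        - np.maximum(joined["Start"], joined["Start_b"])
    )
    per = joined.groupby(["rid", "inst"], as_index=False)["ov"].sum()
    per["rank"] = per["inst"].map(
        {i: order[inst.instance_id] for i, inst in enumerate(instances)}
    )
    per = per.sort_values(["rid", "ov", "rank"], ascending=[True, False, True])
    winners = per.drop_duplicates("rid", keep="first")
    np.add.at(counts, winners["inst"].to_numpy(), 1)
    return counts


def build_region_matrix(
    region_sets: Mapping[str, Sequence[RegionInstance]],
    reads_by_sample: Mapping[str, Sequence[GenomicInterval]],
    lib_sizes: Mapping[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """RPKM matrix (instances x samples) for each region class.

    Classes with no instances are omitted with a warning.  Counting is
    independent per class, so reads may contribute to several classes.
    """
    samples = list(reads_by_sample)
    libs = (
        {s: len(reads_by_sample[s]) for s in samples}
        if lib_sizes is None
        else dict(lib_sizes)
    )
    out: dict[str, pd.DataFrame] = {}
    for cls, instances in region_sets.items():
        if not instances:
            warnings.warn(f"region class {cls!r} has no instances; omitted")
            continue
        lengths = np.array([inst.length for inst in instances], dtype=np.int64)
        if (lengths < 1).any():
            raise ValueError(f"region class {cls!r} has a zero-length instance")
        cols = {}
        for s in samples:
            cnt = _count_region_class(instances, reads_by_sample[s])
            cols[s] = cnt / (lengths / 1000.0) / (libs[s] / 1e6)
        out[cls] = pd.DataFrame(cols, index=[inst.instance_id for inst in instances])
    return out


#: region classes quantified for the methylation-level comparisons
REGION_CLASSES = (
    "CpG", "codexon", "exon", "intron", "UTR5", "UTR3", "UP3K", "Down5K",
    "TSS1K", "wholegene", "LINE", "SINE", "LowComplexity", "Satellite", "LTR",
)


def build_region_sets(windows, islands, annotation) -> dict[str, list[RegionInstance]]:
    """Instantiate the 15 quantified region classes.

    ``windows`` is a :class:`~coldmeth.intervals.FeatureWindows`,
    ``islands`` a list of :class:`~coldmeth.cpg_islands.CpGIsland`, and
    ``annotation`` supplies CDS spans for the coding-exon class.
    Splice-aware classes (exon, codexon, intron) carry multi-block
    instances whose RPKM length is the summed block length.
    """
    out: dict[str, list[RegionInstance]] = {}

    def from_windows(cls_key: str, out_key: str) -> None:
        grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for w in windows.windows.get(cls_key, []):
            grouped.setdefault((w.owner, w.chrom), []).append((w.start, w.end))
        out[out_key] = [
            RegionInstance(f"{out_key}:{owner}", chrom, tuple(sorted(blocks)))
            for (owner, chrom), blocks in sorted(grouped.items())
        ]

    from_windows("exon", "exon")
    from_windows("intron", "intron")
    from_windows("utr5", "UTR5")
    from_windows("utr3", "UTR3")
    from_windows("promoter_up3k", "UP3K")
    from_windows("downstream5k", "Down5K")
    from_windows("tss1k", "TSS1K")
    from_windows("whole_gene", "wholegene")

    out["CpG"] = [
        RegionInstance(
            f"CpG:{isl.interval.chrom}:{isl.interval.start}",
            isl.interval.chrom,
            ((isl.interval.start, isl.interval.end),),
        )
        for isl in islands
    ]

    # coding exon: per-transcript exon blocks clipped to the CDS span
    cds = {
        row.transcript_id: (row.cds_start, row.cds_end)
        for row in annotation.transcripts.itertuples(index=False)
    }
    codexon: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in annotation.exons.itertuples(index=False):
        lo, hi = cds[row.transcript_id]
        s, e = max(row.start, lo), min(row.end, hi)
        if s < e:
            codexon.setdefault((row.transcript_id, row.chrom), []).append((s, e))
    out["codexon"] = [
        RegionInstance(f"codexon:{tx}", chrom, tuple(sorted(blocks)))
        for (tx, chrom), blocks in sorted(codexon.items())
    ]

    for cls in ("LINE", "SINE", "LowComplexity", "Satellite", "LTR"):
        rows = annotation.repeats[annotation.repeats["repeat_class"] == cls]
        out[cls] = [
            RegionInstance(f"{cls}:{r.chrom}:{r.start}", r.chrom, ((r.start, r.end),))
            for r in rows.itertuples(index=False)
        ]
    return out


@dataclass
class Dendrogram:
    """Agglomerative clustering result for the peak matrix rows."""

    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_peaks(matrix: PeakMatrix) -> Dendrogram:
    """Hierarchically cluster peaks on log2(RPM+1).

    Euclidean distance, average linkage — the common defaults for
    methylation heat maps.  Requires >= 2 peaks.
    """
    data = matrix.log_rpm.to_numpy()
    if data.shape[0] < 2:
        raise ValueError("clustering requires >= 2 peaks")
    linkage = sch.linkage(data, method="average", metric="euclidean")
    order = sch.leaves_list(linkage).tolist()
    return Dendrogram(linkage=linkage, leaf_order=order, labels=list(matrix.counts.index))


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Render the merge tree as a Newick string with merge heights."""
    tree = sch.to_tree(dend.linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
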