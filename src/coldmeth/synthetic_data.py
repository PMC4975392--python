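"""Seeded generator of a miniature three-condition MeDIP-seq study.

The generator emits everything the pipeline consumes — a small
multi-chromosome genome with gene models, repeat classes and embedded
CpG islands; transcript/gene/KO/pathway/GO mapping tables with a toy
ontology; and, for each of three conditions (a 28 °C control and two
cold treatments, 5 and 30 days at 18 °C), aligned-read intervals and
peak calls — together with a ground-truth record of every planted
signal: island coordinates, differentially methylated peaks with their
fold and direction, coordinated pathway shifts, and enriched GO terms.

Each condition is a single pooled library (no replicates), mirroring
designs that pool biological replicates before sequencing.  Read counts
per peak are Poisson with rates proportional to the peak's methylation
intensity; 5% of each library is uniform genomic background.  Per-sample
peak calls are the true loci whose sampled count reaches a detection
floor, with +/- 25 bp boundary jitter, so the per-sample peak sets
disagree slightly and exercise the REF merging stage.

Every stage draws from its own RNG stream keyed by (seed, stage), so
stages are independently reproducible.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cpg_islands
from .intervals import (
    GenomicInterval,
    RefPeakSet,
    derive_feature_windows,
    merge_peak_sets,
)
from .io_formats import AnnotationTable, SequenceRecord, write_bed, write_fasta, write_table

__all__ = [
    "SimConfig",
    "SimGenome",
    "TruthSet",
    "SimStudy",
    "SAMPLES",
    "COMPARISONS",
    "generate_genome",
    "generate_methylome",
    "generate_reads",
    "simulate",
    "write_study",
    "match_ref_to_truth",
]

SAMPLES = ("28C", "18C_5d", "18C_30d")
COMPARISONS = (("18C_5d", "28C"), ("18C_30d", "28C"), ("18C_30d", "18C_5d"))

_STAGE_KEYS = {"genome": 11, "methylome": 22, "mappings": 33, "reads": 44}

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Satellite", "LowComplexity")

#: single-label placement probabilities for peak loci
PEAK_CLASS_PROBS = {
    "promoter": 0.08,
    "exon": 0.12,
    "intron": 0.39,
    "downstream": 0.03,
    "intergenic": 0.38,
}


@dataclass
class SimConfig:
    """Study conditions for the simulated experiment."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 500_000
    n_genes: int = 300
    n_repeats_per_class: int = 100
    n_islands: int = 60
    n_peaks: int = 3000
    lib_size: int = 200_000
    read_len: int = 50
    frac_dmr: float = 0.1
    dmr_fold: tuple = (2.0, 8.0)
    n_pathways: int = 30
    planted_shifted_pathways: int = 2
    go_terms: int = 150
    planted_enriched_go: int = 5
    background_read_frac: float = 0.05
    min_call_count: int = 10
    jitter_bp: int = 25
    peak_width: tuple = (100, 200)
    min_peak_gap: int = 60
    intensity_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_len", "n_genes", "n_islands", "n_peaks",
                     "lib_size", "read_len", "n_pathways", "go_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.frac_dmr < 1):
            raise ValueError("frac_dmr must lie in (0, 1)")
        if self.dmr_fold[0] < 2:
            raise ValueError("dmr_fold lower bound must be >= 2 so planted DMRs pass the fold filter")


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE_KEYS[stage]])


@dataclass
class SimGenome:
    records: list
    annotation: AnnotationTable
    chrom_sizes: dict
    tx2gene: pd.DataFrame
    islands: list  # planted island intervals


@dataclass
class TruthSet:
    """Ground truth sufficient to score every downstream recovery test."""

    planted_islands: list
    planted_dmrs: pd.DataFrame  # locus_id, comparison columns, direction, fold
    pathway_shifts: pd.DataFrame  # pathway_id, direction, factor, n_member_peaks
    planted_go: list
    baseline: pd.DataFrame  # locus_id, chrom, start, end, intensity, is_null


@dataclass
class SimStudy:
    config: SimConfig
    genome: SimGenome
    loci: list  # true peak loci as GenomicInterval, sorted
    loci_ref: RefPeakSet  # the loci as a reference set (for truth linking)
    intensities: pd.DataFrame  # locus rows x SAMPLES columns
    truth: TruthSet
    mappings: dict  # tx2gene, tx2ko, ko2pathway, gene2go DataFrames
    ontology_text: str
    reads: dict = field(default_factory=dict)  # sample -> list of intervals
    peak_calls: dict = field(default_factory=dict)  # sample -> list of intervals


# ---------------------------------------------------------------------------
# genome

_ISLAND_GC_MARGIN = 60.0
_ISLAND_OE_MARGIN = 0.8


def _island_sequence(rng: np.random.Generator, length: int) -> str:
    """CG-rich sequence satisfying GC >= 60% and O/E >= 0.8 with margin."""
    for _ in range(50):
        parts: list[str] = []
        total = 0
        while total < length:
            if rng.random() < 0.17:
                parts.append("CG")
                total += 2
            else:
                parts.append("ACGT"[rng.choice(4, p=[0.15, 0.25, 0.25, 0.35])])
                total += 1
        seq = "".join(parts)[:length]
        if (
            cpg_islands.gc_content(seq) >= _ISLAND_GC_MARGIN
            and cpg_islands.obs_exp_cpg(seq) >= _ISLAND_OE_MARGIN
        ):
            return seq
    raise RuntimeError("failed to construct a qualifying island sequence")


def _background_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """AT-rich background (~40% GC) as a byte array."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.choice(4, size=length, p=[0.3, 0.2, 0.2, 0.3])]


def _accidental_island_windows(
    seq_bytes: np.ndarray, islands: list, params: cpg_islands.IslandParams
) -> np.ndarray:
    """Start positions of 500 bp windows meeting both ratio criteria while
    disjoint from every planted island."""
    stats = cpg_islands._SegmentStats(seq_bytes.tobytes().decode("ascii"))
    w = params.len_min
    ok = stats.window_meets_array(w, params)
    if not ok.any():
        return np.empty(0, dtype=np.int64)
    pos = np.flatnonzero(ok)
    keep = np.ones(len(pos), dtype=bool)
    for isl in islands:
        keep &= (pos + w <= isl.start) | (pos >= isl.end)
    return pos[keep]


def _pack_spans(
    rng: np.random.Generator, chrom_len: int, lengths: Sequence[int], min_gap: int
) -> list[tuple[int, int]]:
    """Place non-overlapping spans of the given lengths with random gaps."""
    total = int(sum(lengths)) + min_gap * (len(lengths) + 1)
    slack = chrom_len - total
    if slack < 0:
        raise ValueError(
            f"infeasible packing: {sum(lengths)} feature bp into {chrom_len} bp"
        )
    extra = rng.multinomial(slack, np.ones(len(lengths) + 1) / (len(lengths) + 1))
    spans = []
    pos = 0
    for length, pad in zip(lengths, extra[:-1]):
        pos += min_gap + int(pad)
        spans.append((pos, pos + int(length)))
        pos += int(length)
    return spans


def generate_genome(config: SimConfig) -> SimGenome:
    """Emit the genome FASTA, gene models, repeats and island truth.

    Background is ~40% GC; islands are CG-rich segments built to pass
    the detection criteria with margin (GC >= 60%, O/E >= 0.8, >= 700
    bp).  After assembly the generator scans the background for
    accidental windows meeting the detection criteria and rewrites them,
    so the only qualifying islands are the planted ones.
    """
    rng = _rng(config, "genome")
    params = cpg_islands.IslandParams()
    per_chrom_genes = _split(config.n_genes, config.n_chroms)
    per_chrom_islands = _split(config.n_islands, config.n_chroms)
    per_chrom_repeats = _split(config.n_repeats_per_class * len(REPEAT_CLASSES), config.n_chroms)

    records = []
    tx_rows, exon_rows, repeat_rows = [], [], []
    island_truth: list[GenomicInterval] = []
    chrom_sizes = {}

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_sizes[chrom] = config.chrom_len
        seq = _background_sequence(rng, config.chrom_len)

        # gene structures first (short exons, wide introns), then packing
        n_genes = per_chrom_genes[ci]
        structures = []
        for _ in range(n_genes):
            n_exons = int(rng.integers(2, 9))
            exon_lens = rng.integers(80, 151, size=n_exons)
            intron_lens = rng.integers(200, 801, size=n_exons - 1)
            blocks = []
            pos = 0
            for k in range(n_exons):
                blocks.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            structures.append((blocks, pos))
        spans = _pack_spans(
            rng, config.chrom_len, [length for _, length in structures], min_gap=200
        )
        for gi, ((blocks, _), (gstart, _)) in enumerate(zip(structures, spans)):
            tx_id = f"tx_{ci + 1}_{gi + 1:04d}"
            gene_id = f"gene_{ci + 1}_{gi + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [(gstart + s, gstart + e) for s, e in blocks]
            gend = exons[-1][1]
            first_len = exons[0][1] - exons[0][0]
            last_len = exons[-1][1] - exons[-1][0]
            cds_start = exons[0][0] + int(rng.integers(1, max(2, first_len)))
            cds_end = exons[-1][1] - int(rng.integers(1, max(2, last_len)))
            if cds_start >= cds_end:
                cds_start, cds_end = exons[0][0], exons[-1][1]
            tx_rows.append(
                (tx_id, gene_id, chrom, gstart, gend, strand, cds_start, cds_end)
            )
            for es, ee in exons:
                exon_rows.append((tx_id, chrom, es, ee))

        # repeats: annotation-only intervals, free to overlap genes
        for ri in range(per_chrom_repeats[ci]):
            cls = REPEAT_CLASSES[ri % len(REPEAT_CLASSES)]
            length = int(rng.integers(150, 501))
            start = int(rng.integers(0, config.chrom_len - length))
            repeat_rows.append((chrom, start, start + length, cls))

        # islands: disjoint CG-rich inserts
        placed: list[tuple[int, int]] = []
        for _ in range(per_chrom_islands[ci]):
            length = int(rng.integers(700, 1201))
            for _attempt in range(1000):
                start = int(rng.integers(0, config.chrom_len - length))
                end = start + length
                if all(start >= e + 300 or end <= s - 300 for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise ValueError("infeasible packing: too many islands for chrom_len")
            isl_seq = _island_sequence(rng, length)
            seq[start:end] = np.frombuffer(isl_seq.encode("ascii"), dtype=np.uint8)
            island_truth.append(GenomicInterval(chrom, start, end))

        chrom_islands = [iv for iv in island_truth if iv.chrom == chrom]
        for _round in range(20):
            bad = _accidental_island_windows(seq, chrom_islands, params)
            if len(bad) == 0:
                break
            for pos in bad[:50]:
                seq[pos : pos + params.len_min] = _background_sequence(rng, params.len_min)
        else:
            raise RuntimeError("could not eliminate accidental CpG islands")

        records.append(SequenceRecord(chrom, seq.tobytes().decode("ascii")))

    cols5 = ["transcript_id", "chrom", "start", "end"]
    annotation = AnnotationTable(
        transcripts=pd.DataFrame(
            tx_rows,
            columns=["transcript_id", "gene_id", "chrom", "start", "end",
                     "strand", "cds_start", "cds_end"],
        ),
        exons=pd.DataFrame(exon_rows, columns=cols5),
        repeats=pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "repeat_class"]),
    )
    annotation.utr5, annotation.utr3 = _derive_utrs(annotation)
    tx2gene = annotation.transcripts[["transcript_id", "gene_id"]].copy()
    return SimGenome(
        records=records,
        annotation=annotation,
        chrom_sizes=chrom_sizes,
        tx2gene=tx2gene,
        islands=island_truth,
    )


def _derive_utrs(annotation: AnnotationTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    utr5_rows, utr3_rows = [], []
    cds = {
        row.transcript_id: (row.cds_start, row.cds_end, row.strand)
        for row in annotation.transcripts.itertuples(index=False)
    }
    for row in annotation.exons.itertuples(index=False):
        lo, hi, strand = cds[row.transcript_id]
        for s, e in ((row.start, min(row.end, lo)), (max(row.start, hi), row.end)):
            if s >= e:
                continue
            five_prime = (e <= lo) == (strand == "+")
            (utr5_rows if five_prime else utr3_rows).append(
                (row.transcript_id, row.chrom, s, e)
            )
    cols = ["transcript_id", "chrom", "start", "end"]
    return (
        pd.DataFrame(utr5_rows, columns=cols),
        pd.DataFrame(utr3_rows, columns=cols),
    )


def _split(n: int, k: int) -> list[int]:
    base = n // k
    return [base + (1 if i < n % k else 0) for i in range(k)]


# ---------------------------------------------------------------------------
# methylome

def _subtract(pool, others):
    """(starts, ends) of pool minus the union of the other pools."""
    import itertools as it

    segs = list(zip(pool[0].tolist(), pool[1].tolist()))
    for os_, oe_ in others:
        new = []
        other = list(zip(os_.tolist(), oe_.tolist()))
        for s, e in segs:
            cur = s
            for o_s, o_e in other:
                if o_e <= cur or o_s >= e:
                    continue
                if o_s > cur:
                    new.append((cur, o_s))
                cur = max(cur, o_e)
                if cur >= e:
                    break
            if cur < e:
                new.append((cur, e))
        segs = new
    starts = np.array([s for s, _ in segs], dtype=np.int64)
    ends = np.array([e for _, e in segs], dtype=np.int64)
    return starts, ends


def _class_quotas(n_peaks: int) -> dict[str, int]:
    """Largest-remainder allocation of loci to the 5 placement classes."""
    raw = {cls: p * n_peaks for cls, p in PEAK_CLASS_PROBS.items()}
    base = {cls: int(v) for cls, v in raw.items()}
    short = n_peaks - sum(base.values())
    for cls in sorted(raw, key=lambda c: raw[c] - base[c], reverse=True)[:short]:
        base[cls] += 1
    return base


class _PlacedLoci:
    """Sorted placed loci per chromosome with a minimum-gap check."""

    def __init__(self, gap: int):
        self.gap = gap
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}

    def try_add(self, chrom: str, start: int, end: int) -> tuple[bool, int]:
        """Insert [start, end) if it keeps >= gap bp to its neighbours.

        On rejection, returns the end of the blocking locus so callers
        can jump past it.
        """
        ss = self.starts.setdefault(chrom, [])
        ee = self.ends.setdefault(chrom, [])
        i = bisect.bisect_left(ss, start)
        if i > 0 and ee[i - 1] + self.gap > start:
            return False, ee[i - 1]
        if i < len(ss) and end + self.gap > ss[i]:
            return False, ee[i]
        ss.insert(i, start)
        ee.insert(i, end)
        return True, end


def _place_loci(rng, config: SimConfig, genome: SimGenome, windows, pools):
    """Pack peak loci into precedence-resolved feature-class pools.

    Class quotas follow the 5-way placement probabilities.  Exon-class
    loci are placed to overlap an exon window while avoiding promoter
    windows (any overlap suffices for the exon label); the remaining
    classes are packed strictly inside their disjoint pools, left to
    right with randomized spacing.  Quota a pool cannot hold spills into
    the remaining free pool space, so the realized class mix follows the
    probabilities only as far as the genome's geometry permits.
    """
    gap = config.min_peak_gap
    w0, w1 = config.peak_width
    pad = gap // 2
    quotas = _class_quotas(config.n_peaks)
    placed = _PlacedLoci(gap)
    loci: list[GenomicInterval] = []

    def record(chrom: str, start: int, width: int) -> bool:
        ok, _ = placed.try_add(chrom, start, start + width)
        if ok:
            loci.append(GenomicInterval(chrom, start, start + width))
        return ok

    # exon class: overlap an exon, stay clear of promoter windows
    exon_windows = windows.windows.get("exon", [])
    want_exon = quotas["exon"]
    tries = 0
    while want_exon > 0 and exon_windows and tries < quotas["exon"] * 200:
        tries += 1
        w = int(rng.integers(w0, w1 + 1))
        ex = exon_windows[int(rng.integers(len(exon_windows)))]
        start = ex.start + int(rng.integers(-(w - 1), max(1, ex.end - ex.start)))
        end = start + w
        if start < 0 or end > genome.chrom_sizes[ex.chrom]:
            continue
        ps, pe = pools[ex.chrom]["promoter"]
        i = int(np.searchsorted(pe, start, side="right"))
        if i < len(ps) and ps[i] < end:  # touches a promoter window
            continue
        if record(ex.chrom, start, w):
            want_exon -= 1
    quotas["exon"] = want_exon

    def pack_segments(segments, want: int):
        """Sequential left-to-right packing; returns (placed, leftovers)."""
        leftovers = []
        for chrom, s, e in segments:
            pos = int(s) + pad
            if want <= 0:
                leftovers.append((chrom, int(s), int(e)))
                continue
            while want > 0:
                w = int(rng.integers(w0, w1 + 1))
                start = pos + int(rng.integers(0, 21))
                if start + w > e - pad:
                    break
                ok, blocker_end = placed.try_add(chrom, start, start + w)
                if ok:
                    loci.append(GenomicInterval(chrom, start, start + w))
                    want -= 1
                    pos = start + w + gap
                else:
                    pos = blocker_end + gap
            if pos < e - pad:
                leftovers.append((chrom, pos, int(e)))
        return want, leftovers

    leftover_segments = []
    for cls in ("promoter", "intron", "downstream", "intergenic"):
        segments = []
        for chrom in sorted(pools):
            starts, ends = pools[chrom][cls]
            segments.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        rng.shuffle(segments)
        quotas[cls], tails = pack_segments(segments, quotas[cls])
        leftover_segments.extend(tails)

    spill = sum(quotas.values())
    if spill > 0:
        rng.shuffle(leftover_segments)
        spill, _ = pack_segments(leftover_segments, spill)
    if spill > 0:
        raise ValueError(
            f"infeasible packing: {spill} of {config.n_peaks} peaks did not fit"
        )
    loci.sort(key=lambda iv: (iv.chrom, iv.start))
    return loci


def generate_methylome(config: SimConfig, genome: SimGenome):
    """Place peak loci and assign per-condition methylation intensities.

    Loci are packed disjointly (with a guard gap so boundary jitter can
    never merge neighbours) into feature-class pools sampled with the
    5-way placement probabilities.  Baseline intensity is LogNormal; a
    planted DMR multiplies (hyper) or divides (hypo) the baseline by its
    fold in the designated comparison(s); half the planted DMRs are
    shifted in both cold comparisons and form the CRM truth.
    """
    rng = _rng(config, "methylome")
    windows = derive_feature_windows(genome.annotation, genome.chrom_sizes)

    # precedence-resolved placement pools per chromosome
    pools: dict[str, dict[str, tuple]] = {}
    merged = {
        "promoter": windows.merged("promoter_up3k"),
        "exon": windows.merged("exon"),
        "intron": windows.merged("intron"),
        "downstream": windows.merged("downstream5k"),
    }
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    for chrom, size in genome.chrom_sizes.items():
        prom = merged["promoter"].get(chrom, empty)
        exon = _subtract(merged["exon"].get(chrom, empty), [prom])
        intron = _subtract(merged["intron"].get(chrom, empty), [prom, exon])
        down = _subtract(merged["downstream"].get(chrom, empty), [prom, exon, intron])
        genome_pool = (np.array([0], dtype=np.int64), np.array([size], dtype=np.int64))
        intergenic = _subtract(genome_pool, [prom, exon, intron, down])
        pools[chrom] = {
            "promoter": prom, "exon": exon, "intron": intron,
            "downstream": down, "intergenic": intergenic,
        }

    loci = _place_loci(rng, config, genome, windows, pools)
    loci_ref = merge_peak_sets({"truth": loci})
    locus_ids = loci_ref.peak_ids

    baseline = rng.lognormal(mean=0.0, sigma=config.intensity_sigma, size=len(loci))
    intens = pd.DataFrame(
        {s: baseline.copy() for s in SAMPLES}, index=locus_ids
    )

    # plant DMRs: half in both cold comparisons (CRM truth), a quarter
    # each in only one of them.  Two constraints shape the selection:
    # the genes touched by DMR peaks are capped at ~25% of all genes so
    # GO enrichment of DMR genes is a recoverable signal rather than a
    # near-complete background, and hyper/hypo directions are assigned
    # by greedy intensity-mass balancing so the per-condition totals
    # stay matched and RPM normalization does not drift the null peaks.
    from .enrichment import link_peaks_to_genes

    tx2gene_map = dict(zip(genome.tx2gene["transcript_id"], genome.tx2gene["gene_id"]))
    peak_genes = link_peaks_to_genes(loci_ref, windows, tx2gene_map)
    genes_of_peak: dict[str, set] = {}
    for row in peak_genes.itertuples(index=False):
        genes_of_peak.setdefault(row.peak_id, set()).add(row.gene_id)

    n_dmr = int(round(config.frac_dmr * len(loci)))
    gene_cap = max(1, int(0.25 * genome.tx2gene["gene_id"].nunique()))
    order = rng.permutation(len(loci))
    dmr_idx: list[int] = []
    fg_genes: set = set()
    for idx in order.tolist():
        if len(dmr_idx) >= n_dmr:
            break
        linked = genes_of_peak.get(locus_ids[idx], set())
        if len(fg_genes | linked) > gene_cap:
            continue
        fg_genes |= linked
        dmr_idx.append(idx)

    dmr_rows = []
    mass_delta = {"18C_5d": 0.0, "18C_30d": 0.0}
    for j, idx in enumerate(sorted(dmr_idx)):
        fold = float(rng.uniform(*config.dmr_fold))
        group = j % 4  # 0,1 -> both; 2 -> 5d only; 3 -> 30d only
        in_5d = group in (0, 1, 2)
        in_30d = group in (0, 1, 3)
        b = baseline[idx]
        d_hyper = b * (fold - 1.0)
        d_hypo = -b * (1.0 - 1.0 / fold)
        conds = [c for c, flag in (("18C_5d", in_5d), ("18C_30d", in_30d)) if flag]
        tot = sum(mass_delta[c] for c in conds)
        hyper = abs(tot + len(conds) * d_hyper) <= abs(tot + len(conds) * d_hypo)
        factor = fold if hyper else 1.0 / fold
        lid = locus_ids[idx]
        for cond in conds:
            intens.loc[lid, cond] = b * factor
            mass_delta[cond] += d_hyper if hyper else d_hypo
        dmr_rows.append(
            (lid, in_5d, in_30d, "hyper" if hyper else "hypo", fold)
        )
    planted_dmrs = pd.DataFrame(
        dmr_rows, columns=["locus_id", "in_5d", "in_30d", "direction", "fold"]
    )
    baseline_df = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": [iv.chrom for iv in loci],
            "start": [iv.start for iv in loci],
            "end": [iv.end for iv in loci],
            "intensity": baseline,
        }
    )
    baseline_df["is_null"] = ~baseline_df["locus_id"].isin(planted_dmrs["locus_id"])
    return windows, loci, loci_ref, intens, planted_dmrs, baseline_df


# ---------------------------------------------------------------------------
# mappings, pathway shifts and GO truth

def _generate_mappings(config, genome, windows, loci_ref, intens, planted_dmrs, baseline_df):
    from .enrichment import link_peaks_to_genes

    rng = _rng(config, "mappings")
    tx2gene_map = dict(zip(genome.tx2gene["transcript_id"], genome.tx2gene["gene_id"]))
    genes = sorted(set(tx2gene_map.values()))

    # one KO per gene; each KO on 1-2 pathways
    tx2ko_rows = []
    ko_of_gene = {}
    for i, gene in enumerate(genes):
        ko = f"K{i + 1:05d}"
        ko_of_gene[gene] = ko
    for tx, gene in tx2gene_map.items():
        tx2ko_rows.append((tx, ko_of_gene[gene]))
    tx2ko = pd.DataFrame(tx2ko_rows, columns=["transcript_id", "ko_id"])
    pathway_ids = [f"ko{i + 1:05d}" for i in range(config.n_pathways)]
    ko2pw_rows = []
    for gene in genes:
        n_pw = 1 + int(rng.random() < 0.3)
        for pw in rng.choice(config.n_pathways, size=n_pw, replace=False):
            ko2pw_rows.append((ko_of_gene[gene], pathway_ids[int(pw)]))
    ko2pathway = pd.DataFrame(ko2pw_rows, columns=["ko_id", "pathway_id"]).drop_duplicates()

    peak_genes = link_peaks_to_genes(loci_ref, windows, tx2gene_map)
    gene2pw = (
        tx2ko.merge(genome.tx2gene, on="transcript_id")
        .merge(ko2pathway, on="ko_id")[["gene_id", "pathway_id"]]
        .drop_duplicates()
    )
    pw_peaks = (
        peak_genes.merge(gene2pw, on="gene_id")
        .groupby("pathway_id")["peak_id"]
        .apply(lambda s: sorted(set(s)))
    )

    # plant coordinated pathway shifts in the 5-day condition: pick the
    # best-populated pathways, alternate down (x0.5) and up (x2)
    shifted_rows = []
    dmr_loci = set(planted_dmrs["locus_id"])
    # smallest pathways clearing the floor, so the planted shift stays a
    # pathway-level signal rather than a library-wide one
    eligible = sorted(
        (pw for pw in pw_peaks.index if len(pw_peaks[pw]) >= 20),
        key=lambda pw: (len(pw_peaks[pw]), pw),
    )
    used_peaks: set[str] = set()
    for k, pw in enumerate(eligible[: config.planted_shifted_pathways]):
        factor = 0.5 if k % 2 == 0 else 2.0
        members = [p for p in pw_peaks[pw] if p not in used_peaks]
        for lid in members:
            intens.loc[lid, "18C_5d"] *= factor
            used_peaks.add(lid)
        shifted_rows.append(
            (pw, "down" if factor < 1 else "up", factor, len(members))
        )
    pathway_shifts = pd.DataFrame(
        shifted_rows, columns=["pathway_id", "direction", "factor", "n_member_peaks"]
    )
    baseline_df["is_null"] &= ~baseline_df["locus_id"].isin(used_peaks)

    # GO: random annotations plus planted terms enriched among DMR genes
    background_genes = sorted(set(peak_genes["gene_id"]))
    dmr_genes = sorted(
        set(peak_genes[peak_genes["peak_id"].isin(dmr_loci)]["gene_id"])
    )
    other_genes = sorted(set(background_genes) - set(dmr_genes))
    term_ids = [f"GO:{i + 1:07d}" for i in range(config.go_terms)]
    n_planted = min(config.planted_enriched_go, config.go_terms)
    planted_terms = term_ids[-n_planted:] if n_planted else []
    go_rows = []
    plain_terms = term_ids[: config.go_terms - n_planted]
    for gene in genes:
        for t in rng.choice(len(plain_terms), size=min(3, len(plain_terms)), replace=False):
            go_rows.append((gene, plain_terms[int(t)]))
    for term in planted_terms:
        n_fg = min(len(dmr_genes), 20)
        n_bg = min(len(other_genes), 8)
        for g in rng.choice(len(dmr_genes), size=n_fg, replace=False):
            go_rows.append((dmr_genes[int(g)], term))
        for g in rng.choice(len(other_genes), size=n_bg, replace=False):
            go_rows.append((other_genes[int(g)], term))
    gene2go = pd.DataFrame(go_rows, columns=["gene_id", "go_id"]).drop_duplicates()

    ontology_text = _ontology_obo(rng, term_ids, planted_terms)
    mappings = {
        "tx2gene": genome.tx2gene,
        "tx2ko": tx2ko,
        "ko2pathway": ko2pathway,
        "gene2go": gene2go,
    }
    return mappings, ontology_text, pathway_shifts, planted_terms, baseline_df


def _ontology_obo(rng, term_ids, planted_terms) -> str:
    """Toy is_a DAG in OBO syntax.

    The first three terms are namespace roots; every later term gets one
    random earlier parent.  Planted (enrichment-truth) terms are never
    chosen as parents, so they stay childless and ancestor propagation
    cannot dilute their gene sets.
    """
    lines = ["format-version: 1.2", "ontology: synthetic-go-subset", ""]
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    parent_pool: list[str] = []
    planted = set(planted_terms)
    for i, term in enumerate(term_ids):
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: synthetic term {i + 1}",
            f"namespace: {namespaces[i % 3]}",
        ]
        if i >= 3 and parent_pool:
            parent = parent_pool[int(rng.integers(0, len(parent_pool)))]
            lines.append(f"is_a: {parent} ! synthetic parent")
        if term not in planted:
            parent_pool.append(term)
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# reads and peak calls

def generate_reads(
    config: SimConfig,
    loci: Sequence[GenomicInterval],
    intensities: pd.DataFrame,
    chrom_sizes: dict,
):
    """Sample per-sample reads and peak calls from the intensity map.

    Per peak and sample the read count is Poisson with rate
    lib_size * (1 - background) * intensity / total intensity; reads are
    uniform within their peak.  A further ``background_read_frac`` of
    the library is uniform genome-wide.  The per-sample peak-call file
    contains the loci whose sampled count reached the detection floor,
    with boundaries jittered +/- jitter_bp.
    """
    rng = _rng(config, "reads")
    reads: dict[str, list] = {}
    calls: dict[str, list] = {}
    chroms = sorted(chrom_sizes)
    chrom_offsets = np.cumsum([0] + [chrom_sizes[c] for c in chroms])
    genome_len = int(chrom_offsets[-1])
    for sample in SAMPLES:
        intens = intensities[sample].to_numpy()
        lam = config.lib_size * (1 - config.background_read_frac) * intens / intens.sum()
        counts = rng.poisson(lam)
        sample_reads: list[GenomicInterval] = []
        for iv, cnt in zip(loci, counts):
            if cnt == 0:
                continue
            hi = max(iv.start + 1, iv.end - config.read_len + 1)
            starts = rng.integers(iv.start, hi, size=cnt)
            limit = chrom_sizes[iv.chrom]
            for s in starts.tolist():
                e = min(s + config.read_len, limit)
                sample_reads.append(GenomicInterval(iv.chrom, s, e))
        n_bg = int(round(config.lib_size * config.background_read_frac))
        flat = rng.integers(0, genome_len - config.read_len, size=n_bg)
        which = np.searchsorted(chrom_offsets, flat, side="right") - 1
        for pos, wi in zip(flat.tolist(), which.tolist()):
            chrom = chroms[wi]
            s = pos - int(chrom_offsets[wi])
            s = min(s, chrom_sizes[chrom] - config.read_len)
            sample_reads.append(GenomicInterval(chrom, s, s + config.read_len))
        reads[sample] = sample_reads

        sample_calls = []
        for iv, cnt in zip(loci, counts):
            if cnt < config.min_call_count:
                continue
            j1 = int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
            j2 = int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
            s = max(0, iv.start + j1)
            e = min(chrom_sizes[iv.chrom], iv.end + j2)
            if s >= e:
                s, e = iv.start, iv.end
            sample_calls.append(GenomicInterval(iv.chrom, s, e))
        calls[sample] = sample_calls
    return reads, calls


# ---------------------------------------------------------------------------
# top level

def simulate(config: SimConfig) -> SimStudy:
    """Run every generator stage and return the full in-memory study."""
    genome = generate_genome(config)
    windows, loci, loci_ref, intens, planted_dmrs, baseline_df = generate_methylome(
        config, genome
    )
    mappings, obo_text, pathway_shifts, planted_go, baseline_df = _generate_mappings(
        config, genome, windows, loci_ref, intens, planted_dmrs, baseline_df
    )
    reads, calls = generate_reads(config, loci, intens, genome.chrom_sizes)
    truth = TruthSet(
        planted_islands=genome.islands,
        planted_dmrs=planted_dmrs,
        pathway_shifts=pathway_shifts,
        planted_go=planted_go,
        baseline=baseline_df,
    )
    return SimStudy(
        config=config,
        genome=genome,
        loci=loci,
        loci_ref=loci_ref,
        intensities=intens,
        truth=truth,
        mappings=mappings,
        ontology_text=obo_text,
        reads=reads,
        peak_calls=calls,
    )


def match_ref_to_truth(ref: RefPeakSet, loci_ref: RefPeakSet) -> pd.DataFrame:
    """Map downstream REF peak ids to true locus ids by largest overlap."""
    rows = []
    for peak in ref:
        starts, ends, idx = loci_ref.chrom_arrays(peak.chrom)
        if len(starts) == 0:
            continue
        i0 = int(np.searchsorted(ends, peak.start, side="right"))
        best, best_ov = None, 0
        j = i0
        while j < len(starts) and starts[j] < peak.end:
            ov = min(int(ends[j]), peak.end) - max(int(starts[j]), peak.start)
            if ov > best_ov:
                best_ov, best = ov, loci_ref[idx[j]].peak_id
            j += 1
        if best is not None:
            rows.append((peak.peak_id, best, best_ov))
    return pd.DataFrame(rows, columns=["peak_id", "locus_id", "overlap"])


def _bed12_rows(annotation: AnnotationTable) -> list[GenomicInterval]:
    rows = []
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    for row in annotation.exons.itertuples(index=False):
        exons_by_tx.setdefault(row.transcript_id, []).append((row.start, row.end))
    for row in annotation.transcripts.itertuples(index=False):
        ex = sorted(exons_by_tx[row.transcript_id])
        sizes = ",".join(str(e - s) for s, e in ex) + ","
        offsets = ",".join(str(s - row.start) for s, _ in ex) + ","
        rows.append(
            GenomicInterval(
                row.chrom, row.start, row.end, row.strand,
                attrs=(
                    row.transcript_id, "0", row.strand,
                    str(row.cds_start), str(row.cds_end), "0",
                    str(len(ex)), sizes, offsets,
                ),
            )
        )
    return rows


def write_study(study: SimStudy, outdir: str | Path) -> dict:
    """Write every pipeline input plus the truth files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(study.genome.records, paths["genome"])
    paths["gene_models"] = outdir / "genes.bed12"
    write_bed(_bed12_rows(study.genome.annotation), paths["gene_models"])
    paths["repeats"] = outdir / "repeats.bed"
    rep = study.genome.annotation.repeats
    write_bed(
        [
            GenomicInterval(r.chrom, r.start, r.end, attrs=(r.repeat_class,))
            for r in rep.itertuples(index=False)
        ],
        paths["repeats"],
    )
    for key, df in study.mappings.items():
        paths[key] = outdir / f"{key}.tsv"
        write_table(df, paths[key])
    paths["ontology"] = outdir / "ontology.obo"
    paths["ontology"].write_text(study.ontology_text)
    for sample in SAMPLES:
        paths[f"reads_{sample}"] = outdir / f"reads_{sample}.bed"
        write_bed(study.reads[sample], paths[f"reads_{sample}"])
        paths[f"peaks_{sample}"] = outdir / f"peaks_{sample}.bed"
        write_bed(study.peak_calls[sample], paths[f"peaks_{sample}"])
    paths["truth_islands"] = outdir / "planted_islands.bed"
    write_bed(study.truth.planted_islands, paths["truth_islands"])
    paths["truth_dmrs"] = outdir / "planted_dmrs.tsv"
    write_table(study.truth.planted_dmrs, paths["truth_dmrs"])
    paths["truth_pathways"] = outdir / "planted_pathways.tsv"
    write_table(study.truth.pathway_shifts, paths["truth_pathways"])
    paths["truth_go"] = outdir / "planted_go.tsv"
    write_table(pd.DataFrame({"go_id": study.truth.planted_go}), paths["truth_go"])
    paths["truth_baseline"] = outdir / "planted_baseline.tsv"
    write_table(study.truth.baseline, paths["truth_baseline"])
    return paths
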