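"""Pathway-level and GO-level statistics for differential methylation.

KEGG procedure: every REF peak is linked to the transcripts whose gene
span, 3 kb upstream promoter or 5 kb downstream window it overlaps;
links propagate transcript -> KEGG ortholog (KO) -> pathway.  Each
pathway with enough linked peaks is tested with the Wilcoxon
signed-rank test on the paired per-peak RPM values of the two
conditions, and flagged when p <= 0.05 and the median pseudocounted RPM
ratio falls outside [1/1.1, 1.1].

GO procedure: genes linked to at least one DMR form the foreground,
genes linked to at least one REF peak the background; annotations are
propagated to all is_a ancestors; each term is scored with the
hypergeometric upper tail and the enrichment ratio
(foreground fraction) / (background fraction).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .intervals import FeatureWindows, RefPeakSet, merge_interval_arrays
from .io_formats import Ontology
from .quantify import PeakMatrix

__all__ = [
    "link_peaks_to_transcripts",
    "link_peaks_to_genes",
    "link_peaks_to_pathways",
    "wilcoxon_signed_rank",
    "kegg_pathway_test",
    "go_enrich",
]

#: above this many nonzero pairs the signed-rank test switches from the
#: exact tie-aware distribution to a normal approximation
EXACT_WILCOXON_MAX_N = 25


def link_peaks_to_transcripts(
    ref: RefPeakSet, windows: FeatureWindows
) -> pd.DataFrame:
    """(peak_id, transcript_id) pairs by >= 1 bp overlap.

    Here the per-transcript promoter and downstream windows drive the
    pairs; the gene-span route is added by :func:`link_peaks_to_genes`,
    which is what pathway and GO linking consume.
    """
    tx_ivs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for cls in ("promoter_up3k", "downstream5k"):
        for w in windows.windows.get(cls, []):
            tx_ivs.setdefault((w.owner, w.chrom), []).append((w.start, w.end))
    rows = []
    for (tx, chrom), ivs in tx_ivs.items():
        starts, ends = merge_interval_arrays(ivs)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), tx))
    pairs: set[tuple[str, str]] = set()
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, tx in rows:
        per_chrom.setdefault(chrom, []).append((s, e, tx))
    for peak in ref:
        for s, e, tx in per_chrom.get(peak.chrom, []):
            if s < peak.end and e > peak.start:
                pairs.add((peak.peak_id, tx))
    return pd.DataFrame(sorted(pairs), columns=["peak_id", "transcript_id"])


def link_peaks_to_genes(
    ref: RefPeakSet, windows: FeatureWindows, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """(peak_id, gene_id) pairs: gene span or any transcript's
    promoter/downstream window overlapping the peak."""
    pairs: set[tuple[str, str]] = set()
    tx_pairs = link_peaks_to_transcripts(ref, windows)
    for row in tx_pairs.itertuples(index=False):
        gene = tx2gene.get(row.transcript_id)
        if gene is not None:
            pairs.add((row.peak_id, gene))
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for w in windows.windows.get("whole_gene", []):
        per_chrom.setdefault(w.chrom, []).append((w.start, w.end, w.owner))
    for peak in ref:
        for s, e, gene in per_chrom.get(peak.chrom, []):
            if s < peak.end and e > peak.start:
                pairs.add((peak.peak_id, gene))
    return pd.DataFrame(sorted(pairs), columns=["peak_id", "gene_id"])


def link_peaks_to_pathways(
    peak_genes: pd.DataFrame,
    tx2gene: pd.DataFrame,
    tx2ko: pd.DataFrame,
    ko2pathway: pd.DataFrame,
) -> dict[str, frozenset]:
    """pathway_id -> set of linked peak ids via gene -> KO -> pathway."""
    gene2ko = tx2ko.merge(tx2gene, on="transcript_id")[["gene_id", "ko_id"]]
    gene2pw = gene2ko.merge(ko2pathway, on="ko_id")[["gene_id", "pathway_id"]]
    merged = peak_genes.merge(gene2pw, on="gene_id")
    out: dict[str, set] = {}
    for row in merged.itertuples(index=False):
        out.setdefault(row.pathway_id, set()).add(row.peak_id)
    return {k: frozenset(v) for k, v in out.items()}


def _exact_signed_rank_p(ranks: np.ndarray, signs: np.ndarray) -> float:
    """Exact two-sided p by the distribution of W over all sign flips.

    Uses the subset-sum distribution of doubled ranks (average ranks
    from ties are half-integers), equivalent to enumerating all 2^n
    sign assignments; two-sided rule is P(|W - E[W]| >= |w_obs - E[W]|).
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else counts[r:]
    w2 = int(np.rint((ranks[signs > 0] * 2).sum()))
    mean2 = total / 2.0
    dev = abs(w2 - mean2)
    ks = np.arange(total + 1)
    extreme = np.abs(ks - mean2) >= dev - 1e-9
    return float(counts[extreme].sum() / 2.0 ** len(r2))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped; ties receive average ranks.  With at
    most :data:`EXACT_WILCOXON_MAX_N` nonzero pairs the p-value is the
    exact sign-enumeration probability; beyond that a normal
    approximation with tie correction and 0.5 continuity correction is
    used.  All differences zero gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    if n <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p(ranks, np.sign(d))
    w = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class PathwayTestResult:
    ko_id: str
    n_peaks: int
    median_ratio: float
    p: float
    flagged: bool


def kegg_pathway_test(
    matrix: PeakMatrix,
    pathway_peaks: Mapping[str, frozenset],
    treat: str,
    control: str,
    min_peaks: int = 5,
    pseudocount: float = 0.5,
    p_max: float = 0.05,
    ratio_band: float = 1.1,
    median_mode: str = "median_of_ratios",
) -> pd.DataFrame:
    """Signed-rank test of per-peak RPM between two conditions, per pathway.

    ``median_mode``: ``median_of_ratios`` takes the median of per-peak
    pseudocounted RPM ratios; ``ratio_of_medians`` divides the pathway
    median RPMs instead.  A pathway is flagged when p <= p_max and the
    median ratio is >= ratio_band or <= 1/ratio_band.  Pathways with
    fewer than ``min_peaks`` linked peaks are omitted.
    """
    if median_mode not in ("median_of_ratios", "ratio_of_medians"):
        raise ValueError(f"unknown median_mode {median_mode!r}")
    rpm = matrix.rpm
    rows = []
    for pw in sorted(pathway_peaks):
        peaks = sorted(pathway_peaks[pw])
        peaks = [p for p in peaks if p in rpm.index]
        if len(peaks) < min_peaks:
            continue
        rt = rpm.loc[peaks, treat].to_numpy()
        rc = rpm.loc[peaks, control].to_numpy()
        if median_mode == "median_of_ratios":
            mr = float(np.median((rt + pseudocount) / (rc + pseudocount)))
        else:
            mr = float((np.median(rt) + pseudocount) / (np.median(rc) + pseudocount))
        p = wilcoxon_signed_rank(rt, rc)
        flagged = p <= p_max and (mr >= ratio_band or mr <= 1.0 / ratio_band)
        rows.append((pw, len(peaks), mr, p, flagged))
    return pd.DataFrame(
        rows, columns=["ko_id", "n_peaks", "median_ratio", "p", "flagged"]
    )


def _propagated_annotations(
    gene2go: pd.DataFrame, ontology: Ontology
) -> dict[str, frozenset]:
    """gene -> set of annotated GO terms plus all their is_a ancestors."""
    out: dict[str, set] = {}
    for row in gene2go.itertuples(index=False):
        if row.go_id not in ontology:
            continue
        terms = out.setdefault(row.gene_id, set())
        terms.add(row.go_id)
        terms.update(ontology.ancestors(row.go_id))
    return {g: frozenset(t) for g, t in out.items()}


def go_enrich(
    dmr_genes: Sequence[str],
    background: Sequence[str],
    gene2go: pd.DataFrame,
    ontology: Ontology,
    ratio_min: float = 1.3,
    p_max: float = 0.05,
    fdr_max: float = 0.2,
    figure_ratio_min: float = 1.5,
) -> pd.DataFrame:
    """Hypergeometric GO enrichment of DMR-linked genes.

    ``enriched`` requires p <= p_max and ratio >= ratio_min;
    ``table_tier`` additionally requires fdr < fdr_max, and
    ``figure_tier`` tightens the ratio to ``figure_ratio_min``.  BH
    correction spans every term annotated in the background (K >= 1).
    """
    bg = sorted(set(background))
    if not bg:
        raise ValueError("empty background gene set")
    fg = sorted(set(dmr_genes))
    if not set(fg) <= set(bg):
        raise ValueError("foreground genes must be a subset of the background")
    ann = _propagated_annotations(gene2go, ontology)
    n_total, n_fg = len(bg), len(fg)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    fg_set = set(fg)
    for gene in bg:
        for term in ann.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in fg_set:
                term_fg[term] = term_fg.get(term, 0) + 1
    rows = []
    for term in sorted(term_bg):
        big_k = term_bg[term]
        k = term_fg.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_fg)) if k > 0 else 1.0
        ratio = (k / n_fg) / (big_k / n_total) if n_fg and k else 0.0
        rows.append((term, ontology.terms[term].name, k, n_fg, big_k, n_total, ratio, p))
    out = pd.DataFrame(
        rows, columns=["go_id", "name", "k", "n", "K", "N", "ratio", "p"]
    )
    out["fdr"] = bh_fdr(out["p"]) if len(out) else []
    out["enriched"] = (out["p"] <= p_max) & (out["ratio"] >= ratio_min)
    out["table_tier"] = out["enriched"] & (out["fdr"] < fdr_max)
    out["figure_tier"] = (out["p"] <= p_max) & (out["ratio"] >= figure_ratio_min)
    return out
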