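"""Pathway and GO statistics: signed-rank oracle, linking, enrichment."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from coldmeth.enrichment import (
    go_enrich,
    kegg_pathway_test,
    link_peaks_to_genes,
    link_peaks_to_pathways,
    wilcoxon_signed_rank,
)
from coldmeth.intervals import GenomicInterval, merge_peak_sets
from coldmeth.io_formats import OboTerm, Ontology
from coldmeth.quantify import PeakMatrix


def wilcoxon_oracle(x, y):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    mean = ranks.sum() / 2.0
    w_obs = ranks[d > 0].sum()
    dev = abs(w_obs - mean)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    return hits / 2.0 ** n


class TestWilcoxonSignedRank:
    def test_three_positive_differences(self):
        assert wilcoxon_signed_rank([1, 2, 3], [0, 0, 0]) == pytest.approx(0.25)

    def test_identical_pairs_give_p_one(self):
        assert wilcoxon_signed_rank([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        # only the nonzero pairs should matter
        p_with = wilcoxon_signed_rank([1, 2, 3, 7], [0, 0, 0, 7])
        assert p_with == pytest.approx(0.25)

    def test_ten_random_pairs_match_full_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            wilcoxon_oracle(x, y), abs=1e-12
        )

    @given(
        n=st.integers(1, 12),
        seed=st.integers(0, 10_000),
        with_ties=st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_sign_flip_enumeration(self, n, seed, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
        else:
            x = rng.normal(size=n)
            y = rng.normal(size=n)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            wilcoxon_oracle(x, y), abs=1e-12
        )

    def test_large_n_normal_approximation_is_sane(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.8, 1, size=60)
        y = rng.normal(0, 1, size=60)
        p = wilcoxon_signed_rank(x, y)
        from scipy import stats

        ref = stats.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1])


def _matrix(counts_by_sample, libs):
    samples = list(counts_by_sample)
    n = len(next(iter(counts_by_sample.values())))
    ref = merge_peak_sets(
        {"s": [GenomicInterval("c", 1000 * i, 1000 * i + 400) for i in range(n)]}
    )
    df = pd.DataFrame(counts_by_sample, index=ref.peak_ids)
    return PeakMatrix(ref=ref, samples=samples, counts=df, lib_sizes=pd.Series(libs))


class TestKeggPathwayTest:
    def test_doubled_pathway_flagged(self):
        # 8 peaks, treat RPM = 2x control RPM, all >= 10 RPM
        control = [20, 30, 40, 25, 35, 45, 50, 60]
        treat = [2 * c for c in control]
        m = _matrix({"t": treat, "c": control}, {"t": 10**6, "c": 10**6})
        pw = {"ko00001": frozenset(m.counts.index)}
        out = kegg_pathway_test(m, pw, "t", "c")
        row = out.iloc[0]
        assert row["median_ratio"] > 1.1
        assert row["p"] == pytest.approx(wilcoxon_oracle(treat, control), abs=1e-12)
        assert bool(row["flagged"]) == (row["p"] <= 0.05)

    def test_self_comparison_not_flagged(self):
        control = [20, 30, 40, 25, 35]
        m = _matrix({"t": control, "c": list(control)}, {"t": 10**6, "c": 10**6})
        pw = {"ko00001": frozenset(m.counts.index)}
        row = kegg_pathway_test(m, pw, "t", "c").iloc[0]
        assert row["median_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)
        assert not row["flagged"]

    def test_small_pathway_omitted(self):
        m = _matrix({"t": [5, 5], "c": [5, 5]}, {"t": 100, "c": 100})
        pw = {"ko00001": frozenset(m.counts.index)}
        assert kegg_pathway_test(m, pw, "t", "c", min_peaks=5).empty

    def test_ratio_of_medians_mode(self):
        control = [10, 20, 30, 40, 50]
        treat = [20, 40, 60, 80, 100]
        m = _matrix({"t": treat, "c": control}, {"t": 10**6, "c": 10**6})
        pw = {"k": frozenset(m.counts.index)}
        row = kegg_pathway_test(m, pw, "t", "c", median_mode="ratio_of_medians").iloc[0]
        assert row["median_ratio"] == pytest.approx(60.5 / 30.5)


def go_tail_oracle(k, n_total, big_k, n_fg):
    """Upper hypergeometric tail by direct summation of binomials."""
    denom = math.comb(n_total, n_fg)
    return sum(
        math.comb(big_k, i) * math.comb(n_total - big_k, n_fg - i) / denom
        for i in range(k, min(big_k, n_fg) + 1)
    )


def _flat_ontology(term_ids, parents=None):
    parents = parents or {}
    return Ontology(
        terms={
            t: OboTerm(t, f"name {t}", "biological_process", tuple(parents.get(t, ())))
            for t in term_ids
        }
    )


class TestGoEnrich:
    def _run(self, k=5, big_k=10, n_fg=20, n_total=100):
        genes = [f"g{i}" for i in range(n_total)]
        fg = genes[:n_fg]
        # term covers k foreground genes and big_k - k background-only genes
        members = fg[:k] + genes[n_fg : n_fg + big_k - k]
        gene2go = pd.DataFrame({"gene_id": members, "go_id": "GO:1"})
        return go_enrich(fg, genes, gene2go, _flat_ontology(["GO:1"]))

    def test_ratio_and_tail_probability(self):
        out = self._run()
        row = out.iloc[0]
        assert row["ratio"] == pytest.approx((5 / 20) / (10 / 100))
        assert row["p"] == pytest.approx(go_tail_oracle(5, 100, 10, 20), abs=1e-12)

    def test_zero_hits_not_enriched(self):
        out = self._run(k=0)
        row = out.iloc[0]
        assert row["ratio"] == 0.0 and not row["enriched"]

    def test_child_annotations_propagate_to_parent(self):
        genes = [f"g{i}" for i in range(10)]
        ont = _flat_ontology(["GO:p", "GO:c"], parents={"GO:c": ("GO:p",)})
        gene2go = pd.DataFrame({"gene_id": genes[:3], "go_id": "GO:c"})
        out = go_enrich(genes[:3], genes, gene2go, ont).set_index("go_id")
        assert out.loc["GO:p", "K"] == 3 and out.loc["GO:p", "k"] == 3
        assert out.loc["GO:c", "K"] == 3

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrich(["x"], ["a", "b"], pd.DataFrame(columns=["gene_id", "go_id"]),
                      _flat_ontology(["GO:1"]))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            go_enrich([], [], pd.DataFrame(columns=["gene_id", "go_id"]),
                      _flat_ontology(["GO:1"]))

    def test_tail_matches_oracle_across_sizes(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_total = int(rng.integers(20, 500))
            n_fg = int(rng.integers(1, n_total))
            big_k = int(rng.integers(1, n_total))
            k = int(rng.integers(0, min(n_fg, big_k) + 1))
            genes = [f"g{i}" for i in range(n_total)]
            fg = genes[:n_fg]
            members = fg[:k] + genes[n_fg : n_fg + (big_k - k)]
            if len(members) != big_k:
                continue
            gene2go = pd.DataFrame({"gene_id": members, "go_id": "GO:1"})
            out = go_enrich(fg, genes, gene2go, _flat_ontology(["GO:1"]))
            if k == 0:
                assert out.iloc[0]["p"] == 1.0
            else:
                assert out.iloc[0]["p"] == pytest.approx(
                    go_tail_oracle(k, n_total, big_k, n_fg), abs=1e-10
                )


class TestPeakLinking:
    def test_association_chain_to_pathway(self, small_study):
        from coldmeth.intervals import derive_feature_windows

        windows = derive_feature_windows(
            small_study.genome.annotation, small_study.genome.chrom_sizes
        )
        ref = small_study.loci_ref
        tx2gene = small_study.mappings["tx2gene"]
        peak_genes = link_peaks_to_genes(
            ref, windows, dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
        )
        assert not peak_genes.empty
        pw = link_peaks_to_pathways(
            peak_genes, tx2gene, small_study.mappings["tx2ko"],
            small_study.mappings["ko2pathway"],
        )
        assert pw  # at least one pathway receives peaks
        all_pw_peaks = set().union(*pw.values())
        assert all_pw_peaks <= set(ref.peak_ids)

    def test_isolated_peak_links_nowhere(self, small_study):
        from coldmeth.intervals import derive_feature_windows, RefPeakSet, RefPeak

        windows = derive_feature_windows(
            small_study.genome.annotation, small_study.genome.chrom_sizes
        )
        # a peak on a chromosome name with no annotation
        lonely = RefPeakSet(
            [RefPeak("peak_00001", GenomicInterval("chrUn", 10, 60), frozenset())]
        )
        tx2gene = small_study.mappings["tx2gene"]
        links = link_peaks_to_genes(
            lonely, windows, dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
        )
        assert links.empty
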