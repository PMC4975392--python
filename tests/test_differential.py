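"""Differential calling: Fisher oracle, BH oracle, DMR/CRM logic."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldmeth.differential import (
    P_FLOOR,
    bh_fdr,
    call_crms,
    call_dmrs,
    compare_region_levels,
    fisher_exact_two_sided,
)
from coldmeth.intervals import GenomicInterval, merge_peak_sets
from coldmeth.quantify import PeakMatrix


def fisher_oracle(a, b, na, nb):
    """Exact two-sided p by direct enumeration of all tables with the
    observed margins, summing probabilities <= the observed table's."""
    m = a + b
    lo, hi = max(0, m - nb), min(m, na)
    denom = math.comb(na + nb, m)
    probs = {k: math.comb(na, k) * math.comb(nb, m - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def bh_oracle(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = running
    return q


class TestFisherExact:
    def test_empty_cells_give_p_one(self):
        assert fisher_exact_two_sided(0, 0, 50, 80) == pytest.approx(1.0)

    def test_two_outcome_enumeration(self):
        assert fisher_exact_two_sided(1, 0, 1, 1) == pytest.approx(1.0)

    def test_spec_style_table_matches_enumeration(self):
        p = fisher_exact_two_sided(12, 2, 100, 100)
        assert p == pytest.approx(fisher_oracle(12, 2, 100, 100), abs=1e-12)

    @given(
        na=st.integers(1, 200),
        nb=st.integers(1, 200),
        fa=st.floats(0, 1),
        fb=st.floats(0, 1),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, na, nb, fa, fb):
        a, b = int(round(fa * na)), int(round(fb * nb))
        assert fisher_exact_two_sided(a, b, na, nb) == pytest.approx(
            fisher_oracle(a, b, na, nb), abs=1e-11
        )

    def test_doubling_variant_bounds_minlike(self):
        # doubling can only be >= the minimum-likelihood p
        p_min = fisher_exact_two_sided(12, 2, 100, 100)
        p_dbl = fisher_exact_two_sided(12, 2, 100, 100, method="doubling")
        assert p_dbl >= p_min - 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(11, 0, 10, 10)


class TestBhFdr:
    def test_uniformly_spaced_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_identity(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=200)
        assert np.allclose(bh_fdr(p), bh_oracle(p.tolist()), atol=1e-12)

    def test_monotone_in_sorted_order_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _matrix(counts_by_sample, libs):
    samples = list(counts_by_sample)
    n = len(next(iter(counts_by_sample.values())))
    ref = merge_peak_sets(
        {"s": [GenomicInterval("c", 1000 * i, 1000 * i + 400) for i in range(n)]}
    )
    df = pd.DataFrame(counts_by_sample, index=ref.peak_ids)
    return PeakMatrix(ref=ref, samples=samples, counts=df, lib_sizes=pd.Series(libs))


class TestCallDmrs:
    def test_fold_arithmetic_with_pseudocount(self):
        m = _matrix({"t": [40], "c": [10]}, {"t": 10**6, "c": 10**6})
        rec = call_dmrs(m, "t", "c").iloc[0]
        assert rec["fold"] == pytest.approx(40.5 / 10.5)
        assert rec["direction"] == "hyper"
        # fold qualifies; DMR status tracks the q threshold exactly
        assert rec["is_dmr"] == (rec["fold"] >= 2 and rec["q"] <= 0.01)
        assert rec["p"] == pytest.approx(fisher_oracle(40, 10, 10**6, 10**6), rel=1e-9)

    def test_equal_counts_are_not_dmrs(self):
        m = _matrix({"t": [10], "c": [10]}, {"t": 10**6, "c": 10**6})
        rec = call_dmrs(m, "t", "c").iloc[0]
        assert rec["fold"] == pytest.approx(1.0)
        assert not rec["is_dmr"]

    def test_zero_count_hypo_direction_and_symmetric_fold(self):
        m = _matrix({"t": [0], "c": [50]}, {"t": 10**6, "c": 10**6})
        rec = call_dmrs(m, "t", "c").iloc[0]
        assert rec["direction"] == "hypo"
        assert rec["fold"] < 0.5

    def test_every_reported_dmr_respects_thresholds(self, small_study):
        from coldmeth.quantify import build_peak_matrix

        ref = merge_peak_sets(small_study.peak_calls)
        matrix = build_peak_matrix(ref, small_study.reads)
        table = call_dmrs(matrix, "18C_5d", "28C")
        dmrs = table[table["is_dmr"]]
        assert len(dmrs) > 0
        assert ((dmrs["fold"] >= 2.0) | (dmrs["fold"] <= 0.5)).all()
        assert (dmrs["q"] <= 0.01).all()

    def test_unknown_sample_rejected(self):
        m = _matrix({"t": [1], "c": [1]}, {"t": 10, "c": 10})
        with pytest.raises(ValueError, match="unknown sample"):
            call_dmrs(m, "nope", "c")


def _dmr_frame(flags_dirs):
    return pd.DataFrame(
        {
            "peak_id": [f"peak_{i:05d}" for i in range(1, len(flags_dirs) + 1)],
            "is_dmr": [f for f, _ in flags_dirs],
            "direction": [d for _, d in flags_dirs],
        }
    )


class TestCallCrms:
    def test_discordant_directions_still_crm(self):
        crm = call_crms(
            _dmr_frame([(True, "hyper")]), _dmr_frame([(True, "hypo")])
        )
        assert len(crm) == 1 and not crm["concordant"].iloc[0]

    def test_single_comparison_dmr_excluded(self):
        crm = call_crms(
            _dmr_frame([(True, "hyper"), (False, "hypo")]),
            _dmr_frame([(False, "hyper"), (False, "hypo")]),
        )
        assert crm.empty

    def test_mismatched_reference_rejected(self):
        a = _dmr_frame([(True, "hyper")])
        b = _dmr_frame([(True, "hyper"), (True, "hypo")])
        with pytest.raises(ValueError, match="different reference"):
            call_crms(a, b)


class TestCompareRegionLevels:
    def test_identical_samples_give_null_result(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        out = compare_region_levels({"exon": mat}, [("b", "a")])
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_constant_log_shift_hits_p_floor(self):
        a = np.array([4.0, 8.0, 16.0, 32.0, 64.0])
        mat = pd.DataFrame({"a": a, "b": (a + 1) * 2 - 1})  # log2(b+1)=log2(a+1)+1
        out = compare_region_levels({"exon": mat}, [("b", "a")])
        assert out["p"].iloc[0] == P_FLOOR

    def test_noisy_shift_matches_closed_form_paired_t(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(1, 50, size=5)
        b = a * 2 + rng.uniform(0, 1, size=5)
        mat = pd.DataFrame({"a": a, "b": b})
        out = compare_region_levels({"exon": mat}, [("b", "a")])
        d = np.log2(b + 1) - np.log2(a + 1)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        assert out["t"].iloc[0] == pytest.approx(t)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), len(d) - 1))

    def test_single_instance_class_skipped(self):
        mats = {
            "solo": pd.DataFrame({"a": [1.0], "b": [2.0]}),
            "pair": pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]}),
        }
        with pytest.warns(UserWarning, match="solo"):
            out = compare_region_levels(mats, [("b", "a")])
        assert set(out["region_class"]) == {"pair"}

    def test_fdr_spans_all_emitted_tests(self):
        rng = np.random.default_rng(9)
        mats = {
            c: pd.DataFrame(rng.uniform(0, 10, size=(8, 2)), columns=["a", "b"])
            for c in ("x", "y", "z")
        }
        out = compare_region_levels(mats, [("b", "a"), ("a", "b")])
        assert len(out) == 6
        assert np.allclose(out["fdr"], bh_oracle(out["p"].tolist()))
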