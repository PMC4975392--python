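"""Differential methylation: per-peak Fisher tests, DMR and CRM calling,
and region-class methylation-level comparisons.

The three conditions are single pooled libraries (biological replicates
pooled before sequencing), so per-peak differential calls use Fisher's
exact test on the 2x2 table of (reads in peak, reads elsewhere) for the
two libraries, Benjamini-Hochberg FDR across all REF peaks of a
comparison, and a symmetric fold filter on pseudocounted RPM.  A peak is
a DMR when |fold change| >= 2 and q <= 0.01; a cold-related methylation
region (CRM) is a peak that is a DMR in both the short-term and the
long-term cold comparison against control.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import PeakMatrix

__all__ = [
    "fisher_exact_two_sided",
    "bh_fdr",
    "call_dmrs",
    "call_crms",
    "compare_region_levels",
]

DMR_COLUMNS = [
    "peak_id", "treat", "control", "count_treat", "count_control",
    "rpm_treat", "rpm_control", "fold", "p", "q", "direction", "is_dmr",
]


def fisher_exact_two_sided(
    a: int, b: int, na: int, nb: int, method: str = "minlike"
) -> float:
    """Two-sided Fisher exact p for the table [[a, na-a], [b, nb-b]].

    ``minlike`` (default) sums the probability of every table with fixed
    margins whose probability does not exceed the observed table's;
    ``doubling`` doubles the smaller one-sided tail (capped at 1).
    """
    if min(a, b, na, nb) < 0:
        raise ValueError("negative inputs")
    if a > na or b > nb:
        raise ValueError("cell exceeds its margin")
    if method == "minlike":
        return float(stats.fisher_exact([[a, na - a], [b, nb - b]])[1])
    if method == "doubling":
        m = a + b
        rv = stats.hypergeom(na + nb, na, m)
        less, greater = float(rv.cdf(a)), float(rv.sf(a - 1))
        return min(1.0, 2.0 * min(less, greater))
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    matrix: PeakMatrix,
    treat: str,
    control: str,
    fold_min: float = 2.0,
    q_max: float = 0.01,
    pseudocount: float = 0.5,
    fisher_method: str = "minlike",
) -> pd.DataFrame:
    """Per-peak differential methylation for one comparison.

    One row per REF peak; fold = (rpm_treat + c) / (rpm_control + c)
    with pseudocount c in RPM units; BH correction spans all REF peaks
    of the comparison; is_dmr requires (fold >= fold_min or
    fold <= 1/fold_min) and q <= q_max; direction is ``hyper`` when
    rpm_treat > rpm_control, else ``hypo``.
    """
    for s in (treat, control):
        if s not in matrix.samples:
            raise ValueError(f"unknown sample {s!r}")
    ct = matrix.counts[treat].to_numpy()
    cc = matrix.counts[control].to_numpy()
    nt = int(matrix.lib_sizes[treat])
    nc = int(matrix.lib_sizes[control])
    rpm_t = ct / nt * 1e6
    rpm_c = cc / nc * 1e6
    fold = (rpm_t + pseudocount) / (rpm_c + pseudocount)
    p = np.array(
        [fisher_exact_two_sided(int(t), int(c), nt, nc, method=fisher_method)
         for t, c in zip(ct, cc)]
    )
    q = bh_fdr(p)
    direction = np.where(rpm_t > rpm_c, "hyper", "hypo")
    is_dmr = ((fold >= fold_min) | (fold <= 1.0 / fold_min)) & (q <= q_max)
    return pd.DataFrame(
        {
            "peak_id": matrix.counts.index,
            "treat": treat,
            "control": control,
            "count_treat": ct,
            "count_control": cc,
            "rpm_treat": rpm_t,
            "rpm_control": rpm_c,
            "fold": fold,
            "p": p,
            "q": q,
            "direction": direction,
            "is_dmr": is_dmr,
        }
    ).reset_index(drop=True)


def call_crms(dmrs_5d: pd.DataFrame, dmrs_30d: pd.DataFrame) -> pd.DataFrame:
    """Peaks that are DMRs in both cold comparisons (direction-agnostic).

    The concordance flag records whether the two comparisons moved the
    peak the same way.  Both inputs must cover the same REF peaks.
    """
    if set(dmrs_5d["peak_id"]) != set(dmrs_30d["peak_id"]):
        raise ValueError("DMR tables cover different reference peak sets")
    a = dmrs_5d[dmrs_5d["is_dmr"]].set_index("peak_id")
    b = dmrs_30d[dmrs_30d["is_dmr"]].set_index("peak_id")
    common = a.index.intersection(b.index)
    out = pd.DataFrame(
        {
            "peak_id": common,
            "direction_5d": a.loc[common, "direction"].to_numpy(),
            "direction_30d": b.loc[common, "direction"].to_numpy(),
        }
    )
    out["concordant"] = out["direction_5d"] == out["direction_30d"]
    return out.sort_values("peak_id").reset_index(drop=True)


# paired-t p-value floor when every pairwise difference is identical
P_FLOOR = 1e-300


def compare_region_levels(
    region_matrices: Mapping[str, pd.DataFrame],
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Paired t-tests of log2(RPKM+1) per region class and comparison.

    Region instances are identical across samples, so the test pairs
    each instance's two values.  BH correction spans every
    (class x comparison) test emitted together.  Classes with fewer
    than two instances are skipped with a warning; a zero-variance
    nonzero shift reports the p floor rather than NaN.
    """
    rows = []
    for cls in sorted(region_matrices):
        mat = region_matrices[cls]
        if len(mat) < 2:
            warnings.warn(f"region class {cls!r} has < 2 instances; skipped")
            continue
        log = np.log2(mat + 1.0)
        for treat, control in comparisons:
            d = log[treat].to_numpy() - log[control].to_numpy()
            if np.allclose(d.std(ddof=1), 0.0):
                t = 0.0 if np.allclose(d.mean(), 0.0) else np.inf
                p = 1.0 if np.allclose(d.mean(), 0.0) else P_FLOOR
            else:
                t, p = stats.ttest_rel(log[treat], log[control])
                p = max(float(p), P_FLOOR)
            rows.append((cls, treat, control, len(mat), float(t), float(p)))
    out = pd.DataFrame(
        rows, columns=["region_class", "treat", "control", "n", "t", "p"]
    )
    out["fdr"] = bh_fdr(out["p"]) if len(out) else []
    return out
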