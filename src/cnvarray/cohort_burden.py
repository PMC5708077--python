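"""Per-sample CNV burden summaries and rank-sum group comparisons.

Burden is the per-sample count of called aberrations, split into gains
and losses and optionally stratified by chromosome. Group differences are
tested with the two-sided Wilcoxon rank-sum (Mann-Whitney) test: exact
enumeration of the permutation distribution for small groups, and the
tie-corrected normal approximation with continuity correction otherwise.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CnvCall, validate_sample_sheet

__all__ = ["count_burden", "rank_sum_test", "compare_groups"]

#: exact enumeration is used when either group is smaller than this...
_EXACT_MIN_N = 8
#: ...and the pooled size keeps the exact count in float64-exact range.
_EXACT_MAX_N = 50


def count_burden(
    calls: Iterable[CnvCall],
    sample_sheet: pd.DataFrame,
    stratify_by_chromosome: bool = False,
) -> pd.DataFrame:
    """Exact per-sample counts of total/gain/loss calls.

    Every sample in the sheet appears, with zeros when it has no calls.
    A call whose sample_id is missing from the sheet is an error.

    Returns a DataFrame indexed by sample_id with columns
    ``(group, total, gain, loss)``; when stratified, one row per
    (sample_id, chromosome) with the same count columns.
    """
    sheet = validate_sample_sheet(sample_sheet)
    known = set(sheet.index)
    rows = []
    for call in calls:
        if call.sample_id not in known:
            raise ValueError(f"call for unknown sample {call.sample_id!r}")
        rows.append((call.sample_id, call.chromosome, call.kind))
    df = pd.DataFrame(rows, columns=["sample_id", "chromosome", "kind"])

    if not stratify_by_chromosome:
        out = pd.DataFrame(
            0, index=sheet.index, columns=["gain", "loss"], dtype=np.int64
        )
        if len(df):
            counts = df.pivot_table(
                index="sample_id", columns="kind", aggfunc="size", fill_value=0
            )
            for kind in ("gain", "loss"):
                if kind in counts:
                    out.loc[counts.index, kind] = counts[kind]
        out.insert(0, "group", sheet["group"])
        out.insert(1, "total", out["gain"] + out["loss"])
        return out

    chroms = sorted(df["chromosome"].unique()) if len(df) else []
    idx = pd.MultiIndex.from_product(
        [sheet.index, chroms], names=["sample_id", "chromosome"]
    )
    out = pd.DataFrame(0, index=idx, columns=["gain", "loss"], dtype=np.int64)
    if len(df):
        counts = (
            df.groupby(["sample_id", "chromosome", "kind"]).size().unstack(fill_value=0)
        )
        for kind in ("gain", "loss"):
            if kind in counts:
                out.loc[counts.index, kind] = counts[kind]
    out = out.reset_index()
    out.insert(1, "group", out["sample_id"].map(sheet["group"]))
    out.insert(3, "total", out["gain"] + out["loss"])
    return out


def _rank_sum_statistic(x_ranks: np.ndarray) -> float:
    return float(np.sum(x_ranks))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of mid-ranks of ``x`` in the
    pooled sample. ``method`` is ``auto`` (exact for small groups, normal
    approximation otherwise), ``exact`` or ``normal``. The exact branch
    computes the full permutation distribution of W over all group
    assignments of the pooled values (by exact subset-sum counting) and
    returns ``P(|W - E[W]| >= |w_obs - E[W]|)``; the normal branch uses
    the tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    w_obs = _rank_sum_statistic(ranks[:n1])
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0

    if method == "auto":
        method = "exact" if min(n1, n2) < _EXACT_MIN_N and n <= _EXACT_MAX_N else "normal"

    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError("groups too large for exact enumeration")
        # doubled mid-ranks are integers, so the permutation distribution
        # of 2W is counted exactly by a subset-sum convolution
        r2 = np.rint(2 * ranks).astype(np.int64)
        w_max = int(r2.sum())
        dp = np.zeros((n1 + 1, w_max + 1))
        dp[0, 0] = 1.0
        for r in r2:
            for k in range(n1, 0, -1):
                dp[k, r:] += dp[k - 1, : w_max + 1 - r]
        counts = dp[n1]
        d_obs = abs(int(round(2 * w_obs)) - int(round(2 * mean_w)))
        w_vals = np.arange(w_max + 1)
        in_tail = np.abs(w_vals - int(round(2 * mean_w))) >= d_obs
        return w_obs, float(counts[in_tail].sum() / counts.sum())

    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    # tie-corrected variance of W
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all values identical
        return w_obs, 1.0
    z = (abs(w_obs - mean_w) - 0.5) / np.sqrt(var_w)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return w_obs, p


def compare_groups(
    burden: pd.DataFrame,
    group_a: str,
    group_b: str,
    metrics: Sequence[str] = ("total", "gain", "loss"),
    by_chromosome: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Rank-sum comparison report between two groups of a burden table.

    ``burden`` is the output of :func:`count_burden` (optionally
    stratified). Returns one row per metric (and chromosome when
    stratified) with group sizes, the rank-sum statistic and the
    two-sided p-value. Benjamini-Hochberg adjusted q-values are appended
    when ``fdr`` is set (off by default, mirroring per-test reporting).
    """
    df = burden.reset_index() if burden.index.name == "sample_id" else burden.copy()
    rows = []
    strata = (
        sorted(df["chromosome"].unique()) if by_chromosome and "chromosome" in df else [None]
    )
    for chrom in strata:
        sub = df if chrom is None else df[df["chromosome"] == chrom]
        a = sub[sub["group"] == group_a]
        b = sub[sub["group"] == group_b]
        for metric in metrics:
            w, p = rank_sum_test(a[metric].to_numpy(), b[metric].to_numpy())
            rows.append(
                {
                    "chromosome": chrom if chrom is not None else "all",
                    "metric": metric,
                    "group_a": group_a,
                    "n_a": len(a),
                    "group_b": group_b,
                    "n_b": len(b),
                    "rank_sum": w,
                    "p_value": p,
                }
            )
    report = pd.DataFrame(rows)
    if fdr and len(report):
        from statsmodels.stats.multitest import multipletests

        report["q_value"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
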