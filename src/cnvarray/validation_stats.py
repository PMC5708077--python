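"""Contingency statistics for deletion-genotype validation.

Given 2x3 case/control counts of no / heterozygous / homozygous deletion
at a locus, the table is collapsed to 2x2 in one of two exposure modes —
homozygous deletion vs the rest, or any deletion vs none — and the odds
ratio computed as (a*d)/(b*c) with a = exposed cases, b = unexposed
cases, c = exposed controls, d = unexposed controls. Tables containing a
zero cell receive the Haldane-Anscombe +0.5 in every cell first. The
default 95% confidence interval is the Woolf log-normal interval
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); a conditional exact
interval is available as an option.

Deletion spans printed by sequencing reports are 1-based inclusive, so a
span's length is stop - start + 1; converters to the package's internal
0-based half-open convention are provided.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb
import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable, validate_sample_sheet

__all__ = [
    "OddsRatioResult",
    "odds_ratio",
    "fisher_exact_2x2",
    "deletion_span",
    "genotype_table_from_truth",
    "one_based_inclusive_to_half_open",
    "half_open_to_one_based_inclusive",
]


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    mode: str
    ci_method: str
    haldane_applied: bool


def _collapse(table: GenotypeTable, mode: str) -> tuple[float, float, float, float]:
    no_c, het_c, hom_c = table.control
    no_a, het_a, hom_a = table.case
    if mode == "hom_vs_rest":
        a, b = hom_a, no_a + het_a
        c, d = hom_c, no_c + het_c
    elif mode == "any_del_vs_none":
        a, b = het_a + hom_a, no_a
        c, d = het_c + hom_c, no_c
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(a), float(b), float(c), float(d)


def odds_ratio(
    table: GenotypeTable,
    mode: str = "hom_vs_rest",
    ci_method: str = "woolf",
    alpha: float = 0.05,
    zero_cell_rule: str = "haldane",
) -> OddsRatioResult:
    """Odds ratio of deletion exposure in cases vs controls, with 95% CI.

    ``mode`` selects the exposure (``hom_vs_rest`` or
    ``any_del_vs_none``); when any collapsed cell is zero the
    Haldane-Anscombe +0.5 is added to all four cells before both the
    point estimate and the CI. ``ci_method`` is ``woolf`` (log-normal,
    default) or ``exact_conditional``.
    """
    a, b, c, d = _collapse(table, mode)
    haldane = False
    if zero_cell_rule == "haldane" and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        haldane = True
    elif zero_cell_rule not in ("haldane", "none"):
        raise ValueError(f"unknown zero_cell_rule {zero_cell_rule!r}")
    if 0.0 in (b, c):
        raise ValueError("odds ratio undefined with zero unexposed/exposed margin")
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "woolf":
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = float(np.exp(np.log(or_) - z * se)), float(np.exp(np.log(or_) + z * se))
    elif ci_method == "exact_conditional":
        res = stats.contingency.odds_ratio(
            np.array([[a, b], [c, d]]).round().astype(int), kind="conditional"
        )
        ci = res.confidence_interval(confidence_level=1 - alpha)
        lo, hi = float(ci.low), float(ci.high)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return OddsRatioResult(float(or_), lo, hi, mode, ci_method, haldane)


def fisher_exact_2x2(table2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the probabilities not exceeding the
    observed table's (computed in exact rational arithmetic). A table
    with a zero margin admits only itself, giving p = 1.
    """
    t = np.asarray(table2x2)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0
    denom = comb(n, row1)

    def weight(k: int) -> int:  # numerator of P(a = k), exact integer
        return comb(col1, k) * comb(n - col1, row1 - k)

    w_obs = weight(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    total = sum(w for k in range(lo, hi + 1) if (w := weight(k)) <= w_obs)
    return total / denom


def deletion_span(start_1based_inclusive: int, stop_1based_inclusive: int) -> int:
    """Length in bp of a 1-based inclusive printed span: stop - start + 1."""
    if stop_1based_inclusive < start_1based_inclusive:
        raise ValueError("stop must be >= start for a 1-based inclusive span")
    return stop_1based_inclusive - start_1based_inclusive + 1


def one_based_inclusive_to_half_open(start: int, stop: int) -> tuple[int, int]:
    """(start, stop) 1-based inclusive -> 0-based half-open."""
    return start - 1, stop


def half_open_to_one_based_inclusive(start: int, stop: int) -> tuple[int, int]:
    """(start, stop) 0-based half-open -> 1-based inclusive."""
    return start + 1, stop


def genotype_table_from_truth(
    truth: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    locus: str,
    case_group: str = "case",
    control_group: str = "control",
) -> GenotypeTable:
    """Cross-tabulate simulated truth genotypes at one deletion locus.

    ``truth`` is the samples x loci genotype frame emitted by the cohort
    simulator (entries no/het/hom); every sheet sample must have a
    genotype at ``locus``.
    """
    if locus not in truth.columns:
        raise KeyError(f"locus {locus!r} not in truth table")
    sheet = validate_sample_sheet(sample_sheet)
    counts = {case_group: [0, 0, 0], control_group: [0, 0, 0]}
    order = {"no": 0, "het": 1, "hom": 2}
    for sample_id, group in zip(sheet.index, sheet["group"]):
        if sample_id not in truth.index:
            raise ValueError(f"missing genotype for sample {sample_id!r}")
        g = truth.loc[sample_id, locus]
        if g not in order:
            raise ValueError(
                f"genotype {g!r} at {locus} is not a deletion genotype (no/het/hom)"
            )
        if group in counts:
            counts[group][order[g]] += 1
    return GenotypeTable(
        locus=locus,
        control=tuple(counts[control_group]),
        case=tuple(counts[case_group]),
    )
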