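"""Cross-sample CNV regions and two-stage disease-association selection.

Per-sample calls are merged into CNV regions (CNVRs) by single-linkage
reciprocal overlap, gains and losses kept separate. Disease-related
regions are then selected in two stages:

1. genome-wide stage — keep regions of at least ``min_length_bp``
   (default 1 kb) whose case carrier count strictly exceeds
   ``case_control_ratio`` (default 2) times the control carrier count;
   split survivors at ``size_cut_bp`` (default 10 kb);
2. fine-tiling stage — regions at or above the size cut are re-assayed in
   an independent cohort on a dense probe tiling (default 205 bp spacing)
   restricted to the candidate regions plus a flank, re-called with the
   stricter correlation aberration filter, re-merged and re-selected.

Small stage-1 survivors are carried to the final set unchanged (a flag
controls this); large regions survive only if the second stage confirms
them, possibly with refined boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aberration_calling import CallingParams, call_aberrations
from .core import CnvCall, CnvRegion, ProbeMap, validate_sample_sheet
from .synthetic_cohort import Cohort, make_probe_map

__all__ = [
    "SelectionParams",
    "merge_regions",
    "select_disease_related",
    "partition_by_size",
    "design_fine_probe_map",
    "second_stage_reevaluate",
    "run_two_stage",
]


@dataclass(frozen=True)
class SelectionParams:
    """Disease-association selection thresholds.

    ``case_control_ratio`` is applied with strict inequality to carrier
    counts by default (``frequency_mode`` compares carrier fractions
    instead, which matters when group sizes differ).
    """

    min_length_bp: int = 1_000
    case_control_ratio: float = 2.0
    size_cut_bp: int = 10_000
    frequency_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.case_control_ratio <= 0:
            raise ValueError("case_control_ratio must be positive")
        if self.size_cut_bp <= 0:
            raise ValueError("size_cut_bp must be positive")


def _reciprocal_overlap(a_start: int, a_stop: int, b_start: int, b_stop: int) -> float:
    o = min(a_stop, b_stop) - max(a_start, b_start)
    if o <= 0:
        return 0.0
    return o / max(a_stop - a_start, b_stop - b_start)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_regions(
    calls: Iterable[CnvCall],
    sample_sheet: pd.DataFrame,
    reciprocal_overlap: float = 0.5,
) -> list[CnvRegion]:
    """Single-linkage merge of same-kind calls into CNV regions.

    Two intervals merge when their reciprocal overlap (shared bp divided
    by the longer interval) reaches the threshold; merging is transitive,
    and passes are repeated on the growing region spans until a fixed
    point, so the operation is idempotent. A region's span is the union
    of its members' spans and its carriers the union of their samples,
    split by group. Regions are returned sorted by
    (chromosome, start, kind).
    """
    sheet = validate_sample_sheet(sample_sheet)
    groups: dict[str, str] = dict(zip(sheet.index, sheet["group"]))
    by_key: dict[tuple[str, str], list[tuple[int, int, frozenset]]] = {}
    for call in calls:
        if call.sample_id not in groups:
            raise ValueError(f"call for unknown sample {call.sample_id!r}")
        by_key.setdefault((call.chromosome, call.kind), []).append(
            (call.start, call.stop, frozenset([call.sample_id]))
        )

    regions: list[CnvRegion] = []
    for (chrom, kind), items in by_key.items():
        while True:
            items = sorted(items)
            uf = _UnionFind(len(items))
            merged_any = False
            for i, (a_start, a_stop, _) in enumerate(items):
                for j in range(i + 1, len(items)):
                    b_start, b_stop, _ = items[j]
                    if b_start >= a_stop:
                        break
                    if (
                        _reciprocal_overlap(a_start, a_stop, b_start, b_stop)
                        >= reciprocal_overlap
                    ):
                        if uf.find(i) != uf.find(j):
                            merged_any = True
                        uf.union(i, j)
            if not merged_any:
                break
            clusters: dict[int, list[tuple[int, int, frozenset]]] = {}
            for i, item in enumerate(items):
                clusters.setdefault(uf.find(i), []).append(item)
            items = [
                (
                    min(s for s, _, _ in cl),
                    max(t for _, t, _ in cl),
                    frozenset().union(*(m for _, _, m in cl)),
                )
                for cl in clusters.values()
            ]
        for start, stop, members in items:
            carriers: dict[str, set] = {}
            for sample_id in members:
                carriers.setdefault(groups[sample_id], set()).add(sample_id)
            regions.append(
                CnvRegion(
                    chromosome=chrom,
                    start=start,
                    stop=stop,
                    kind=kind,
                    carriers={g: frozenset(s) for g, s in carriers.items()},
                )
            )
    return sorted(regions, key=lambda r: (r.chromosome, r.start, r.kind))


def select_disease_related(
    regions: Iterable[CnvRegion],
    params: SelectionParams | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    case_group: str = "case",
    control_group: str = "control",
) -> list[CnvRegion]:
    """Keep regions passing the length and case-excess carrier filters.

    A region passes when its length is at least ``min_length_bp`` and its
    case carrier count strictly exceeds ``case_control_ratio`` times the
    control carrier count (zero control carriers pass with any case
    carrier). In frequency mode carrier fractions are compared instead,
    requiring the group sizes.
    """
    params = params or SelectionParams()
    if params.frequency_mode and (not n_cases or not n_controls):
        raise ValueError("frequency_mode requires n_cases and n_controls")
    out = []
    for region in regions:
        if region.length_bp < params.min_length_bp:
            continue
        a = region.carrier_count(case_group)
        c = region.carrier_count(control_group)
        if params.frequency_mode:
            passed = a / n_cases > params.case_control_ratio * (c / n_controls)
        else:
            passed = a > params.case_control_ratio * c
        if passed:
            out.append(region)
    return out


def partition_by_size(
    regions: Iterable[CnvRegion], size_cut_bp: int = 10_000
) -> tuple[list[CnvRegion], list[CnvRegion]]:
    """Split regions into (length < cut, length >= cut)."""
    if size_cut_bp <= 0:
        raise ValueError("size_cut_bp must be positive")
    small = [r for r in regions if r.length_bp < size_cut_bp]
    large = [r for r in regions if r.length_bp >= size_cut_bp]
    return small, large


def design_fine_probe_map(
    regions: Sequence[CnvRegion],
    fine_spacing_bp: int = 205,
    flank_fraction: float = 0.10,
) -> ProbeMap:
    """Dense tiling over candidate regions plus a proportional flank.

    Windows of overlapping flanked regions are merged per chromosome and
    tiled at ``fine_spacing_bp``; probe ids are prefixed ``fine``.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        flank = int(round(flank_fraction * r.length_bp))
        windows.setdefault(r.chromosome, []).append(
            (max(0, r.start - flank), r.stop + flank)
        )
    positions: dict[str, np.ndarray] = {}
    probe_ids: dict[str, np.ndarray] = {}
    chroms = sorted(windows)
    for chrom in chroms:
        merged: list[list[int]] = []
        for start, stop in sorted(windows[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], stop)
            else:
                merged.append([start, stop])
        pos = np.concatenate(
            [np.arange(start, stop, fine_spacing_bp) for start, stop in merged]
        ).astype(np.int64)
        positions[chrom] = pos
        probe_ids[chrom] = np.array(
            [f"{chrom}_fine{i:06d}" for i in range(pos.size)], dtype=object
        )
    return ProbeMap(tuple(chroms), positions, probe_ids)


def _overlaps_candidate(region: CnvRegion, candidates: Sequence[CnvRegion]) -> bool:
    for c in candidates:
        if (
            c.chromosome == region.chromosome
            and c.kind == region.kind
            and region.start < c.stop
            and c.start < region.stop
        ):
            return True
    return False


def second_stage_reevaluate(
    large_regions: Sequence[CnvRegion],
    stage2_cohort: Cohort,
    stage1_sample_ids: Iterable[str],
    calling_params: CallingParams | None = None,
    selection_params: SelectionParams | None = None,
    reciprocal_overlap: float = 0.5,
) -> list[CnvRegion]:
    """Re-evaluate large candidate regions in an independent fine-tiled cohort.

    The stage-2 cohort must be disjoint from the stage-1 samples and its
    profiles must live on a fine probe map covering the candidates (see
    :func:`design_fine_probe_map`). Calls are made with the correlation
    aberration filter by default, merged, re-selected with the same
    case-excess rule under the stage-2 group sizes, and restricted to
    regions overlapping a candidate. Boundaries may shift relative to the
    stage-1 candidates — that is the point of the fine tiling.
    """
    if not large_regions:
        return []
    stage1_ids = set(stage1_sample_ids)
    overlap = stage1_ids & set(stage2_cohort.sample_ids)
    if overlap:
        raise ValueError(
            f"stage-2 cohort overlaps stage-1 samples: {sorted(overlap)[:3]}..."
        )
    calling_params = calling_params or CallingParams(filter_mode="correlation")
    selection_params = selection_params or SelectionParams()
    calls: list[CnvCall] = []
    for profile in stage2_cohort.profiles:
        calls.extend(call_aberrations(profile, params=calling_params))
    regions = merge_regions(calls, stage2_cohort.sample_sheet, reciprocal_overlap)
    cfg = stage2_cohort.config
    selected = select_disease_related(
        regions,
        selection_params,
        n_cases=cfg.n_cases,
        n_controls=cfg.n_controls,
        case_group=cfg.case_group,
        control_group=cfg.control_group,
    )
    return [r for r in selected if _overlaps_candidate(r, large_regions)]


def run_two_stage(
    stage1_cohort: Cohort,
    stage2_cohort: Cohort,
    calling_params: CallingParams | None = None,
    selection_params: SelectionParams | None = None,
    reciprocal_overlap: float = 0.5,
    carry_small_without_retest: bool = True,
    stage1_calls: Sequence[CnvCall] | None = None,
) -> dict:
    """Full two-stage disease-association selection on simulated cohorts.

    Stage 1 calls every stage-1 profile (correlation filter by default),
    merges, selects, and partitions by size; stage 2 re-evaluates the
    large candidates in the independent stage-2 cohort. Precomputed
    stage-1 calls may be supplied to skip the (expensive) calling pass.
    Returns a dict with the intermediate and final region lists
    (key ``final``).
    """
    calling_params = calling_params or CallingParams(filter_mode="correlation")
    selection_params = selection_params or SelectionParams()
    if stage1_calls is not None:
        calls = list(stage1_calls)
    else:
        calls = []
        for profile in stage1_cohort.profiles:
            calls.extend(call_aberrations(profile, params=calling_params))
    regions = merge_regions(calls, stage1_cohort.sample_sheet, reciprocal_overlap)
    cfg = stage1_cohort.config
    selected = select_disease_related(
        regions,
        selection_params,
        n_cases=cfg.n_cases,
        n_controls=cfg.n_controls,
        case_group=cfg.case_group,
        control_group=cfg.control_group,
    )
    small, large = partition_by_size(selected, selection_params.size_cut_bp)
    confirmed = second_stage_reevaluate(
        large,
        stage2_cohort,
        stage1_sample_ids=stage1_cohort.sample_ids,
        calling_params=calling_params,
        selection_params=selection_params,
        reciprocal_overlap=reciprocal_overlap,
    )
    final = (small if carry_small_without_retest else []) + confirmed
    return {
        "stage1_calls": calls,
        "stage1_regions": regions,
        "stage1_selected": selected,
        "small": small,
        "large": large,
        "stage2_confirmed": confirmed,
        "final": sorted(final, key=lambda r: (r.chromosome, r.start)),
    }
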