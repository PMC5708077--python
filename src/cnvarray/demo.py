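"""Seeded demonstration analysis used by examples and acceptance checks.

Builds the demonstration case/control study end to end in memory: a
4 x 1 Mb toy genome tiled at 500 bp, a stage-1 cohort of 48 cases and
24 controls, and an independent stage-2 cohort of 40/40 assayed on a
205 bp fine tiling over the large stage-1 candidates, with the truth set
of :func:`cnvarray.synthetic_cohort.demo_truth_cnvs`.
"""
from __future__ import annotations

from typing import Sequence

from .aberration_calling import CallingParams, call_aberrations
from .cnv_association import (
    SelectionParams,
    design_fine_probe_map,
    merge_regions,
    partition_by_size,
    run_two_stage,
    select_disease_related,
)
from .core import CnvRegion
from .synthetic_cohort import (
    SimulationConfig,
    TruthCnv,
    demo_chromosome_lengths,
    demo_truth_cnvs,
    make_probe_map,
    simulate_cohort,
)

__all__ = ["run_demo_two_stage", "truth_recovered"]


def truth_recovered(
    cnv: TruthCnv,
    regions: Sequence[CnvRegion],
    min_reciprocal_overlap: float = 0.5,
) -> bool:
    """True when some region of the same kind reciprocally overlaps the truth CNV."""
    for r in regions:
        if r.chromosome != cnv.chromosome or r.kind != cnv.kind:
            continue
        o = min(r.stop, cnv.stop) - max(r.start, cnv.start)
        if o > 0 and o / max(r.length_bp, cnv.length_bp) >= min_reciprocal_overlap:
            return True
    return False


def run_demo_two_stage(seed: int = 1, mean_spacing_bp: int = 500) -> dict:
    """Simulate both demo cohorts and run the two-stage selection.

    Returns the :func:`run_two_stage` result dict extended with the
    cohorts and the truth split (``qualifying`` / ``null``).
    """
    lengths = demo_chromosome_lengths()
    truth = demo_truth_cnvs()
    pm = make_probe_map(lengths, mean_spacing_bp, seed=seed)
    cohort1 = simulate_cohort(
        pm, truth, SimulationConfig(n_cases=48, n_controls=24, seed=seed), "s1_"
    )
    calling = CallingParams(filter_mode="correlation")
    selection = SelectionParams()

    calls = []
    for p in cohort1.profiles:
        calls.extend(call_aberrations(p, params=calling))
    regions = merge_regions(calls, cohort1.sample_sheet)
    selected = select_disease_related(regions, selection, 48, 24)
    _, large = partition_by_size(selected, selection.size_cut_bp)

    fine_pm = design_fine_probe_map(large) if large else None
    if fine_pm is not None:
        truth2 = tuple(t for t in truth if t.chromosome in fine_pm.chroms)
        cohort2 = simulate_cohort(
            fine_pm,
            truth2,
            SimulationConfig(n_cases=40, n_controls=40, seed=seed + 1_000_003),
            "s2_",
        )
        result = run_two_stage(
            cohort1, cohort2, calling, selection, stage1_calls=calls
        )
    else:  # no large candidates: single-stage result
        cohort2 = None
        small, lg = partition_by_size(selected, selection.size_cut_bp)
        result = {
            "stage1_calls": calls,
            "stage1_regions": regions,
            "stage1_selected": selected,
            "small": small,
            "large": lg,
            "stage2_confirmed": [],
            "final": small,
        }
    result["stage1_cohort"] = cohort1
    result["stage2_cohort"] = cohort2
    result["qualifying"] = truth[:10]
    result["null"] = truth[10:]
    return result
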