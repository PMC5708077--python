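import numpy as np
import pandas as pd
import pytest

from cnvarray.cnv_association import (
    SelectionParams,
    design_fine_probe_map,
    merge_regions,
    partition_by_size,
    second_stage_reevaluate,
    select_disease_related,
)
from cnvarray.core import CnvCall, CnvRegion
from cnvarray.synthetic_cohort import SimulationConfig, TruthCnv, make_probe_map, simulate_cohort


def _call(sample, start, stop, chrom="chr1", mean=-0.8):
    kind = "gain" if mean > 0 else "loss"
    return CnvCall(sample, chrom, start, stop, 5, mean, 9.0, kind)


def _region(start, stop, case_carriers=(), control_carriers=(), chrom="chr1", kind="loss"):
    return CnvRegion(chrom, start, stop, kind,
                     {"case": frozenset(case_carriers), "control": frozenset(control_carriers)})


@pytest.fixture
def big_sheet():
    ids = [f"case_{i:03d}" for i in range(1, 7)] + [f"control_{i:03d}" for i in range(1, 4)]
    return pd.DataFrame({
        "sample_id": ids,
        "group": ["case"] * 6 + ["control"] * 3,
        "sex": ["M", "F"] * 4 + ["M"],
    })


class TestMergeRegions:
    def test_single_call_single_region(self, big_sheet):
        regions = merge_regions([_call("case_001", 10_000, 20_000)], big_sheet)
        assert len(regions) == 1
        assert regions[0].carrier_count("case") == 1
        assert (regions[0].start, regions[0].stop) == (10_000, 20_000)

    def test_identical_intervals_merge(self, big_sheet):
        calls = [_call("case_001", 10_000, 20_000), _call("control_001", 10_000, 20_000)]
        regions = merge_regions(calls, big_sheet)
        assert len(regions) == 1
        assert regions[0].carrier_count("case") == 1
        assert regions[0].carrier_count("control") == 1

    def test_forty_percent_overlap_stays_split(self, big_sheet):
        # [0,10000) vs [6000,16000): overlap 4000/10000 = 0.4 < 0.5
        calls = [_call("case_001", 0, 10_000), _call("case_002", 6_000, 16_000)]
        regions = merge_regions(calls, big_sheet)
        assert len(regions) == 2

    def test_gains_and_losses_never_merge(self, big_sheet):
        calls = [_call("case_001", 0, 10_000, mean=-0.8), _call("case_002", 0, 10_000, mean=0.8)]
        regions = merge_regions(calls, big_sheet)
        assert {r.kind for r in regions} == {"gain", "loss"}
        assert len(regions) == 2

    def test_transitive_single_linkage(self, big_sheet):
        calls = [
            _call("case_001", 0, 10_000),
            _call("case_002", 5_000, 15_000),
            _call("case_003", 10_000, 20_000),
        ]
        regions = merge_regions(calls, big_sheet)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].stop) == (0, 20_000)
        assert regions[0].carrier_count("case") == 3

    def test_idempotent_on_random_instances(self, big_sheet):
        rng = np.random.default_rng(5)
        samples = list(big_sheet["sample_id"])
        calls = []
        for _ in range(60):
            start = int(rng.integers(0, 200)) * 1_000
            length = int(rng.integers(2, 30)) * 1_000
            calls.append(_call(samples[int(rng.integers(0, len(samples)))],
                               start, start + length,
                               mean=-0.8 if rng.random() < 0.5 else 0.8))
        regions = merge_regions(calls, big_sheet)
        # re-merge the regions themselves (as one pseudo-call each)
        pseudo = [
            _call(sorted(r.all_carriers())[0], r.start, r.stop,
                  mean=-0.8 if r.kind == "loss" else 0.8)
            for r in regions
        ]
        again = merge_regions(pseudo, big_sheet)
        assert [(r.chromosome, r.start, r.stop, r.kind) for r in again] == [
            (r.chromosome, r.start, r.stop, r.kind) for r in regions
        ]

    def test_empty_input(self, big_sheet):
        assert merge_regions([], big_sheet) == []


class TestSelectDiseaseRelated:
    def test_short_region_excluded(self):
        r = _region(0, 900, case_carriers={"a", "b", "c"})
        assert select_disease_related([r]) == []

    def test_strict_ratio_boundary(self):
        kept = _region(0, 5_000, case_carriers={f"c{i}" for i in range(5)},
                       control_carriers={"x", "y"})
        dropped = _region(10_000, 15_000, case_carriers={f"c{i}" for i in range(4)},
                          control_carriers={"x", "y"})
        assert select_disease_related([kept, dropped]) == [kept]

    def test_zero_controls_pass_with_one_case(self):
        r = _region(0, 5_000, case_carriers={"a"})
        assert select_disease_related([r]) == [r]

    def test_output_subset_and_ratio_monotone(self):
        rng = np.random.default_rng(11)
        regions = [
            _region(i * 10_000, i * 10_000 + int(rng.integers(500, 20_000)),
                    case_carriers={f"c{k}" for k in range(int(rng.integers(0, 8)))},
                    control_carriers={f"x{k}" for k in range(int(rng.integers(0, 4)))})
            for i in range(30)
        ]
        loose = select_disease_related(regions, SelectionParams(case_control_ratio=1.5))
        strict = select_disease_related(regions, SelectionParams(case_control_ratio=3.0))
        assert set(r.region_id for r in strict) <= set(r.region_id for r in loose)
        assert set(r.region_id for r in loose) <= set(r.region_id for r in regions)

    def test_frequency_mode_differs_with_unbalanced_groups(self):
        # 6 of 48 cases vs 2 of 24 controls: count ratio 3 > 2 passes,
        # frequency ratio 0.125/0.0833 = 1.5 < 2 fails
        r = _region(0, 5_000, case_carriers={f"c{i}" for i in range(6)},
                    control_carriers={"x", "y"})
        assert select_disease_related([r]) == [r]
        assert select_disease_related(
            [r], SelectionParams(frequency_mode=True), n_cases=48, n_controls=24
        ) == []


class TestPartitionBySize:
    def test_boundary_semantics(self):
        regions = [_region(0, 9_999), _region(20_000, 30_000), _region(40_000, 50_001)]
        small, large = partition_by_size(regions, 10_000)
        assert [r.length_bp for r in small] == [9_999]
        assert sorted(r.length_bp for r in large) == [10_000, 10_001]

    def test_empty_and_conservation(self):
        assert partition_by_size([], 10_000) == ([], [])
        regions = [_region(0, 2_000), _region(5_000, 8_000)]
        small, large = partition_by_size(regions, 10_000)
        assert large == [] and len(small) == 2


class TestSecondStage:
    def test_fine_map_spacing_and_flank(self):
        r = _region(100_000, 120_000)
        pm = design_fine_probe_map([r], fine_spacing_bp=205, flank_fraction=0.10)
        pos = pm.positions["chr1"]
        assert pos[0] == 98_000  # 10% of 20 kb flank
        assert pos[-1] < 122_000
        assert np.all(np.diff(pos) == 205)

    def test_overlapping_windows_merge(self):
        pm = design_fine_probe_map([_region(0, 10_000), _region(9_000, 20_000)])
        assert np.all(np.diff(pm.positions["chr1"]) > 0)

    def test_empty_candidates(self):
        cohort = _stage2_cohort([_region(50_000, 80_000)], seed=3)
        assert second_stage_reevaluate([], cohort, ["s1_a"]) == []

    def test_sample_overlap_rejected(self):
        region = _region(50_000, 80_000)
        cohort = _stage2_cohort([region], seed=3)
        with pytest.raises(ValueError, match="overlaps stage-1"):
            second_stage_reevaluate([region], cohort, cohort.sample_ids[:1])

    def test_true_cnv_confirmed_with_refined_boundary(self):
        truth = TruthCnv("chr1", 50_000, 80_000, "loss", 0.4, 0.05)
        candidate = _region(49_000, 81_500)  # stage-1 span, off by a coarse probe
        cohort = _stage2_cohort([candidate], seed=3, truth=truth)
        out = second_stage_reevaluate([candidate], cohort, ["s1_x"])
        assert len(out) == 1
        assert abs(out[0].start - truth.start) <= 2 * 205
        assert abs(out[0].stop - truth.stop) <= 2 * 205

    def test_null_cnv_eliminated(self):
        truth = TruthCnv("chr1", 50_000, 80_000, "loss", 0.2, 0.2)
        candidate = _region(49_000, 81_500)
        cohort = _stage2_cohort([candidate], seed=4, truth=truth)
        assert second_stage_reevaluate([candidate], cohort, ["s1_x"]) == []


def _stage2_cohort(candidates, seed, truth=None):
    pm = design_fine_probe_map(candidates)
    cnvs = [truth] if truth is not None else []
    return simulate_cohort(
        pm, cnvs, SimulationConfig(n_cases=40, n_controls=40, noise_sd=0.15, seed=seed), "s2_"
    )
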