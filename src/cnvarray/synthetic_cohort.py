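"""Synthetic array-CGH cohorts with known spiked-in CNV truth.

The generator emulates the statistical structure a two-channel aCGH
case/control analysis assumes: an ordered probe grid (genome-wide
~7 kb spacing, or a 205 bp fine tiling over candidate regions), per-probe
log2 ratios that are 0 in diploid background and shifted inside carried
CNVs, and i.i.d. Gaussian probe noise whose magnitude is read out by the
derivative log ratio spread (DLRS) QC metric.

Copy-number expectations come from diploid arithmetic: a heterozygous
deletion is log2(1/2) = -1, a single-copy gain log2(3/2) ~ +0.585, and a
homozygous deletion (log2(0/2) = -inf in theory) is capped at a
configurable floor mimicking residual background hybridization. A
multiplicative ``attenuation`` factor models the signal compression of
real hybridizations; the default of 1.0 keeps noiseless profiles
analytically checkable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LogRatioProfile, ProbeMap

__all__ = [
    "TruthCnv",
    "SimulationConfig",
    "Cohort",
    "make_probe_map",
    "simulate_cohort",
    "make_gene_model_frame",
    "make_element_track_frame",
    "demo_chromosome_lengths",
    "demo_truth_cnvs",
]

#: log2 expectation per truth genotype at attenuation 1.0
_HET_LOSS_LOG2 = -1.0               # log2(1/2)
_GAIN_LOG2 = math.log2(3.0 / 2.0)   # single-copy gain
_HOM_LOSS_LOG2 = -3.0               # capped; true value is -inf


@dataclass(frozen=True)
class TruthCnv:
    """A spiked-in CNV with controlled case/control carrier frequencies.

    ``genotype`` applies to every carrier of this event and is only
    meaningful for losses (``het`` or ``hom``); gains are single-copy.
    """

    chromosome: str
    start: int
    stop: int
    kind: str  # gain | loss
    case_frequency: float
    control_frequency: float
    genotype: str = "het"

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "gain" and self.genotype == "hom":
            raise ValueError("hom genotype implies a loss")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        for f in (self.case_frequency, self.control_frequency):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def cnv_id(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.stop}:{self.kind}"

    @property
    def length_bp(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    noise_sd is the per-probe Gaussian sd in log2 units; it is also the
    asymptotic DLRS of a noise-only profile, so values inside
    ``target_dlrs_range`` (defaults cover the 0.11-0.17 band typical of
    arrays that pass the < 0.30 QC bound) yield QC-passing samples.
    """

    n_cases: int = 48
    n_controls: int = 24
    noise_sd: float = 0.15
    target_dlrs_range: tuple[float, float] = (0.11, 0.17)
    het_loss_log2: float = _HET_LOSS_LOG2
    hom_loss_log2: float = _HOM_LOSS_LOG2
    gain_log2: float = _GAIN_LOG2
    attenuation: float = 1.0
    seed: int = 0
    case_group: str = "case"
    control_group: str = "control"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in (0, 1]")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")

    def signal_for(self, kind: str, genotype: str) -> float:
        if kind == "gain":
            return self.attenuation * self.gain_log2
        if genotype == "hom":
            return self.attenuation * self.hom_loss_log2
        return self.attenuation * self.het_loss_log2


@dataclass
class Cohort:
    """A simulated case/control cohort with its ground truth."""

    probe_map: ProbeMap
    profiles: list[LogRatioProfile]
    sample_sheet: pd.DataFrame  # sample_id, group, sex
    truth: pd.DataFrame         # samples x truth CNVs, entries no|het|hom|gain
    truth_cnvs: tuple[TruthCnv, ...]
    config: SimulationConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_sheet["sample_id"])

    def profile(self, sample_id: str) -> LogRatioProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)


def make_probe_map(
    chromosome_lengths: dict[str, int],
    mean_spacing_bp: float,
    jitter_bp: float = 0.0,
    seed: int = 0,
    prefix: str = "p",
) -> ProbeMap:
    """Lay out probes along chromosomes at roughly even spacing.

    Probes sit at ``0, s, 2s, ...`` before jitter, so a chromosome of
    length L carries ``ceil(L / s)`` probes. Uniform jitter in
    ``[-jitter_bp, +jitter_bp]`` is applied and strict ordering restored.
    """
    if mean_spacing_bp <= 0:
        raise ValueError("mean_spacing_bp must be positive")
    if jitter_bp < 0 or jitter_bp >= mean_spacing_bp:
        raise ValueError("jitter_bp must satisfy 0 <= jitter_bp < mean_spacing_bp")
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    probe_ids: dict[str, np.ndarray] = {}
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        base = np.arange(0, length, mean_spacing_bp)
        pos = np.rint(base).astype(np.int64)
        if jitter_bp > 0:
            pos = pos + np.rint(
                rng.uniform(-jitter_bp, jitter_bp, size=pos.size)
            ).astype(np.int64)
            pos = np.clip(pos, 0, length - 1)
            pos.sort()
            # restore strict ordering after jitter collisions
            for k in range(1, pos.size):
                if pos[k] <= pos[k - 1]:
                    pos[k] = pos[k - 1] + 1
        positions[chrom] = pos
        probe_ids[chrom] = np.array(
            [f"{chrom}_{prefix}{i:06d}" for i in range(pos.size)], dtype=object
        )
    return ProbeMap(tuple(chromosome_lengths), positions, probe_ids)


def _check_truth_compatible(probe_map: ProbeMap, truth_cnvs: Sequence[TruthCnv]) -> None:
    known = set(probe_map.chroms)
    for cnv in truth_cnvs:
        if cnv.chromosome not in known:
            raise ValueError(f"truth CNV on unknown chromosome {cnv.chromosome!r}")
    # opposite-kind overlap on the same chromosome could put contradictory
    # signal on one sample; rejected outright (conservative).
    by_chrom: dict[str, list[TruthCnv]] = {}
    for cnv in truth_cnvs:
        by_chrom.setdefault(cnv.chromosome, []).append(cnv)
    for chrom, cnvs in by_chrom.items():
        cnvs = sorted(cnvs, key=lambda c: c.start)
        for a, b in zip(cnvs, cnvs[1:]):
            if b.start < a.stop and a.kind != b.kind:
                raise ValueError(
                    f"overlapping truth CNVs of opposite kind on {chrom}: "
                    f"{a.cnv_id} vs {b.cnv_id}"
                )


def simulate_cohort(
    probe_map: ProbeMap,
    truth_cnvs: Sequence[TruthCnv],
    config: SimulationConfig,
    sample_prefix: str = "",
) -> Cohort:
    """Simulate per-sample log2-ratio profiles with recorded truth genotypes.

    Carrier status is Bernoulli(group frequency) per sample and CNV, drawn
    from one cohort-level stream so the carrier pattern does not depend on
    the probe grid; per-sample probe noise comes from deterministic
    substreams spawned from the same seed. Same seed => bit-identical output.
    """
    truth_cnvs = tuple(truth_cnvs)
    _check_truth_compatible(probe_map, truth_cnvs)

    n = config.n_cases + config.n_controls
    sample_ids = [
        f"{sample_prefix}{config.case_group}_{i + 1:03d}" for i in range(config.n_cases)
    ] + [
        f"{sample_prefix}{config.control_group}_{i + 1:03d}"
        for i in range(config.n_controls)
    ]
    groups = [config.case_group] * config.n_cases + [
        config.control_group
    ] * config.n_controls
    sexes = ["M" if i % 2 == 0 else "F" for i in range(n)]
    sample_sheet = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "sex": sexes}
    )

    root = np.random.SeedSequence(config.seed)
    carrier_seq, noise_seq = root.spawn(2)
    carrier_rng = np.random.default_rng(carrier_seq)
    noise_rngs = [np.random.default_rng(s) for s in noise_seq.spawn(max(n, 1))]

    # carrier/genotype assignment: samples x CNVs
    truth_mat = np.full((n, len(truth_cnvs)), "no", dtype=object)
    for j, cnv in enumerate(truth_cnvs):
        for i, group in enumerate(groups):
            freq = (
                cnv.case_frequency
                if group == config.case_group
                else cnv.control_frequency
            )
            if carrier_rng.random() < freq:
                truth_mat[i, j] = "gain" if cnv.kind == "gain" else cnv.genotype
    truth = pd.DataFrame(
        truth_mat, index=sample_ids, columns=[c.cnv_id for c in truth_cnvs]
    )
    truth.index.name = "sample_id"

    profiles: list[LogRatioProfile] = []
    n_probes = probe_map.n_probes
    for i, (sample_id, group) in enumerate(zip(sample_ids, groups)):
        if config.noise_sd > 0:
            ratios = noise_rngs[i].normal(0.0, config.noise_sd, size=n_probes)
        else:
            ratios = np.zeros(n_probes)
        for j, cnv in enumerate(truth_cnvs):
            genotype = truth_mat[i, j]
            if genotype == "no":
                continue
            sl = probe_map.probes_in(cnv.chromosome, cnv.start, cnv.stop)
            ratios[sl] += config.signal_for(cnv.kind, "het" if genotype == "gain" else genotype)
        profiles.append(LogRatioProfile(sample_id, group, probe_map, ratios))

    return Cohort(probe_map, profiles, sample_sheet, truth, truth_cnvs, config)


def make_gene_model_frame(
    chromosome_lengths: dict[str, int],
    n_genes_per_chrom: int = 20,
    gene_length_bp: tuple[int, int] = (5_000, 60_000),
    n_exons: tuple[int, int] = (2, 10),
    exon_length_bp: tuple[int, int] = (100, 1_500),
    seed: int = 0,
) -> pd.DataFrame:
    """Random non-overlapping gene models as a BED12-shaped DataFrame.

    Genes are placed without overlap along each chromosome; exon blocks are
    drawn inside the gene span with the first block starting at the gene
    start and the last ending at the gene end (BED12 convention).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chromosome_lengths.items():
        cursor = 0
        for g in range(n_genes_per_chrom):
            glen = int(rng.integers(gene_length_bp[0], gene_length_bp[1] + 1))
            gap = int(rng.integers(1_000, max(2_000, length // (n_genes_per_chrom * 2))))
            start = cursor + gap
            stop = start + glen
            if stop >= length:
                break
            k = int(rng.integers(n_exons[0], n_exons[1] + 1))
            sizes = rng.integers(exon_length_bp[0], exon_length_bp[1] + 1, size=k)
            if k == 1 or int(sizes.sum()) >= glen:
                k, sizes = 1, np.array([glen])
            # interior gaps sum to the slack, so the first block starts at 0
            # and the last ends at the gene end (BED12 convention)
            slack = glen - int(sizes.sum())
            cuts = (
                np.sort(rng.integers(0, slack + 1, size=k - 2))
                if k > 2
                else np.array([], dtype=int)
            )
            gaps = np.diff(np.concatenate([[0], cuts, [slack]])) if k > 1 else []
            starts = [0]
            for size, gap in zip(sizes[:-1], gaps):
                starts.append(starts[-1] + int(size) + int(gap))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "stop": stop,
                    "name": f"{chrom}_gene{g + 1:03d}",
                    "score": 0,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "thick_start": start,
                    "thick_stop": stop,
                    "rgb": "0",
                    "block_count": k,
                    "block_sizes": ",".join(str(int(s)) for s in sizes),
                    "block_starts": ",".join(str(int(s)) for s in starts),
                }
            )
            cursor = stop
    return pd.DataFrame(rows)


def demo_chromosome_lengths(n_chroms: int = 4, length: int = 1_000_000) -> dict[str, int]:
    """Toy genome for the demonstration cohort: 4 x 1 Mb chromosomes.

    At the default 500 bp probe spacing this gives 2,000 probes per
    chromosome — a desk-scale stand-in for a genome-wide CNV array that
    keeps exhaustive interval search affordable.
    """
    return {f"chr{i + 1}": length for i in range(n_chroms)}


def demo_truth_cnvs() -> tuple[TruthCnv, ...]:
    """Ground truth for the demonstration case/control cohort.

    Ten disease-associated CNVs carry a case/control frequency
    differential (0.25 vs 0.05): five below the 10 kb size cut (3-8 kb,
    confirmed by the genome-wide stage alone) and five at or above it
    (12-40 kb, requiring fine-tiling confirmation). Ten null CNVs have
    equal frequency 0.20 in both groups; all are at least 10 kb so the
    independent second-stage cohort gets to reject them — with unequal
    group sizes (48 vs 24) an equal-frequency CNV sits exactly at the
    carrier-count ratio 2, so the genome-wide stage alone cannot filter
    it reliably. Gains, heterozygous and homozygous losses are all
    represented.
    """
    q = dict(case_frequency=0.25, control_frequency=0.05)
    null = dict(case_frequency=0.20, control_frequency=0.20)
    return (
        # disease-associated, < 10 kb
        TruthCnv("chr1", 100_000, 103_000, "loss", **q),
        TruthCnv("chr1", 300_000, 304_000, "gain", **q),
        TruthCnv("chr2", 120_000, 125_000, "loss", **q),
        TruthCnv("chr3", 140_000, 146_000, "loss", genotype="hom", **q),
        TruthCnv("chr4", 160_000, 168_000, "gain", **q),
        # disease-associated, >= 10 kb
        TruthCnv("chr1", 500_000, 512_000, "loss", **q),
        TruthCnv("chr2", 340_000, 355_000, "gain", **q),
        TruthCnv("chr3", 360_000, 380_000, "loss", **q),
        TruthCnv("chr4", 400_000, 428_000, "loss", genotype="hom", **q),
        TruthCnv("chr2", 600_000, 640_000, "loss", **q),
        # null (equal-frequency), all >= 10 kb
        TruthCnv("chr1", 700_000, 711_000, "loss", **null),
        TruthCnv("chr1", 850_000, 863_000, "gain", **null),
        TruthCnv("chr2", 760_000, 776_000, "loss", **null),
        TruthCnv("chr2", 900_000, 910_000, "loss", **null),
        TruthCnv("chr3", 500_000, 518_000, "gain", **null),
        TruthCnv("chr3", 700_000, 722_000, "loss", **null),
        TruthCnv("chr3", 860_000, 874_000, "loss", **null),
        TruthCnv("chr4", 600_000, 625_000, "gain", **null),
        TruthCnv("chr4", 700_000, 735_000, "loss", **null),
        TruthCnv("chr4", 800_000, 812_000, "loss", **null),
    )


_ELEMENT_TYPES = ("repeat", "CpG_island", "lincRNA", "DNase_HS", "TF_binding")


def make_element_track_frame(
    chromosome_lengths: dict[str, int],
    n_elements_per_chrom: int = 40,
    element_length_bp: tuple[int, int] = (200, 5_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Random typed non-coding elements as a BED4-shaped DataFrame."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chromosome_lengths.items():
        for _ in range(n_elements_per_chrom):
            elen = int(rng.integers(element_length_bp[0], element_length_bp[1] + 1))
            if elen >= length:
                continue
            start = int(rng.integers(0, length - elen))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "stop": start + elen,
                    "name": _ELEMENT_TYPES[int(rng.integers(0, len(_ELEMENT_TYPES)))],
                }
            )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
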