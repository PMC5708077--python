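"""Readers and writers for the pipeline's plain-text artifacts.

Tabular outputs are TSV with a single ``#``-prefixed header line;
interval files are BED (0-based half-open). These formats are the
interchange surface between pipeline stages, so real data prepared in
the same shapes drops in for the simulated inputs.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CnvCall, CnvRegion, LogRatioProfile, ProbeMap

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_probe_map_bed",
    "read_probe_map_bed",
    "write_profiles_tsv",
    "read_profiles_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_calls_bed",
    "read_calls_bed",
    "write_regions_bed",
    "write_bed12",
    "write_bed4",
]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """TSV with one '#'-prefixed header line."""
    path = Path(path)
    out = df.reset_index() if index else df
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        names = header[1:].split("\t")
        return pd.read_csv(fh, sep="\t", names=names)


def write_probe_map_bed(pm: ProbeMap, path: str | Path) -> None:
    """Probe map as BED3+name (one 1-bp interval per probe)."""
    with open(path, "w") as fh:
        for chrom in pm.chroms:
            for pos, pid in zip(pm.positions[chrom], pm.probe_ids[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pid}\n")


def read_probe_map_bed(path: str | Path) -> ProbeMap:
    chroms: list[str] = []
    positions: dict[str, list[int]] = {}
    probe_ids: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _stop, name = line.split("\t")[:4]
            if chrom not in positions:
                chroms.append(chrom)
                positions[chrom] = []
                probe_ids[chrom] = []
            positions[chrom].append(int(start))
            probe_ids[chrom].append(name)
    return ProbeMap(
        tuple(chroms),
        {c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        {c: np.array(v, dtype=object) for c, v in probe_ids.items()},
    )


def write_profiles_tsv(
    profiles: Sequence[LogRatioProfile], path: str | Path
) -> None:
    """Wide TSV: probe_id, chrom, pos, then one log2-ratio column per sample."""
    if not profiles:
        raise ValueError("no profiles to write")
    pm = profiles[0].probe_map
    df = pm.to_frame()
    for p in profiles:
        df[p.sample_id] = p.ratios
    write_tsv(df, path)


def read_profiles_tsv(
    path: str | Path, sample_sheet: pd.DataFrame
) -> tuple[ProbeMap, list[LogRatioProfile]]:
    df = read_tsv(path)
    chroms = list(dict.fromkeys(df["chrom"]))
    positions = {
        c: df.loc[df["chrom"] == c, "pos"].to_numpy(np.int64) for c in chroms
    }
    probe_ids = {
        c: df.loc[df["chrom"] == c, "probe_id"].to_numpy(object) for c in chroms
    }
    pm = ProbeMap(tuple(chroms), positions, probe_ids)
    groups = dict(zip(sample_sheet["sample_id"], sample_sheet["group"]))
    profiles = []
    for col in df.columns[3:]:
        if col not in groups:
            raise ValueError(f"profile column {col!r} missing from sample sheet")
        profiles.append(
            LogRatioProfile(col, groups[col], pm, df[col].to_numpy(float))
        )
    return pm, profiles


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    write_tsv(sheet[["sample_id", "group", "sex"]], path)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return read_tsv(path)


def write_calls_bed(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Calls as BED6+ (name = sample id) with kind, n_probes, mean_log2."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tstop\tname\tscore\tstrand\tkind\tn_probes\tmean_log2\n"
        )
        for c in sorted(calls, key=lambda c: (c.chromosome, c.start, c.sample_id)):
            fh.write(
                f"{c.chromosome}\t{c.start}\t{c.stop}\t{c.sample_id}\t"
                f"{c.score:.4f}\t.\t{c.kind}\t{c.n_probes}\t{c.mean_log2:.4f}\n"
            )


def read_calls_bed(path: str | Path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            calls.append(
                CnvCall(
                    sample_id=f[3],
                    chromosome=f[0],
                    start=int(f[1]),
                    stop=int(f[2]),
                    n_probes=int(f[7]),
                    mean_log2=float(f[8]),
                    score=float(f[4]),
                    kind=f[6],
                )
            )
    return calls


def write_regions_bed(regions: Iterable[CnvRegion], path: str | Path) -> None:
    """Regions as BED6+ with per-group carrier counts and carrier lists."""
    regions = list(regions)
    group_names = sorted({g for r in regions for g in r.carriers})
    cols = "".join(f"\tn_{g}" for g in group_names)
    with open(path, "w") as fh:
        fh.write(f"#chrom\tstart\tstop\tname\tscore\tstrand\tkind\tlength_bp{cols}\tcarriers\n")
        for r in sorted(regions, key=lambda r: (r.chromosome, r.start)):
            counts = "".join(f"\t{r.carrier_count(g)}" for g in group_names)
            carriers = ",".join(sorted(r.all_carriers()))
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.stop}\t{r.region_id}\t0\t.\t"
                f"{r.kind}\t{r.length_bp}{counts}\t{carriers}\n"
            )


def write_bed12(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED12-shaped gene-model DataFrame (see synthetic_cohort)."""
    cols = [
        "chrom", "start", "stop", "name", "score", "strand",
        "thick_start", "thick_stop", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bed4(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "stop", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )
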