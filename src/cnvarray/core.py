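"""Shared domain containers for the array-CGH CNV pipeline.

All genomic coordinates handled by this package are 0-based, half-open
``[start, stop)`` unless a function explicitly converts to the 1-based
inclusive convention used by PCR/sequencing reports
(:mod:`cnvarray.validation_stats`).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMap",
    "LogRatioProfile",
    "CnvCall",
    "CnvRegion",
    "GenotypeTable",
]


@dataclass(frozen=True)
class ProbeMap:
    """Ordered probe positions per chromosome defining the measurement grid.

    Parameters
    ----------
    chroms
        Chromosome labels in the order probes are laid out globally.
    positions
        Per-chromosome arrays of probe positions (bp, 0-based), strictly
        increasing within each chromosome.
    probe_ids
        Per-chromosome arrays of unique probe labels.
    """

    chroms: tuple[str, ...]
    positions: Mapping[str, np.ndarray]
    probe_ids: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        offsets: dict[str, tuple[int, int]] = {}
        norm_pos: dict[str, np.ndarray] = {}
        norm_ids: dict[str, np.ndarray] = {}
        lo = 0
        for chrom in self.chroms:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            ids = np.asarray(self.probe_ids[chrom])
            if pos.ndim != 1 or ids.shape != pos.shape:
                raise ValueError(f"positions/probe_ids mismatch on {chrom}")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
            dup = seen_ids.intersection(ids.tolist())
            if dup:
                raise ValueError(f"duplicate probe ids: {sorted(dup)[:3]}...")
            seen_ids.update(ids.tolist())
            norm_pos[chrom] = pos
            norm_ids[chrom] = ids
            offsets[chrom] = (lo, lo + pos.size)
            lo += pos.size
        object.__setattr__(self, "positions", norm_pos)
        object.__setattr__(self, "probe_ids", norm_ids)
        object.__setattr__(self, "chroms", tuple(self.chroms))
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_n_probes", lo)

    @property
    def n_probes(self) -> int:
        return self._n_probes  # type: ignore[attr-defined]

    def slice_of(self, chrom: str) -> slice:
        """Global index slice of a chromosome's probes."""
        lo, hi = self._offsets[chrom]  # type: ignore[attr-defined]
        return slice(lo, hi)

    def probes_in(self, chrom: str, start: int, stop: int) -> slice:
        """Global index slice of probes with ``start <= pos < stop``."""
        lo, hi = self._offsets[chrom]  # type: ignore[attr-defined]
        pos = np.asarray(self.positions[chrom])
        i = int(np.searchsorted(pos, start, side="left"))
        j = int(np.searchsorted(pos, stop, side="left"))
        return slice(lo + i, lo + j)

    def all_positions(self) -> np.ndarray:
        return np.concatenate(
            [np.asarray(self.positions[c]) for c in self.chroms]
        ) if self.chroms else np.empty(0, dtype=np.int64)

    def all_probe_ids(self) -> np.ndarray:
        return np.concatenate(
            [np.asarray(self.probe_ids[c]) for c in self.chroms]
        ) if self.chroms else np.empty(0, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            pos = np.asarray(self.positions[chrom])
            ids = np.asarray(self.probe_ids[chrom])
            rows.append(
                pd.DataFrame({"probe_id": ids, "chrom": chrom, "pos": pos})
            )
        if not rows:
            return pd.DataFrame(columns=["probe_id", "chrom", "pos"])
        return pd.concat(rows, ignore_index=True)


@dataclass
class LogRatioProfile:
    """One sample's per-probe log2 ratios aligned to a :class:`ProbeMap`."""

    sample_id: str
    group: str
    probe_map: ProbeMap
    ratios: np.ndarray
    dlrs: float | None = None  # filled in by QC (aberration_calling.compute_dlrs)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (self.probe_map.n_probes,):
            raise ValueError(
                f"{self.sample_id}: ratio vector length {self.ratios.size} "
                f"!= probe count {self.probe_map.n_probes}"
            )


@dataclass(frozen=True)
class CnvCall:
    """A called aberration interval in one sample.

    ``start``/``stop`` span the first to last probe of the interval,
    0-based half-open. ``kind`` is ``gain`` iff ``mean_log2 > 0``.
    """

    sample_id: str
    chromosome: str
    start: int
    stop: int
    n_probes: int
    mean_log2: float
    score: float
    kind: str

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")
        expected = "gain" if self.mean_log2 > 0 else "loss"
        if self.kind != expected:
            raise ValueError(f"kind {self.kind!r} contradicts mean_log2 {self.mean_log2}")

    @property
    def length_bp(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class CnvRegion:
    """A cross-sample merged CNV locus with per-group carrier sets."""

    chromosome: str
    start: int
    stop: int
    kind: str
    carriers: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("region must have positive length")
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"unknown kind {self.kind!r}")
        object.__setattr__(
            self, "carriers", {g: frozenset(s) for g, s in self.carriers.items()}
        )

    @property
    def length_bp(self) -> int:
        return self.stop - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.stop}:{self.kind}"

    def carrier_count(self, group: str) -> int:
        return len(self.carriers.get(group, frozenset()))

    def all_carriers(self) -> frozenset:
        out: frozenset = frozenset()
        for s in self.carriers.values():
            out = out | s
        return out


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 case/control counts of no / heterozygous / homozygous deletion."""

    locus: str
    control: tuple[int, int, int]
    case: tuple[int, int, int]

    def __post_init__(self) -> None:
        for row in (self.control, self.case):
            if len(row) != 3 or any((c < 0 or int(c) != c) for c in row):
                raise ValueError("counts must be three non-negative integers")
        if sum(self.control) == 0 or sum(self.case) == 0:
            raise ValueError("each group total must be > 0")

    def as_array(self) -> np.ndarray:
        """Rows (control, case) x columns (no, het, hom)."""
        return np.array([self.control, self.case], dtype=np.int64)


def validate_sample_sheet(sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the (sample_id, group, sex) sheet and return it indexed by sample."""
    required = {"sample_id", "group", "sex"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sample_sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sample_sheet.set_index("sample_id", drop=False)
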