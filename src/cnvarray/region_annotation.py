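"""Classification of CNV regions against gene models and element tracks.

A region is *exonic* ("exon-containing") when it overlaps at least 1 bp
of any exon, *intronic* when it overlaps a gene span but no exon, and
*intergenic* otherwise; the exon > intron precedence applies across all
overlapping genes. Non-coding element tracks (repeats, CpG islands,
lincRNAs, DNase-hypersensitive sites, TF-binding sites) are reported as
the set of element types the region touches; an empty set marks a region
in non-functional sequence.

Gene models are consumed as BED12 (blocks = exons) or GFF3 (gene/exon
features); overlapping transcripts of one gene are collapsed to union
exons. All coordinates are 0-based half-open internally (GFF3 input is
converted on read).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .core import CnvRegion

__all__ = [
    "GeneModel",
    "ElementTrack",
    "classify_region",
    "element_overlap",
    "annotate_regions",
]


@dataclass
class GeneModel:
    """Named gene spans with per-gene exon intervals.

    ``genes`` maps chromosome -> {gene name -> (start, stop)};
    ``exons`` maps gene name -> list of (start, stop) within the span.
    ``chromosomes`` is the known-chromosome universe (defaults to the
    chromosomes that carry genes); classifying a region on a chromosome
    outside it is an error.
    """

    genes: Mapping[str, Mapping[str, tuple[int, int]]]
    exons: Mapping[str, list[tuple[int, int]]]
    chromosomes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.chromosomes:
            self.chromosomes = frozenset(self.genes)
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for chrom, genes in self.genes.items():
            gt = IntervalTree()
            et = IntervalTree()
            for name, (start, stop) in genes.items():
                gt[start:stop] = name
                for estart, estop in self.exons.get(name, []):
                    if estart < start or estop > stop:
                        raise ValueError(
                            f"exon [{estart},{estop}) outside gene {name} span"
                        )
                    et[estart:estop] = name
            self._gene_trees[chrom] = gt
            self._exon_trees[chrom] = et

    @classmethod
    def from_bed12(cls, path: str | Path, chromosomes: Iterable[str] = ()) -> "GeneModel":
        """Read a BED12 gene model; blocks are exons."""
        genes: dict[str, dict[str, tuple[int, int]]] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"BED12 line with {len(f)} fields: {line[:60]}")
                chrom, start, stop, name = f[0], int(f[1]), int(f[2]), f[3]
                sizes = [int(s) for s in f[10].rstrip(",").split(",")]
                starts = [int(s) for s in f[11].rstrip(",").split(",")]
                if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                    raise ValueError(f"BED12 block count mismatch for {name}")
                genes.setdefault(chrom, {})
                span = genes[chrom].get(name)
                genes[chrom][name] = (
                    (start, stop) if span is None else (min(span[0], start), max(span[1], stop))
                )
                blocks = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
                exons.setdefault(name, []).extend(blocks)
        return cls(genes, _collapse_exons(exons), frozenset(chromosomes) or frozenset(genes))

    @classmethod
    def from_gff3(cls, path: str | Path, chromosomes: Iterable[str] = ()) -> "GeneModel":
        """Read a GFF3 gene model (gene and exon features, via gffutils)."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes: dict[str, dict[str, tuple[int, int]]] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        for gene in db.features_of_type("gene"):
            name = gene.attributes.get("Name", [gene.id])[0]
            # GFF3 is 1-based inclusive
            genes.setdefault(gene.seqid, {})[name] = (gene.start - 1, gene.end)
            for exon in db.children(gene, featuretype="exon"):
                exons.setdefault(name, []).append((exon.start - 1, exon.end))
            exons.setdefault(name, [])
        return cls(genes, _collapse_exons(exons), frozenset(chromosomes) or frozenset(genes))


def _collapse_exons(exons: Mapping[str, list[tuple[int, int]]]) -> dict[str, list[tuple[int, int]]]:
    """Union overlapping exon intervals per gene (collapse transcripts)."""
    out: dict[str, list[tuple[int, int]]] = {}
    for name, ivals in exons.items():
        merged: list[list[int]] = []
        for start, stop in sorted(ivals):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], stop)
            else:
                merged.append([start, stop])
        out[name] = [(a, b) for a, b in merged]
    return out


@dataclass
class ElementTrack:
    """Typed non-coding element intervals (may overlap each other)."""

    elements: Mapping[str, list[tuple[int, int, str]]]  # chrom -> (start, stop, type)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivals in self.elements.items():
            t = IntervalTree()
            for start, stop, etype in ivals:
                t[start:stop] = etype
            self._trees[chrom] = t

    @classmethod
    def from_bed4(cls, path: str | Path) -> "ElementTrack":
        """Read a BED4 track with the element type in the name column."""
        elements: dict[str, list[tuple[int, int, str]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"BED4 line with {len(f)} fields: {line[:60]}")
                elements.setdefault(f[0], []).append((int(f[1]), int(f[2]), f[3]))
        return cls(elements)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElementTrack":
        elements: dict[str, list[tuple[int, int, str]]] = {}
        for row in df.itertuples(index=False):
            elements.setdefault(row.chrom, []).append(
                (int(row.start), int(row.stop), str(row.name))
            )
        return cls(elements)


def classify_region(region: CnvRegion, gene_model: GeneModel) -> str:
    """Classify a region as ``exonic``, ``intronic`` or ``intergenic``.

    1 bp of exon overlap suffices for ``exonic``; any gene-span overlap
    without exon overlap is ``intronic``; otherwise ``intergenic``.
    """
    chrom = region.chromosome
    if chrom not in gene_model.chromosomes:
        raise ValueError(f"unknown chromosome {chrom!r} for this gene model")
    et = gene_model._exon_trees.get(chrom)
    if et is not None and et.overlap(region.start, region.stop):
        return "exonic"
    gt = gene_model._gene_trees.get(chrom)
    if gt is not None and gt.overlap(region.start, region.stop):
        return "intronic"
    return "intergenic"


def element_overlap(region: CnvRegion, element_track: ElementTrack) -> set[str]:
    """Set of element types overlapping the region by >= 1 bp."""
    tree = element_track._trees.get(region.chromosome)
    if tree is None:
        return set()
    return {iv.data for iv in tree.overlap(region.start, region.stop)}


def annotate_regions(
    regions: Iterable[CnvRegion],
    gene_model: GeneModel,
    element_track: ElementTrack | None = None,
) -> pd.DataFrame:
    """Annotated region table: class plus overlapping element types."""
    rows = []
    for region in regions:
        row = {
            "region_id": region.region_id,
            "chrom": region.chromosome,
            "start": region.start,
            "stop": region.stop,
            "kind": region.kind,
            "length_bp": region.length_bp,
            "genomic_class": classify_region(region, gene_model),
        }
        if element_track is not None:
            row["elements"] = ",".join(sorted(element_overlap(region, element_track)))
        rows.append(row)
    return pd.DataFrame(rows)
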