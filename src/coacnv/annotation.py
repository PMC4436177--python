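"""Interval annotation of CNV loci and linkage regions against gene lists."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .model import Interval


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.symbol}: end must exceed start")
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")


@dataclass(frozen=True)
class GeneHit:
    symbol: str
    overlap_bp: int
    contained: bool


@dataclass
class RegionAnnotation:
    region: Interval
    overlapping_genes: list[GeneHit]


def _check_chrom_naming(regions: Sequence[Interval], genes: Sequence[GeneRecord]) -> None:
    if not regions or not genes:
        return
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if region_chroms.isdisjoint(gene_chroms):
        r_pref = all(c.startswith("chr") for c in region_chroms)
        g_pref = all(c.startswith("chr") for c in gene_chroms)
        if r_pref != g_pref:
            raise ValueError(
                "chromosome naming mismatch between regions and gene list "
                "(e.g. 'chr1' vs '1'); normalize names before annotating"
            )


def annotate_regions(
    regions: Sequence[Interval],
    genes: Sequence[GeneRecord],
    mode: str = "any_overlap",
) -> list[RegionAnnotation]:
    """List genes intersecting each region.

    ``any_overlap`` keeps genes overlapping by >= 1 bp; ``containment``
    keeps only genes fully inside the region.  Gene lists per region are
    sorted by gene start.
    """
    if mode not in ("any_overlap", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_chrom_naming(regions, genes)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    annotations = []
    for region in regions:
        pairs: list[tuple[GeneRecord, GeneHit]] = []
        tree = trees.get(region.chrom)
        if tree is not None:
            for iv in tree.overlap(region.start, region.end):
                g: GeneRecord = iv.data
                contained = g.start >= region.start and g.end <= region.end
                if mode == "containment" and not contained:
                    continue
                overlap = min(g.end, region.end) - max(g.start, region.start)
                pairs.append((g, GeneHit(symbol=g.symbol, overlap_bp=overlap, contained=contained)))
        pairs.sort(key=lambda p: (p[0].start, p[0].symbol))
        annotations.append(RegionAnnotation(region=region, overlapping_genes=[h for _, h in pairs]))
    return annotations


def summarize_matches(annotations: Sequence[RegionAnnotation]) -> tuple[int, int]:
    """(number of regions with >= 1 gene, number of distinct gene symbols)."""
    n_regions = sum(1 for a in annotations if a.overlapping_genes)
    symbols = {h.symbol for a in annotations for h in a.overlapping_genes}
    return n_regions, len(symbols)
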