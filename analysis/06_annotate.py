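#!/usr/bin/env python
"""Annotate the recovered loci against a small cardiac gene panel.

The panel here is a bundled example (a handful of hg19 gene intervals from
the loci this pipeline plants or reports); a real analysis would pass the
full curated cardiac gene list as a BED4/TSV file.
"""

from pathlib import Path

from coacnv.annotation import GeneRecord, annotate_regions, summarize_matches
from coacnv.model import Interval
from coacnv.report import write_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"

# example panel, hg19 coordinates
PANEL = [
    GeneRecord("GSTM1", "chr1", 110_230_418, 110_236_367),
    GeneRecord("GSTM2", "chr1", 110_210_644, 110_252_171),
    GeneRecord("TRPM2", "chr21", 45_770_046, 45_862_964),
    GeneRecord("NKX2-5", "chr5", 172_659_106, 172_662_360),
    GeneRecord("SEPT9", "chr17", 75_277_492, 75_496_678),
]


def read_regions(path):
    out = []
    for line in path.read_text().splitlines()[1:]:
        f = line.split("\t")
        out.append(Interval(f[0], int(f[1]) - 1, int(f[2])))
    return out


def main() -> None:
    regions = read_regions(ROOT / "association.tsv")
    fam = ROOT / "family_overlap.tsv"
    if fam.exists():
        for line in fam.read_text().splitlines()[1:]:
            f = line.split("\t")
            start = int(f[1]) - 1
            regions.append(Interval(f[0], start, start + int(f[2])))

    annotations = annotate_regions(regions, PANEL, mode="any_overlap")
    n_regions, n_genes = summarize_matches(annotations)
    write_tsv(
        ROOT / "annotation.tsv",
        ["chrom", "start", "end", "genes"],
        [
            [a.region.chrom, a.region.start + 1, a.region.end,
             ",".join(h.symbol for h in a.overlapping_genes)]
            for a in annotations
        ],
    )
    print(f"{n_regions}/{len(regions)} regions overlap panel genes "
          f"({n_genes} distinct genes)")
    for a in annotations:
        if a.overlapping_genes:
            symbols = ",".join(h.symbol for h in a.overlapping_genes)
            print(f"  {a.region.chrom}:{a.region.start + 1}-{a.region.end}: {symbols}")


if __name__ == "__main__":
    main()
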