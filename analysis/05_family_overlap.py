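#!/usr/bin/env python
"""Shared CNV regions in the simulated families, and their overlap with the
sporadic association loci.

Looks for regions (>10 kb) carried by >= 4 affected family members and no
unaffected member, in each direction, then intersects them with the loci
from 04_association.py.  The planted chr21 duplication is shared 6/0 and
overlaps the sporadic 21q22.3 locus.
"""

from pathlib import Path

from coacnv.familial import cross_cohort_overlap, shared_regions
from coacnv.io import read_genome, read_samples, read_segments
from coacnv.model import Direction
from coacnv.report import SHARED_HEADER, shared_rows, write_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"


class _Locus:
    """Minimal region view over a row of association.tsv."""

    def __init__(self, chrom, start, end, direction):
        self.chrom, self.start, self.end = chrom, start, end
        self.direction = Direction(direction)


def read_assoc_loci(path):
    loci = []
    for line in path.read_text().splitlines()[1:]:
        f = line.split("\t")
        loci.append(_Locus(f[0], int(f[1]) - 1, int(f[2]), f[3]))
    return loci


def main() -> None:
    genome = read_genome(ROOT / "cohort" / "genome.yaml")
    samples = [s for s in read_samples(ROOT / "cohort" / "samples.tsv")
               if s.status.is_familial]
    member_ids = {s.sample_id for s in samples}
    segments = [s for s in read_segments(ROOT / "cohort" / "segments.tsv")
                if s.sample_id in member_ids]

    regions = []
    for direction in (Direction.loss, Direction.gain):
        regions.extend(shared_regions(segments, samples, genome, min_affected=4,
                                      direction=direction, max_unaffected=0))
    regions.sort(key=lambda r: (r.chrom, r.start))
    write_tsv(ROOT / "family_overlap.tsv", SHARED_HEADER, shared_rows(regions))

    print(f"{len(regions)} shared regions (>=4 affected, 0 unaffected):")
    for r in regions:
        print(f"  {r.chrom}:{r.start + 1}-{r.end} {r.direction.value} "
              f"{r.count_label} ({r.families_represented} families)")

    loci = read_assoc_loci(ROOT / "association.tsv")
    overlaps = cross_cohort_overlap(loci, regions)
    print(f"{len(overlaps)} sporadic/familial locus overlaps:")
    for o in overlaps:
        print(f"  {o.chrom}:{o.overlap_start + 1}-{o.overlap_end} "
              f"({o.overlap_bp} bp, {o.direction.value})")


if __name__ == "__main__":
    main()
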