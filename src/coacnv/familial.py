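"""Shared CNV regions among affected family members.

A sweep-line over the breakpoints of same-direction segments partitions each
chromosome into atomic intervals with a constant set of carriers.  A shared
region is a maximal run of atomic intervals whose *affected* carrier set is
identical throughout, contains at least ``min_affected`` members, and on
which at most ``max_unaffected`` distinct unaffected members carry an
overlapping same-direction segment.  Requiring an identical affected set
(rather than only a count) guarantees that every reported affected
individual carries the whole region, at the cost of splitting a qualifying
stretch where the carrier set changes — e.g. a 4/0 plateau inside a longer
3/0 stretch is reported as separate loci, which is how per-threshold locus
tables are usually presented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    CnvSegment,
    Direction,
    GenomeModel,
    SampleRecord,
    check_unique_samples,
    direction_of,
)


@dataclass(frozen=True)
class SharedRegion:
    chrom: str
    start: int
    end: int
    direction: Direction
    affected_ids: frozenset[str]
    n_unaffected: int
    families_represented: int

    @property
    def n_affected(self) -> int:
        return len(self.affected_ids)

    @property
    def count_label(self) -> str:
        return f"{self.n_affected}/{self.n_unaffected}"


def _qualifying(
    segments: Sequence[CnvSegment],
    index: dict[str, SampleRecord],
    direction: Direction,
    genome: GenomeModel,
    min_size: int,
) -> list[CnvSegment]:
    out = []
    for seg in segments:
        if seg.length <= min_size:
            continue
        sample = index.get(seg.sample_id)
        if sample is None:
            raise ValueError(f"segment references unknown sample {seg.sample_id!r}")
        if direction_of(seg, sample.sex, genome) is direction:
            out.append(seg)
    return out


def shared_regions(
    segments: Sequence[CnvSegment],
    samples: Sequence[SampleRecord],
    genome: GenomeModel,
    min_affected: int,
    direction: Direction,
    max_unaffected: int = 0,
    min_size: int = 10_000,
) -> list[SharedRegion]:
    """Maximal regions carried by >= min_affected affected and <= max_unaffected
    unaffected family members; sorted by (chrom, start)."""
    index = check_unique_samples(samples)
    affected_ids = {s.sample_id for s in samples if s.status.value == "affected"}
    if not affected_ids:
        raise ValueError("no affected samples in cohort")
    unaffected_ids = {s.sample_id for s in samples if s.status.value == "unaffected"}

    quals = _qualifying(segments, index, direction, genome, min_size)
    by_chrom: dict[str, list[CnvSegment]] = {}
    for seg in quals:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    regions: list[SharedRegion] = []
    for chrom in sorted(by_chrom):
        segs = by_chrom[chrom]
        points = sorted({s.start for s in segs} | {s.end for s in segs})
        # atomic intervals between consecutive breakpoints
        atoms: list[tuple[int, int, frozenset[str], frozenset[str]]] = []
        for lo, hi in zip(points[:-1], points[1:]):
            aff = frozenset(
                s.sample_id for s in segs
                if s.sample_id in affected_ids and s.start <= lo and s.end >= hi
            )
            unaff = frozenset(
                s.sample_id for s in segs
                if s.sample_id in unaffected_ids and s.start <= lo and s.end >= hi
            )
            atoms.append((lo, hi, aff, unaff))

        i = 0
        while i < len(atoms):
            lo, hi, aff, _ = atoms[i]
            if len(aff) < min_affected:
                i += 1
                continue
            j = i
            while (
                j + 1 < len(atoms)
                and atoms[j + 1][0] == atoms[j][1]  # contiguous
                and atoms[j + 1][2] == aff
            ):
                j += 1
            start, end = atoms[i][0], atoms[j][1]
            # unaffected members with any overlapping same-direction segment
            unaff_over = {
                s.sample_id for s in segs
                if s.sample_id in unaffected_ids and s.start < end and s.end > start
            }
            if len(unaff_over) <= max_unaffected:
                families = {index[a].family_id for a in aff}
                regions.append(
                    SharedRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        direction=direction,
                        affected_ids=aff,
                        n_unaffected=len(unaff_over),
                        families_represented=len(families),
                    )
                )
            i = j + 1
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


@dataclass(frozen=True)
class RegionOverlap:
    chrom: str
    direction: Direction
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    overlap_start: int
    overlap_end: int

    @property
    def overlap_bp(self) -> int:
        return self.overlap_end - self.overlap_start


def cross_cohort_overlap(
    regions_a: Sequence, regions_b: Sequence, min_bp: int = 1
) -> list[RegionOverlap]:
    """All same-chromosome, same-direction pairs overlapping by >= min_bp.

    Accepts any objects with chrom/start/end/direction attributes (e.g.
    association loci vs familial shared regions).
    """
    out = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.chrom != rb.chrom or ra.direction != rb.direction:
                continue
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if hi - lo >= min_bp:
                out.append(
                    RegionOverlap(
                        chrom=ra.chrom,
                        direction=ra.direction,
                        a_start=ra.start,
                        a_end=ra.end,
                        b_start=rb.start,
                        b_end=rb.end,
                        overlap_start=lo,
                        overlap_end=hi,
                    )
                )
    out.sort(key=lambda o: (o.chrom, o.overlap_start))
    return out
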