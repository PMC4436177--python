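"""Domain types and segment classification rules.

Copy-number variant (CNV) segments are stored with 0-based half-open
coordinates internally; the canonical TSV dialect and all report output use
1-based inclusive coordinates (see :mod:`coacnv.io`).

A "CNV" is defined relative to expected ploidy: 2 on autosomes and on the
female X, 1 on the male X outside the pseudo-autosomal regions (PARs).
Male X segments that touch a PAR are excluded from sex-specific X analyses
entirely rather than trimmed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Status(str, enum.Enum):
    """Phenotype label: case/control for cohorts, affected/unaffected in families."""

    case = "case"
    control = "control"
    affected = "affected"
    unaffected = "unaffected"

    @property
    def is_case_like(self) -> bool:
        return self in (Status.case, Status.affected)

    @property
    def is_familial(self) -> bool:
        return self in (Status.affected, Status.unaffected)


class CnvClass(str, enum.Enum):
    not_cnv = "not_cnv"
    autosomal_cnv = "autosomal_cnv"
    x_male_cnv = "x_male_cnv"
    x_female_cnv = "x_female_cnv"
    par_excluded = "par_excluded"


class Direction(str, enum.Enum):
    loss = "loss"
    gain = "gain"
    none = "none"


class SizeBin(str, enum.Enum):
    sub_threshold = "sub_threshold"
    small = "small"
    large = "large"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    sex: Sex
    status: Status
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status.is_familial and self.family_id is None:
            raise ValueError(
                f"sample {self.sample_id!r}: affected/unaffected status requires a family_id"
            )
        if not self.status.is_familial and self.family_id is not None:
            raise ValueError(
                f"sample {self.sample_id!r}: family_id only allowed for affected/unaffected samples"
            )


@dataclass(frozen=True)
class CnvSegment:
    """One called copy-number segment in one sample (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_markers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")
        if self.n_markers is not None and self.n_markers <= 0:
            raise ValueError("n_markers must be positive when present")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end}: end must exceed start")

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


# hg19 X pseudo-autosomal regions (0-based half-open).
HG19_PAR1 = (60000, 2699520)
HG19_PAR2 = (154931043, 155260560)

# hg19 chromosome lengths (chr1..22, X, Y).
HG19_CHROM_LENGTHS = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}


@dataclass
class GenomeModel:
    """Chromosome lengths plus PAR intervals on the X (optionally Y)."""

    chromosomes: dict[str, int] = field(default_factory=lambda: dict(HG19_CHROM_LENGTHS))
    par_intervals: list[Interval] = field(
        default_factory=lambda: [
            Interval("chrX", *HG19_PAR1),
            Interval("chrX", *HG19_PAR2),
        ]
    )
    x_name: str = "chrX"
    y_name: str = "chrY"

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")
        for iv in self.par_intervals:
            if iv.chrom not in self.chromosomes:
                raise ValueError(f"PAR interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chromosomes[iv.chrom]:
                raise ValueError(f"PAR interval {iv} exceeds chromosome bounds")

    def is_x(self, chrom: str) -> bool:
        return chrom == self.x_name

    def is_y(self, chrom: str) -> bool:
        return chrom == self.y_name

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.chromosomes and not (self.is_x(chrom) or self.is_y(chrom))

    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if self.is_autosome(c)]

    def in_par(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any PAR interval by >= 1 bp."""
        probe = Interval(chrom, start, end)
        return any(probe.overlaps(iv) for iv in self.par_intervals)


@dataclass(frozen=True)
class SizeBinConfig:
    """Size strata: (min_size, large_threshold] is "small", above is "large".

    Both boundaries are strict in the "greater than" sense: a segment of
    exactly ``min_size`` is sub-threshold, one of exactly ``large_threshold``
    is small.
    """

    min_size: int = 10_000
    large_threshold: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.min_size < self.large_threshold):
            raise ValueError("require 0 < min_size < large_threshold")


def expected_ploidy(chrom: str, sex: Sex, genome: GenomeModel) -> int:
    """Expected copy number: 2 everywhere except the male non-PAR X (1)."""
    if genome.is_x(chrom) and sex is Sex.male:
        return 1
    return 2


def classify_segment(segment: CnvSegment, sex: Sex, genome: GenomeModel) -> CnvClass:
    """Assign a segment to exactly one analysis class given carrier sex.

    Autosomes: CNV iff copy number != 2. Male X: segments touching a PAR are
    dropped (par_excluded); otherwise CNV iff copy number != 1. Female X: as
    autosomes. Y segments are never counted as CNVs.
    """
    if segment.chrom not in genome.chromosomes:
        raise ValueError(f"chromosome {segment.chrom!r} not in genome model")
    if genome.is_y(segment.chrom):
        return CnvClass.not_cnv
    if genome.is_autosome(segment.chrom):
        return CnvClass.autosomal_cnv if segment.copy_number != 2 else CnvClass.not_cnv
    # X chromosome
    if sex is Sex.unknown:
        raise ValueError(
            f"segment {segment.sample_id}:{segment.chrom}: sex must be known for X-chromosome segments"
        )
    if sex is Sex.male:
        if genome.in_par(segment.chrom, segment.start, segment.end):
            return CnvClass.par_excluded
        return CnvClass.x_male_cnv if segment.copy_number != 1 else CnvClass.not_cnv
    return CnvClass.x_female_cnv if segment.copy_number != 2 else CnvClass.not_cnv


def direction_of(segment: CnvSegment, sex: Sex, genome: GenomeModel) -> Direction:
    """Loss/gain relative to expected ploidy; ``none`` at expected ploidy."""
    ploidy = expected_ploidy(segment.chrom, sex, genome)
    if segment.copy_number < ploidy:
        return Direction.loss
    if segment.copy_number > ploidy:
        return Direction.gain
    return Direction.none


def size_bin(segment: CnvSegment, config: SizeBinConfig = SizeBinConfig()) -> SizeBin:
    if segment.length <= config.min_size:
        return SizeBin.sub_threshold
    if segment.length <= config.large_threshold:
        return SizeBin.small
    return SizeBin.large


def check_unique_samples(samples: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    """Index samples by id, enforcing uniqueness."""
    index: dict[str, SampleRecord] = {}
    for s in samples:
        if s.sample_id in index:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        index[s.sample_id] = s
    return index
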