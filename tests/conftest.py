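import pytest

from coacnv.model import (
    CnvSegment,
    GenomeModel,
    Interval,
    SampleRecord,
    Sex,
    Status,
)


@pytest.fixture(scope="session")
def genome() -> GenomeModel:
    """Default genome model (hg19 lengths, X PAR1/PAR2)."""
    return GenomeModel()


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeModel:
    """Small two-chromosome genome for hand-constructed cases."""
    return GenomeModel(
        chromosomes={"chr1": 1_000_000, "chrX": 1_000_000},
        par_intervals=[Interval("chrX", 0, 10_000), Interval("chrX", 990_000, 1_000_000)],
    )


def make_sample(sid, sex="male", status="case", family=None):
    return SampleRecord(sid, Sex(sex), Status(status), family)


def make_segment(sid, chrom, start, end, cn, nm=10):
    return CnvSegment(sid, chrom, start, end, cn, nm)


@pytest.fixture
def seg_factory():
    return make_segment


@pytest.fixture
def sample_factory():
    return make_sample
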