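"""Seeded synthetic CNV cohorts and pedigrees with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: per-sample autosomal segment counts (negative binomial), heavy-tailed
segment lengths (log-normal truncated below), sex-specific X-chromosome
segment counts, an odds-multiplier ``theta`` that enriches *large*
(> large_threshold) segments on the case male X — the exact quantity the
burden test measures — planted case/control-frequency loci for association
recovery, count outliers for QC testing, and families with a shared
duplication in all affected members.

Marker counts are assigned deterministically from length
(``round(marker_density * length)``, floored at 1) so the >= 5-marker
association filter is exercisable.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .model import (
    CnvSegment,
    Direction,
    GenomeModel,
    Interval,
    SampleRecord,
    Sex,
    SizeBinConfig,
    Status,
)


@dataclass(frozen=True)
class PlantedLocus:
    chrom: str
    start: int
    end: int
    direction: Direction
    f_case: float
    f_control: float
    n_markers: int = 25

    def __post_init__(self) -> None:
        if not (0 <= self.f_case <= 1 and 0 <= self.f_control <= 1):
            raise ValueError("planted locus frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    n_affected: int = 2
    n_unaffected: int = 2
    shared_segments: tuple[tuple[str, int, int, Direction], ...] = ()
    jitter_bp: int = 0
    unaffected_carry: bool = False  # plant the segment in unaffected members too


@dataclass
class SimulationConfig:
    """Study-scale defaults mirror the sporadic cohort: 70 cases (51 male) vs
    605 controls (382 male); ~13 X segments per male, log-normal lengths with
    a minority of > 100 kb events."""

    seed: int = 0
    n_case_male: int = 51
    n_case_female: int = 19
    n_control_male: int = 382
    n_control_female: int = 223
    count_model: tuple[float, float] = (25.0, 10.0)  # (mean, dispersion) autosomal counts
    length_model: tuple[float, float] = (np.log(20_000.0), 1.0)  # log-normal (mu, sigma)
    length_floor: int = 1_000
    x_count_model: dict = field(default_factory=lambda: {"male": 12.0, "female": 2.0})
    x_large_enrichment_or: float = 1.0  # theta
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 5.0
    marker_density: float = 1.0 / 1_800.0  # SNP-array scale: one marker per ~1.8 kb
    bins: SizeBinConfig = field(default_factory=SizeBinConfig)
    families: list[FamilySpec] = field(default_factory=list)


@dataclass
class TruthTable:
    planted_carriers: dict[str, list[str]]  # locus key -> carrier sample ids
    theta: float
    outlier_ids: list[str]
    shared_cores: dict[str, tuple[str, int, int]] = field(default_factory=dict)


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Exact inverse-CDF sampling of a log-normal restricted to (lo, hi]."""
    a = norm.cdf((np.log(max(lo, 1e-9)) - mu) / sigma)
    b = norm.cdf((np.log(hi) - mu) / sigma) if np.isfinite(hi) else 1.0
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


def _p_large(cfg: SimulationConfig) -> float:
    """P(length > large_threshold | length > floor) under the length model."""
    mu, sigma = cfg.length_model
    tail_t = norm.sf((np.log(cfg.bins.large_threshold) - mu) / sigma)
    tail_f = norm.sf((np.log(cfg.length_floor) - mu) / sigma)
    return float(tail_t / tail_f)


def _draw_lengths(
    rng: np.random.Generator, cfg: SimulationConfig, n: int, p_large: float
) -> np.ndarray:
    """Mixture draw: Bernoulli(p_large) size class, then length from the
    log-normal truncated to that class (and above the floor)."""
    mu, sigma = cfg.length_model
    t = float(cfg.bins.large_threshold)
    is_large = rng.uniform(size=n) < p_large
    lengths = np.empty(n)
    n_large = int(is_large.sum())
    if n_large:
        lengths[is_large] = _truncated_lognormal(rng, mu, sigma, t, np.inf, n_large)
    n_small = n - n_large
    if n_small:
        lengths[~is_large] = _truncated_lognormal(rng, mu, sigma, cfg.length_floor, t, n_small)
    out = np.round(lengths).astype(np.int64)
    # rounding must not flip the drawn size class
    out[is_large] = np.maximum(out[is_large], int(t) + 1)
    out[~is_large] = np.clip(out[~is_large], cfg.length_floor, int(t))
    return out


def _n_markers(cfg: SimulationConfig, lengths: np.ndarray) -> np.ndarray:
    return np.maximum(1, np.round(cfg.marker_density * lengths)).astype(np.int64)


def _place(
    rng: np.random.Generator, chrom_len: int, length: int
) -> tuple[int, int]:
    length = min(length, chrom_len - 1)
    start = int(rng.integers(0, chrom_len - length))
    return start, start + length


def _background_segments(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genome: GenomeModel,
    sample: SampleRecord,
    n_auto: int,
    n_x: int,
    theta_applies: bool,
) -> list[CnvSegment]:
    segs: list[CnvSegment] = []
    autosomes = genome.autosomes()
    auto_lengths = np.array([genome.chromosomes[c] for c in autosomes], dtype=float)
    auto_probs = auto_lengths / auto_lengths.sum()
    p0 = _p_large(cfg)
    odds = p0 / (1 - p0)
    theta = cfg.x_large_enrichment_or if theta_applies else 1.0
    p_x = (theta * odds) / (1 + theta * odds)

    if n_auto > 0:
        chrom_idx = rng.choice(len(autosomes), size=n_auto, p=auto_probs)
        lengths = _draw_lengths(rng, cfg, n_auto, p0)
        gains = rng.uniform(size=n_auto) < 0.5
        marks = _n_markers(cfg, lengths)
        for i in range(n_auto):
            chrom = autosomes[chrom_idx[i]]
            start, end = _place(rng, genome.chromosomes[chrom], int(lengths[i]))
            segs.append(
                CnvSegment(
                    sample_id=sample.sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    copy_number=3 if gains[i] else 1,
                    n_markers=int(marks[i]),
                )
            )
    if n_x > 0:
        lengths = _draw_lengths(rng, cfg, n_x, p_x)
        gains = rng.uniform(size=n_x) < 0.5
        marks = _n_markers(cfg, lengths)
        ploidy = 1 if sample.sex is Sex.male else 2
        for i in range(n_x):
            start, end = _place(rng, genome.chromosomes[genome.x_name], int(lengths[i]))
            segs.append(
                CnvSegment(
                    sample_id=sample.sample_id,
                    chrom=genome.x_name,
                    start=start,
                    end=end,
                    copy_number=ploidy + 1 if gains[i] else ploidy - 1,
                    n_markers=int(marks[i]),
                )
            )
    return segs


def _locus_key(locus: PlantedLocus) -> str:
    return f"{locus.chrom}:{locus.start}-{locus.end}:{locus.direction.value}"


def simulate_cohort(
    config: SimulationConfig, genome: Optional[GenomeModel] = None
) -> tuple[list[CnvSegment], list[SampleRecord], TruthTable]:
    """Simulate a case-control cohort of CNV segment lists.

    Returns (segments, samples, truth).  Byte-identical output for a fixed
    config (all randomness flows through one seeded generator).
    """
    genome = genome or GenomeModel()
    for locus in config.planted_loci:
        if locus.chrom not in genome.chromosomes or locus.end > genome.chromosomes[locus.chrom]:
            raise ValueError(f"planted locus {_locus_key(locus)} outside genome model")
    rng = np.random.default_rng(config.seed)

    samples: list[SampleRecord] = []
    specs = [
        (config.n_case_male, Sex.male, Status.case, "CA-M"),
        (config.n_case_female, Sex.female, Status.case, "CA-F"),
        (config.n_control_male, Sex.male, Status.control, "CO-M"),
        (config.n_control_female, Sex.female, Status.control, "CO-F"),
    ]
    for n, sex, status, prefix in specs:
        for i in range(n):
            samples.append(SampleRecord(f"{prefix}{i:04d}", sex, status))

    mean, dispersion = config.count_model
    n_samples = len(samples)
    if mean > 0:
        p_nb = dispersion / (dispersion + mean)
        auto_counts = rng.negative_binomial(dispersion, p_nb, size=n_samples)
    else:
        auto_counts = np.zeros(n_samples, dtype=np.int64)

    n_outliers = int(round(config.outlier_fraction * n_samples))
    outlier_idx = rng.choice(n_samples, size=n_outliers, replace=False) if n_outliers else []
    outlier_ids = []
    for idx in outlier_idx:
        auto_counts[idx] = int(np.ceil(auto_counts[idx] * config.outlier_multiplier)) + 1
        outlier_ids.append(samples[idx].sample_id)

    segments: list[CnvSegment] = []
    planted_carriers: dict[str, list[str]] = {_locus_key(l): [] for l in config.planted_loci}
    for i, sample in enumerate(samples):
        x_mean = float(config.x_count_model.get(sample.sex.value, 0.0))
        n_x = int(rng.poisson(x_mean)) if x_mean > 0 else 0
        theta_applies = sample.sex is Sex.male and sample.status.is_case_like
        segments.extend(
            _background_segments(
                rng, config, genome, sample, int(auto_counts[i]), n_x, theta_applies
            )
        )
        for locus in config.planted_loci:
            f = locus.f_case if sample.status.is_case_like else locus.f_control
            if f > 0 and rng.uniform() < f:
                if genome.is_x(locus.chrom):
                    ploidy = 1 if sample.sex is Sex.male else 2
                else:
                    ploidy = 2
                cn = ploidy + 1 if locus.direction is Direction.gain else ploidy - 1
                segments.append(
                    CnvSegment(
                        sample_id=sample.sample_id,
                        chrom=locus.chrom,
                        start=locus.start,
                        end=locus.end,
                        copy_number=cn,
                        n_markers=locus.n_markers,
                    )
                )
                planted_carriers[_locus_key(locus)].append(sample.sample_id)

    truth = TruthTable(
        planted_carriers=planted_carriers,
        theta=config.x_large_enrichment_or,
        outlier_ids=sorted(outlier_ids),
    )
    return segments, samples, truth


def simulate_families(
    config: SimulationConfig, genome: Optional[GenomeModel] = None
) -> tuple[list[CnvSegment], list[SampleRecord], TruthTable]:
    """Simulate pedigrees with planted shared segments in affected members.

    Per-person breakpoint jitter erodes each planted interval inward by a
    uniform 0..jitter_bp at each end, so the shared core — the intersection
    across carriers — always lies inside the planted interval and contains
    the doubly-eroded core [start + jitter, end - jitter].
    """
    genome = genome or GenomeModel()
    if not config.families:
        raise ValueError("no family specs in config")
    rng = np.random.default_rng(config.seed)

    samples: list[SampleRecord] = []
    segments: list[CnvSegment] = []
    shared_cores: dict[str, tuple[str, int, int]] = {}
    background_cfg = replace(config, families=[])

    for fam in config.families:
        for chrom, start, end, _d in fam.shared_segments:
            if fam.jitter_bp * 2 >= end - start:
                raise ValueError(
                    f"family {fam.family_id}: jitter {fam.jitter_bp} too large for "
                    f"planted interval of length {end - start}"
                )
        members: list[SampleRecord] = []
        for i in range(fam.n_affected):
            sex = Sex.male if rng.uniform() < 0.5 else Sex.female
            members.append(
                SampleRecord(f"{fam.family_id}-A{i}", sex, Status.affected, fam.family_id)
            )
        for i in range(fam.n_unaffected):
            sex = Sex.male if rng.uniform() < 0.5 else Sex.female
            members.append(
                SampleRecord(f"{fam.family_id}-U{i}", sex, Status.unaffected, fam.family_id)
            )
        samples.extend(members)

        mean, dispersion = config.count_model
        for member in members:
            if mean > 0:
                p_nb = dispersion / (dispersion + mean)
                n_auto = int(rng.negative_binomial(dispersion, p_nb))
            else:
                n_auto = 0
            segments.extend(
                _background_segments(rng, background_cfg, genome, member, n_auto, 0, False)
            )
            carries = member.status is Status.affected or fam.unaffected_carry
            if not carries:
                continue
            for chrom, start, end, d in fam.shared_segments:
                jl = int(rng.integers(0, fam.jitter_bp + 1)) if fam.jitter_bp else 0
                jr = int(rng.integers(0, fam.jitter_bp + 1)) if fam.jitter_bp else 0
                s, e = start + jl, end - jr
                cn = 3 if d is Direction.gain else 1
                if genome.is_x(chrom) and member.sex is Sex.male:
                    cn = 2 if d is Direction.gain else 0
                length = e - s
                segments.append(
                    CnvSegment(
                        sample_id=member.sample_id,
                        chrom=chrom,
                        start=s,
                        end=e,
                        copy_number=cn,
                        n_markers=max(1, int(round(config.marker_density * length))),
                    )
                )
        for chrom, start, end, d in fam.shared_segments:
            key = f"{fam.family_id}:{chrom}:{start}-{end}:{d.value}"
            shared_cores[key] = (chrom, start + fam.jitter_bp, end - fam.jitter_bp)

    truth = TruthTable(
        planted_carriers={},
        theta=config.x_large_enrichment_or,
        outlier_ids=[],
        shared_cores=shared_cores,
    )
    return segments, samples, truth
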