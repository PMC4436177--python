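"""Breakpoint pseudo-marker construction and permutation case-control association.

Every start and end point of a qualifying CNV segment defines a pseudo-marker
(per chromosome and per direction, losses and gains tested separately).  A
sample carries a marker when one of its same-direction segments covers the
breakpoint position; a segment carries its own endpoints.  At each marker
the test statistic is the number of case carriers, and its permutation null
(uniform relabelings with the case count fixed) is the hypergeometric
distribution of carriers drawn into the case group.  Monte-carlo mode samples
that permutation distribution directly with a seeded generator; exhaustive
mode literally enumerates every label assignment.  The empirical p uses the
+1 correction (R+1)/(N+1), so its floor at N permutations is 1/(N+1).

Runs of consecutive significant markers with the same direction and an
identical carrier set are merged into a single locus.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    CnvSegment,
    Direction,
    GenomeModel,
    SampleRecord,
    Sex,
    Status,
    check_unique_samples,
    direction_of,
)

EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class PseudoMarker:
    chrom: str
    position: int
    direction: Direction
    carriers: frozenset[str]


@dataclass
class AssociationResult:
    chrom: str
    start: int
    end: int
    direction: Direction
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    empirical_p: float
    carrier_or: Optional[float]
    n_permutations: int
    mode: str
    carriers: frozenset[str] = frozenset()
    stratum: str = "all"


def filter_for_association(
    segments: Sequence[CnvSegment], min_markers: int = 5, min_span: int = 10_000
) -> list[CnvSegment]:
    """Keep segments with >= min_markers markers spanning >= min_span bp
    (both bounds inclusive)."""
    kept = []
    for seg in segments:
        if min_markers > 0 and seg.n_markers is None:
            raise ValueError(
                f"segment {seg.sample_id}:{seg.chrom}:{seg.start}-{seg.end} lacks n_markers, "
                "required by the marker-count filter"
            )
        if min_markers > 0 and seg.n_markers < min_markers:
            continue
        if seg.length < min_span:
            continue
        kept.append(seg)
    return kept


def build_pseudomarkers(
    segments: Sequence[CnvSegment],
    samples: Sequence[SampleRecord],
    genome: GenomeModel,
) -> list[PseudoMarker]:
    """One pseudo-marker per unique (chrom, breakpoint, direction).

    Carrier rule: a sample carries the marker iff it has a same-direction
    segment with start <= position <= end — closed containment, so a segment
    carries both of its own breakpoints (equivalent to evaluating end
    breakpoints at position - 1 on the half-open interval).
    """
    index = check_unique_samples(samples)
    by_key: dict[tuple[str, Direction], list[CnvSegment]] = {}
    for seg in segments:
        sex = index[seg.sample_id].sex
        d = direction_of(seg, sex, genome)
        if d is Direction.none:
            continue
        by_key.setdefault((seg.chrom, d), []).append(seg)

    markers: list[PseudoMarker] = []
    for (chrom, d), segs in by_key.items():
        positions = np.unique(
            np.array([s.start for s in segs] + [s.end for s in segs], dtype=np.int64)
        )
        starts = np.array([s.start for s in segs], dtype=np.int64)
        ends = np.array([s.end for s in segs], dtype=np.int64)
        sample_ids = [s.sample_id for s in segs]
        covered = (starts[:, None] <= positions[None, :]) & (positions[None, :] <= ends[:, None])
        for j, pos in enumerate(positions):
            carriers = frozenset(sample_ids[i] for i in np.nonzero(covered[:, j])[0])
            markers.append(PseudoMarker(chrom, int(pos), d, carriers))
    markers.sort(key=lambda m: (m.chrom, m.position, m.direction.value))
    return markers


def marker_seed(master_seed: int, chrom: str, position: int, direction: str) -> int:
    """Stable per-marker seed, independent of traversal order."""
    token = f"{chrom}:{position}:{direction}".encode()
    return (int(master_seed) * 2654435761 + zlib.crc32(token)) % (2**31 - 1)


def permutation_test(
    carriers: frozenset[str] | set[str],
    labels: Mapping[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
    mode: str = "monte_carlo",
) -> tuple[float, int]:
    """One-sided permutation p for an excess of case carriers.

    Returns (empirical_p, observed case carrier count).  ``monte_carlo``
    draws ``n_perm`` uniform case/control relabelings with the case count
    fixed — realized by sampling the carrier count among cases, whose
    permutation distribution is hypergeometric — and applies the +1
    correction.  ``exhaustive`` enumerates all C(n, n_cases) assignments and
    returns the exact tail fraction.
    """
    unknown = set(carriers) - set(labels)
    if unknown:
        raise ValueError(f"carriers not covered by labels: {sorted(unknown)[:5]}")
    sample_ids = sorted(labels)
    is_case = np.array([labels[s] == "case" for s in sample_ids], dtype=bool)
    is_carrier = np.array([s in carriers for s in sample_ids], dtype=bool)
    n = len(sample_ids)
    n_cases = int(is_case.sum())
    k_carriers = int(is_carrier.sum())
    t_obs = int((is_case & is_carrier).sum())

    if mode == "exhaustive":
        total = math.comb(n, n_cases)
        if total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{total} label assignments exceed the exhaustive limit {EXHAUSTIVE_LIMIT}; "
                "use monte_carlo mode"
            )
        exceed = 0
        for case_set in itertools.combinations(range(n), n_cases):
            t = int(is_carrier[list(case_set)].sum())
            if t >= t_obs:
                exceed += 1
        return exceed / total, t_obs
    if mode == "monte_carlo":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1 in monte_carlo mode")
        rng = np.random.default_rng(seed)
        t_perm = rng.hypergeometric(k_carriers, n - k_carriers, n_cases, size=n_perm)
        r = int((t_perm >= t_obs).sum())
        return (r + 1) / (n_perm + 1), t_obs
    raise ValueError(f"unknown mode {mode!r}")


def carrier_odds_ratio(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    zero_policy: str = "undefined",
) -> Optional[float]:
    """Carrier-based sample OR between cases and controls."""
    a, b = case_carriers, n_cases - case_carriers
    c, d = control_carriers, n_controls - control_carriers
    if min(a, b, c, d) < 0:
        raise ValueError("carrier counts exceed group sizes")
    if 0 in (a, b, c, d):
        if zero_policy == "undefined":
            return None
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a / b) / (c / d)


def _status_label(status: Status) -> str:
    return "case" if status.is_case_like else "control"


def _associate_subset(
    markers: Sequence[PseudoMarker],
    labels: Mapping[str, str],
    n_perm: int,
    seed: int,
    threshold: float,
    mode: str,
    stratum: str,
) -> list[AssociationResult]:
    n_cases = sum(1 for v in labels.values() if v == "case")
    n_controls = len(labels) - n_cases

    significant: list[tuple[PseudoMarker, float, int]] = []
    for m in markers:
        carriers = frozenset(c for c in m.carriers if c in labels)
        if not carriers:
            continue
        p, t_obs = permutation_test(
            carriers,
            labels,
            n_perm=n_perm,
            seed=marker_seed(seed, m.chrom, m.position, m.direction.value),
            mode=mode,
        )
        if p <= threshold:
            significant.append((PseudoMarker(m.chrom, m.position, m.direction, carriers), p, t_obs))

    # merge consecutive significant markers with identical carrier sets
    results: list[AssociationResult] = []
    significant.sort(key=lambda t: (t[0].chrom, t[0].direction.value, t[0].position))
    i = 0
    while i < len(significant):
        m0, p0, t0 = significant[i]
        j = i
        best_p = p0
        while (
            j + 1 < len(significant)
            and significant[j + 1][0].chrom == m0.chrom
            and significant[j + 1][0].direction == m0.direction
            and significant[j + 1][0].carriers == m0.carriers
        ):
            j += 1
            best_p = min(best_p, significant[j][1])
        m_last = significant[j][0]
        # locus = [first breakpoint, last breakpoint); widen a lone marker to 1 bp
        locus_end = max(m_last.position, m0.position + 1)
        case_c = t0
        control_c = len(m0.carriers) - t0
        results.append(
            AssociationResult(
                chrom=m0.chrom,
                start=m0.position,
                end=locus_end,
                direction=m0.direction,
                case_carriers=case_c,
                control_carriers=control_c,
                n_cases=n_cases,
                n_controls=n_controls,
                empirical_p=best_p,
                carrier_or=carrier_odds_ratio(case_c, n_cases, control_c, n_controls),
                n_permutations=n_perm,
                mode=mode,
                carriers=m0.carriers,
                stratum=stratum,
            )
        )
        i = j + 1
    return results


def associate(
    segments: Sequence[CnvSegment],
    samples: Sequence[SampleRecord],
    genome: GenomeModel,
    n_perm: int = 100_000,
    seed: int = 0,
    threshold: float = 5e-5,
    min_markers: int = 5,
    min_span: int = 10_000,
    sex_stratify_x: bool = True,
    mode: str = "monte_carlo",
) -> list[AssociationResult]:
    """Genome-wide pseudo-marker permutation association.

    Autosomal markers are tested in the full cohort; X-chromosome markers are
    tested separately within males and within females when
    ``sex_stratify_x``.  Only merged loci with empirical p <= ``threshold``
    are returned, sorted by (chrom, start).
    """
    index = check_unique_samples(samples)
    filtered = filter_for_association(segments, min_markers=min_markers, min_span=min_span)
    markers = build_pseudomarkers(filtered, samples, genome)

    auto_markers = [m for m in markers if genome.is_autosome(m.chrom)]
    x_markers = [m for m in markers if genome.is_x(m.chrom)]

    all_labels = {s.sample_id: _status_label(s.status) for s in samples}
    results = _associate_subset(auto_markers, all_labels, n_perm, seed, threshold, mode, "all")
    if x_markers:
        if sex_stratify_x:
            for sex in (Sex.male, Sex.female):
                labels = {
                    s.sample_id: _status_label(s.status) for s in samples if s.sex is sex
                }
                if not labels:
                    continue
                sub = [m for m in x_markers if any(index[c].sex is sex for c in m.carriers)]
                results.extend(
                    _associate_subset(sub, labels, n_perm, seed, threshold, mode, sex.value)
                )
        else:
            results.extend(
                _associate_subset(x_markers, all_labels, n_perm, seed, threshold, mode, "all")
            )
    results.sort(key=lambda r: (r.chrom, r.start, r.direction.value, r.stratum))
    return results
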