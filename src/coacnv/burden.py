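"""Size-stratified CNV burden contingency analysis.

For each stratum (autosomes, male X, female X) the segments longer than
``min_size`` are split into "small" ((min_size, large_threshold]) and
"large" (> large_threshold) bins, giving a 2x2 table of segment counts
(cases vs controls).  Evidence for an excess of large CNVs in cases is the
one-sided Fisher exact p-value (alternative: odds ratio > 1), with
Bonferroni correction across the strata tested in the run.

The reported odds ratio is the unconditional sample (cross-product) odds
ratio a*d / (b*c); zero cells flag the OR undefined unless the
Haldane-Anscombe +0.5 correction is requested.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import (
    CnvClass,
    CnvSegment,
    Direction,
    GenomeModel,
    SampleRecord,
    Sex,
    SizeBin,
    SizeBinConfig,
    check_unique_samples,
    classify_segment,
    direction_of,
    size_bin,
)


class Stratum(str, enum.Enum):
    autosomes = "autosomes"
    x_male = "x_male"
    x_female = "x_female"


_STRATUM_CLASS = {
    Stratum.autosomes: CnvClass.autosomal_cnv,
    Stratum.x_male: CnvClass.x_male_cnv,
    Stratum.x_female: CnvClass.x_female_cnv,
}


class ZeroPolicy(str, enum.Enum):
    undefined = "undefined"
    haldane = "haldane"


@dataclass(frozen=True)
class BurdenTable:
    """2x2 segment counts: (large, small) x (group1, group2)."""

    stratum: Stratum
    direction_filter: str  # "all", "loss" or "gain"
    a: int  # large, group1
    b: int  # small, group1
    c: int  # large, group2
    d: int  # small, group2
    group1: str = "cases"
    group2: str = "controls"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class BurdenResult:
    table: BurdenTable
    odds_ratio: Optional[float]
    p_value: float
    alternative: str
    alpha: float
    bonferroni_threshold: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.bonferroni_threshold


def sample_odds_ratio(
    table: BurdenTable, zero_policy: ZeroPolicy = ZeroPolicy.undefined
) -> Optional[float]:
    """Cross-product odds ratio (a/b)/(c/d); None when a zero cell makes it
    undefined and the policy is ``undefined``."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        if zero_policy is ZeroPolicy.undefined:
            return None
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a / b) / (c / d)


def fisher_exact_p(table: BurdenTable, alternative: str = "greater") -> float:
    """Exact hypergeometric tail probability for a 2x2 table with fixed margins.

    ``greater``: P(X >= a); ``less``: P(X <= a); ``two_sided``: sum of the
    point probabilities of all tables no more likely than the observed one
    (the "minlike" rule).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b  # group1 margin
    col1 = a + c  # large margin
    if alternative == "greater":
        return float(min(1.0, hypergeom.sf(a - 1, n, row1, col1)))
    if alternative == "less":
        return float(min(1.0, hypergeom.cdf(a, n, row1, col1)))
    if alternative == "two_sided":
        support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
        pmf = hypergeom.pmf(support, n, row1, col1)
        p_obs = hypergeom.pmf(a, n, row1, col1)
        # 1+1e-10 relative guard against float noise at ties
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-10)].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


def build_burden_table(
    segments: Sequence[CnvSegment],
    samples: Sequence[SampleRecord],
    stratum: Stratum,
    genome: GenomeModel,
    direction_filter: str = "all",
    bins: SizeBinConfig = SizeBinConfig(),
    groups: tuple[str, str] = ("cases", "controls"),
) -> BurdenTable:
    """Count segments (not carriers) by size bin in one stratum.

    Group membership comes from each sample's status: case-like samples
    (case/affected) form group1, control-like (control/unaffected) group2.
    Sub-threshold segments are excluded.
    """
    index = check_unique_samples(samples)
    if stratum is Stratum.x_male and not any(s.sex is Sex.male for s in samples):
        raise ValueError("x_male stratum requires at least one male sample")
    if stratum is Stratum.x_female and not any(s.sex is Sex.female for s in samples):
        raise ValueError("x_female stratum requires at least one female sample")
    want_class = _STRATUM_CLASS[stratum]
    cells = {("g1", SizeBin.small): 0, ("g1", SizeBin.large): 0,
             ("g2", SizeBin.small): 0, ("g2", SizeBin.large): 0}
    for seg in segments:
        sample = index.get(seg.sample_id)
        if sample is None:
            raise ValueError(f"segment references unknown sample {seg.sample_id!r}")
        if classify_segment(seg, sample.sex, genome) is not want_class:
            continue
        if direction_filter != "all":
            if direction_of(seg, sample.sex, genome) is not Direction(direction_filter):
                continue
        sbin = size_bin(seg, bins)
        if sbin is SizeBin.sub_threshold:
            continue
        group = "g1" if sample.status.is_case_like else "g2"
        cells[(group, sbin)] += 1
    return BurdenTable(
        stratum=stratum,
        direction_filter=direction_filter,
        a=cells[("g1", SizeBin.large)],
        b=cells[("g1", SizeBin.small)],
        c=cells[("g2", SizeBin.large)],
        d=cells[("g2", SizeBin.small)],
        group1=groups[0],
        group2=groups[1],
    )


def burden_analysis(
    segments: Sequence[CnvSegment],
    samples: Sequence[SampleRecord],
    genome: GenomeModel,
    strata: Sequence[Stratum] = (Stratum.autosomes, Stratum.x_male, Stratum.x_female),
    direction_filters: Sequence[str] = ("all",),
    alpha: float = 0.05,
    bins: SizeBinConfig = SizeBinConfig(),
    alternative: str = "greater",
    zero_policy: ZeroPolicy = ZeroPolicy.undefined,
) -> list[BurdenResult]:
    """One burden test per (stratum x direction filter), Bonferroni-corrected
    at family-wise level ``alpha`` over the tests actually run."""
    combos = [(st, df) for st in strata for df in direction_filters]
    threshold = alpha / len(combos)
    results = []
    for stratum, direction_filter in sorted(combos, key=lambda t: (t[0].value, t[1])):
        table = build_burden_table(
            segments, samples, stratum, genome, direction_filter=direction_filter, bins=bins
        )
        results.append(
            BurdenResult(
                table=table,
                odds_ratio=sample_odds_ratio(table, zero_policy),
                p_value=fisher_exact_p(table, alternative),
                alternative=alternative,
                alpha=alpha,
                bonferroni_threshold=threshold,
            )
        )
    return results


def conditional_mle_odds_ratio(table: BurdenTable) -> Optional[float]:
    """Conditional maximum-likelihood OR (noncentral hypergeometric), offered
    as an alternative to the sample OR; None for degenerate margins."""
    from scipy.stats.contingency import odds_ratio as _cor

    if (table.a + table.b == 0) or (table.c + table.d == 0):
        return None
    res = _cor([[table.a, table.b], [table.c, table.d]], kind="conditional")
    val = float(res.statistic)
    return val if math.isfinite(val) else None
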