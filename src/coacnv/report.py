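"""Report formatting: paper-style rounding and table serialization.

All report output uses 1-based inclusive coordinates; numbers use
half-away-from-zero rounding (so 56.625 prints as 56.63, not banker's
56.62), and permutation p-values print in the compact exponent style used in
locus tables (e.g. 1.0E-5).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Union


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (decimal rounding, not binary banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_or(value: Optional[float], ndigits: int = 2) -> str:
    if value is None:
        return "N/A"
    return f"{round_half_away(value, ndigits):.{ndigits}f}"


def fmt_p(p: float) -> str:
    """Compact scientific notation for small p-values (1.0E-5 style)."""
    if p >= 0.001:
        return f"{round_half_away(p, 3):g}"
    mantissa_exp = f"{p:.1E}"  # e.g. '1.0E-05'
    mantissa, exp = mantissa_exp.split("E")
    return f"{mantissa}E{int(exp)}"


def write_tsv(
    path: Union[str, Path],
    header: Sequence[str],
    rows: Sequence[Sequence],
    comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def burden_rows(results) -> list[list]:
    rows = []
    for r in results:
        t = r.table
        rows.append(
            [
                t.stratum.value,
                t.direction_filter,
                t.a,
                t.b,
                t.c,
                t.d,
                fmt_or(r.odds_ratio),
                fmt_p(r.p_value),
                f"{r.bonferroni_threshold:.4f}",
                str(r.significant).lower(),
            ]
        )
    return rows


BURDEN_HEADER = [
    "stratum", "direction", "large_group1", "small_group1", "large_group2",
    "small_group2", "odds_ratio", "p_value", "bonferroni_threshold", "significant",
]

ASSOC_HEADER = [
    "chrom", "start", "end", "direction", "stratum", "case_carriers", "n_cases",
    "control_carriers", "n_controls", "empirical_p", "odds_ratio",
]


def assoc_rows(results) -> list[list]:
    return [
        [
            r.chrom,
            r.start + 1,  # report 1-based inclusive
            r.end,
            r.direction.value,
            r.stratum,
            r.case_carriers,
            r.n_cases,
            r.control_carriers,
            r.n_controls,
            fmt_p(r.empirical_p),
            fmt_or(r.carrier_or),
        ]
        for r in results
    ]


SHARED_HEADER = [
    "chrom", "start", "length_bp", "direction", "affected_unaffected", "families", "genes",
]


def shared_rows(regions, gene_labels: Optional[dict] = None) -> list[list]:
    gene_labels = gene_labels or {}
    return [
        [
            r.chrom,
            r.start + 1,
            r.end - r.start,
            r.direction.value,
            r.count_label,
            r.families_represented,
            gene_labels.get((r.chrom, r.start, r.end), ""),
        ]
        for r in regions
    ]
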