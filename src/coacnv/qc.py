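"""Per-cohort sample exclusion by the segment-count cutoff rule.

Within each cohort the cutoff is ``median + (median - minimum)`` of the
per-sample CNV segment counts; samples with strictly more segments than the
cutoff are excluded from burden analysis.  An even-length median is the
midpoint of the central pair, so the cutoff may be non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .model import CnvSegment, SampleRecord, SizeBinConfig, check_unique_samples


@dataclass
class QcReport:
    cohort_label: str
    per_sample_counts: dict[str, int]
    median: float
    minimum: int
    cutoff: float
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort_label,
            "n_samples": len(self.per_sample_counts),
            "median": self.median,
            "minimum": self.minimum,
            "cutoff": self.cutoff,
            "excluded": sorted(self.excluded),
        }


def qc_cutoff(counts: Sequence[int]) -> float:
    """Cutoff = 2 * median(counts) - min(counts)."""
    if len(counts) == 0:
        raise ValueError("cannot compute a QC cutoff from an empty cohort")
    arr = np.asarray(counts)
    return float(2 * np.median(arr) - arr.min())


GroupKey = Union[str, Callable[[SampleRecord], str]]


def apply_qc(
    segments: Sequence[CnvSegment],
    samples: Sequence[SampleRecord],
    cohort_partition: GroupKey = "status",
    min_size: Optional[int] = None,
) -> tuple[list[SampleRecord], list[QcReport]]:
    """Single-pass QC: exclude samples with more segments than their cohort cutoff.

    The cutoff is computed independently within each cohort group (default
    grouping: phenotype status).  Counts include every segment attributed to
    a sample; pass ``min_size`` to count only segments longer than that many
    bp instead (e.g. ``SizeBinConfig().min_size``).

    Returns the retained samples (input order preserved) and one
    :class:`QcReport` per cohort, ordered by cohort label.
    """
    index = check_unique_samples(samples)
    counts = {s.sample_id: 0 for s in samples}
    for seg in segments:
        if seg.sample_id not in index:
            raise ValueError(f"segment references unknown sample {seg.sample_id!r}")
        if min_size is not None and seg.length <= min_size:
            continue
        counts[seg.sample_id] += 1

    if callable(cohort_partition):
        key = cohort_partition
    elif cohort_partition == "status":
        key = lambda s: s.status.value  # noqa: E731
    else:
        raise ValueError(f"unknown cohort partition {cohort_partition!r}")

    groups: dict[str, list[SampleRecord]] = {}
    for s in samples:
        groups.setdefault(key(s), []).append(s)

    reports: list[QcReport] = []
    excluded_ids: set[str] = set()
    for label in sorted(groups):
        members = groups[label]
        group_counts = {s.sample_id: counts[s.sample_id] for s in members}
        values = list(group_counts.values())
        cutoff = qc_cutoff(values)
        excluded = [sid for sid, c in group_counts.items() if c > cutoff]
        excluded_ids.update(excluded)
        reports.append(
            QcReport(
                cohort_label=label,
                per_sample_counts=group_counts,
                median=float(np.median(values)),
                minimum=int(min(values)),
                cutoff=cutoff,
                excluded=excluded,
            )
        )
    retained = [s for s in samples if s.sample_id not in excluded_ids]
    return retained, reports


__all__ = ["QcReport", "qc_cutoff", "apply_qc", "SizeBinConfig"]
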