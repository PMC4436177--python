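"""End-to-end orchestration: qc -> burden -> association (-> family overlap)
-> annotation, with provenance headers on every artifact."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .annotation import GeneRecord, annotate_regions, summarize_matches
from .association import associate
from .burden import burden_analysis, Stratum
from .familial import shared_regions, cross_cohort_overlap
from .io import read_genome, read_intervals, read_samples, read_segments, write_json
from .model import Direction, GenomeModel, Interval, SizeBinConfig
from .qc import apply_qc
from .report import (
    ASSOC_HEADER,
    BURDEN_HEADER,
    SHARED_HEADER,
    assoc_rows,
    burden_rows,
    shared_rows,
    write_tsv,
)

log = logging.getLogger("coacnv")


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    segments: Path
    samples: Path
    out_dir: Path
    genome: Optional[Path] = None
    genes: Optional[Path] = None
    linkage_regions: Optional[Path] = None
    seed: int = 0
    n_perm: int = 10_000
    assoc_threshold: float = 5e-5
    min_markers: int = 5
    min_span: int = 10_000
    alpha: float = 0.05
    bins: SizeBinConfig = field(default_factory=SizeBinConfig)
    min_affected: int = 2
    max_unaffected: int = 0
    annotate: bool = False
    run_association: bool = True

    def validate(self) -> None:
        for label, p in (("segments", self.segments), ("samples", self.samples)):
            if not Path(p).exists():
                raise ConfigurationError(f"{label} file not found: {p}")
        for label, p in (
            ("genome", self.genome),
            ("genes", self.genes),
            ("linkage_regions", self.linkage_regions),
        ):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{label} file not found: {p}")
        if self.annotate and self.genes is None:
            raise ConfigurationError("annotation requested but no gene list configured")

    def digest(self) -> str:
        # out_dir is where results land, not what they are
        payload = {k: str(v) for k, v in vars(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"coacnv {__version__}",
        f"seed {config.seed}",
        f"config {config.digest()}",
    ]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all configured stages; returns the map of artifact names to paths.

    Stages never mutate their inputs; each stage logs its input/output
    record counts and every artifact carries a provenance header (tool
    version, seed, config hash).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    artifacts: dict[str, Path] = {}

    genome = read_genome(config.genome) if config.genome else GenomeModel()
    segments = read_segments(config.segments)
    samples = read_samples(config.samples)
    log.info("loaded %d segments, %d samples", len(segments), len(samples))

    # -- QC ---------------------------------------------------------------
    retained, reports = apply_qc(segments, samples)
    retained_ids = {s.sample_id for s in retained}
    qc_segments = [s for s in segments if s.sample_id in retained_ids]
    log.info(
        "qc: %d/%d samples retained (%d segments in, %d retained, %d excluded)",
        len(retained), len(samples), len(segments), len(qc_segments),
        len(segments) - len(qc_segments),
    )
    qc_path = out / "qc_report.json"
    write_json({"provenance": prov, "cohorts": [r.to_dict() for r in reports]}, qc_path)
    write_tsv(
        out / "qc_report.tsv",
        ["cohort", "n_samples", "median", "minimum", "cutoff", "n_excluded", "excluded"],
        [
            [r.cohort_label, len(r.per_sample_counts), r.median, r.minimum, r.cutoff,
             len(r.excluded), ",".join(sorted(r.excluded))]
            for r in reports
        ],
        comments=prov,
    )
    artifacts["qc"] = qc_path

    # -- burden -----------------------------------------------------------
    results = burden_analysis(
        qc_segments, retained, genome, alpha=config.alpha, bins=config.bins
    )
    burden_path = out / "burden.tsv"
    write_tsv(burden_path, BURDEN_HEADER, burden_rows(results), comments=prov)
    artifacts["burden"] = burden_path
    log.info("burden: %d strata tested", len(results))

    # -- association ------------------------------------------------------
    assoc_results = []
    if config.run_association:
        assoc_results = associate(
            qc_segments,
            retained,
            genome,
            n_perm=config.n_perm,
            seed=config.seed,
            threshold=config.assoc_threshold,
            min_markers=config.min_markers,
            min_span=config.min_span,
        )
        assoc_path = out / "association.tsv"
        write_tsv(assoc_path, ASSOC_HEADER, assoc_rows(assoc_results), comments=prov)
        artifacts["association"] = assoc_path
        log.info("association: %d significant loci", len(assoc_results))

    # -- familial overlap -------------------------------------------------
    familial_samples = [s for s in retained if s.status.is_familial]
    shared = []
    if familial_samples:
        fam_segments = [
            s for s in qc_segments
            if s.sample_id in {m.sample_id for m in familial_samples}
        ]
        for direction in (Direction.loss, Direction.gain):
            shared.extend(
                shared_regions(
                    fam_segments,
                    familial_samples,
                    genome,
                    min_affected=config.min_affected,
                    direction=direction,
                    max_unaffected=config.max_unaffected,
                    min_size=config.bins.min_size,
                )
            )
        shared.sort(key=lambda r: (r.chrom, r.start))
        shared_path = out / "family_overlap.tsv"
        write_tsv(shared_path, SHARED_HEADER, shared_rows(shared), comments=prov)
        artifacts["family_overlap"] = shared_path
        log.info("family overlap: %d shared regions", len(shared))
        if assoc_results:
            overlaps = cross_cohort_overlap(assoc_results, shared)
            write_tsv(
                out / "cross_cohort_overlap.tsv",
                ["chrom", "direction", "sporadic_start", "sporadic_end",
                 "familial_start", "familial_end", "overlap_bp"],
                [
                    [o.chrom, o.direction.value, o.a_start + 1, o.a_end,
                     o.b_start + 1, o.b_end, o.overlap_bp]
                    for o in overlaps
                ],
                comments=prov,
            )
            artifacts["cross_cohort_overlap"] = out / "cross_cohort_overlap.tsv"

    # -- annotation -------------------------------------------------------
    if config.annotate:
        named = read_intervals(config.genes)
        genes = [GeneRecord(name, iv.chrom, iv.start, iv.end) for name, iv in named]
        regions = [Interval(r.chrom, r.start, r.end) for r in assoc_results]
        regions += [Interval(r.chrom, r.start, r.end) for r in shared]
        if config.linkage_regions:
            regions += [iv for _, iv in read_intervals(config.linkage_regions)]
        annotations = annotate_regions(regions, genes, mode="any_overlap")
        n_regions, n_genes = summarize_matches(annotations)
        ann_path = out / "annotation.tsv"
        write_tsv(
            ann_path,
            ["chrom", "start", "end", "genes"],
            [
                [a.region.chrom, a.region.start + 1, a.region.end,
                 ",".join(h.symbol for h in a.overlapping_genes)]
                for a in annotations
            ],
            comments=prov + [f"regions_with_genes {n_regions}", f"distinct_genes {n_genes}"],
        )
        artifacts["annotation"] = ann_path
        log.info("annotation: %d regions with genes, %d distinct genes", n_regions, n_genes)

    return artifacts
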