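"""Readers and writers for the tabular/interval formats the pipeline uses.

Dialects
--------
canonical_tsv
    Tab-separated with header ``sample_id chrom start end copy_number
    n_markers``; coordinates are 1-based inclusive on disk and converted to
    the internal 0-based half-open convention on read.
bed
    BED6+1: ``chrom start end name score strand [n_markers]`` with 0-based
    half-open coordinates, ``name`` = sample id, ``score`` = copy number,
    strand written as ``.``.

Sample sheets are TSV with header ``sample_id sex status family_id``
(family_id may be empty).  The genome model round-trips through YAML with
0-based half-open PAR intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .model import (
    CnvSegment,
    GenomeModel,
    Interval,
    SampleRecord,
    Sex,
    Status,
)

PathLike = Union[str, Path]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_number", "n_markers"]
SAMPLE_COLUMNS = ["sample_id", "sex", "status", "family_id"]


class ParseError(ValueError):
    """Malformed input row; message names the file and 1-based line number."""


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_segments(path: PathLike, dialect: str = "canonical_tsv") -> list[CnvSegment]:
    """Read CNV segments, preserving input order."""
    path = Path(path)
    if dialect not in ("canonical_tsv", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    segments: list[CnvSegment] = []
    header_seen = False
    for lineno, fields in _data_lines(path):
        if dialect == "canonical_tsv" and not header_seen:
            header_seen = True
            if fields[: len(SEGMENT_COLUMNS)] != SEGMENT_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected header {SEGMENT_COLUMNS}")
            continue
        try:
            if dialect == "canonical_tsv":
                sample_id, chrom, start, end, cn, nm = fields[:6]
                # 1-based inclusive -> 0-based half-open
                seg = CnvSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    copy_number=int(cn),
                    n_markers=None if nm in ("", ".", "NA") else int(nm),
                )
            else:
                chrom, start, end, name, score = fields[:5]
                nm = fields[6] if len(fields) > 6 else ""
                seg = CnvSegment(
                    sample_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    copy_number=int(score),
                    n_markers=None if nm in ("", ".", "NA") else int(nm),
                )
        except ParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed segment row ({exc})") from exc
        segments.append(seg)
    return segments


def write_segments(
    segments: Sequence[CnvSegment],
    path: PathLike,
    dialect: str = "canonical_tsv",
    header_comments: Sequence[str] = (),
) -> None:
    """Write segments; output is bit-stable for a fixed input ordering."""
    path = Path(path)
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        if dialect == "canonical_tsv":
            fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
            for seg in segments:
                nm = "" if seg.n_markers is None else str(seg.n_markers)
                fh.write(
                    f"{seg.sample_id}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t{seg.copy_number}\t{nm}\n"
                )
        elif dialect == "bed":
            for seg in segments:
                nm = "." if seg.n_markers is None else str(seg.n_markers)
                fh.write(
                    f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.sample_id}\t{seg.copy_number}\t.\t{nm}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_samples(path: PathLike) -> list[SampleRecord]:
    path = Path(path)
    samples: list[SampleRecord] = []
    header_seen = False
    for lineno, fields in _data_lines(path):
        if not header_seen:
            header_seen = True
            if fields[: len(SAMPLE_COLUMNS)] != SAMPLE_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected header {SAMPLE_COLUMNS}")
            continue
        try:
            sample_id, sex, status = fields[:3]
            family = fields[3] if len(fields) > 3 and fields[3] != "" else None
            samples.append(
                SampleRecord(sample_id=sample_id, sex=Sex(sex), status=Status(status), family_id=family)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed sample row ({exc})") from exc
    return samples


def write_samples(samples: Sequence[SampleRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex.value}\t{s.status.value}\t{s.family_id or ''}\n")


def read_genome(path: PathLike) -> GenomeModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    chromosomes = {str(c["name"]): int(c["length"]) for c in doc["chromosomes"]}
    pars = [
        Interval(str(p["chrom"]), int(p["start"]), int(p["end"]))
        for p in doc.get("par_intervals", [])
    ]
    return GenomeModel(
        chromosomes=chromosomes,
        par_intervals=pars,
        x_name=doc.get("x_name", "chrX"),
        y_name=doc.get("y_name", "chrY"),
    )


def write_genome(genome: GenomeModel, path: PathLike) -> None:
    doc = {
        "chromosomes": [{"name": n, "length": l} for n, l in genome.chromosomes.items()],
        "par_intervals": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in genome.par_intervals
        ],
        "x_name": genome.x_name,
        "y_name": genome.y_name,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_intervals(path: PathLike) -> list[tuple[str, Interval]]:
    """Read a BED4/TSV file of named intervals (gene lists, linkage regions).

    Columns: chrom, start (0-based), end, name.  Lines starting with ``#``
    or a ``chrom`` header are skipped.
    """
    path = Path(path)
    out: list[tuple[str, Interval]] = []
    for lineno, fields in _data_lines(path):
        if fields[0] in ("chrom", "track"):
            continue
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{fields[1]}-{fields[2]}"
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed interval row ({exc})") from exc
        out.append((name, Interval(chrom, start, end)))
    return out


def write_json(obj: object, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
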