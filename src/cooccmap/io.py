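"""Readers and writers for the plain-text formats the pipeline consumes.

BED dialects supported: bed3, bed6, narrowPeak, broadPeak. Lines starting
with ``track``, ``browser`` or ``#`` are ignored. Gene annotations travel as
a TSV with columns ``gene_id, chrom, strand, tx_start, tx_end, exon_starts,
exon_ends`` (comma-separated coordinate lists).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import GeneModel, GenomeAnnotation
from .intervals import Interval, intervals_to_frame

__all__ = [
    "BedParseError",
    "read_bed",
    "read_bed_frame",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

# minimum required column count per dialect
_DIALECTS = {"bed3": 3, "bed6": 3, "narrowPeak": 10, "broadPeak": 9}


class BedParseError(ValueError):
    """Raised on a malformed BED record, carrying the offending line number."""


def _skip(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("track", "browser", "#"))


def _parse_bed_line(fields: list[str], dialect: str, lineno: int) -> Interval:
    if len(fields) < _DIALECTS[dialect]:
        raise BedParseError(
            f"line {lineno}: expected >= {_DIALECTS[dialect]} fields for "
            f"{dialect}, got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = score = strand = None
    if dialect != "bed3" and len(fields) > 3:
        name = fields[3] if fields[3] != "." else None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-numeric score") from exc
        if len(fields) > 5 and fields[5] != ".":
            strand = fields[5]
    try:
        return Interval(chrom, start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path: str | Path, dialect: str = "bed6") -> list[Interval]:
    """Read a BED-family file into a list of :class:`Interval`, order preserved."""
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _skip(line):
                continue
            out.append(_parse_bed_line(line.rstrip("\n").split("\t"), dialect, lineno))
    return out


def read_bed_frame(path: str | Path) -> pd.DataFrame:
    """Read only chrom/start/end of a BED file into a DataFrame (fast path
    for fragment libraries with millions of records)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str},
    )
    bad = frame.index[frame["end"] <= frame["start"]]
    if len(bad):
        raise BedParseError(f"line {bad[0] + 1}: end must exceed start")
    return frame


def write_bed(intervals, path: str | Path) -> None:
    """Write intervals (list of Interval or chrom/start/end DataFrame) as BED.

    Optional name/score/strand fields are emitted when present on any record
    (missing values become ``.``).
    """
    if isinstance(intervals, pd.DataFrame):
        intervals.to_csv(path, sep="\t", header=False, index=False)
        return
    has_extra = any(
        iv.name is not None or iv.score is not None or iv.strand is not None
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if has_extra:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "exon_starts",
    "exon_ends",
]


def _parse_coord_list(text: str) -> list[int]:
    text = str(text).strip().strip(",")
    if not text or text == "nan":
        return []
    return [int(x) for x in text.split(",")]


def read_gene_table(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> GenomeAnnotation:
    """Read a gene-annotation TSV into a :class:`GenomeAnnotation`."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    genes: list[GeneModel] = []
    for row in table.itertuples(index=False):
        starts = _parse_coord_list(row.exon_starts)
        ends = _parse_coord_list(row.exon_ends)
        if len(starts) != len(ends):
            raise ValueError(f"gene {row.gene_id}: exon list length mismatch")
        exons = [Interval(row.chrom, s, e) for s, e in zip(starts, ends)]
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                exons=exons,
            )
        )
    return GenomeAnnotation(genes=genes, chrom_sizes=dict(chrom_sizes or {}))


def write_gene_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for g in annotation.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if _skip(line):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
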