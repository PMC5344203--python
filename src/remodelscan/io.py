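"""Readers and writers for the tag-level formats the pipeline touches.

All intervals are 0-based half-open throughout the package; the only
coordinate conversions happen here, at file boundaries.  Tags are aligned
single-end reads reduced to (chrom, 5' position, strand); BED6 is the
on-disk representation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "pos5", "strand"]

#: Read length assumed when writing tags back to BED (MNase geometry).
TAG_BED_LENGTH = 147


class FormatError(ValueError):
    """A file violated the expected column/coordinate conventions."""


class ValidationError(ValueError):
    """An in-memory table violated an invariant (duplicate ids, overlap...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_tags(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read a 6-column BED file of aligned tags.

    Returns a DataFrame with columns (chrom, pos5, strand) and the number
    of malformed lines that were skipped.  ``pos5`` is the 0-based position
    of the 5' end: BED ``start`` for + strand tags, ``end - 1`` for -.
    """
    chroms: list[str] = []
    pos5s: list[int] = []
    strands: list[str] = []
    n_malformed = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                n_malformed += 1
                continue
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"missing/invalid strand column: {line!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                n_malformed += 1
                continue
            if start < 0 or end <= start:
                raise FormatError(f"negative or inverted coordinates: {line!r}")
            chroms.append(chrom)
            pos5s.append(start if strand == "+" else end - 1)
            strands.append(strand)
    tags = pd.DataFrame(
        {
            "chrom": pd.array(chroms, dtype="str"),
            "pos5": np.asarray(pos5s, dtype=np.int64),
            "strand": pd.array(strands, dtype="str"),
        }
    )
    return tags, n_malformed


def write_tags(tags: pd.DataFrame, path: str | Path, read_length: int = TAG_BED_LENGTH) -> None:
    """Write tags as BED6; inverse of :func:`read_tags` for valid tag sets."""
    with open(path, "w") as fh:
        for i, (chrom, pos5, strand) in enumerate(
            zip(tags["chrom"], tags["pos5"], tags["strand"])
        ):
            if strand == "+":
                start, end = pos5, pos5 + read_length
            else:
                start, end = pos5 - read_length + 1, pos5 + 1
            fh.write(f"{chrom}\t{start}\t{end}\tt{i}\t0\t{strand}\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene table (TSV: gene_id, chrom, strand, tss; extra columns kept).

    TSS coordinates are 0-based.  Duplicate gene ids are rejected; rows come
    back sorted by (chrom, tss).
    """
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(genes.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError("strand column must be '+' or '-'")
    return genes.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)


def write_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def promoter_interval(tss: int, half_width: int = 1000) -> tuple[int, int]:
    """Promoter window around a TSS: [tss - hw, tss + hw), strand-symmetric."""
    return max(0, tss - half_width), tss + half_width


def write_bedgraph(
    bins: Iterable[tuple[str, int, int, float]], path: str | Path, precision: int = 6
) -> None:
    """Write per-bin values as bedGraph, merging adjacent equal-valued bins.

    Bins must be sorted and non-overlapping within each chromosome.
    """
    out = _io.StringIO()
    prev: list | None = None  # [chrom, start, end, formatted value]
    last_end: dict[str, int] = {}
    for chrom, start, end, value in bins:
        if start >= end:
            raise ValidationError(f"empty bin {chrom}:{start}-{end}")
        if start < last_end.get(chrom, 0):
            raise ValidationError(
                f"overlapping or unsorted bins at {chrom}:{start}-{end}"
            )
        last_end[chrom] = end
        text = f"{value:.{precision}g}"
        if prev is not None and prev[0] == chrom and prev[2] == start and prev[3] == text:
            prev[2] = end
        else:
            if prev is not None:
                out.write("{}\t{}\t{}\t{}\n".format(*prev))
            prev = [chrom, start, end, text]
    if prev is not None:
        out.write("{}\t{}\t{}\t{}\n".format(*prev))
    Path(path).write_text(out.getvalue())


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    track = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return track


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression table: gene_id plus one FPKM column per cell state."""
    expr = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in expr.columns:
        raise FormatError("expression table requires a gene_id column")
    if expr["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene ids in expression table")
    return expr


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
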