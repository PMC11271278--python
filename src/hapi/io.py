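"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalized to a single internal convention: 0-based,
half-open ``[start, end)``.  BEDPE/BED inputs are already in that convention
and pass through unshifted; SEG input (1-based inclusive) is shifted on read.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

from hapi import __version__

__all__ = [
    "GenomicInterval",
    "Loop",
    "TSSRecord",
    "CNSegment",
    "ValidPair",
    "BedpeDialect",
    "TssColumns",
    "ParseError",
    "DialectError",
    "SegmentOverlapError",
    "read_loops",
    "write_loops",
    "read_tss",
    "write_tss",
    "read_bed",
    "read_cn_segments",
    "read_valid_pairs",
    "write_bedgraph",
    "read_bedgraph",
    "header_comment",
]


class ParseError(ValueError):
    """A malformed line in an input file (carries path and line number)."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class DialectError(ValueError):
    """The column layout of a file does not match the configured dialect."""


class SegmentOverlapError(ValueError):
    """Overlapping copy-number segments within one sample/chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True on >= 1 bp overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Loop:
    """A pair of genomic anchors with a supporting PET count.

    Anchors are canonically ordered (anchor1 <= anchor2 by chrom, start,
    end) at construction time, so building a Loop from swapped anchors
    yields an identical object.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pets: int

    def __post_init__(self) -> None:
        if self.pets < 1:
            raise ValueError(f"pets must be >= 1, got {self.pets}")
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)

    @property
    def is_trans(self) -> bool:
        return self.anchor1.chrom != self.anchor2.chrom

    @property
    def span(self) -> float:
        """Distance between anchor midpoints (cis loops only)."""
        if self.is_trans:
            raise ValueError("span undefined for inter-chromosomal loops")
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)


@dataclass(frozen=True, order=True)
class TSSRecord:
    gene: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS position for {self.gene}: {self.tss}")


@dataclass(frozen=True)
class CNSegment:
    chrom: str
    start: int
    end: int
    log2cn: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start >= end: {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class ValidPair:
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("valid-pair positions must be >= 0")


@dataclass(frozen=True)
class BedpeDialect:
    """Column layout of a BEDPE loop file.

    pet_column is 0-based; None selects column 6 for 7-column files and
    column 7 otherwise (loop callers commonly insert a name column before
    the PET count).
    """

    pet_column: int | None = None
    add_chr_prefix: bool = False


@dataclass(frozen=True)
class TssColumns:
    """0-based column indices of a TSS annotation table."""

    gene: int = 0
    chrom: int = 1
    tss: int = 2
    strand: int = 3
    add_chr_prefix: bool = False


def _chrom(name: str, add_prefix: bool) -> str:
    if add_prefix and not name.startswith("chr"):
        return "chr" + name
    return name


def header_comment(**params) -> str:
    """Standard writer header: tool version plus effective parameters."""
    extra = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# hapi v{__version__}" + (f" {extra}" if extra else "")


def _data_lines(handle: TextIO) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#") or line.startswith("track"):
            continue
        yield lineno, line.split("\t")


def _int_field(path, lineno: int, value: str, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {value!r}") from None


def read_loops(path: str | Path, dialect: BedpeDialect | None = None) -> list[Loop]:
    """Read a BEDPE loop file into canonically ordered :class:`Loop` objects.

    No filtering happens here: every data row yields exactly one loop.
    """
    dialect = dialect or BedpeDialect()
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 7:
                raise ParseError(path, lineno, f"expected >= 7 columns, got {len(fields)}")
            if dialect.pet_column is not None:
                pet_col = dialect.pet_column
            else:
                pet_col = 6 if len(fields) == 7 else 7
            if pet_col >= len(fields):
                raise DialectError(
                    f"{path}: PET column {pet_col} out of range (row has {len(fields)} columns)"
                )
            coords = [_int_field(path, lineno, fields[i], "coordinate") for i in (1, 2, 4, 5)]
            pets = _int_field(path, lineno, fields[pet_col], "PET count")
            try:
                a1 = GenomicInterval(_chrom(fields[0], dialect.add_chr_prefix), coords[0], coords[1])
                a2 = GenomicInterval(_chrom(fields[3], dialect.add_chr_prefix), coords[2], coords[3])
                loops.append(Loop(a1, a2, pets))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return loops


def write_loops(loops: Iterable[Loop], path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(format="bedpe", **params) + "\n")
        for lp in loops:
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t{lp.pets}\n"
            )


def read_tss(path: str | Path, columns: TssColumns | None = None) -> list[TSSRecord]:
    """Read a TSS table; duplicate (gene, chrom, tss) rows collapse to one."""
    columns = columns or TssColumns()
    needed = max(columns.gene, columns.chrom, columns.tss, columns.strand) + 1
    seen: dict[tuple[str, str, int], TSSRecord] = {}
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < needed:
                raise ParseError(path, lineno, f"expected >= {needed} columns, got {len(fields)}")
            tss = _int_field(path, lineno, fields[columns.tss], "TSS position")
            try:
                rec = TSSRecord(
                    gene=fields[columns.gene],
                    chrom=_chrom(fields[columns.chrom], columns.add_chr_prefix),
                    tss=tss,
                    strand=fields[columns.strand],
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            seen.setdefault((rec.gene, rec.chrom, rec.tss), rec)
    return list(seen.values())


def write_tss(records: Iterable[TSSRecord], path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(format="tss", **params) + "\n")
        for rec in records:
            fh.write(f"{rec.gene}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")


def read_bed(path: str | Path, add_chr_prefix: bool = False) -> list[GenomicInterval]:
    """Read a 3+ column BED file (e.g. a blacklist) into intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
            start = _int_field(path, lineno, fields[1], "start")
            end = _int_field(path, lineno, fields[2], "end")
            try:
                out.append(GenomicInterval(_chrom(fields[0], add_chr_prefix), start, end))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(format="bed", **params) + "\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_cn_segments(path: str | Path) -> dict[str, list[CNSegment]]:
    """Read a SEG file (sample, chrom, start, end, num-probes, seg-mean).

    SEG coordinates are 1-based inclusive; starts are shifted to the
    internal 0-based half-open convention.  Returns segments grouped per
    sample.  Overlapping segments within one sample and chromosome are an
    input error.
    """
    per_sample: dict[str, list[CNSegment]] = {}
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected >= 6 columns, got {len(fields)}")
            if lineno == 1 and not fields[2].lstrip("-").isdigit():
                continue  # header row of a standard SEG export
            start = _int_field(path, lineno, fields[2], "start")
            end = _int_field(path, lineno, fields[3], "end")
            try:
                log2cn = float(fields[5])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric seg-mean: {fields[5]!r}") from None
            try:
                seg = CNSegment(chrom=fields[1], start=start - 1, end=end, log2cn=log2cn)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            per_sample.setdefault(fields[0], []).append(seg)

    for sample, segs in per_sample.items():
        segs.sort(key=lambda s: (s.chrom, s.start))
        offenders = [
            (a, b)
            for a, b in zip(segs, segs[1:])
            if a.chrom == b.chrom and b.start < a.end
        ]
        if offenders:
            detail = "; ".join(f"{a} overlaps {b}" for a, b in offenders)
            raise SegmentOverlapError(f"sample {sample}: overlapping segments: {detail}")
    return per_sample


def read_valid_pairs(path: str | Path) -> Iterator[ValidPair]:
    """Stream a HiC-Pro validPairs file (readID, chr1, pos1, strand1, chr2, pos2, strand2, ...)."""
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 7:
                raise ParseError(path, lineno, f"truncated line: {len(fields)} fields, need >= 7")
            pos1 = _int_field(path, lineno, fields[2], "pos1")
            pos2 = _int_field(path, lineno, fields[5], "pos2")
            try:
                yield ValidPair(fields[1], pos1, fields[4], pos2)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None


def write_bedgraph(track, path: str | Path, **params) -> None:
    """Write a binned track as 4-column bedgraph; zero-valued bins are omitted."""
    keys = sorted(track.bins)
    prev = None
    for key in keys:
        if prev is not None and key[0] == prev[0] and key[1] < prev[1]:
            raise RuntimeError("track bins are not sorted")  # defensive; sorted() above
        prev = key
    with open(path, "w") as fh:
        fh.write(
            header_comment(
                format="bedgraph",
                bin_width=track.bin_width,
                scaled=track.scaled,
                total_pairs=track.total_pairs,
                **params,
            )
            + "\n"
        )
        for chrom, start in keys:
            value = track.bins[(chrom, start)]
            if value == 0:
                continue
            out = repr(float(value)) if track.scaled else str(int(value))
            fh.write(f"{chrom}\t{start}\t{start + track.bin_width}\t{out}\n")


def read_bedgraph(path: str | Path) -> dict[tuple[str, int], float]:
    """Read bedgraph data lines into a (chrom, start) -> value map."""
    bins: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            start = _int_field(path, lineno, fields[1], "start")
            bins[(fields[0], start)] = float(fields[3])
    return bins


def replace(obj, **changes):
    """Convenience re-export of :func:`dataclasses.replace`."""
    return dataclasses.replace(obj, **changes)
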