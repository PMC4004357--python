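"""Streaming readers and writers for the formats the caller touches.

FASTA and FASTQ parsing is delegated to Biopython's low-level iterators
(`SimpleFastaParser`, `FastqGeneralIterator`); this module adds gzip
autodetection, uppercasing, id bookkeeping and error messages that carry the
offending file and approximate line.  Readers are generators and never hold
more than one record in memory, so arbitrarily large read sets stream
through in O(1) space.

Also defined here are the two tool-specific outputs: the TSD-sorted
multi-FASTA of representative junction flanks produced by the reference-free
algorithm, and the tab-separated insertion-call table (1-based inclusive
coordinates) produced by the reference-guided one.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import TifError

CALLS_COLUMNS = [
    "chrom", "tail_junction", "head_junction", "tsd_size", "tsd_seq",
    "direction", "head_support", "tail_support",
]


class ParseError(TifError):
    """Malformed input file."""


@dataclass(frozen=True, slots=True)
class SeqRecord:
    """A named DNA sequence with optional per-base quality."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise TifError(f"record {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise TifError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path) -> IO[str]:
    # gzip detected by magic bytes, not extension
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped) FASTQ file.

    Yields records in file order with sequences uppercased.  Malformed
    records (missing ``@``, seq/qual length mismatch, truncation) raise
    :class:`ParseError` naming the file and the approximate line.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        n = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(
                    f"{os.fspath(path)}: bad FASTQ record near line "
                    f"{4 * n + 1}: {exc}") from exc
            yield SeqRecord(id=title.split()[0], seq=seq.upper(), qual=qual)
            n += 1


def read_fasta(path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped, possibly wrapped) FASTA file.

    Line-wrapped sequences are concatenated and uppercased.  An empty file
    or a duplicated identifier raises :class:`ParseError`.
    """
    seen: set[str] = set()
    n = 0
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else ""
            if not rid:
                raise ParseError(f"{os.fspath(path)}: record {n + 1} has an "
                                 "empty identifier")
            if rid in seen:
                raise ParseError(
                    f"{os.fspath(path)}: duplicate record id {rid!r}")
            seen.add(rid)
            n += 1
            yield SeqRecord(id=rid, seq=seq.upper())
    if n == 0:
        raise ParseError(f"{os.fspath(path)}: no FASTA records found")


def _open_write(path) -> IO[str]:
    if os.fspath(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "wb"), encoding="ascii")
    return open(path, "wt", encoding="ascii")


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    """Write records as 4-line FASTQ (``I`` qualities when absent)."""
    with _open_write(path) as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def write_group_fasta(groups, path) -> None:
    """Write representative flanks of TSD groups as a sorted multi-FASTA.

    Groups are emitted in lexicographic TSD order, two records per group
    with headers ``{TSD}_head`` and ``{TSD}_tail``; the free-text
    description carries the flank length and the read support of that side.
    The file is valid FASTA, directly usable as BLAST query input.
    """
    records = []
    for g in sorted(groups, key=lambda g: g.tsd):
        if g.rep_head is None or g.rep_tail is None:
            raise TifError(
                f"TSD group {g.tsd!r} is missing a representative on one "
                "side; only two-sided groups may be written")
        for side, rep, support in (
            ("head", g.rep_head, len(g.head_flanks)),
            ("tail", g.rep_tail, len(g.tail_flanks)),
        ):
            records.append(SeqRecord(
                id=f"{g.tsd}_{side} flank_len={rep.flank_len} "
                   f"support={support}",
                seq=rep.flank,
            ))
    # ids carry a description after a space; write manually to keep it
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_calls_tsv(calls, path) -> None:
    """Write insertion calls as a TSV with 1-based inclusive coordinates.

    Columns: chrom, tail_junction, head_junction, tsd_size, tsd_seq,
    direction, head_support, tail_support; rows sorted by
    (chrom, min(tail, head)).  An empty call list yields a header-only file.
    """
    rows = sorted(calls, key=lambda c: (c.chrom, min(c.tail_pos, c.head_pos)))
    with _open_write(path) as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in rows:
            fh.write("\t".join(map(str, (
                c.chrom, c.tail_pos, c.head_pos, c.tsd_len, c.tsd_seq,
                c.direction, c.head_support, c.tail_support))) + "\n")


def read_calls_tsv(path) -> list:
    """Read a call table written by :func:`write_calls_tsv`."""
    from .extended import InsertionCall  # local import: avoids cycle

    calls = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALLS_COLUMNS:
            raise ParseError(f"{os.fspath(path)}: unexpected call-table "
                             f"header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(CALLS_COLUMNS):
                raise ParseError(f"{os.fspath(path)}: line {lineno} has "
                                 f"{len(fields)} fields")
            calls.append(InsertionCall(
                chrom=fields[0],
                tail_pos=int(fields[1]),
                head_pos=int(fields[2]),
                tsd_len=int(fields[3]),
                tsd_seq=fields[4],
                direction=fields[5],
                head_support=int(fields[6]),
                tail_support=int(fields[7]),
            ))
    return calls
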