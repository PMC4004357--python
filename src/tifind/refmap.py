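"""Exact, unique placement of junction flanks on a reference genome.

A seeded exact matcher stands in for a general-purpose aligner: the
reference is indexed by its plus-strand k-mers (seed length 13 by default)
and a flank is placed only when its full length matches exactly, on either
strand, at exactly one genomic location.  Ambiguous (multi-mapped) and
unmatched flanks are rejected with a reason rather than rescued — the
deterministic contract deliberately trades a little sensitivity near
repeats for reproducible calls, and insertions inside perfect repeats are
out of reach by construction.

The junction coordinate reported is the reference base adjacent to the
element, always in plus-strand coordinates: for a head flank the last flank
base, for a tail flank the first, mirrored when the flank matches the minus
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import HEAD, TAIL, TifError, revcomp
from .scan import FlankRecord
from .seqio import SeqRecord, read_fasta

DEFAULT_SEED_LEN = 13


class RefIndex:
    """Seed-and-verify exact substring index over a reference genome.

    Stores every plus-strand seed k-mer position; queries are verified
    against the sequence store by direct comparison, on both strands.
    Deterministic for fixed input.
    """

    def __init__(self, chroms: Mapping[str, str],
                 seed_len: int = DEFAULT_SEED_LEN) -> None:
        if not chroms:
            raise TifError("reference contains no sequences")
        if seed_len < 4:
            raise TifError(f"seed_len must be >= 4, got {seed_len}")
        self.chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            if name in self.chroms:
                raise TifError(f"duplicate chromosome name {name!r}")
            self.chroms[name] = seq.upper()
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.chroms.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i:i + seed_len]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((name, i))

    @classmethod
    def from_records(cls, records: Iterable[SeqRecord],
                     seed_len: int = DEFAULT_SEED_LEN) -> "RefIndex":
        chroms: dict[str, str] = {}
        for rec in records:
            if rec.id in chroms:
                raise TifError(f"duplicate chromosome name {rec.id!r}")
            chroms[rec.id] = rec.seq
        return cls(chroms, seed_len=seed_len)

    @classmethod
    def from_fasta(cls, path,
                   seed_len: int = DEFAULT_SEED_LEN) -> "RefIndex":
        return cls.from_records(read_fasta(path), seed_len=seed_len)

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        """Plus-strand start positions (0-based) of an exact occurrence."""
        if len(query) < self.seed_len:
            hits = []
            for name, seq in self.chroms.items():
                i = seq.find(query)
                while i != -1:
                    hits.append((name, i))
                    i = seq.find(query, i + 1)
            return hits
        hits = []
        for name, pos in self._seeds.get(query[:self.seed_len], ()):
            if self.chroms[name].startswith(query, pos):
                hits.append((name, pos))
        return hits

    def find_exact(self, query: str) -> list[tuple[str, int, str]]:
        """All exact full-length matches as (chrom, start0, strand).

        A minus-strand match at (chrom, i) means the reverse complement of
        ``query`` occupies plus-strand interval ``[i, i+len)``.
        """
        matches = [(c, i, "+") for c, i in self._occurrences(query)]
        rc = revcomp(query)
        if rc != query:  # avoid double-counting palindromic queries
            matches += [(c, i, "-") for c, i in self._occurrences(rc)]
        return matches


@dataclass(frozen=True, slots=True)
class MappedJunction:
    """A uniquely placed flank, reduced to its junction coordinate."""

    chrom: str
    pos: int  # 1-based, plus strand: flank base adjacent to the element
    side: str  # HEAD or TAIL
    ref_strand: str  # "+" or "-"
    read_id: str
    flank_len: int

    def interval(self) -> tuple[int, int]:
        """1-based inclusive plus-strand interval covered by the flank."""
        if (self.side, self.ref_strand) in ((HEAD, "+"), (TAIL, "-")):
            return self.pos - self.flank_len + 1, self.pos
        return self.pos, self.pos + self.flank_len - 1


UNMAPPED = "unmapped"
MULTI_MAPPED = "multi-mapped"
TOO_SHORT = "too-short"


@dataclass(frozen=True, slots=True)
class MapOutcome:
    junction: MappedJunction | None
    reason: str | None  # set iff junction is None


def map_flank(flank: FlankRecord, index: RefIndex,
              min_flank: int = 20) -> MapOutcome:
    """Place one flank; succeed only on an exact, genome-wide-unique match.

    Junction coordinate: head flank on + → interval end; tail on + →
    interval start; mirrored for minus-strand matches, always reported in
    plus-strand coordinates.
    """
    if flank.flank_len < min_flank:
        return MapOutcome(None, TOO_SHORT)
    matches = index.find_exact(flank.flank)
    if not matches:
        return MapOutcome(None, UNMAPPED)
    if len(matches) > 1:
        return MapOutcome(None, MULTI_MAPPED)
    chrom, start0, strand = matches[0]
    a, b = start0 + 1, start0 + flank.flank_len  # 1-based inclusive
    if (flank.side, strand) in ((HEAD, "+"), (TAIL, "-")):
        pos = b
    else:
        pos = a
    return MapOutcome(
        MappedJunction(chrom=chrom, pos=pos, side=flank.side,
                       ref_strand=strand, read_id=flank.read_id,
                       flank_len=flank.flank_len),
        None,
    )
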