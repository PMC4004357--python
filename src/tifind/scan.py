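"""Signature scanning: find reads crossing a TE junction, extract the flank.

Step one of both calling algorithms.  Each read and its reverse complement
are searched for exact occurrences of the element's head and tail
signatures.  A head hit at offset ``p`` means the read runs genomic flank →
element 5' end, so the flank is everything before ``p`` and its suffix is
the putative TSD.  A tail hit means element 3' end → genomic flank, so the
flank is everything after the hit and its prefix is the putative TSD.

Matching is exact by design: a single substitution in a terminal signature
makes the read invisible, which is the method's documented sensitivity
limitation, traded for zero false signature hits.  Scanning the reverse
complement makes the search strand-agnostic; flanks recovered from the
reverse-complement pass are plus-strand with respect to the sequenced
molecule, though for a reverse-oriented element copy they still read as the
minus strand of the reference (reference placement resolves that later).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from .core import HEAD, TAIL, TESignature, TIFParams, TifError, revcomp
from .seqio import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class FlankRecord:
    """Genomic flank of one junction-bearing read.

    ``side`` says which element end was matched; ``detected_on`` whether the
    match was found on the read as sequenced or on its reverse complement.
    A head flank ends at the element 5' junction (suffix = putative TSD);
    a tail flank starts at the element 3' junction (prefix = putative TSD).
    """

    read_id: str
    side: str  # HEAD or TAIL
    detected_on: str  # "read" or "revcomp"
    flank: str

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL):
            raise TifError(f"invalid side {self.side!r}")
        if not self.flank:
            raise TifError("empty flank")

    @property
    def flank_len(self) -> int:
        return len(self.flank)


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_read(read: SeqRecord, sig: TESignature) -> list[FlankRecord]:
    """All junction flanks recoverable from one read.

    Both the read and its reverse complement are scanned with forward-strand
    rules; every signature occurrence yields one record (a read carrying
    both signatures yields both).  Empty flanks — signature flush with the
    read end — are dropped.  Reads without a signature yield ``[]``.
    """
    out: list[FlankRecord] = []
    k = sig.k
    for origin, seq in (("read", read.seq), ("revcomp", revcomp(read.seq))):
        for p in _find_all(seq, sig.head):
            if p > 0:
                out.append(FlankRecord(read.id, HEAD, origin, seq[:p]))
        for p in _find_all(seq, sig.tail):
            flank = seq[p + k:]
            if flank:
                out.append(FlankRecord(read.id, TAIL, origin, flank))
    return out


@dataclass
class ScanResult:
    """Flanks surviving the length filter, plus per-side match counts."""

    flanks: list[FlankRecord]
    n_reads: int
    n_head: int
    n_tail: int

    def __iter__(self):
        return iter(self.flanks)

    def __len__(self) -> int:
        return len(self.flanks)


def scan_stream(
    reads: Iterable[SeqRecord],
    sig: TESignature,
    params: TIFParams,
    mode: str = "basic",
) -> ScanResult:
    """Scan a read stream and keep flanks long enough for the chosen mode.

    Basic mode keeps flanks of at least ``params.effective_min_flank_basic``
    bp (default: the TSD length, so every kept flank contains a full TSD);
    extended mode keeps flanks of at least ``params.min_flank_map`` bp,
    long enough for specific reference placement.  Duplicate reads are not
    collapsed, so downstream support counts reflect raw read evidence.
    """
    if mode == "basic":
        min_len = params.effective_min_flank_basic
    elif mode == "extended":
        min_len = params.min_flank_map
    else:
        raise TifError(f"unknown scan mode {mode!r}")
    kept: list[FlankRecord] = []
    n_reads = n_head = n_tail = 0
    for read in reads:
        n_reads += 1
        for rec in scan_read(read, sig):
            if rec.side == HEAD:
                n_head += 1
            else:
                n_tail += 1
            if rec.flank_len >= min_len:
                kept.append(rec)
    logger.info(
        "scanned %d reads: %d head hits, %d tail hits, %d flanks >= %d bp",
        n_reads, n_head, n_tail, len(kept), min_len)
    return ScanResult(flanks=kept, n_reads=n_reads, n_head=n_head,
                      n_tail=n_tail)
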