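"""Reference-guided insertion calling by junction pairing and TSD check.

Algorithm: flanks from the signature scan are placed on the reference
(:mod:`tifind.refmap`), reads witnessing the same junction are collapsed
into clusters, and head/tail cluster pairs lying within a strict 10-bp
window on one chromosome are candidate insertion sites.  Each candidate is
verified by demanding that the head representative's junction-adjacent
bases, the tail representative's, and the reference substring spanned by
the two junctions are one and the same string — the TSD.  The TSD length
therefore never has to be supplied; it is read off the junction geometry,
and the element's orientation follows from which junction lies left.

Verification makes mis-assignment by TSD-string coincidence (the failure
mode of the reference-free algorithm) impossible: two insertions sharing a
TSD string still sit at different loci and yield two calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import (FORWARD, HEAD, REVERSE, TAIL, TESignature, TIFParams,
                   TifError, revcomp, tsd_from_junctions)
from .refmap import MappedJunction, RefIndex, map_flank
from .scan import FlankRecord, scan_stream
from .seqio import SeqRecord, write_calls_tsv


@dataclass(frozen=True, slots=True)
class InsertionCall:
    """One called insertion site (1-based inclusive coordinates).

    ``tail_pos``/``head_pos`` are the reference bases adjacent to the
    element tail and head; the duplicated site spans
    ``[min..max]`` of the two and ``tsd_seq`` is that plus-strand reference
    substring.  ``direction`` is forward when the head junction lies right
    of the tail junction.
    """

    chrom: str
    tail_pos: int
    head_pos: int
    tsd_len: int
    tsd_seq: str
    direction: str
    head_support: int
    tail_support: int

    def validate(self) -> None:
        exp_len, exp_dir = tsd_from_junctions(self.tail_pos, self.head_pos)
        if self.tsd_len != exp_len:
            raise TifError(f"{self}: tsd_len {self.tsd_len} != |head-tail|+1 "
                           f"= {exp_len}")
        if len(self.tsd_seq) != self.tsd_len:
            raise TifError(f"{self}: tsd_seq length != tsd_len")
        if self.direction != exp_dir:
            raise TifError(f"{self}: direction {self.direction!r} "
                           f"inconsistent with junction order")
        if self.head_support < 1 or self.tail_support < 1:
            raise TifError(f"{self}: support must be >= 1 on both sides")

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tail_pos, self.head_pos),
                max(self.tail_pos, self.head_pos))


@dataclass
class JunctionCluster:
    """All reads witnessing one (chrom, side, pos) junction."""

    chrom: str
    side: str
    pos: int
    members: list[tuple[FlankRecord, MappedJunction]]

    @property
    def support(self) -> int:
        return len(self.members)

    def representative(self) -> tuple[FlankRecord, MappedJunction]:
        """Longest member flank; ties broken by smallest read id."""
        return min(self.members,
                   key=lambda m: (-m[0].flank_len, m[0].read_id))


@dataclass(frozen=True, slots=True)
class Rejection:
    """A candidate junction pair that failed TSD verification."""

    chrom: str
    tail_pos: int
    head_pos: int
    reason: str


def cluster_junctions(
    mapped: Iterable[tuple[FlankRecord, MappedJunction]],
) -> list[JunctionCluster]:
    """Collapse identically placed junctions; support = read count."""
    buckets: dict[tuple[str, str, int], list] = {}
    for flank, mj in mapped:
        buckets.setdefault((mj.chrom, mj.side, mj.pos), []).append((flank, mj))
    return [JunctionCluster(chrom=c, side=s, pos=p, members=ms)
            for (c, s, p), ms in sorted(buckets.items())]


def pair_junctions(
    clusters: Iterable[JunctionCluster],
    params: TIFParams,
) -> list[tuple[JunctionCluster, JunctionCluster]]:
    """All (head, tail) cluster pairs closer than the window on one chrom.

    The window is strict (< ``params.pair_window``); a cluster may appear
    in several candidates at this stage — verification disambiguates.
    """
    heads = [c for c in clusters if c.side == HEAD]
    tails = [c for c in clusters if c.side == TAIL]
    pairs = []
    for h in heads:
        for t in tails:
            if h.chrom == t.chrom and abs(h.pos - t.pos) < params.pair_window:
                pairs.append((h, t))
    return pairs


def _junction_adjacent_bases(member: tuple[FlankRecord, MappedJunction],
                             lo: int, hi: int) -> str | None:
    """Plus-strand bases of a flank over span [lo..hi], or None if outside."""
    flank, mj = member
    a, b = mj.interval()
    if not (a <= lo and hi <= b):
        return None
    plus = flank.flank if mj.ref_strand == "+" else revcomp(flank.flank)
    return plus[lo - a:hi - a + 1]


def verify_tsd(
    pair: tuple[JunctionCluster, JunctionCluster],
    reference: Mapping[str, str],
) -> InsertionCall | Rejection:
    """Check a candidate pair for a genuine target site duplication.

    The span between the two junctions (inclusive) must read identically in
    the head representative, the tail representative and the reference;
    on success the call carries that substring as the TSD.
    """
    head_c, tail_c = pair
    lo = min(head_c.pos, tail_c.pos)
    hi = max(head_c.pos, tail_c.pos)
    ref_tsd = reference[head_c.chrom][lo - 1:hi]
    for cluster in (head_c, tail_c):
        sub = _junction_adjacent_bases(cluster.representative(), lo, hi)
        if sub is None:
            return Rejection(head_c.chrom, tail_c.pos, head_c.pos,
                             f"{cluster.side}-flank-does-not-cover-span")
        if sub != ref_tsd:
            return Rejection(head_c.chrom, tail_c.pos, head_c.pos,
                             f"{cluster.side}-flank-reference-mismatch")
    tsd_len, direction = tsd_from_junctions(tail_c.pos, head_c.pos)
    call = InsertionCall(
        chrom=head_c.chrom, tail_pos=tail_c.pos, head_pos=head_c.pos,
        tsd_len=tsd_len, tsd_seq=ref_tsd, direction=direction,
        head_support=head_c.support, tail_support=tail_c.support)
    call.validate()
    return call


def run_extended(
    reads: Iterable[SeqRecord],
    sig: TESignature,
    reference,
    params: TIFParams | None = None,
    out_tsv=None,
) -> list[InsertionCall]:
    """End-to-end reference-guided run.

    ``reference`` may be a prebuilt :class:`RefIndex`, an iterable of
    records, or a FASTA path.  Returns verified calls sorted by locus;
    deterministic for fixed inputs.  No TSD length is required.
    """
    if params is None:
        params = TIFParams()
    if isinstance(reference, RefIndex):
        index = reference
    elif isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        index = RefIndex.from_fasta(reference)
    else:
        index = RefIndex.from_records(reference)
    scan = scan_stream(reads, sig, params, mode="extended")
    mapped = []
    for flank in scan:
        outcome = map_flank(flank, index, min_flank=params.min_flank_map)
        if outcome.junction is not None:
            mapped.append((flank, outcome.junction))
    clusters = cluster_junctions(mapped)
    calls = []
    for pair in pair_junctions(clusters, params):
        result = verify_tsd(pair, index.chroms)
        if isinstance(result, InsertionCall):
            if min(result.head_support, result.tail_support) >= params.min_support:
                calls.append(result)
    calls.sort(key=lambda c: (c.chrom, c.span))
    if out_tsv is not None:
        write_calls_tsv(calls, out_tsv)
    return calls


@dataclass
class DiffResult:
    """Partition of two call sets into shared and set-specific loci."""

    sample_specific: list[InsertionCall]
    control_specific: list[InsertionCall]
    n_common: int

    @property
    def summary(self) -> tuple[int, int, int]:
        return (self.n_common, len(self.sample_specific),
                len(self.control_specific))


def diff_calls(sample: list[InsertionCall],
               control: list[InsertionCall]) -> DiffResult:
    """Subtract a control call set, e.g. the parent line of a derivative.

    Two calls are the same locus when their TSD spans overlap on the same
    chromosome.  Returns the sample-specific calls (the de novo events)
    together with control-specific calls and the common count.
    """
    def overlaps(a: InsertionCall, b: InsertionCall) -> bool:
        if a.chrom != b.chrom:
            return False
        (alo, ahi), (blo, bhi) = a.span, b.span
        return alo <= bhi and blo <= ahi

    sample_specific = [a for a in sample
                       if not any(overlaps(a, b) for b in control)]
    control_specific = [b for b in control
                        if not any(overlaps(b, a) for a in sample)]
    n_common = len(sample) - len(sample_specific)
    return DiffResult(sample_specific=sample_specific,
                      control_specific=control_specific,
                      n_common=n_common)
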