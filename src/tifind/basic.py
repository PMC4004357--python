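"""Reference-free insertion detection by TSD grouping.

Algorithm: flanks extracted by the signature scan are grouped by their
putative TSD string — the length-L suffix of each head flank and length-L
prefix of each tail flank.  A TSD string observed on both sides is evidence
for one insertion site; the longest flank on each side is kept as the
group's representative and the representatives are written out as a
TSD-sorted multi-FASTA for downstream placement (e.g. BLAST).

No reference genome is needed, which is what lets this mode find insertions
even inside repetitive regions.  The cost is that two distinct insertions
whose sites happen to share a TSD string collapse into one group — for
uniform 5-mers a 1/1024 chance per pair — which the reference-guided
algorithm in :mod:`tifind.extended` resolves.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .core import HEAD, TESignature, TIFParams, TifError
from .scan import FlankRecord, scan_stream
from .seqio import SeqRecord, write_group_fasta


@dataclass
class TSDGroup:
    """Head and tail flanks sharing one TSD string."""

    tsd: str
    head_flanks: list[FlankRecord] = field(default_factory=list)
    tail_flanks: list[FlankRecord] = field(default_factory=list)
    rep_head: FlankRecord | None = None
    rep_tail: FlankRecord | None = None


def _best(flanks: list[FlankRecord]) -> FlankRecord:
    # longest flank; ties broken by lexicographically smallest read id
    return min(flanks, key=lambda f: (-f.flank_len, f.read_id))


def select_representatives(group: TSDGroup) -> TSDGroup:
    """Set ``rep_head``/``rep_tail`` to the longest flank on each side."""
    if not group.head_flanks or not group.tail_flanks:
        raise TifError(f"TSD group {group.tsd!r} has an empty side")
    group.rep_head = _best(group.head_flanks)
    group.rep_tail = _best(group.tail_flanks)
    return group


def group_by_tsd(flanks: Iterable[FlankRecord], tsd_len: int) -> list[TSDGroup]:
    """Group flanks by TSD string; keep only two-sided groups.

    Head flanks are keyed by their length-L suffix, tail flanks by their
    length-L prefix.  Only TSD strings seen on both sides become groups
    (one-sided evidence cannot delimit an insertion); groups are returned
    sorted by TSD with representatives selected.
    """
    if tsd_len < 1:
        raise TifError(f"tsd_len must be >= 1, got {tsd_len}")
    heads: dict[str, list[FlankRecord]] = defaultdict(list)
    tails: dict[str, list[FlankRecord]] = defaultdict(list)
    for f in flanks:
        if f.flank_len < tsd_len:
            continue
        if f.side == HEAD:
            heads[f.flank[-tsd_len:]].append(f)
        else:
            tails[f.flank[:tsd_len]].append(f)
    groups = []
    for tsd in sorted(heads.keys() & tails.keys()):
        groups.append(select_representatives(
            TSDGroup(tsd=tsd, head_flanks=heads[tsd], tail_flanks=tails[tsd])))
    return groups


def run_basic(
    reads: Iterable[SeqRecord],
    sig: TESignature,
    tsd_len: int,
    out_fasta=None,
    params: TIFParams | None = None,
) -> list[TSDGroup]:
    """End-to-end reference-free run: scan → group → representatives.

    Deterministic for fixed input (grouping and tie-breaks are canonical,
    so the output is invariant to read order).  When ``out_fasta`` is given
    the representative flanks are also written as a sorted multi-FASTA.
    """
    if params is None:
        params = TIFParams(tsd_len=tsd_len)
    elif params.tsd_len != tsd_len:
        raise TifError("params.tsd_len disagrees with tsd_len argument")
    scan = scan_stream(reads, sig, params, mode="basic")
    groups = group_by_tsd(scan.flanks, tsd_len)
    if out_fasta is not None:
        write_group_fasta(groups, out_fasta)
    return groups
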