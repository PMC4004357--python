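"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: full scans over the raw strings, no seeding, no index.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def naive_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def naive_locate(chroms: dict[str, str], query: str):
    """All exact matches of query on either strand, full genome scan.

    Returns (chrom, start0, strand) tuples; minus-strand matches are
    positions of the reverse complement on the plus strand.  Mirrors the
    contract of RefIndex.find_exact without sharing any code with it.
    """
    hits = []
    for name, seq in chroms.items():
        for i in naive_find_all(seq, query):
            hits.append((name, i, "+"))
    rc = naive_revcomp(query)
    if rc != query:
        for name, seq in chroms.items():
            for i in naive_find_all(seq, rc):
                hits.append((name, i, "-"))
    return hits


def naive_map(flank_seq: str, side: str, chroms: dict[str, str]):
    """Unique-placement junction coordinate, or the rejection reason."""
    hits = naive_locate(chroms, flank_seq)
    if not hits:
        return None, "unmapped"
    if len(hits) > 1:
        return None, "multi-mapped"
    chrom, start0, strand = hits[0]
    a, b = start0 + 1, start0 + len(flank_seq)
    if (side, strand) in (("head", "+"), ("tail", "-")):
        pos = b
    else:
        pos = a
    return (chrom, pos, strand), None
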