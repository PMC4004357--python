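"""Domain primitives for TSD-based transposon insertion calling.

LTR retrotransposons (e.g. the rice Ty1-copia element Tos17) and TIR DNA
transposons (e.g. the Drosophila P-element) duplicate a short stretch of the
target site on insertion — the target site duplication (TSD), at most ~10 bp,
5 bp for Tos17 and 8 bp for the P-element.  A de novo insertion therefore
leaves two diagnostic junctions in the genome, each flanked by one copy of
the TSD, and short reads crossing either junction carry the first (head) or
last (tail) ``k`` bases of the element next to genomic sequence.  This module
holds the vocabulary shared by the rest of the package: signatures, TSD
arithmetic and the parameter bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

FORWARD = "forward"
REVERSE = "reverse"

HEAD = "head"
TAIL = "tail"

DNA_ALPHABET = frozenset("ACGTN")
SIGNATURE_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class TifError(ValueError):
    """Domain error raised for invalid sequences, parameters or inputs."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    ``N`` maps to ``N``; any other character raises :class:`TifError`.
    The operation is an involution: ``revcomp(revcomp(s)) == s``.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise TifError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TESignature:
    """Terminal signature of a transposable element.

    ``head`` is the first ``k`` bases of the element (5' end) and ``tail``
    the last ``k`` bases (3' end).  Signatures must be unambiguous
    (no ``N``) and at least 8 bp; 17 bp is the default used throughout,
    the shortest length at which terminal k-mers of a typical element are
    effectively unique in a host genome.
    """

    name: str
    head: str
    tail: str

    def __post_init__(self) -> None:
        if len(self.head) != len(self.tail):
            raise TifError(
                f"head ({len(self.head)} bp) and tail ({len(self.tail)} bp) "
                "signatures must have equal length"
            )
        if len(self.head) < 8:
            raise TifError(f"signature length {len(self.head)} < 8 bp")
        for label, s in ((HEAD, self.head), (TAIL, self.tail)):
            bad = set(s) - SIGNATURE_ALPHABET
            if bad:
                raise TifError(f"{label} signature contains {sorted(bad)}; "
                               "only A/C/G/T allowed")

    @property
    def k(self) -> int:
        """Signature length in bp."""
        return len(self.head)


DEFAULT_SIGNATURE_LEN = 17


def signature_from_te(te, k: int = DEFAULT_SIGNATURE_LEN) -> TESignature:
    """Build a :class:`TESignature` from a full-length element sequence.

    Takes the first and last ``k`` bases of ``te.seq`` (any object with
    ``id`` and ``seq`` attributes, e.g. :class:`tifind.seqio.SeqRecord`).
    The element must be at least ``2k`` long so that head and tail do not
    overlap; ambiguous bases in either terminal window are rejected with
    advice to supply explicit signatures instead.
    """
    seq = te.seq.upper()
    if len(seq) < 2 * k:
        raise TifError(
            f"element {te.id!r} is {len(seq)} bp, shorter than 2*k={2 * k}; "
            "cannot take non-overlapping terminal signatures"
        )
    head, tail = seq[:k], seq[-k:]
    for label, s in ((HEAD, head), (TAIL, tail)):
        if "N" in s:
            raise TifError(
                f"{label} window of element {te.id!r} contains N; "
                "provide explicit head/tail signatures instead"
            )
    return TESignature(name=te.id, head=head, tail=tail)


def tsd_collision_prob(tsd_len: int) -> float:
    """Probability that two independent uniform TSDs of this length coincide.

    Equals ``4**-L``: 1/1024 for the 5-bp TSD of an LTR retrotransposon like
    Tos17, which is why reference-free grouping by TSD string alone is safe
    only when the number of independent insertions is small.
    """
    if tsd_len < 0:
        raise TifError(f"TSD length must be non-negative, got {tsd_len}")
    return 4.0 ** (-tsd_len)


def tsd_from_junctions(tail_pos: int, head_pos: int) -> tuple[int, str]:
    """TSD length and element orientation implied by a junction pair.

    Both coordinates are 1-based positions on the same chromosome: the
    reference base adjacent to the element tail and head respectively.
    The duplicated site spans ``[min(tail_pos, head_pos)..max(...)]`` so its
    length is ``|head_pos - tail_pos| + 1``.  The element runs forward when
    the head junction lies right of the tail junction, reverse otherwise;
    the degenerate ``head_pos == tail_pos`` case (1-bp span) is reported as
    forward by convention.
    """
    tsd_len = abs(head_pos - tail_pos) + 1
    direction = FORWARD if head_pos >= tail_pos else REVERSE
    return tsd_len, direction


@dataclass
class TIFParams:
    """Tunable parameters of the caller.

    tsd_len
        Expected TSD length L in bp.  Required by the reference-free (basic)
        algorithm, unused by the reference-guided (extended) one.
    pair_window
        Maximum distance in bp between a head and a tail junction for them
        to be considered one insertion site; strict (< window).  Default 10,
        covering every TSD length the model admits.
    min_flank_basic
        Minimum genomic flank length kept in basic mode; defaults to
        ``tsd_len`` (a flank must at least contain the full TSD).
    min_flank_map
        Minimum flank length submitted to reference placement in extended
        mode; default 20 bp for placement specificity.
    min_support
        Minimum read support required on each side of a verified call.
    """

    tsd_len: int | None = None
    pair_window: int = 10
    min_flank_basic: int | None = None
    min_flank_map: int = 20
    min_support: int = 1

    def __post_init__(self) -> None:
        if self.tsd_len is not None:
            if not 1 <= self.tsd_len <= 10:
                raise TifError(
                    f"tsd_len must be in [1, 10], got {self.tsd_len}")
            if self.pair_window < self.tsd_len:
                raise TifError(
                    f"pair_window ({self.pair_window}) must be >= tsd_len "
                    f"({self.tsd_len})")
        if self.pair_window < 1:
            raise TifError("pair_window must be positive")
        if self.min_flank_map < 1:
            raise TifError("min_flank_map must be positive")
        if self.min_support < 1:
            raise TifError("min_support must be >= 1")

    @property
    def effective_min_flank_basic(self) -> int:
        if self.min_flank_basic is not None:
            return self.min_flank_basic
        if self.tsd_len is None:
            raise TifError("basic mode requires tsd_len (or an explicit "
                           "min_flank_basic)")
        return self.tsd_len
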