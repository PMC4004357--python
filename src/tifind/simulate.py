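"""Synthetic genomes, planted insertions and short-read simulation.

The generator emulates the study design the caller is meant for: a host
genome, a derivative line carrying de novo TE insertions that created TSDs,
and whole-genome Illumina-style paired-end reads of the derivative.
Defaults mirror that setting — 100 bp reads, 30x coverage, 5 bp TSDs, a
strict substitution-only error model — and every function is deterministic
for a fixed seed.

Truth records are expressed in PRE-insertion (reference) coordinates: the
1-based inclusive span of the duplicated site, its sequence and the element
orientation, which is exactly the coordinate system insertion calls are
reported in, so :func:`evaluate` can demand exact agreement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import FORWARD, REVERSE, TifError, revcomp
from .extended import InsertionCall
from .seqio import SeqRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True, slots=True)
class SimTruth:
    """One planted insertion, in pre-insertion reference coordinates."""

    chrom: str
    tsd_start: int  # 1-based inclusive
    tsd_end: int
    orientation: str  # FORWARD or REVERSE
    te_name: str
    tsd_seq: str

    def __post_init__(self) -> None:
        if self.tsd_end - self.tsd_start + 1 != len(self.tsd_seq):
            raise TifError(f"{self}: span and tsd_seq length disagree")


def make_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc: float = 0.5,
    seed: int = 0,
) -> list[SeqRecord]:
    """Random i.i.d. genome at the given GC content.

    Chromosomes are named ``chr01``, ``chr02``, ...  Lengths of at least
    ~10 kb keep 20-mers effectively unique, which unique-placement mapping
    relies on.
    """
    if len(lengths) != n_chrom:
        raise TifError(f"{n_chrom} chromosomes but {len(lengths)} lengths")
    if any(l <= 0 for l in lengths):
        raise TifError("chromosome lengths must be positive")
    if not 0.0 <= gc <= 1.0:
        raise TifError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i, length in enumerate(lengths, start=1):
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        records.append(SeqRecord(id=f"chr{i:02d}", seq=seq))
    return records


def random_te(length: int = 400, gc: float = 0.5, seed: int = 1,
              name: str = "toyTE") -> SeqRecord:
    """A random toy element to plant; long enough for 17-bp signatures."""
    (rec,) = make_genome(1, [length], gc=gc, seed=seed)
    return SeqRecord(id=name, seq=rec.seq)


def _count_occurrences(chroms: dict[str, str], pattern: str) -> int:
    total = 0
    for seq in chroms.values():
        i = seq.find(pattern)
        while i != -1:
            total += 1
            i = seq.find(pattern, i + 1)
    return total


def _site_ok(chroms, chrom, s, tsd_len, context, min_gap, chosen) -> bool:
    seq = chroms[chrom]
    e = s + tsd_len - 1
    if s - context < 1 or e + context > len(seq):
        return False
    for c, s2 in chosen:
        if c == chrom and abs(s2 - s) < min_gap:
            return False
    window = seq[s - 1 - context:e + context]
    if _count_occurrences(chroms, window) != 1:
        return False
    if _count_occurrences(chroms, revcomp(window)) != 0:
        return False
    return True


def choose_sites(
    genome: Sequence[SeqRecord],
    n: int,
    tsd_len: int = 5,
    *,
    seed: int = 0,
    min_gap: int = 1000,
    context: int = 150,
    distinct_tsds: bool = True,
) -> list[tuple[str, int]]:
    """Pick ``n`` insertion sites with unique local context.

    Each site's +/- ``context`` bp window must occur exactly once in the
    genome (either strand) and sites are at least ``min_gap`` bp apart, so
    that exact unique flank placement is achievable by construction.  With
    ``distinct_tsds`` the TSD strings are pairwise distinct even up to
    reverse complement.  Raises when the constraints cannot be met.
    """
    chroms = {r.id: r.seq for r in genome}
    rng = np.random.default_rng(seed)
    names = [r.id for r in genome]
    weights = np.array([len(r.seq) for r in genome], dtype=float)
    weights /= weights.sum()
    chosen: list[tuple[str, int]] = []
    used_tsds: set[str] = set()
    for _ in range(500 * n):
        if len(chosen) == n:
            break
        chrom = names[rng.choice(len(names), p=weights)]
        seq = chroms[chrom]
        s = int(rng.integers(context + 1, len(seq) - tsd_len - context + 1))
        if not _site_ok(chroms, chrom, s, tsd_len, context, min_gap, chosen):
            continue
        tsd = seq[s - 1:s - 1 + tsd_len]
        canon = min(tsd, revcomp(tsd))
        if distinct_tsds and canon in used_tsds:
            continue
        used_tsds.add(canon)
        chosen.append((chrom, s))
    if len(chosen) < n:
        raise TifError(f"could only place {len(chosen)} of {n} sites under "
                       "the uniqueness/spacing constraints")
    return chosen


def choose_shared_tsd_sites(
    genome: Sequence[SeqRecord],
    tsd_len: int = 5,
    *,
    seed: int = 0,
    min_gap: int = 1000,
    context: int = 150,
    max_tries: int = 20000,
) -> list[tuple[str, int]]:
    """Two valid sites whose TSD strings are identical.

    Used to reproduce the TSD-coincidence failure mode of reference-free
    grouping: two distinct loci sharing one TSD string merge into a single
    group while reference-guided calling keeps them apart.
    """
    chroms = {r.id: r.seq for r in genome}
    rng = np.random.default_rng(seed)
    names = [r.id for r in genome]
    weights = np.array([len(r.seq) for r in genome], dtype=float)
    weights /= weights.sum()
    by_tsd: dict[str, list[tuple[str, int]]] = {}
    for _ in range(max_tries):
        chrom = names[rng.choice(len(names), p=weights)]
        seq = chroms[chrom]
        s = int(rng.integers(context + 1, len(seq) - tsd_len - context + 1))
        tsd = seq[s - 1:s - 1 + tsd_len]
        prior = by_tsd.setdefault(tsd, [])
        if not _site_ok(chroms, chrom, s, tsd_len, context, min_gap, prior):
            continue
        prior.append((chrom, s))
        if len(prior) == 2:
            return prior
    raise TifError("could not find two unique-context sites sharing a TSD")


def plant_insertions(
    genome: Sequence[SeqRecord],
    te: SeqRecord,
    n: int | None = None,
    tsd_len: int = 5,
    frac_reverse: float = 0.0,
    *,
    seed: int = 0,
    min_gap: int = 1000,
    context: int = 150,
    distinct_tsds: bool = True,
    sites: Sequence[tuple[str, int]] | None = None,
) -> tuple[list[SeqRecord], list[SimTruth]]:
    """Insert the element at chosen sites, duplicating the target site.

    At a site whose pre-insertion TSD span is ``[s..e]`` the mutant
    chromosome becomes prefix-through-``e`` + element + suffix-from-``s``,
    i.e. left TSD copy, element (reverse-complemented for reverse
    orientation), right TSD copy.  Exactly ``round(frac_reverse * n)``
    sites get reverse orientation (assignment shuffled by seed), so a
    requested mix is always realised.  Returns the mutant genome and truth
    records in pre-insertion coordinates.
    """
    rng = np.random.default_rng(seed)
    if sites is None:
        if n is None:
            raise TifError("either n or explicit sites must be given")
        sites = choose_sites(genome, n, tsd_len, seed=int(rng.integers(2**31)),
                             min_gap=min_gap, context=context,
                             distinct_tsds=distinct_tsds)
    n = len(sites)
    n_rev = int(round(frac_reverse * n))
    orientations = [REVERSE] * n_rev + [FORWARD] * (n - n_rev)
    rng.shuffle(orientations)

    chroms = {r.id: r.seq for r in genome}
    truths = []
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for (chrom, s), orient in zip(sites, orientations):
        if chrom not in chroms:
            raise TifError(f"unknown chromosome {chrom!r}")
        e = s + tsd_len - 1
        tsd = chroms[chrom][s - 1:e]
        truths.append(SimTruth(chrom=chrom, tsd_start=s, tsd_end=e,
                               orientation=orient, te_name=te.id,
                               tsd_seq=tsd))
        per_chrom.setdefault(chrom, []).append((s, orient))

    mutant = {}
    for rec in genome:
        seq = rec.seq
        # apply right-to-left so earlier coordinates stay valid
        for s, orient in sorted(per_chrom.get(rec.id, []), reverse=True):
            e = s + tsd_len - 1
            te_seq = te.seq if orient == FORWARD else revcomp(te.seq)
            seq = seq[:e] + te_seq + seq[s - 1:]
        mutant[rec.id] = seq
    mutant_records = [SeqRecord(id=r.id, seq=mutant[r.id]) for r in genome]
    truths.sort(key=lambda t: (t.chrom, t.tsd_start))
    return mutant_records, truths


def _apply_errors(seq: str, rng: np.random.Generator,
                  error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def generate_reads(
    genome: Sequence[SeqRecord],
    read_len: int = 100,
    coverage: float = 30.0,
    paired: bool = True,
    insert_mean: int = 300,
    insert_sd: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Uniform-coverage reads from a genome, both strands.

    Total read count is ``round(coverage * genome_len / read_len)``
    (fragments halved when paired, two mates each).  Fragment lengths are
    normal(insert_mean, insert_sd) clipped to [read_len, chromosome];
    substitution errors are i.i.d. per base at ``error_rate``.  Read ids
    are ``frag{i}/1`` and ``frag{i}/2`` (or ``read{i}`` single-end).
    """
    if any(read_len > len(r.seq) for r in genome):
        raise TifError("read_len exceeds a chromosome length")
    rng = np.random.default_rng(seed)
    total_len = sum(len(r.seq) for r in genome)
    weights = np.array([len(r.seq) for r in genome], dtype=float) / total_len
    reads: list[SeqRecord] = []
    if paired:
        n_frag = int(round(coverage * total_len / read_len / 2))
        for i in range(n_frag):
            rec = genome[rng.choice(len(genome), p=weights)]
            flen = int(round(rng.normal(insert_mean, insert_sd)))
            flen = max(read_len, min(flen, len(rec.seq)))
            start = int(rng.integers(0, len(rec.seq) - flen + 1))
            frag = rec.seq[start:start + flen]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            r1 = _apply_errors(frag[:read_len], rng, error_rate)
            r2 = _apply_errors(revcomp(frag)[:read_len], rng, error_rate)
            q = "I" * read_len
            reads.append(SeqRecord(id=f"frag{i:07d}/1", seq=r1, qual=q))
            reads.append(SeqRecord(id=f"frag{i:07d}/2", seq=r2, qual=q))
    else:
        n_reads = int(round(coverage * total_len / read_len))
        for i in range(n_reads):
            rec = genome[rng.choice(len(genome), p=weights)]
            start = int(rng.integers(0, len(rec.seq) - read_len + 1))
            seq = rec.seq[start:start + read_len]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SeqRecord(id=f"read{i:07d}",
                                   seq=_apply_errors(seq, rng, error_rate),
                                   qual="I" * read_len))
    return reads


TRUTH_COLUMNS = ["chrom", "tsd_start", "tsd_end", "tsd_seq", "orientation",
                 "te_name"]


def write_truth_tsv(truths: Iterable[SimTruth], path) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in sorted(truths, key=lambda t: (t.chrom, t.tsd_start)):
            fh.write("\t".join(map(str, (t.chrom, t.tsd_start, t.tsd_end,
                                         t.tsd_seq, t.orientation,
                                         t.te_name))) + "\n")


def read_truth_tsv(path) -> list[SimTruth]:
    truths = []
    with open(path, "rt", encoding="ascii") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise TifError(f"{os.fspath(path)}: unexpected truth header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truths.append(SimTruth(chrom=f[0], tsd_start=int(f[1]),
                                   tsd_end=int(f[2]), tsd_seq=f[3],
                                   orientation=f[4], te_name=f[5]))
    return truths


@dataclass
class EvalResult:
    """Truth-based scoring of a call set."""

    recall: float
    precision: float
    n_truth: int
    n_calls: int
    matched: list[tuple[SimTruth, InsertionCall]]
    missed: list[SimTruth]
    spurious: list[InsertionCall]


def evaluate(calls: Sequence[InsertionCall],
             truths: Sequence[SimTruth]) -> EvalResult:
    """Exact matching of calls to planted insertions.

    A call matches a truth record iff chromosome, the ordered junction span
    (min, max), the TSD sequence and the orientation all agree exactly;
    each truth record can absorb at most one call.
    """
    def truth_key(t: SimTruth):
        return (t.chrom, t.tsd_start, t.tsd_end, t.tsd_seq, t.orientation)

    def call_key(c: InsertionCall):
        lo, hi = c.span
        return (c.chrom, lo, hi, c.tsd_seq, c.direction)

    remaining = {truth_key(t): list() for t in truths}
    for t in truths:
        remaining[truth_key(t)].append(t)
    matched, spurious = [], []
    for c in calls:
        bucket = remaining.get(call_key(c))
        if bucket:
            matched.append((bucket.pop(), c))
        else:
            spurious.append(c)
    missed = [t for bucket in remaining.values() for t in bucket]
    recall = len(matched) / len(truths) if truths else 1.0
    precision = len(matched) / len(calls) if calls else 1.0
    return EvalResult(recall=recall, precision=precision,
                      n_truth=len(truths), n_calls=len(calls),
                      matched=matched, missed=missed, spurious=spurious)
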