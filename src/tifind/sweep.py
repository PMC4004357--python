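"""Parameter sweeps and run summaries.

The two lengths that govern sensitivity and specificity are the signature
length ``k`` (shorter signatures hit the genome by chance and inflate the
flank pool) and, for the reference-free algorithm, the assumed TSD length
``L`` (the locus count collapses as soon as L departs from the element's
true TSD length, because the head-flank suffix and tail-flank prefix of a
real junction only agree at the true L).  ``run_sweep`` re-runs the
reference-free grouping over a (k, L) grid, optionally projecting each
group onto the reference to count verified loci, and returns a tidy table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .basic import TSDGroup, group_by_tsd
from .core import TESignature, TIFParams, revcomp, signature_from_te
from .extended import InsertionCall, diff_calls
from .refmap import RefIndex, map_flank
from .scan import scan_stream
from .seqio import SeqRecord

SWEEP_COLUMNS = ["sig_len", "tsd_len", "n_flank_records", "n_groups",
                 "n_loci"]


def project_group_loci(
    groups: Iterable[TSDGroup],
    index: RefIndex,
    tsd_len: int,
    pair_window: int = 10,
    min_flank_map: int = 20,
) -> set[tuple[str, int, int]]:
    """Reference loci supported by group representatives.

    A group projects to a locus when both representative flanks place
    uniquely on one chromosome, the junctions lie within the strict pairing
    window with span length equal to ``tsd_len``, and the spanned reference
    substring equals the group's TSD string on either strand (a
    reverse-oriented element is grouped under the reverse complement of the
    plus-strand TSD).
    """
    loci: set[tuple[str, int, int]] = set()
    for g in groups:
        oh = map_flank(g.rep_head, index, min_flank=min_flank_map)
        ot = map_flank(g.rep_tail, index, min_flank=min_flank_map)
        if oh.junction is None or ot.junction is None:
            continue
        h, t = oh.junction, ot.junction
        if h.chrom != t.chrom or abs(h.pos - t.pos) >= pair_window:
            continue
        lo, hi = min(h.pos, t.pos), max(h.pos, t.pos)
        if hi - lo + 1 != tsd_len:
            continue
        ref_tsd = index.chroms[h.chrom][lo - 1:hi]
        if ref_tsd == g.tsd or ref_tsd == revcomp(g.tsd):
            loci.add((h.chrom, lo, hi))
    return loci


def run_sweep(
    reads: Sequence[SeqRecord],
    te: SeqRecord,
    reference=None,
    k_values: Sequence[int] = (17,),
    tsd_values: Sequence[int] = (5,),
    pair_window: int = 10,
    min_flank_map: int = 20,
) -> pd.DataFrame:
    """Reference-free grouping over a (signature length, TSD length) grid.

    ``reads`` must be re-iterable (a list, not a one-shot stream).  Columns:
    sig_len, tsd_len, n_flank_records (flanks surviving the length filter),
    n_groups (two-sided TSD groups) and n_loci (reference-verified loci;
    -1 when no reference was supplied).
    """
    if not k_values or not tsd_values:
        raise ValueError("k_values and tsd_values must be nonempty")
    index = None
    if reference is not None:
        index = (reference if isinstance(reference, RefIndex)
                 else RefIndex.from_records(reference))
    rows = []
    for k in k_values:
        sig = signature_from_te(te, k=k)
        for L in tsd_values:
            params = TIFParams(tsd_len=L, pair_window=pair_window,
                               min_flank_map=min_flank_map)
            scan = scan_stream(reads, sig, params, mode="basic")
            groups = group_by_tsd(scan.flanks, L)
            n_loci = -1
            if index is not None:
                n_loci = len(project_group_loci(
                    groups, index, L, pair_window=pair_window,
                    min_flank_map=min_flank_map))
            rows.append((k, L, len(scan), len(groups), n_loci))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def report_summary(
    calls: Sequence[InsertionCall],
    control_calls: Sequence[InsertionCall] | None = None,
) -> str:
    """Human-readable summary of a call set.

    Totals, per-chromosome counts and orientation breakdown; when a control
    call set is supplied, the common / sample-only / control-only partition
    is appended.
    """
    lines = [f"total calls\t{len(calls)}"]
    per_chrom: dict[str, int] = {}
    per_dir: dict[str, int] = {}
    for c in calls:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
        per_dir[c.direction] = per_dir.get(c.direction, 0) + 1
    for chrom in sorted(per_chrom):
        lines.append(f"chrom {chrom}\t{per_chrom[chrom]}")
    for d in sorted(per_dir):
        lines.append(f"direction {d}\t{per_dir[d]}")
    if control_calls is not None:
        diff = diff_calls(list(calls), list(control_calls))
        common, a_only, b_only = diff.summary
        lines.append(f"common with control\t{common}")
        lines.append(f"sample-specific\t{a_only}")
        lines.append(f"control-specific\t{b_only}")
    return "\n".join(lines) + "\n"
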