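"""Bundled reference call set: validated Tos17 insertions in rice lines.

The package ships the published, PCR/sequencing-validated set of de novo
Tos17 insertion loci found in two regenerated Nipponbare derivative lines
(ttm2 and ttm5), as assigned to the IRGSP reference genome.  It serves as a
fixed ground truth for coordinate arithmetic (every locus carries a 5-bp
TSD whose length equals ``|head - tail| + 1``) and for sanity-checking the
reporting conventions: 1-based junction coordinates, TSD sequence, and
orientation read off the junction order.

One ttm5 locus group on chr07 carries two coordinate pairs under a single
TSD string; it is stored as one row with two pairs.  One chr10 locus was
reported by a competing detector only and failed validation; it is retained
with ``confirmed=False``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

from .core import TifError, tsd_from_junctions

_DATA_NAME = "rice_tos17_calls.tsv"
_DATA_SHA256 = "f7d21a2e35c8b29d4dd37f2066ca47f3535d9351c09efc38c0f8964f1f39dd49"


@dataclass(frozen=True)
class KnownCall:
    """One curated insertion locus row (possibly several junction pairs)."""

    row: int
    line: str
    chrom: str
    pairs: tuple[tuple[int, int], ...]  # (tail_junction, head_junction)
    tsd_len: int
    tsd_tail: str | None  # None when that detector saw no tail evidence
    tsd_head: str
    direction: str
    by_tif: bool
    by_relocate: bool
    confirmed: bool


def _read_data_text() -> str:
    data = (resources.files("tifind") / "data" / _DATA_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _DATA_SHA256:
        raise TifError(
            f"bundled call set {_DATA_NAME} failed its checksum "
            f"({digest[:12]}... != {_DATA_SHA256[:12]}...); "
            "the installation is corrupt")
    return data.decode("ascii")


def load_rice_tos17_calls() -> list[KnownCall]:
    """Load the curated rice Tos17 call set (16 loci, 17 junction pairs)."""
    lines = _read_data_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    rows: dict[int, dict] = {}
    order: list[int] = []
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        row = int(rec["row"])
        pair = (int(rec["tail_junction"]), int(rec["head_junction"]))
        if row in rows:
            rows[row]["pairs"].append(pair)
            continue
        order.append(row)
        rows[row] = dict(
            row=row,
            line=rec["line"],
            chrom=rec["chrom"],
            pairs=[pair],
            tsd_len=int(rec["tsd_size"]),
            tsd_tail=None if rec["tsd_tail"] == "-" else rec["tsd_tail"],
            tsd_head=rec["tsd_head"],
            direction=rec["direction"],
            by_tif=rec["by_tif"] == "yes",
            by_relocate=rec["by_relocate"] == "yes",
            confirmed=rec["confirmed"] == "yes",
        )
    calls = []
    for row in order:
        d = rows[row]
        d["pairs"] = tuple(d["pairs"])
        call = KnownCall(**d)
        for tail, head in call.pairs:
            length, direction = tsd_from_junctions(tail, head)
            if length != call.tsd_len or direction != call.direction:
                raise TifError(f"curated row {row} is internally "
                               "inconsistent")
        calls.append(call)
    return calls


def count_loci(calls: list[KnownCall], line: str | None = None,
               detector: str | None = None,
               confirmed: bool | None = None) -> int:
    """Count junction pairs (loci) matching the given filters.

    ``detector`` is ``"tif"``, ``"relocate"`` or ``"both"``.
    """
    n = 0
    for c in calls:
        if line is not None and c.line != line:
            continue
        if detector == "tif" and not c.by_tif:
            continue
        if detector == "relocate" and not c.by_relocate:
            continue
        if detector == "both" and not (c.by_tif and c.by_relocate):
            continue
        if confirmed is not None and c.confirmed != confirmed:
            continue
        n += len(c.pairs)
    return n
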