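"""Read-to-panel alignment: ingestion, filtering and best-hit selection.

Production pipelines map reads with an external short-read mapper and hand
over SAM; this module reads such SAM (NM tags required) and also ships an
exhaustive infix aligner for desk-scale panels, so the test suite and the
examples run with no external mapper. Downstream only needs, per read, the
set of references tied at the minimal edit distance — hits above 5% of the
read length are discarded first, mirroring the high-confidence filter the
assignment step assumes.

Coordinate conventions: hits store 1-based reference starts (as SAM
prints); strand "-" hits store the CIGAR in reference-forward orientation
over the reverse-complemented read, again as SAM does.
"""

from __future__ import annotations

import io
import math
import tempfile
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import pysam

from .preprocess import Read
from .simulate import revcomp

__all__ = [
    "AlignmentHit",
    "read_sam",
    "write_sam",
    "exhaustive_align",
    "align_library",
    "edit_distance_filter",
    "best_hits",
]

_CIG_OP = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_read_len(cigar: str) -> int:
    """Read bases consumed by a CIGAR (M/I/S/=/X)."""
    return sum(
        int(n) for n, op in _CIG_OP.findall(cigar) if op in "MIS=X"
    )


def _to_sam_cigar(extended: str) -> str:
    """Collapse edlib's =/X ops into M runs (I/D kept)."""
    out: list[tuple[int, str]] = []
    for n, op in _CIG_OP.findall(extended):
        op = "M" if op in "=X" else op
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + int(n), op)
        else:
            out.append((int(n), op))
    return "".join(f"{n}{op}" for n, op in out)


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-reference alignment."""

    read_id: str
    ref_accession: str
    edit_distance: int
    ref_start: int  # 1-based, as in SAM
    strand: str  # "+" or "-"
    cigar: str
    read_len: int

    def __post_init__(self) -> None:
        if self.edit_distance > self.read_len:
            raise ValueError(
                f"{self.read_id}: edit distance exceeds read length"
            )
        consumed = cigar_read_len(self.cigar)
        if consumed != self.read_len:
            raise ValueError(
                f"{self.read_id}: CIGAR {self.cigar} consumes {consumed} "
                f"bases, read length is {self.read_len}"
            )


def read_sam(text: str) -> dict[str, list[AlignmentHit]]:
    """Parse SAM text into hits grouped by read id.

    Unmapped records are skipped; secondary alignments are kept. A mapped
    record without an NM tag is a hard error naming the record.
    """
    hits: dict[str, list[AlignmentHit]] = {}
    with tempfile.NamedTemporaryFile("w", suffix=".sam") as tmp:
        tmp.write(text)
        tmp.flush()
        sam = pysam.AlignmentFile(tmp.name, "r", check_sq=False)
        for rec in sam:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NM"):
                raise ValueError(
                    f"record {rec.query_name} @ {rec.reference_name}:"
                    f"{rec.reference_start + 1} lacks an NM tag"
                )
            hit = AlignmentHit(
                read_id=rec.query_name,
                ref_accession=rec.reference_name,
                edit_distance=int(rec.get_tag("NM")),
                ref_start=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                cigar=rec.cigarstring,
                read_len=rec.query_length,
            )
            hits.setdefault(hit.read_id, []).append(hit)
    return hits


def write_sam(
    hits_by_read: Mapping[str, list[AlignmentHit]],
    reads: Mapping[str, Read],
    panel: Mapping[str, str],
) -> str:
    """Serialize hits to SAM text (primary + secondary records)."""
    out = io.StringIO()
    refs = sorted(panel)
    out.write("@HD\tVN:1.6\tSO:unknown\n")
    for acc in refs:
        out.write(f"@SQ\tSN:{acc}\tLN:{len(panel[acc])}\n")
    for read_id in hits_by_read:
        seq = reads[read_id].sequence
        qual = reads[read_id].quality or ("F" * len(seq))
        for i, h in enumerate(hits_by_read[read_id]):
            flag = 0
            if h.strand == "-":
                flag |= 16
            if i > 0:
                flag |= 256
            s = revcomp(seq) if h.strand == "-" else seq
            q = qual[::-1] if h.strand == "-" else qual
            out.write(
                f"{read_id}\t{flag}\t{h.ref_accession}\t{h.ref_start}\t255\t"
                f"{h.cigar}\t*\t0\t0\t{s}\t{q}\tNM:i:{h.edit_distance}\n"
            )
    return out.getvalue()


def _canonical_hw_alignment(
    query: str, ref: str, end: int, dist: int
) -> tuple[int, str]:
    """Re-derive a canonical infix alignment ending at ``end`` (0-based,
    inclusive) with edit distance ``dist``.

    Edit distance admits cost-equal representations of a terminal mismatch
    as a terminal gap; the traceback here prefers substitutions over gaps,
    so fragment termini keep their reference pairing — the 5′ bases are
    exactly where the deamination signal lives. Returns (0-based start,
    SAM cigar).
    """
    m = len(query)
    wstart = max(0, end + 1 - (m + dist))
    wend = min(len(ref), end + 1 + dist)
    win = ref[wstart:wend]
    w = len(win)
    prev = [0] * (w + 1)  # free leading reference gap (infix semantics)
    rows = [prev]
    for i in range(1, m + 1):
        qc = query[i - 1]
        cur = [i] + [0] * w
        p = prev
        for j in range(1, w + 1):
            cur[j] = min(
                p[j - 1] + (qc != win[j - 1]),
                p[j] + 1,
                cur[j - 1] + 1,
            )
        rows.append(cur)
        prev = cur
    # free trailing reference gap: end at the rightmost minimal column, so a
    # terminal substitution wins over a cost-equal terminal insertion
    last = rows[m]
    best = min(last)
    j = max(jj for jj in range(w + 1) if last[jj] == best)
    ops: list[str] = []
    i = m
    while i > 0:
        diag = rows[i - 1][j - 1] + (query[i - 1] != win[j - 1]) if j > 0 else None
        here = rows[i][j]
        if j > 0 and diag == here:
            ops.append("M")
            i -= 1
            j -= 1
        elif rows[i - 1][j] + 1 == here:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    merged: list[tuple[int, str]] = []
    for op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + 1, op)
        else:
            merged.append((1, op))
    cigar = "".join(f"{n}{op}" for n, op in merged)
    return wstart + j, cigar


def exhaustive_align(
    read: Read,
    panel: Mapping[str, str],
    max_edit: int,
) -> list[AlignmentHit]:
    """Best infix alignments of one read against every panel reference.

    For each reference and strand the minimal edit distance of the read
    against any reference window is computed (banded at ``max_edit``);
    every (reference, strand, position) achieving that minimum is emitted
    when the minimum is <= max_edit. Intended for at most thousands of
    reads against dozens of references.
    """
    hits: list[AlignmentHit] = []
    queries = {"+": read.sequence, "-": revcomp(read.sequence)}
    for acc in sorted(panel):
        ref = panel[acc]
        for strand, query in queries.items():
            res = edlib.align(query, ref, mode="HW", task="path", k=max_edit)
            if res["editDistance"] < 0:
                continue
            first_cigar = _to_sam_cigar(res["cigar"])
            seen_starts: set[int] = set()
            for li, (_start, end) in enumerate(res["locations"]):
                start = _start if _start is not None else 0
                if li == 0:
                    cigar = first_cigar
                else:
                    # the reported CIGAR belongs to the first location;
                    # repeats get theirs from a global alignment of the window
                    sub = edlib.align(
                        query, ref[start : end + 1], mode="NW", task="path"
                    )
                    cigar = _to_sam_cigar(sub["cigar"])
                if "I" in cigar or "D" in cigar:
                    # gapped representations of terminal mismatches are
                    # rewritten so fragment ends keep a reference pairing
                    start, cigar = _canonical_hw_alignment(
                        query, ref, end, res["editDistance"]
                    )
                if start in seen_starts:
                    continue
                seen_starts.add(start)
                hits.append(
                    AlignmentHit(
                        read_id=read.read_id,
                        ref_accession=acc,
                        edit_distance=res["editDistance"],
                        ref_start=start + 1,
                        strand=strand,
                        cigar=cigar,
                        read_len=len(read.sequence),
                    )
                )
    return hits


def align_library(
    reads: Iterable[Read],
    panel: Mapping[str, str],
    edit_frac: float = 0.05,
) -> dict[str, list[AlignmentHit]]:
    """Align every read, banding the search at floor(edit_frac · length).

    Only alignments that can pass the edit-distance filter are searched
    for; reads with no qualifying hit are absent from the result.
    """
    out: dict[str, list[AlignmentHit]] = {}
    for read in reads:
        k = math.floor(edit_frac * len(read.sequence))
        hits = exhaustive_align(read, panel, max_edit=k)
        if hits:
            out[read.read_id] = hits
    return out


def edit_distance_filter(
    hits: Iterable[AlignmentHit], frac: float = 0.05
) -> list[AlignmentHit]:
    """Keep hits with edit distance <= frac × read length.

    Equality is kept (NM = 5 on a 100-mer passes at the default); strictly
    above is discarded.
    """
    if frac < 0:
        raise ValueError("frac must be >= 0")
    return [h for h in hits if h.edit_distance <= frac * h.read_len]


def best_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Tie set at the minimal edit distance for one read.

    Hits to the same reference at different positions collapse to one hit
    per reference, so a long reference cannot dominate the downstream LCA
    vote. Returns [] for empty input.
    """
    hits = list(hits)
    if not hits:
        return []
    if len({h.read_id for h in hits}) > 1:
        raise ValueError("best_hits expects hits of a single read")
    d = min(h.edit_distance for h in hits)
    tie, seen = [], set()
    for h in hits:
        if h.edit_distance == d and h.ref_accession not in seen:
            seen.add(h.ref_accession)
            tie.append(h)
    return tie
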