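"""Read-level filters applied before alignment.

Three bespoke filters: exact-duplicate removal (same sequence and same
length — strand-naive and quality-blind, so a reverse complement is not a
duplicate), a minimum-length filter (fragments shorter than 25 nt carry
too little signal to place taxonomically), and a DUST-style
low-complexity filter on trinucleotide over-representation.

Adapter trimming, quality trimming and read-pair collapsing are consumed
as already done upstream; this module starts from collapsed single-end
reads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Read",
    "reads_from_fastq",
    "reads_to_fastq",
    "remove_exact_duplicates",
    "length_filter",
    "dust_score",
    "dust_filter",
    "FilterReport",
    "run_filters",
]


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: quality length != sequence length"
            )


def reads_from_fastq(text: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(io.StringIO(text), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def reads_to_fastq(reads: Iterable[Read]) -> str:
    chunks = []
    for r in reads:
        qual = r.quality if r.quality is not None else "F" * len(r.sequence)
        chunks.append(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
    return "".join(chunks)


def remove_exact_duplicates(reads: Iterable[Read]) -> Iterator[Read]:
    """Drop reads whose sequence string was already seen.

    First occurrence kept, order preserved. Identity is the full sequence
    (same sequence, same length); reverse complements are distinct.
    """
    seen: set[str] = set()
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            yield r


def length_filter(reads: Iterable[Read], min_len: int = 25) -> Iterator[Read]:
    """Keep reads of length >= min_len (a 25-mer passes at the default)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return (r for r in reads if len(r.sequence) >= min_len)


def dust_score(sequence: str) -> float:
    """Low-complexity score from trinucleotide over-representation.

    Over every sliding window of length w = min(64, len): count occurrences
    c_t of each trinucleotide (triplets containing N are skipped) and score
    the window as Σ_t c_t(c_t−1)/2 divided by (w − 3). The read score is
    the maximum over windows. A homopolymer of length 64 scores 31.0; a
    uniform random 64-mer scores far below 1. Reads scoring above 1 are
    dropped by :func:`dust_filter`; a score of exactly 1 is kept.

    Sequences shorter than 3 score 0 by convention.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 3:
        return 0.0
    w = min(64, n)
    best = 0.0
    for start in range(0, n - w + 1):
        window = seq[start : start + w]
        counts: dict[str, int] = {}
        for i in range(w - 2):
            t = window[i : i + 3]
            if "N" in t:
                continue
            counts[t] = counts.get(t, 0) + 1
        s = sum(c * (c - 1) // 2 for c in counts.values()) / (w - 3)
        if s > best:
            best = s
    return best


def dust_filter(reads: Iterable[Read], max_score: float = 1.0) -> Iterator[Read]:
    """Drop reads with dust score strictly above ``max_score``."""
    return (r for r in reads if dust_score(r.sequence) <= max_score)


@dataclass
class FilterReport:
    n_input: int
    n_after_duplicates: int
    n_after_length: int
    n_after_dust: int

    def to_tsv(self) -> str:
        return (
            "stage\tsurvivors\n"
            f"input\t{self.n_input}\n"
            f"duplicate_removal\t{self.n_after_duplicates}\n"
            f"length_filter\t{self.n_after_length}\n"
            f"dust_filter\t{self.n_after_dust}\n"
        )


def run_filters(
    reads: Iterable[Read],
    min_len: int = 25,
    dust_max: float = 1.0,
) -> tuple[list[Read], FilterReport]:
    """duplicate → length → dust, with per-stage survivor counts."""
    reads = list(reads)
    n_input = len(reads)
    dedup = list(remove_exact_duplicates(reads))
    lenok = list(length_filter(dedup, min_len=min_len))
    clean = list(dust_filter(lenok, max_score=dust_max))
    report = FilterReport(n_input, len(dedup), len(lenok), len(clean))
    return clean, report
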