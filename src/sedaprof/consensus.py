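"""Majority-rule consensus from reads realigned to a single reference.

Reads assigned to one taxon are piled up on its reference mitogenome:
each reference position takes the most frequent observed base (ties and
uncovered positions call N, avoiding reference bias), and the mean
coverage depth — aligned read bases per reference position — summarises
support. The result is evidence for the taxon's presence in a layer, not
the genome of any single individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .align import AlignmentHit, _CIG_OP
from .preprocess import Read
from .simulate import revcomp

__all__ = ["ConsensusResult", "pileup_consensus"]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    mean_depth: float
    depth: np.ndarray  # per-position aligned-base count
    n_reads: int


def pileup_consensus(
    hits: Iterable[AlignmentHit],
    reads: Mapping[str, Read],
    ref_accession: str,
    ref_seq: str,
    min_depth: int = 1,
) -> ConsensusResult:
    """Per-position majority consensus over one reference.

    Matches/mismatches add observations at their reference position;
    deletions leave the position unobserved; insertions are ignored in
    consensus coordinates. Positions with depth below ``min_depth`` (or a
    tie for the most frequent base) are called N.
    """
    L = len(ref_seq)
    obs = np.zeros((L, 4), dtype=np.int64)
    n_reads = 0
    for hit in hits:
        if hit.ref_accession != ref_accession:
            raise ValueError(
                f"hit of read {hit.read_id} targets {hit.ref_accession}, "
                f"not {ref_accession}"
            )
        n_reads += 1
        seq = reads[hit.read_id].sequence
        if hit.strand == "-":
            seq = revcomp(seq)  # reference-forward orientation, as in SAM
        read_i = 0
        ref_i = hit.ref_start - 1
        for n_s, op in _CIG_OP.findall(hit.cigar):
            n = int(n_s)
            if op in "M=X":
                for k in range(n):
                    base = seq[read_i + k]
                    pos = ref_i + k
                    if 0 <= pos < L and base in _BASE_IDX:
                        obs[pos, _BASE_IDX[base]] += 1
                read_i += n
                ref_i += n
            elif op in "IS":
                read_i += n
            elif op in "DN":
                ref_i += n
    depth = obs.sum(axis=1)
    consensus = np.full(L, "N", dtype="U1")
    covered = depth >= max(1, min_depth)
    if covered.any():
        top = obs.argmax(axis=1)
        top_count = obs.max(axis=1)
        # a tie for the modal base yields N
        n_at_top = (obs == top_count[:, None]).sum(axis=1)
        unambiguous = covered & (n_at_top == 1)
        bases = np.array(["A", "C", "G", "T"])
        consensus[unambiguous] = bases[top[unambiguous]]
    return ConsensusResult(
        sequence="".join(consensus),
        mean_depth=float(depth.sum() / L) if L else 0.0,
        depth=depth,
        n_reads=n_reads,
    )
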