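"""Per-read taxonomic assignment from best-hit tie sets.

A read with a single best reference is assigned directly to that
reference's taxon; a read tied between several references is assigned to
the lowest common ancestor of their taxa. Ambiguity therefore moves a
read up the tree instead of forcing a guess — the property that makes
the downstream faunal profiles conservative.

Vertebrate profiles only admit assignments resolved to family level or
lower; helminth evidence is counted per target species, from reads whose
assignment node IS that species (a read stuck at genus Taenia supports
no particular tapeworm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import AlignmentHit
from .taxonomy import TaxonomyTree

__all__ = [
    "ReadAssignment",
    "AssignmentLog",
    "assign_read",
    "assign_all",
    "restrict_vertebrate",
    "helminth_unique_counts",
    "assignments_to_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    taxid: int
    n_tied_refs: int
    unique: bool  # assigned from a single best reference


@dataclass
class AssignmentLog:
    """Conservation ledger: input = assigned + unassigned + dropped."""

    n_input: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    n_dropped_unmapped: int = 0


def assign_read(
    tie_set: Sequence[AlignmentHit],
    acc_map: Mapping[str, int],
    tree: TaxonomyTree,
    log: AssignmentLog | None = None,
) -> ReadAssignment | None:
    """Resolve one read's best-hit tie set to a taxonomy node.

    References missing from the accession→taxid map are dropped with a
    logged count (obsolete identifiers); if nothing remains the read is
    unassigned. One distinct taxid → that node, unique; several → their
    LCA, non-unique.
    """
    if not tie_set:
        raise ValueError("assign_read requires a nonempty tie set")
    taxids = set()
    n_unmapped = 0
    for hit in tie_set:
        taxid = acc_map.get(hit.ref_accession)
        if taxid is None:
            n_unmapped += 1
        else:
            taxids.add(taxid)
    if n_unmapped:
        logger.debug(
            "read %s: %d hit(s) to unmapped accessions dropped",
            tie_set[0].read_id, n_unmapped,
        )
        if log is not None:
            log.n_dropped_unmapped += n_unmapped
    if not taxids:
        return None
    if len(taxids) == 1:
        return ReadAssignment(
            read_id=tie_set[0].read_id,
            taxid=next(iter(taxids)),
            n_tied_refs=len(tie_set),
            unique=True,
        )
    return ReadAssignment(
        read_id=tie_set[0].read_id,
        taxid=tree.lca(taxids),
        n_tied_refs=len(tie_set),
        unique=False,
    )


def assign_all(
    tie_sets: Mapping[str, Sequence[AlignmentHit]],
    acc_map: Mapping[str, int],
    tree: TaxonomyTree,
) -> tuple[list[ReadAssignment], AssignmentLog]:
    log = AssignmentLog(n_input=len(tie_sets))
    out = []
    for read_id in tie_sets:
        a = assign_read(tie_sets[read_id], acc_map, tree, log=log)
        if a is None:
            log.n_unassigned += 1
        else:
            log.n_assigned += 1
            out.append(a)
    return out, log


def restrict_vertebrate(
    assignments: Iterable[ReadAssignment],
    tree: TaxonomyTree,
    clade_name: str = "Vertebrata",
    rank: str = "family",
) -> list[ReadAssignment]:
    """Keep assignments within Vertebrata resolved to family level or lower.

    Reads whose LCA lands above family (e.g. at class Mammalia) stay in
    the raw assignment output but are excluded here, with a logged count.
    """
    kept, dropped = [], 0
    for a in assignments:
        if tree.is_within(a.taxid, clade_name) and tree.is_at_or_below_rank(
            a.taxid, rank
        ):
            kept.append(a)
        else:
            dropped += 1
    if dropped:
        logger.info(
            "restrict_vertebrate: %d assignment(s) above %s or outside %s "
            "excluded from profiles", dropped, rank, clade_name,
        )
    return kept


def helminth_unique_counts(
    assignments: Iterable[ReadAssignment],
    tree: TaxonomyTree,
    targets: Sequence[int],
    families: Sequence[str] = ("Taeniidae", "Toxocaridae"),
) -> dict[int, int]:
    """Reads assigned uniquely to each target parasite species.

    Only reads whose assignment node is exactly the target count; a read
    resolved to an ancestor (genus or family) supports no single species.
    Targets must be species nodes within the parasite families.
    """
    for t in targets:
        if tree.rank(t) != "species" or not any(
            tree.is_within(t, fam) for fam in families
        ):
            raise ValueError(
                f"target {t} ({tree.name(t)}) is not a species within "
                f"{'/'.join(families)}"
            )
    counts = {t: 0 for t in targets}
    for a in assignments:
        if a.taxid in counts:
            counts[a.taxid] += 1
    return counts


def assignments_to_tsv(
    assignments: Iterable[ReadAssignment], tree: TaxonomyTree
) -> str:
    lines = ["read_id\ttaxid\trank\tname\tn_tied_refs\tunique"]
    for a in assignments:
        lines.append(
            f"{a.read_id}\t{a.taxid}\t{tree.rank(a.taxid)}"
            f"\t{tree.name(a.taxid)}\t{a.n_tied_refs}\t{int(a.unique)}"
        )
    return "\n".join(lines) + "\n"
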