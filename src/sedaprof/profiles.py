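"""Per-layer faunal profiles from read assignments.

Sediment and helminth libraries from the same stratigraphic layer are
merged wholesale to raise per-layer read counts; taxa that appear at
several nested nodes but represent a single species in the data are
collapsed to that species (Bos/Bovinae → Bos and kin); relative
abundances, the vertebrate-DNA concentration (vertebrate reads per
million reads analysed) and rank tallies summarise each layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assign import ReadAssignment
from .taxonomy import TaxonomyTree

__all__ = [
    "LibraryMeta",
    "LayerProfile",
    "merge_layers",
    "default_collapse_rules",
    "collapse_taxa",
    "auto_collapse",
    "relative_abundance",
    "vertebrate_concentration",
    "rank_tally",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryMeta:
    library_id: str
    site: str
    layer: str
    culture: str = ""
    library_type: str = "sediment"  # or "helminth"
    n_reads_analysed: int = 0

    def __post_init__(self) -> None:
        if self.library_type not in ("sediment", "helminth"):
            raise ValueError(f"unknown library_type {self.library_type!r}")
        if self.n_reads_analysed < 0:
            raise ValueError("n_reads_analysed must be >= 0")


@dataclass
class LayerProfile:
    site: str
    layer: str
    counts: dict[int, int] = field(default_factory=dict)
    total_reads_analysed: int = 0
    culture: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.site, self.layer)

    def total_assigned(self) -> int:
        return sum(self.counts.values())


def counts_from_assignments(
    assignments: Iterable[ReadAssignment],
) -> dict[int, int]:
    counts: dict[int, int] = {}
    for a in assignments:
        counts[a.taxid] = counts.get(a.taxid, 0) + 1
    return counts


def merge_layers(
    per_library: Mapping[str, Iterable[ReadAssignment]],
    metas: Sequence[LibraryMeta],
) -> dict[tuple[str, str], LayerProfile]:
    """Sum assignment counts of all libraries sharing a (site, layer).

    total_reads_analysed sums each library's analysed read count, the
    denominator of the vertebrate-DNA concentration. A library without
    metadata is a hard error.
    """
    meta_by_id = {m.library_id: m for m in metas}
    profiles: dict[tuple[str, str], LayerProfile] = {}
    for lib_id, assignments in per_library.items():
        meta = meta_by_id.get(lib_id)
        if meta is None:
            raise ValueError(f"library {lib_id!r} has no layer metadata")
        key = (meta.site, meta.layer)
        prof = profiles.setdefault(
            key,
            LayerProfile(site=meta.site, layer=meta.layer, culture=meta.culture),
        )
        for taxid, n in counts_from_assignments(assignments).items():
            prof.counts[taxid] = prof.counts.get(taxid, 0) + n
        prof.total_reads_analysed += meta.n_reads_analysed
    return profiles


def default_collapse_rules(tree: TaxonomyTree) -> list[tuple[list[int], int]]:
    """The five name-keyed collapses used for display profiles.

    Bos/Bovinae → Bos; Canis, C. lupus, C. l. familiaris → C. lupus;
    Pusa, P. hispida → P. hispida; Balaenidae, B. mysticetus →
    B. mysticetus; Cervidae, Odocoileinae, R. tarandus → R. tarandus.
    Rules whose names are absent from the tree are skipped.
    """
    name_rules = [
        (["Bovinae", "Bos"], "Bos"),
        (["Canis", "Canis lupus", "Canis lupus familiaris"], "Canis lupus"),
        (["Pusa", "Pusa hispida"], "Pusa hispida"),
        (["Balaenidae", "Balaena mysticetus"], "Balaena mysticetus"),
        (["Cervidae", "Odocoileinae", "Rangifer tarandus"], "Rangifer tarandus"),
    ]
    rules = []
    for sources, target in name_rules:
        try:
            src_ids = [tree.find_name(s) for s in sources]
            tgt_id = tree.find_name(target)
        except KeyError:
            continue
        rules.append((src_ids, tgt_id))
    return rules


def collapse_taxa(
    profile: LayerProfile,
    tree: TaxonomyTree,
    rules: Sequence[tuple[Sequence[int], int]] | None = None,
) -> LayerProfile:
    """Add counts of each rule's source nodes into its target node.

    Total counts are conserved. A target that is not a descendant-or-equal
    of its sources' context warns but is still applied.
    """
    if rules is None:
        rules = default_collapse_rules(tree)
    counts = dict(profile.counts)
    for sources, target in rules:
        for src in sources:
            if src == target:
                continue
            if target not in tree.path_to_root(src) and src not in tree.path_to_root(target):
                logger.warning(
                    "collapse rule %s -> %s crosses lineages; applying anyway",
                    tree.name(src), tree.name(target),
                )
            if src in counts:
                counts[target] = counts.get(target, 0) + counts.pop(src)
    out = LayerProfile(
        site=profile.site,
        layer=profile.layer,
        counts=counts,
        total_reads_analysed=profile.total_reads_analysed,
        culture=profile.culture,
    )
    return out


def auto_collapse(profile: LayerProfile, tree: TaxonomyTree) -> LayerProfile:
    """Collapse any counted ancestor whose only counted species-or-lower
    descendant is unique, into that descendant.

    Automates the hand-written display rules: a genus or family count is
    attributed to its single represented species.
    """
    species_ranks = ("species", "subspecies")
    counted = [t for t, n in profile.counts.items() if n > 0]
    rules: list[tuple[list[int], int]] = []
    for anc in counted:
        if tree.rank(anc) in species_ranks:
            continue
        below = [
            t
            for t in counted
            if t != anc
            and tree.rank(t) in species_ranks
            and anc in tree.path_to_root(t)
        ]
        # collapse to the shallowest species-level node in the lineage
        specs = {t for t in below if tree.rank(t) == "species"} or set(below)
        if len(specs) == 1:
            rules.append(([anc], specs.pop()))
    return collapse_taxa(profile, tree, rules)


def relative_abundance(
    profile: LayerProfile, taxa: Sequence[int]
) -> dict[int, float]:
    """Fractions over the given taxon subset (sum to 1 if any counts).

    An all-zero subset returns zeros and logs a flag rather than dividing
    by zero.
    """
    total = sum(profile.counts.get(t, 0) for t in taxa)
    if total == 0:
        logger.warning(
            "relative_abundance: zero total over subset at %s/%s",
            profile.site, profile.layer,
        )
        return {t: 0.0 for t in taxa}
    return {t: profile.counts.get(t, 0) / total for t in taxa}


def vertebrate_concentration(
    profile: LayerProfile, tree: TaxonomyTree, clade_name: str = "Vertebrata"
) -> float:
    """Vertebrate DNA reads per million reads analysed."""
    if profile.total_reads_analysed <= 0:
        raise ValueError("profile has no total_reads_analysed")
    n_vert = sum(
        n for t, n in profile.counts.items() if tree.is_within(t, clade_name)
    )
    return 1e6 * n_vert / profile.total_reads_analysed


def rank_tally(
    assignments: Iterable[ReadAssignment], tree: TaxonomyTree
) -> dict[str, int]:
    """Distinct assigned nodes per rank (e.g. {species: 23, genus: 9})."""
    per_rank: dict[str, set[int]] = {}
    for a in assignments:
        per_rank.setdefault(tree.rank(a.taxid), set()).add(a.taxid)
    return {r: len(s) for r, s in sorted(per_rank.items())}


def profiles_to_frame(
    profiles: Mapping[tuple[str, str], LayerProfile], tree: TaxonomyTree
) -> pd.DataFrame:
    """Long-format table: site, layer, taxid, name, rank, count, fraction."""
    rows = []
    for prof in profiles.values():
        total = prof.total_assigned()
        for taxid, n in sorted(prof.counts.items()):
            rows.append(
                {
                    "site": prof.site,
                    "layer": prof.layer,
                    "taxid": taxid,
                    "name": tree.name(taxid),
                    "rank": tree.rank(taxid),
                    "count": n,
                    "fraction": n / total if total else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site", "layer", "taxid", "name", "rank", "count", "fraction"],
    )
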