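"""NCBI-dialect taxonomy trees and lowest-common-ancestor queries.

The taxonomy is the backbone of conservative read assignment: a read that
matches several references equally well is pushed up to the deepest node
ancestral to all of them, so ambiguity costs resolution, never accuracy.

The on-disk dialect is the NCBI taxdump one: fields separated by
``\\t|\\t``, records terminated by ``\\t|``, with ``nodes.dmp`` holding
(taxid, parent taxid, rank) and ``names.dmp`` holding (taxid, name, unique
name, name class); only ``scientific name`` rows bind names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = [
    "RANK_ORDER",
    "FAMILY_OR_LOWER",
    "TaxonomyNode",
    "TaxonomyTree",
    "parse_taxonomy",
    "parse_accession_map",
    "write_accession_map",
]

#: Controlled rank vocabulary, shallowest first.
RANK_ORDER = (
    "no rank",
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
    "subspecies",
)

#: Ranks counted as "family level or lower" when restricting profiles.
FAMILY_OR_LOWER = frozenset(
    {"family", "subfamily", "genus", "species", "subspecies"}
)


@dataclass(frozen=True)
class TaxonomyNode:
    """One taxon: identifier, parent link, rank and scientific name."""

    taxid: int
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted taxonomy supporting ancestor-path, rank and LCA queries.

    The root is its own parent, as in the NCBI dump.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        roots = [n.taxid for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        self.root: int = roots[0]
        self._validate()
        self._name_index: dict[str, list[int]] = {}
        for n in self._nodes.values():
            self._name_index.setdefault(n.name, []).append(n.taxid)

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent not in self._nodes:
                raise ValueError(
                    f"taxid {node.taxid} has dangling parent {node.parent}"
                )
        # Path-to-root termination doubles as cycle detection.
        ok: set[int] = {self.root}
        for taxid in self._nodes:
            path = []
            cur = taxid
            while cur not in ok:
                path.append(cur)
                cur = self._nodes[cur].parent
                if cur in path:
                    raise ValueError(f"cycle in taxonomy at taxid {cur}")
            ok.update(path)

    # -- basic accessors ---------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTree):
            return NotImplemented
        return self._nodes == other._nodes

    def node(self, taxid: int) -> TaxonomyNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def parent(self, taxid: int) -> int:
        return self.node(taxid).parent

    def children(self, taxid: int) -> list[int]:
        self.node(taxid)
        return [
            n.taxid
            for n in self._nodes.values()
            if n.parent == taxid and n.taxid != taxid
        ]

    def leaves(self) -> list[int]:
        parents = {n.parent for n in self._nodes.values()} - {self.root}
        parents.add(self.root)
        return sorted(t for t in self._nodes if t not in parents)

    def find_name(self, name: str) -> int:
        """Resolve a scientific name to a unique taxid; error otherwise."""
        hits = self._name_index.get(name, [])
        if not hits:
            raise KeyError(f"no node named {name!r}")
        if len(hits) > 1:
            raise KeyError(f"ambiguous name {name!r}: taxids {sorted(hits)}")
        return hits[0]

    # -- path queries ------------------------------------------------------

    def path_to_root(self, taxid: int) -> list[int]:
        """Node and all its ancestors, ordered node → root (inclusive)."""
        path = [taxid]
        cur = taxid
        while cur != self.root:
            cur = self.node(cur).parent
            path.append(cur)
        return path

    def depth(self, taxid: int) -> int:
        return len(self.path_to_root(taxid)) - 1

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a nonempty set of taxids.

        The deepest node lying on every member's root path. Commutative,
        associative and idempotent; any set containing the root maps to
        the root.
        """
        taxids = set(taxids)
        if not taxids:
            raise ValueError("lca of empty set")
        it = iter(taxids)
        common = self.path_to_root(next(it))
        for t in it:
            ancestors = set(self.path_to_root(t))
            common = [a for a in common if a in ancestors]
        return common[0]

    def is_within(self, taxid: int, ancestor_name: str) -> bool:
        """True iff the named node lies on ``taxid``'s root path (inclusive)."""
        ancestor = self.find_name(ancestor_name)
        return ancestor in self.path_to_root(taxid)

    def ranked_rank(self, taxid: int) -> str:
        """Rank of the node, or of its nearest ranked ancestor.

        NCBI trees interleave "no rank" nodes; for rank-threshold tests the
        nearest ranked ancestor decides. The root may itself be unranked,
        in which case "no rank" is returned.
        """
        for t in self.path_to_root(taxid):
            r = self.node(t).rank
            if r != "no rank":
                return r
        return "no rank"

    def is_at_or_below_rank(self, taxid: int, rank: str = "family") -> bool:
        """True iff the node's (nearest ranked) rank is ``rank`` or deeper."""
        if rank not in RANK_ORDER or rank == "no rank":
            raise ValueError(f"unknown rank {rank!r}")
        effective = self.ranked_rank(taxid)
        if effective == "no rank":
            return False
        return RANK_ORDER.index(effective) >= RANK_ORDER.index(rank)

    # -- serialization -----------------------------------------------------

    def write_dmp(self, nodes_out: IO[str], names_out: IO[str]) -> None:
        """Write the tree in nodes.dmp / names.dmp dialect."""
        for taxid in sorted(self._nodes):
            n = self._nodes[taxid]
            nodes_out.write(f"{n.taxid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
            names_out.write(
                f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n"
            )


def _dmp_fields(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def parse_taxonomy(nodes: IO[str], names: IO[str]) -> TaxonomyTree:
    """Parse nodes.dmp and names.dmp streams into a :class:`TaxonomyTree`.

    Only ``scientific name`` rows of names.dmp bind names; rows of other
    name classes (synonyms, common names, ...) are ignored. Cycles and
    dangling parents are hard errors naming the offending taxid.
    """
    sci_names: dict[int, str] = {}
    for line in names:
        if not line.strip():
            continue
        fields = _dmp_fields(line)
        if len(fields) >= 4 and fields[3].strip() == "scientific name":
            sci_names[int(fields[0])] = fields[1].strip()
    nodes_list = []
    for line in nodes:
        if not line.strip():
            continue
        fields = _dmp_fields(line)
        taxid = int(fields[0])
        nodes_list.append(
            TaxonomyNode(
                taxid=taxid,
                parent=int(fields[1]),
                rank=fields[2].strip(),
                name=sci_names.get(taxid, ""),
            )
        )
    return TaxonomyTree(nodes_list)


def parse_accession_map(stream: IO[str], tree: TaxonomyTree | None = None) -> dict[str, int]:
    """Read a 2-column accession→taxid TSV.

    Keys are strings so deprecated gi numbers pass through unchanged. When
    a tree is given, every mapped taxid must exist in it.
    """
    mapping: dict[str, int] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        acc, taxid_s = line.split("\t")[:2]
        taxid = int(taxid_s)
        if tree is not None and taxid not in tree:
            raise ValueError(f"accession {acc} maps to unknown taxid {taxid}")
        mapping[acc] = taxid
    return mapping


def write_accession_map(mapping: dict[str, int], stream: IO[str]) -> None:
    for acc in sorted(mapping):
        stream.write(f"{acc}\t{mapping[acc]}\n")
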