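"""Synthetic sediment-DNA libraries with known ground truth.

Real midden shotgun data mixes short, deaminated fragments from many
vertebrate and helminth taxa with PCR duplicates and low-complexity junk.
This module builds a desk-scale counterpart — a toy taxonomy modelled on
the NCBI dump, a panel of pseudo-random "mitogenomes" (one per species or
subspecies leaf), and read libraries with planted 5′ C→T deamination — so
every downstream stage can be tested against a truth table instead of a
two-billion-read archive.

The damage model is the single-stranded-overhang signature only: a C at
5′ position p (1-based) reads as T with probability d1 · decay^(p−1).
The mirrored 3′ G→A signal can be switched on but is off by default, as
the downstream estimator quantifies the 5′ side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .taxonomy import TaxonomyNode, TaxonomyTree

__all__ = [
    "SimConfig",
    "TruthRow",
    "make_toy_taxonomy",
    "make_reference_panel",
    "parse_fasta",
    "simulate_library",
    "truth_to_tsv",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of one simulated library.

    mixture maps leaf taxids to source proportions (must sum to 1);
    damage_d1 is the C→T probability at 5′ position 1 and damage_decay the
    per-position geometric factor; dup_frac of the emitted reads are exact
    copies of earlier reads; lowcomplex_frac are replaced by homopolymer or
    dinucleotide repeats (contaminants, absent from the truth table).
    """

    seed: int
    n_reads: int
    mixture: dict[int, float]
    frag_len_mean: float = 60.0
    frag_len_sd: float = 15.0
    damage_d1: float = 0.0
    damage_decay: float = 0.3
    seq_error: float = 0.0
    dup_frac: float = 0.0
    lowcomplex_frac: float = 0.0
    damage_3p_ga: bool = False

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if any(p < 0 for p in self.mixture.values()):
            raise ValueError("mixture proportions must be nonnegative")
        if self.mixture and abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        for name in ("damage_d1", "seq_error", "dup_frac", "lowcomplex_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.damage_decay < 1.0:
            raise ValueError("damage_decay must be in (0, 1)")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one emitted read (contaminants have no row)."""

    read_id: str
    source_taxid: int
    source_accession: str
    ref_start: int  # 0-based start on the forward reference strand
    strand: str  # "+" or "-"
    damaged_positions: tuple[int, ...]  # 1-based 5′ positions that were C→T'd


# ---------------------------------------------------------------------------
# Toy taxonomy
# ---------------------------------------------------------------------------

# (taxid, parent, rank, name) — mammal prey taxa of a Greenlandic midden plus
# the two host-diagnostic helminth families. Vertebrata is an unranked clade
# as in the NCBI dump.
_TOY_NODES = [
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Eukaryota"),
    (3, 2, "kingdom", "Metazoa"),
    (4, 3, "phylum", "Chordata"),
    (5, 4, "no rank", "Vertebrata"),
    (6, 5, "class", "Mammalia"),
    # orders
    (10, 6, "order", "Artiodactyla"),
    (11, 6, "order", "Carnivora"),
    # families
    (20, 10, "family", "Balaenidae"),
    (21, 10, "family", "Monodontidae"),
    (22, 10, "family", "Cervidae"),
    (23, 10, "family", "Bovidae"),
    (24, 11, "family", "Phocidae"),
    (25, 11, "family", "Odobenidae"),
    (26, 11, "family", "Canidae"),
    # subfamilies
    (30, 23, "subfamily", "Bovinae"),
    (31, 22, "subfamily", "Odocoileinae"),
    # genera
    (40, 20, "genus", "Balaena"),
    (41, 21, "genus", "Monodon"),
    (42, 31, "genus", "Rangifer"),
    (43, 30, "genus", "Bos"),
    (44, 24, "genus", "Pagophilus"),
    (45, 24, "genus", "Pusa"),
    (46, 25, "genus", "Odobenus"),
    (47, 26, "genus", "Canis"),
    # species
    (50, 40, "species", "Balaena mysticetus"),
    (51, 41, "species", "Monodon monoceros"),
    (52, 42, "species", "Rangifer tarandus"),
    (53, 43, "species", "Bos taurus"),
    (54, 44, "species", "Pagophilus groenlandicus"),
    (55, 45, "species", "Pusa hispida"),
    (56, 46, "species", "Odobenus rosmarus"),
    (57, 47, "species", "Canis lupus"),
    # subspecies
    (60, 57, "subspecies", "Canis lupus familiaris"),
    (61, 57, "subspecies", "Canis lupus lupus"),
    # helminths: tapeworms (Taeniidae) and roundworms (Toxocaridae)
    (70, 3, "phylum", "Platyhelminthes"),
    (71, 70, "class", "Cestoda"),
    (72, 71, "order", "Cyclophyllidea"),
    (73, 72, "family", "Taeniidae"),
    (74, 73, "genus", "Taenia"),
    (75, 73, "genus", "Echinococcus"),
    (76, 74, "species", "Taenia hydatigena"),
    (77, 74, "species", "Taenia multiceps"),
    (78, 75, "species", "Echinococcus canadensis"),
    (80, 3, "phylum", "Nematoda"),
    (81, 80, "class", "Chromadorea"),
    (82, 81, "order", "Ascaridida"),
    (83, 82, "family", "Toxocaridae"),
    (84, 83, "genus", "Toxocara"),
    (85, 84, "species", "Toxocara canis"),
    (86, 84, "species", "Toxocara cati"),
]


def make_toy_taxonomy() -> TaxonomyTree:
    """Build the fixed toy taxonomy used throughout the test suite.

    Mirrors the structure of an NCBI subtree: root → Metazoa → Chordata →
    Vertebrata → Mammalia with 7 families, 8 genera, 8 species and 2 wolf
    subspecies, plus the helminth families Taeniidae (3 species) and
    Toxocaridae (2 species).
    """
    return TaxonomyTree(
        TaxonomyNode(taxid=t, parent=p, rank=r, name=n)
        for (t, p, r, n) in _TOY_NODES
    )


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _accession_for(tree: TaxonomyTree, taxid: int) -> str:
    name = tree.name(taxid).replace(" ", "_")
    return f"MT_{taxid:04d}_{name}"


def make_reference_panel(
    tree: TaxonomyTree, seq_len: int = 1000, seed: int = 0
) -> tuple[str, dict[str, int]]:
    """One pseudo-random reference per species/subspecies leaf.

    Returns (FASTA text, accession→taxid map). Leaves sharing a genus get a
    planted identical backbone over the first 30% of the sequence, so reads
    from that region genuinely hit several references equally well and
    exercise the LCA path; outside the backbone, sequences are independent,
    keeping every pair at Hamming distance well above 10% of the length.
    """
    if seq_len < 200:
        raise ValueError("seq_len must be >= 200")
    leaves = tree.leaves()
    if not leaves:
        raise ValueError("tree has no leaves")
    rng = np.random.default_rng(seed)

    # group leaves by their ancestor genus (or by themselves if none)
    def genus_of(taxid: int) -> int:
        for t in tree.path_to_root(taxid):
            if tree.rank(t) == "genus":
                return t
        return taxid

    groups: dict[int, list[int]] = {}
    for leaf in leaves:
        groups.setdefault(genus_of(leaf), []).append(leaf)

    backbone_len = int(round(0.30 * seq_len))
    seqs: dict[int, str] = {}
    for genus in sorted(groups):
        members = sorted(groups[genus])
        backbone = rng.choice(_BASES, size=backbone_len)
        for leaf in members:
            tail = rng.choice(_BASES, size=seq_len - backbone_len)
            if len(members) > 1:
                seq = np.concatenate([backbone, tail])
            else:
                seq = np.concatenate([rng.choice(_BASES, size=backbone_len), tail])
            seqs[leaf] = seq.tobytes().decode()

    # enforce pairwise distinguishability (random pairs sit near 75%
    # mismatch outside shared backbones, so this never fires in practice)
    min_dist = int(math.ceil(0.10 * seq_len))
    taxids = sorted(seqs)
    for i, a in enumerate(taxids):
        for b in taxids[i + 1 :]:
            d = sum(x != y for x, y in zip(seqs[a], seqs[b]))
            if d < min_dist:
                raise RuntimeError(
                    f"panel degenerate: leaves {a},{b} at Hamming {d}"
                )

    records = []
    acc_map: dict[str, int] = {}
    for leaf in taxids:
        acc = _accession_for(tree, leaf)
        acc_map[acc] = leaf
        records.append(f">{acc}\n{seqs[leaf]}\n")
    return "".join(records), acc_map


def parse_fasta(text: str) -> dict[str, str]:
    """Minimal FASTA text → {accession: sequence} (first token of header)."""
    seqs: dict[str, str] = {}
    acc = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if acc is not None:
                seqs[acc] = "".join(chunks)
            acc = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip().upper())
    if acc is not None:
        seqs[acc] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------


def _truncated_normal_len(rng: np.random.Generator, mean: float, sd: float,
                          lo: int, hi: int) -> int:
    while True:
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x


def _lowcomplex_seq(rng: np.random.Generator, length: int) -> str:
    if rng.random() < 0.5:
        base = chr(rng.choice(_BASES).item()[0])
        return base * length
    a, b = rng.choice(_BASES, size=2, replace=False)
    unit = (a + b).decode()
    return (unit * (length // 2 + 1))[:length]


def simulate_library(
    cfg: SimConfig,
    panel_fasta: str,
    acc_map: dict[str, int],
) -> tuple[str, list[TruthRow]]:
    """Draw a shotgun library from the panel under ``cfg``.

    Per read: source leaf from the mixture, fragment length from a
    truncated normal (floor 25 nt, capped at the reference length), start
    uniform, strand uniform; 5′ C→T damage, then uniform sequencing error;
    finally dup_frac of the emitted reads are replaced by verbatim copies
    of earlier reads and lowcomplex_frac by repeat contaminants.

    Returns (FASTQ text, truth rows). Base qualities are constant Q37 —
    quality information plays no role downstream.
    """
    seqs = parse_fasta(panel_fasta)
    taxid_to_acc = {t: a for a, t in acc_map.items()}
    for taxid in cfg.mixture:
        if taxid not in taxid_to_acc:
            raise ValueError(f"mixture taxid {taxid} absent from panel")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    if n == 0:
        return "", []

    taxids = sorted(cfg.mixture)
    probs = np.array([cfg.mixture[t] for t in taxids], dtype=float)
    probs = probs / probs.sum()

    n_dup = int(round(cfg.dup_frac * n))
    n_low = int(round(cfg.lowcomplex_frac * n))
    n_orig = n - n_dup - n_low
    if n_orig < 0:
        raise ValueError("dup_frac + lowcomplex_frac leave no original reads")

    fastq: list[str] = []
    truth: list[TruthRow] = []
    originals: list[tuple[str, TruthRow]] = []

    for i in range(n_orig):
        taxid = int(rng.choice(np.asarray(taxids), p=probs))
        acc = taxid_to_acc[taxid]
        ref = seqs[acc]
        flen = _truncated_normal_len(
            rng, cfg.frag_len_mean, cfg.frag_len_sd, 25, len(ref)
        )
        start = int(rng.integers(0, len(ref) - flen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = ref[start : start + flen]
        if strand == "-":
            frag = revcomp(frag)
        bases = list(frag)
        damaged: list[int] = []
        # 5′ C→T deamination with geometric positional decay
        if cfg.damage_d1 > 0:
            for p in range(1, flen + 1):
                rate = cfg.damage_d1 * cfg.damage_decay ** (p - 1)
                if rate < 1e-12:
                    break
                if bases[p - 1] == "C" and rng.random() < rate:
                    bases[p - 1] = "T"
                    damaged.append(p)
        if cfg.damage_3p_ga and cfg.damage_d1 > 0:
            for q in range(1, flen + 1):
                rate = cfg.damage_d1 * cfg.damage_decay ** (q - 1)
                if rate < 1e-12:
                    break
                if bases[flen - q] == "G" and rng.random() < rate:
                    bases[flen - q] = "A"
        if cfg.seq_error > 0:
            for j in range(flen):
                if rng.random() < cfg.seq_error:
                    others = [b for b in "ACGT" if b != bases[j]]
                    bases[j] = others[int(rng.integers(0, 3))]
        seq = "".join(bases)
        read_id = f"read_{i:07d}"
        row = TruthRow(read_id, taxid, acc, start, strand, tuple(damaged))
        originals.append((seq, row))
        truth.append(row)
        fastq.append(f"@{read_id}\n{seq}\n+\n{'F' * flen}\n")

    for k in range(n_dup):
        src_seq, src_row = originals[int(rng.integers(0, len(originals)))]
        read_id = f"dup_{k:07d}"
        truth.append(
            TruthRow(
                read_id,
                src_row.source_taxid,
                src_row.source_accession,
                src_row.ref_start,
                src_row.strand,
                src_row.damaged_positions,
            )
        )
        fastq.append(f"@{read_id}\n{src_seq}\n+\n{'F' * len(src_seq)}\n")

    for k in range(n_low):
        flen = _truncated_normal_len(rng, cfg.frag_len_mean, cfg.frag_len_sd,
                                     25, 10_000)
        seq = _lowcomplex_seq(rng, flen)
        fastq.append(f"@lowc_{k:07d}\n{seq}\n+\n{'F' * flen}\n")

    return "".join(fastq), truth


def truth_to_tsv(truth: list[TruthRow]) -> str:
    lines = ["read_id\tsource_taxid\tsource_accession\tref_start\tstrand\tdamaged_positions"]
    for r in truth:
        pos = ",".join(map(str, r.damaged_positions))
        lines.append(
            f"{r.read_id}\t{r.source_taxid}\t{r.source_accession}"
            f"\t{r.ref_start}\t{r.strand}\t{pos}"
        )
    return "\n".join(lines) + "\n"
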