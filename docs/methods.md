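# Methods

## The profiling model

`sedaprof` quantifies which vertebrates (and which of their helminth
parasites) contributed DNA to archaeological sediment layers. The chain
of inference is:

1. **Read filtering.** Collapsed shotgun reads are cleaned by three
   bespoke filters: exact-duplicate removal (two reads are duplicates iff
   they have the same sequence and the same length — strand-naive and
   quality-blind, so a reverse complement survives), a minimum-length
   filter (< 25 nt discarded; a 25-mer is kept), and a DUST-style
   low-complexity filter (reads scoring > 1 discarded; exactly 1 kept).
2. **Alignment.** Reads are aligned to a panel of mitochondrial
   references whose headers carry taxonomic identifiers. Alignments with
   edit distance (NM) strictly above 5% of the read length are discarded;
   equality passes. "Equally good" is defined on edit distance, not on a
   mapper-specific alignment score.
3. **LCA assignment.** A read with one best reference is assigned to that
   reference's taxon; a read tied across several references is assigned
   to the lowest common ancestor of their taxa. Ambiguity moves a read
   *up* the taxonomy instead of forcing a guess. Multiple hits to one
   reference collapse to a single vote so long references cannot
   dominate ties.
4. **Profiles.** Sediment and helminth libraries from the same
   stratigraphic layer are merged wholesale. For display, nested taxa
   represented by a single species are collapsed to that species
   (Bos/Bovinae → Bos; Canis, C. lupus, C. l. familiaris → C. lupus;
   Pusa → P. hispida; Balaenidae → B. mysticetus; Cervidae/Odocoileinae →
   R. tarandus), with an automatic mode that generalises the rule.
   Vertebrate profiles admit only assignments within Vertebrata resolved
   to family level or lower; the vertebrate DNA concentration is
   vertebrate reads per million reads analysed. Parasite evidence is
   counted per species from reads assigned *exactly* to that species.
5. **Damage authentication.** Post-mortem cytosine deamination is read as
   C→T at the 5′ terminus. For a taxon's reads (one deterministically
   chosen best alignment each), among reads whose reference base at 5′
   position 1 is C, the estimate is the fraction reading T. Estimates are
   reported only at ≥ 500 supporting reads (binomial noise dominates
   below that).
6. **Ordination and correlation.** Layer profiles are compared by
   Bray–Curtis dissimilarity (1 − 2Σmin/(Σu+Σv)) and embedded in 2-D by
   non-metric MDS minimising Kruskal stress-1. DNA read counts are
   Pearson-correlated against zooarchaeological columns (NISP or expected
   biomass) over the shared species, on raw counts by default (a log
   option exists). MNI counts from a partial excavation scale by
   round(1/excavated_fraction, 1) — 8.7% excavated gives factor 11.5.
7. **Consensus.** Reads assigned to one taxon are piled up on its
   reference; each position takes the majority base, ties and uncovered
   positions call N (avoiding reference bias); mean depth is aligned
   bases per reference position.

## Synthetic data: what it emulates, and what it does not

The generator produces the data structures the pipeline assumes with a
known truth table: a toy NCBI-dialect taxonomy (mammalian midden fauna of
Greenland plus the tapeworm and roundworm families, 51 nodes), one
pseudo-random reference per species/subspecies leaf, and read libraries
with:

- fragment lengths from a truncated normal (mean 60 nt, sd 15, floor
  25 nt — typical collapsed aDNA fragments; the pipeline discards < 25);
- 5′ C→T deamination at position p with probability d1 · decay^(p−1)
  (single-stranded-overhang signature; the mirrored 3′ G→A channel can be
  enabled but is off by default since the estimator quantifies the 5′
  side);
- uniform per-base sequencing error (default 10⁻³);
- a fraction of verbatim duplicate reads and of homopolymer/dinucleotide
  contaminants (the latter carry no truth rows);
- congeneric references share an identical 30% backbone so genuinely
  ambiguous reads occur and exercise the LCA path.

Not emulated: indel-type damage, realistic phylogenetic sequence
divergence (references are random sequences), chimeras, quality-score
variation (constant Q37), and environmental background DNA beyond the
low-complexity contaminants. Passing tests therefore demonstrate the
*pipeline logic* — filtering arithmetic, assignment correctness,
estimator calibration — not robustness to evolutionary divergence between
a sample and its nearest reference.

## Numerical and design choices

- **DUST score.** Over each sliding window of length w = min(64, len):
  triplet counts c_t over the 64 trinucleotides (triplets containing N
  skipped), window score Σ c_t(c_t−1)/2 / (w − 3), read score the max
  over windows. A 64-nt homopolymer scores 31.0; a uniform random 64-mer
  almost surely scores ≪ 1. This normalisation is our fixed choice; the
  package guarantees internal bit-for-bit reproducibility rather than
  parity with any particular external implementation.
- **Canonical alignments.** Edit distance admits cost-equal
  representations of a terminal mismatch as a terminal gap. The
  exhaustive aligner (edlib's infix mode under the hood, banded at the
  5% threshold) rewrites any gapped CIGAR with a small infix DP whose
  traceback prefers substitutions over gaps and ends at the rightmost
  minimal column. Without this, reads whose 5′ base is deaminated can be
  represented with a terminal insertion and silently vanish from the
  position-1 damage tally, biasing the estimate low by a factor ~2.
- **Coordinates.** 0-based half-open internally; 1-based inclusive at
  SAM boundaries. Soft-clipped bases count toward read length for the 5%
  rule. Reads whose alignment starts with an insertion or soft-clip at
  the 5′ end are excluded from position-1 damage tallies (no reference
  base is paired there). Ties among best hits are broken for damage and
  consensus geometry by lexicographically smallest (accession, strand,
  start) — reproducibility, not biology.
- **NMDS.** Stress-1 with primary tie handling in the isotonic
  regression; default 20 restarts, the first initialised from the
  classical (Torgerson) metric solution and the rest random. Among
  restarts whose stress ties within max(10⁻⁴, 1% of the best), the
  configuration whose Shepard plot is most linear is returned: with few,
  tightly clustered profiles non-metric stress admits degenerate
  zero-stress layouts that only preserve rank order, and the metric
  tie-break keeps the embedding faithful to the dissimilarity
  magnitudes.
- **Rank thresholds.** "No rank" nodes (e.g. the Vertebrata clade) defer
  to their nearest ranked ancestor when testing "family level or lower".
- **Accession maps** are string-keyed; deprecated gi integers pass
  through as strings. Reads hitting references absent from the map are
  dropped with a logged count.
- **Consensus** requires depth ≥ 1 by default (configurable); deletions
  leave positions unobserved; insertions are ignored in consensus
  coordinates.
- **Problem sizes.** Qualitative tests run on 1,000-nt references —
  fast, and every contract is length-independent. Quantitative
  abundance-recovery experiments (50,000 reads at the five-species
  mixture) use 12,000-nt references, i.e. mitogenome scale: with 1-kb
  toys the per-species coverage reaches ~1,500× and the exact-duplicate
  filter starts removing genuinely distinct fragments that collide by
  chance, a regime real libraries (~1–25× per species) never enter.
  Damage calibration uses 10,000 reads per rate over the 0–13% grid;
  ordination checks use six 400-read layers from two planted faunas.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_len` | 25 nt | shortest read retained |
| `dust_max` | 1.0 | maximum low-complexity score retained |
| `edit_frac` | 0.05 | maximum edit distance as a fraction of read length |
| `damage_min_reads` | 500 | reads required before a damage estimate is reported |
| `damage_d1` | — | C→T probability at 5′ position 1 (simulator) |
| `damage_decay` | 0.3 | per-position geometric decay of the damage rate |
| `frag_len_mean`, `frag_len_sd` | 60, 15 nt | fragment-length distribution |
| `restarts` (NMDS) | 20 | random restarts; best stress kept |

The filter defaults are the pipeline's published operating point and are
asserted as such in the test suite.

## Known limitations

- The exhaustive aligner is O(reads × references × length) and intended
  for desk-scale panels (thousands of reads × dozens of references); real
  datasets should be mapped externally and ingested as SAM.
- Damage estimation pools reads across tied references after a
  deterministic choice; whether pooling across ties biases estimates for
  heavily ambiguous taxa is flagged, not resolved.
- Reads are single-end and collapsed; paired-end handling, adapter and
  quality trimming are out of scope and assumed done upstream.
- Merged/deleted-node handling of full NCBI dumps is not implemented; the
  parser expects a consistent dump.
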