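# sedaprof

Taxonomic profiling of sedimentary ancient DNA (sedaDNA) from
archaeological middens — for researchers who want to reconstruct past
subsistence economies from the DNA left in refuse layers rather than
from bones alone.

Shotgun reads from sediment are a mixture of short (~30–100 nt),
terminally deaminated fragments from every organism whose tissue,
excreta or bone touched the deposit. `sedaprof` turns such libraries
into per-layer faunal profiles:

- **Filtering** — exact-duplicate removal (same sequence, same length),
  minimum length 25 nt, DUST low-complexity score ≤ 1.
- **Alignment** — against a taxid-tagged mitochondrial reference panel;
  hits with edit distance > 5% of read length are discarded. SAM from an
  external mapper is ingested directly; a built-in exhaustive aligner
  handles desk-scale panels.
- **LCA assignment** — a read with a single best hit is assigned to that
  taxon; a read tied across references goes to the lowest common
  ancestor of their taxa, so ambiguity costs resolution, never accuracy.
  Vertebrate profiles keep assignments at family level or lower within
  Vertebrata; parasite evidence counts reads assigned uniquely to each
  helminth species.
- **Authentication** — per-taxon frequency of C→T at the 5′ terminus
  (cytosine deamination), reported for taxa with ≥ 500 reads.
- **Comparison** — Bray–Curtis dissimilarity + non-metric MDS across
  layers (Kruskal stress-1); Pearson correlation of read counts against
  bone counts (NISP) or expected biomass; MNI scaling from partially
  excavated deposits (8.7% excavated → factor 11.5).
- **Consensus** — majority-rule mitogenome from the reads of one taxon,
  with coverage depth.
- **Synthetic data** — a first-class simulator (toy NCBI-dialect
  taxonomy, reference panel, damaged read libraries with truth tables)
  so every stage is testable without downloads.

## Worked example

`examples/simulate_and_profile.py` simulates a Saqqaq-layer-like library
(4,000 reads, five marine-mammal species, 10% terminal deamination, 10%
PCR duplicates, 2% low-complexity contaminants), filters, aligns,
assigns and profiles it:

```
reads in: 4000   after duplicate/length/DUST filters: 3507
assigned: 3506 reads (0 unassigned, 0 unmapped hits)

species                       planted  recovered
Balaena mysticetus              49.2%      48.1%
Pagophilus groenlandicus        24.2%      25.9%
Rangifer tarandus               18.8%      18.8%
Odobenus rosmarus                5.2%       4.9%
Monodon monoceros                2.6%       2.4%
```

The recovered relative abundances track the planted mixture within
binomial sampling noise. The other examples each exercise one
capability: `damage_authentication.py` (an ancient library shows 10.8%
C→T at 5′ position 1 decaying inward, a modern one 0.0%),
`ordination_of_cultures.py` (marine vs domestic faunas separate cleanly
in NMDS space, stress ≈ 0.0001), `biomass_correlation.py` (read counts
drawn proportional to biomass give rho = 1.00; raw bone counts do not),
and `consensus_mitogenome.py` (a ~6× library reassembles its source at
100% identity where depth ≥ 3).

A command-line layer wraps the same functions:

```bash
sedaprof simulate --seed 4 --n-reads 5000 \
    --mixture "Balaena mysticetus=0.6,Pusa hispida=0.4" --outdir sim/
sedaprof preprocess sim/reads.fastq sim/clean.fastq --report sim/filters.tsv
sedaprof align sim/clean.fastq sim/panel.fasta sim/hits.sam
sedaprof assign sim/hits.sam sim/acc2taxid.tsv sim/nodes.dmp sim/names.dmp sim/assignments.tsv
sedaprof run-all --config config.yaml   # the whole pipeline from YAML
```

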