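# Full-pipeline configuration for `sedaprof run-all --config pipeline_config.yaml`.
# Simulates four libraries across three sites, filters/aligns/assigns them,
# builds per-layer profiles, estimates damage, ordinates the layers and
# assembles a bowhead consensus. All outputs land in `output_dir`.
seed: 11
output_dir: sedaprof_out
panel_seq_len: 1000
filters:
  min_len: 25        # discard fragments shorter than 25 nt
  dust_max: 1.0      # discard low-complexity reads scoring above 1
  edit_frac: 0.05    # discard alignments above 5% of read length
  damage_min_reads: 500
consensus_taxon: Balaena mysticetus
nmds_restarts: 20
biomass:             # expected biomass (kg) for the correlation stage
  Balaena mysticetus: 4000
  Pagophilus groenlandicus: 1500
  Rangifer tarandus: 900
  Odobenus rosmarus: 300
libraries:
  - library_id: QT1_sed
    site: Qeqertasussuk
    layer: L1
    culture: Saqqaq
    library_type: sediment
    n_reads: 1500
    mixture:
      Balaena mysticetus: 0.49
      Pagophilus groenlandicus: 0.25
      Rangifer tarandus: 0.19
      Odobenus rosmarus: 0.05
      Monodon monoceros: 0.02
    damage_d1: 0.10
    dup_frac: 0.05
    lowcomplex_frac: 0.02
  - library_id: QT1_helm
    site: Qeqertasussuk
    layer: L1
    culture: Saqqaq
    library_type: helminth
    n_reads: 400
    mixture:
      Taenia hydatigena: 0.6
      Toxocara canis: 0.4
    damage_d1: 0.08
  - library_id: SN1_sed
    site: Sandnes
    layer: N1
    culture: Norse
    n_reads: 1000
    mixture:
      Bos taurus: 0.7
      Pusa hispida: 0.2
      Rangifer tarandus: 0.1
    damage_d1: 0.02
  - library_id: FL1_sed
    site: Fladstrand
    layer: F1
    culture: Thule
    n_reads: 1000
    mixture:
      Canis lupus familiaris: 0.76
      Pagophilus groenlandicus: 0.14
      Monodon monoceros: 0.10
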