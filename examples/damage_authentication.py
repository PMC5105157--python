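"""Authenticate ancient DNA by its 5′ C→T deamination signature.

Simulates an "ancient" library (10% terminal deamination) and a "modern"
one (no damage), estimates the C→T frequency at the 5′ terminus for each,
and prints the positional decay profile that distinguishes them.
"""

from sedaprof import (
    SimConfig,
    align_library,
    best_hits,
    choose_damage_hit,
    ct_frequency,
    make_reference_panel,
    make_toy_taxonomy,
    reads_from_fastq,
    simulate_library,
)
from sedaprof.simulate import parse_fasta

tree = make_toy_taxonomy()
fasta, acc_map = make_reference_panel(tree, seq_len=1000, seed=7)
panel = parse_fasta(fasta)
bowhead = {tree.find_name("Balaena mysticetus"): 1.0}

for label, d1 in (("ancient (d1=0.10)", 0.10), ("modern  (d1=0.00)", 0.00)):
    cfg = SimConfig(seed=11, n_reads=3000, mixture=bowhead,
                    damage_d1=d1, seq_error=0.001)
    fastq, _ = simulate_library(cfg, fasta, acc_map)
    reads = {r.read_id: r for r in reads_from_fastq(fastq)}
    hits = align_library(reads.values(), panel)
    chosen = [choose_damage_hit(best_hits(h)) for h in hits.values()]
    est = ct_frequency(chosen, reads, panel, taxon="Balaena mysticetus")
    prof = "  ".join(f"{100 * f:4.1f}" for f in est.profile[:5])
    print(f"{label}: n={est.n_reads_used}  "
          f"C→T at 5′ position 1 = {100 * est.freq_ct_pos1:.1f}%")
    print(f"  positions 1-5 (%): {prof}")

print("\nThe ancient library shows an elevated terminal C→T rate decaying "
      "inward; the modern one sits at the sequencing-error background. "
      "Estimates are only reported for taxa with ≥500 supporting reads.")
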