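"""Correlate DNA read counts with the zooarchaeological bone record.

Scales minimum-number-of-individuals (MNI) counts from a partial
excavation to the whole deposit, then correlates synthetic per-species
DNA read counts against expected biomass (reads drawn proportional to
biomass) and against raw bone counts (NISP, uncorrelated with soft-tissue
input), mirroring how the two proxies behave.
"""

import numpy as np

from sedaprof import correlate_profiles, scale_mni

# an ~8.7% excavated sample scales to the full midden by 1/0.087 -> 11.5
mni = {"harp seal": 84, "ringed seal": 31, "fox": 12, "birds": 40}
scaled, factor = scale_mni(mni, excavated_fraction=0.087)
print(f"MNI scaling factor for an 8.7% excavated sample: {factor}")
print(f"scaled MNI: { {k: round(v, 1) for k, v in scaled.items()} }\n")

rng = np.random.default_rng(5)
biomass = {"harp seal": 2400.0, "ringed seal": 900.0, "caribou": 700.0,
           "bowhead whale": 5200.0, "walrus": 1100.0, "fox": 40.0}
total = sum(biomass.values())
reads = rng.multinomial(25_000, [v / total for v in biomass.values()])
dna_counts = {k: int(n) for k, n in zip(biomass, reads)}

nisp = {"harp seal": 4200, "ringed seal": 3900, "caribou": 310,
        "bowhead whale": 3, "walrus": 25, "fox": 880}

bio = correlate_profiles(dna_counts, biomass)
bone = correlate_profiles(dna_counts, nisp)
print(f"DNA reads vs expected biomass: rho={bio.rho:.2f}  "
      f"p={bio.p_two_sided:.2g}  n={bio.n}")
print(f"DNA reads vs raw bone counts:  rho={bone.rho:.2f}  "
      f"p={bone.p_two_sided:.2g}  n={bone.n}")
print("\nRead counts track biomass (soft tissue contributes DNA but no "
      "bones), while raw NISP — dominated by well-preserved small bones — "
      "correlates weakly.")
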