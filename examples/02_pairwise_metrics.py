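"""Compute ANI, TETRA and AAI for genome pairs and read them as a biologist would.

Same-species pairs sit above all three thresholds (ANI > 95, TETRA > 0.99,
AAI > 95); different species fall below on ANI/AAI while TETRA degrades
more slowly — exactly the pattern the triple criterion exploits.
"""

from cladepan import SimulationConfig, compute_all_pairs, simulate_clade

config = SimulationConfig(seed=2, n_species=3, strains_per_species=2,
                          root_family_count=160, gain_rate=60, loss_rate=20)
records, truth = simulate_clade(config)
table = compute_all_pairs(records)

print(f"{'pair':<18}{'ANI':>8}{'TETRA':>9}{'AAI':>8}  relationship")
for a, b in table.pairs():
    m = table.get(a, b)
    kind = "same species" if truth.species_of[a] == truth.species_of[b] else "different"
    print(f"{a}-{b:<10}{m.ani:>8.2f}{m.tetra:>9.4f}{m.aai:>8.2f}  {kind}")
# ANI ~99 / TETRA ~0.998 / AAI ~98 within species; ANI drops to the
# 80s between species while TETRA stays in the 0.95-0.99 range.
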