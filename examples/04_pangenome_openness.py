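"""Pangenome structure, rarefaction and the open/closed verdict.

An infinite pool of novel genes (every gain is a fresh family) keeps the
new-genes curve decaying slower than 1/N (alpha < 1: open); a finite gene
catalogue is exhausted quickly (alpha > 1: closed). The open/closed
contrast is shown on the simulator's true presence/absence matrix, which
isolates the sampling process from protein-clustering effects; the last
block then runs the full protein-level route.
"""

import pandas as pd

from cladepan import (OrthogroupMatrix, SimulationConfig, categorize,
                      cluster_orthogroups, fit_openness, frequency_histogram,
                      per_genome_rates, rarefaction, simulate_clade)
from cladepan.simulate import simulate_gene_content, simulate_species_tree


def truth_matrix(truth):
    leaves = truth.tree.leaf_names()
    fams = sorted(set().union(*(truth.node_families[l] for l in leaves)))
    frame = pd.DataFrame(
        [[1 if f in truth.node_families[l] else 0 for l in leaves] for f in fams],
        index=fams, columns=leaves,
    )
    return OrthogroupMatrix(frame, {})


for label, pool in (("infinite gene pool", "infinite"), ("finite pool of 450", 450)):
    config = SimulationConfig(seed=4, n_species=16, strains_per_species=1,
                              root_family_count=300, gain_rate=400, loss_rate=100,
                              novel_pool=pool)
    tree = simulate_species_tree(config)
    truth = simulate_gene_content(tree, config)
    matrix = truth_matrix(truth)
    curves = rarefaction(matrix, n_permutations=200, seed=4)
    fit = fit_openness(curves)
    print(f"{label}: {matrix.n_families} families,"
          f" alpha = {fit.alpha:.3f} -> {'open' if fit.open else 'closed'}")

# full protein-level route on an infinite-pool clade
config = SimulationConfig(seed=4, n_species=16, strains_per_species=1,
                          root_family_count=222, gain_rate=300, loss_rate=100)
records, _ = simulate_clade(config)
matrix = cluster_orthogroups({r.genome_id: r.proteins for r in records})
summary = categorize(matrix)
curves = rarefaction(matrix, n_permutations=200, seed=4)
fit = fit_openness(curves)
pan_gain, core_loss = per_genome_rates(curves, fit)
_, mean_shared = frequency_histogram(matrix)
print("protein-level clustering (infinite pool):")
print(f"  core/soft-core/shell/cloud = {summary.core}/{summary.soft_core}"
      f"/{summary.shell}/{summary.cloud} of {summary.total}")
print(f"  alpha = {fit.alpha:.3f} -> {'open' if fit.open else 'closed'};"
      f" ~{pan_gain:.1f} new families per genome at N_max,"
      f" {core_loss:.2f} core lost per genome")
# Note: at genus-scale divergence the 80%-identity clustering splits deep
# families between species (as identity-threshold tools do), which lowers
# the core count and steepens nothing -- the openness verdict is robust.
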