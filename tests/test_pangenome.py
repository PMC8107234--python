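import numpy as np
import pandas as pd
import pytest

from cladepan.pangenome import (
    OrthogroupMatrix,
    RarefactionCurves,
    categorize,
    cluster_orthogroups,
    fit_openness,
    frequency_histogram,
    module_completeness,
    per_genome_rates,
    rarefaction,
)


def _matrix(frame):
    return OrthogroupMatrix(frame, {})


def _random_presence(rng, n_fam, n_gen):
    data = (rng.random((n_fam, n_gen)) < rng.random((n_fam, 1))).astype(int)
    data[data.sum(axis=1) == 0, 0] = 1
    return _matrix(
        pd.DataFrame(data, index=[f"F{i}" for i in range(n_fam)], columns=[f"g{j}" for j in range(n_gen)])
    )


class TestClustering:
    def test_identical_proteomes_one_family_each(self, small_clade):
        records, _ = small_clade
        prots = records[0].proteins[:100]
        matrix = cluster_orthogroups({"gA": prots, "gB": [(g, s) for g, s in prots]})
        assert matrix.n_families == 100
        assert (matrix.counts.to_numpy() == 1).all()

    def test_duplicated_gene_counts_twice(self):
        seq = "MKV" * 100
        matrix = cluster_orthogroups({"gA": [("x1", seq), ("x2", seq)]})
        assert matrix.n_families == 1
        assert matrix.counts.iloc[0, 0] == 2

    def test_matrix_matches_truth_on_young_clade(self):
        """Where inter-species protein identity stays above the clustering
        threshold (a shallow clade), the matrix reproduces the simulated
        presence/absence truth almost perfectly."""
        from cladepan.simulate import SimulationConfig, simulate_clade

        config = SimulationConfig(
            seed=19, n_species=4, strains_per_species=2, tree_depth=0.035,
            intra_species_divergence=0.008, root_family_count=100,
            gain_rate=80, loss_rate=30,
        )
        records, truth = simulate_clade(config)
        matrix = cluster_orthogroups({r.genome_id: r.proteins for r in records})
        leaves = truth.tree.leaf_names()
        true_fams = sorted(set().union(*(truth.node_families[l] for l in leaves)))
        inferred_fam_of_gene = {
            gene: fam for fam, members in matrix.members.items() for _, gene in members
        }
        presence = matrix.presence()
        agree = total = 0
        for fam in true_fams:
            carriers = {l for l in leaves if fam in truth.node_families[l]}
            inferred = {inferred_fam_of_gene.get(f"{l}|{fam}") for l in carriers}
            total += len(leaves)
            if len(inferred) == 1 and None not in inferred:
                fam_col = presence.loc[inferred.pop()]
                agree += sum(
                    1 for l in leaves if bool(fam_col[l]) == (fam in truth.node_families[l])
                )
        assert agree / total >= 0.99

    def test_no_cross_family_merging_at_genus_depth(self, small_clade):
        """At genus-scale divergence the 80% threshold may split a family
        between distant species (as gene-neighbourhood-free tools do), but
        it must never merge genes from different simulated families."""
        records, _ = small_clade
        matrix = cluster_orthogroups({r.genome_id: r.proteins for r in records})
        for members in matrix.members.values():
            true_fams = {gene.split("|")[1] for _, gene in members}
            assert len(true_fams) == 1

    def test_input_order_invariance(self, small_clade):
        records, _ = small_clade
        proteomes = {r.genome_id: r.proteins for r in records[:4]}
        reversed_proteomes = {k: list(reversed(v)) for k, v in reversed(list(proteomes.items()))}
        m1 = cluster_orthogroups(proteomes)
        m2 = cluster_orthogroups(reversed_proteomes)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_orthogroups({})


class TestCategorize:
    def test_threshold_arithmetic(self):
        frame = pd.DataFrame(
            {f"g{j}": [1] * 1 + [0] * 0 for j in range(10)}, index=["core_fam"]
        )
        rows = {
            "core_fam": [1] * 10,  # 10/10 -> core
            "soft_fam": [1] * 9 + [0],  # 0.9 -> shell (below soft 0.95)
            "shell_fam": [1, 1] + [0] * 8,  # 0.20 -> shell
            "cloud_fam": [1] + [0] * 9,  # 0.10 -> cloud
        }
        matrix = _matrix(pd.DataFrame.from_dict(rows, orient="index", columns=[f"g{j}" for j in range(10)]))
        summary = categorize(matrix)
        assert (summary.core, summary.soft_core, summary.shell, summary.cloud) == (1, 0, 2, 1)
        assert summary.total == 4

    def test_counts_always_sum_to_total(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            matrix = _random_presence(rng, int(rng.integers(5, 300)), int(rng.integers(2, 30)))
            s = categorize(matrix)
            assert s.core + s.soft_core + s.shell + s.cloud == s.total == matrix.n_families


class TestRarefaction:
    def test_monotonicity_of_every_permutation(self):
        rng = np.random.default_rng(1)
        matrix = _random_presence(rng, 300, 15)
        curves = rarefaction(matrix, n_permutations=50, seed=3, keep_permutations=True)
        assert (np.diff(curves.pan_raw, axis=1) >= 0).all()
        assert (np.diff(curves.core_raw, axis=1) <= 0).all()
        assert (curves.pan_raw[:, -1] == matrix.n_families).all()

    def test_first_step_pan_equals_core(self):
        rng = np.random.default_rng(2)
        matrix = _random_presence(rng, 100, 8)
        curves = rarefaction(matrix, n_permutations=100, seed=1)
        assert curves.pan_median[0] == curves.core_median[0]

    def test_shared_repertoire_gives_flat_curves(self):
        frame = pd.DataFrame(1, index=[f"F{i}" for i in range(40)], columns=[f"g{j}" for j in range(6)])
        curves = rarefaction(_matrix(frame), n_permutations=20, seed=0)
        assert (curves.pan_median == 40).all()
        assert (curves.core_median == 40).all()


class TestOpenness:
    def test_exact_power_law_recovery(self):
        n = np.arange(1, 26)
        new = 100.0 * n ** -0.5
        curves = RarefactionCurves(
            n=n, pan_median=np.cumsum(new), pan_lo=np.zeros(25), pan_hi=np.zeros(25),
            core_median=np.zeros(25), core_lo=np.zeros(25), core_hi=np.zeros(25),
            new_median=new, n_permutations=1, seed=0,
        )
        fit = fit_openness(curves)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.kappa == pytest.approx(100.0, abs=1e-4)
        assert fit.open

    def test_pan_gain_per_genome_closed_form(self):
        n = np.arange(1, 26)
        new = 100.0 * n ** -0.5
        core = np.full(25, 500.0)
        curves = RarefactionCurves(
            n=n, pan_median=np.cumsum(new), pan_lo=np.zeros(25), pan_hi=np.zeros(25),
            core_median=core, core_lo=core, core_hi=core,
            new_median=new, n_permutations=1, seed=0,
        )
        fit = fit_openness(curves)
        pan_gain, core_loss = per_genome_rates(curves, fit)
        assert pan_gain == pytest.approx(20.0, abs=1e-3)
        assert core_loss == pytest.approx(0.0, abs=1e-9)

    def test_core_loss_mirrors_published_statistic(self):
        # 500 core families at N=2 eroding to 438 at N=102: 0.62 per genome
        n = np.arange(1, 103)
        core = np.linspace(502.0, 438.0, 102)
        core[1] = 500.0
        new = 100.0 * n ** -0.7
        curves = RarefactionCurves(
            n=n, pan_median=np.cumsum(new), pan_lo=core, pan_hi=core,
            core_median=core, core_lo=core, core_hi=core,
            new_median=new, n_permutations=1, seed=0,
        )
        _, core_loss = per_genome_rates(curves, fit_openness(curves))
        assert core_loss == pytest.approx(0.62, abs=1e-9)

    def test_all_zero_new_genes_fit_undefined(self):
        n = np.arange(1, 10)
        zero = np.zeros(9)
        curves = RarefactionCurves(
            n=n, pan_median=zero, pan_lo=zero, pan_hi=zero,
            core_median=zero, core_lo=zero, core_hi=zero,
            new_median=zero, n_permutations=1, seed=0,
        )
        with pytest.raises(ValueError):
            fit_openness(curves)


class TestHistogram:
    def test_total_is_family_count(self):
        rng = np.random.default_rng(4)
        matrix = _random_presence(rng, 250, 12)
        hist, _ = frequency_histogram(matrix)
        assert hist.sum() == matrix.n_families

    def test_singletons_mass_at_one(self):
        frame = pd.DataFrame(np.eye(6, dtype=int), index=[f"F{i}" for i in range(6)],
                             columns=[f"g{j}" for j in range(6)])
        hist, _ = frequency_histogram(_matrix(frame))
        assert hist[1] == 6 and hist[2:].sum() == 0

    def test_core_only_mass_at_n_genomes(self):
        frame = pd.DataFrame(1, index=[f"F{i}" for i in range(7)], columns=[f"g{j}" for j in range(5)])
        hist, _ = frequency_histogram(_matrix(frame))
        assert hist[5] == 7 and hist[:4].sum() == 0


class TestModuleCompleteness:
    def _matrix(self):
        frame = pd.DataFrame(
            {"g1": [1, 1, 1, 0], "g2": [1, 1, 0, 1]},
            index=["F1", "F2", "F3", "F4"],
        )
        return _matrix(frame)

    def test_complete_and_partial_modules(self):
        matrix = self._matrix()
        annotations = {"F1": {"s1", "s2"}, "F2": {"s3"}, "F3": {"s4"}}
        modules = {
            "M_full": {"s1", "s2", "s3"},  # all covered by core F1, F2
            "M_most": {"s1", "s2", "s3", "s4", "s5"},  # 3/5 = 60%
            "M_poor": {"s4", "s5", "s6", "s7", "s8", "s9", "s10", "s11", "s12", "s13"},
        }
        result = module_completeness(annotations, modules, matrix)
        assert result["M_full"] == 100.0
        assert result["M_most"] == pytest.approx(60.0)
        assert "M_poor" not in result  # 0/10 < 50% filtered

    def test_eight_of_ten_steps(self):
        matrix = self._matrix()
        annotations = {"F1": {f"s{i}" for i in range(1, 9)}}
        modules = {"M": {f"s{i}" for i in range(1, 11)}}
        assert module_completeness(annotations, modules, matrix)["M"] == pytest.approx(80.0)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module_completeness({"F1": {"s"}}, {"M": set()}, self._matrix())
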