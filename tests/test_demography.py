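"""Scenario builders and the coalescent simulation stage."""

import numpy as np
import pytest

from admixeval.demography import (
    BETA,
    CONTINUOUS_PULSE_TIME,
    SOURCE9_SPLIT_TIME,
    DemographyScenario,
    SimulationConfig,
    build_continuous_after_pulse,
    build_many_pops_tree,
    build_reference_geneflow_tree,
    build_standard_tree,
    build_stepping_stone,
    simulate_genotypes,
)


class TestStandardTree:
    def test_sixteen_labelled_populations(self):
        scen = build_standard_tree(0.5)
        assert len(scen.leaf_names()) == 16
        assert sorted(scen.labels.values(), key=int) == [str(i) for i in range(16)]
        scen.to_msprime().validate()

    def test_beta_pulse_fixed_regardless_of_alpha(self):
        for alpha in (0.0, 0.3, 1.0):
            scen = build_standard_tree(alpha)
            beta_pulse = [p for p in scen.pulses if p.recipient == "p15"][0]
            assert beta_pulse.proportion == BETA
            alpha_pulse = [p for p in scen.pulses if p.recipient == "p14"][0]
            assert alpha_pulse.proportion == alpha

    def test_source9_splits_from_donor_lineage_at_280(self):
        scen = build_standard_tree(0.5)
        split = [s for s in scen.splits if "b14" in s.derived][0]
        assert split.time == SOURCE9_SPLIT_TIME
        assert "anc89" in split.derived  # the 8/9 clade joins the same node

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            build_standard_tree(1.5)

    def test_serialization_round_trip(self, tmp_path):
        scen = build_standard_tree(0.37)
        path = tmp_path / "scenario.json"
        scen.save(path)
        back = DemographyScenario.load(path)
        assert back.to_json() == scen.to_json()
        back.to_msprime().validate()

    def test_lineage_tracing(self):
        scen = build_standard_tree(0.5)
        assert scen.lineage_at("p9", 100) == "p9"
        assert scen.lineage_at("p9", 250) == "anc89"
        assert scen.lineage_at("p9", 350) == "ancB"
        assert scen.lineage_at("p10", 350) == "p10"


class TestGeneflowTree:
    def test_gamma_zero_is_standard_history(self):
        scen = build_reference_geneflow_tree(0.5, 0.0, 200)
        std = build_standard_tree(0.5)
        assert scen.migrations == std.migrations == []
        assert scen.splits == std.splits

    def test_pulse_targets_active_lineage(self):
        # at generation 350 population 9 has merged into its stem with the
        # 14b donor lineage; the pulse must land there
        scen = build_reference_geneflow_tree(0.5, 0.1, 350)
        (edge,) = scen.migrations
        assert edge.dest == "ancB" and edge.source == "p10"
        assert edge.pulse_time == 350
        scen.to_msprime().validate()

    def test_recent_pulse_targets_leaf(self):
        scen = build_reference_geneflow_tree(0.5, 0.25, 200)
        (edge,) = scen.migrations
        assert edge.dest == "p9"
        scen.to_msprime().validate()


class TestManyPops:
    def test_population_count_118(self):
        scen = build_many_pops_tree()
        assert len(scen.leaf_names()) == 118
        scen.to_msprime().validate()

    def test_original_tree_preserved_as_subtree(self):
        scen = build_many_pops_tree()
        std = build_standard_tree(0.5)
        for s in std.splits:
            assert s in scen.splits

    def test_each_pair_splits_fifty_generations_after_attachment(self):
        scen = build_many_pops_tree()
        merges = {m.dest: m.pulse_time for m in scen.migrations if m.rate == 1.0}
        pair_splits = [s for s in scen.splits if s.ancestral.endswith("_anc")]
        assert len(pair_splits) == 51
        for s in pair_splits:
            assert merges[s.ancestral] - s.time == 50.0


class TestContinuous:
    def test_m_zero_is_pure_pulse_at_240(self):
        scen = build_continuous_after_pulse(0.5, 0.0)
        assert scen.migrations == []
        assert scen.pulses[0].time == CONTINUOUS_PULSE_TIME
        scen.to_msprime().validate()

    def test_symmetric_flow_from_both_sources(self):
        scen = build_continuous_after_pulse(0.0, 0.01)
        donors = sorted(m.source for m in scen.migrations)
        assert donors == ["p5", "p9"]
        assert all(m.dest == "p14" and m.rate == 0.01 for m in scen.migrations)
        scen.to_msprime().validate()


class TestSteppingStone:
    def test_nine_populations_and_migrant_count(self):
        scen = build_stepping_stone(0.01)
        assert len(scen.leaf_names()) == 9
        # m = 0.01 with Ne 5,000 demes moves 100 haploid genomes per
        # generation between neighbours
        assert 0.01 * 2 * scen.populations["d0"] == 100
        scen.to_msprime().validate()

    def test_chain_topology(self):
        scen = build_stepping_stone(0.01)
        pairs = {frozenset((m.source, m.dest)) for m in scen.migrations}
        assert pairs == {frozenset((f"d{i}", f"d{i+1}")) for i in range(5)}

    def test_no_migration_variant(self):
        scen = build_stepping_stone(0.0)
        assert scen.migrations == []
        scen.to_msprime().validate()


class TestSimulation:
    CONFIG = dict(scale=1 / 3000, samples_per_population=2)

    def test_deterministic_under_seed(self):
        scen = build_standard_tree(0.5)
        a = simulate_genotypes(scen, SimulationConfig(seed=5, **self.CONFIG))
        b = simulate_genotypes(scen, SimulationConfig(seed=5, **self.CONFIG))
        np.testing.assert_array_equal(a.calls, b.calls)
        assert list(a.snps["physical_pos"]) == list(b.snps["physical_pos"])
        c = simulate_genotypes(scen, SimulationConfig(seed=6, **self.CONFIG))
        assert c.n_sites != a.n_sites or not np.array_equal(a.calls, c.calls)

    def test_structure_of_output(self, standard_sim):
        G = standard_sim
        assert G.n_individuals == 160
        assert set(G.snps["chromosome"]) == set(range(1, 23))
        assert (G.individuals.groupby("population").size() == 10).all()
        G.validate()
        # genetic position consistent with uniform recombination map
        np.testing.assert_allclose(
            G.snps["genetic_pos"], G.snps["physical_pos"] * 1e-8)

    def test_pairwise_diversity_matches_coalescent_expectation(self):
        """One panmictic population: heterozygosity per bp ~ 4*Ne*mu."""
        ne, mu = 10_000.0, 1.5e-8
        scen = DemographyScenario(
            name="single", populations={"pop": ne}, splits=[],
            labels={"pop": "A"},
        )
        pis = []
        for seed in (1, 2, 3, 4):
            config = SimulationConfig(
                chromosome_lengths=[2_000_000] * 4, scale=1.0,
                samples_per_population=1, seed=seed,
            )
            G = simulate_genotypes(scen, config)
            pis.append((G.calls == 1).sum() / 8_000_000)
        assert np.mean(pis) == pytest.approx(4 * ne * mu, rel=0.25)

    def test_sample_size_overrides(self):
        scen = build_standard_tree(0.5)
        config = SimulationConfig(scale=1 / 3000, seed=3,
                                  samples_per_population={"14": 3, "5": 2, "9": 2,
                                                          "0": 2, "7": 2})
        G = simulate_genotypes(scen, config)
        sizes = G.individuals.groupby("population").size()
        assert sizes["14"] == 3 and set(sizes.index) == {"14", "5", "9", "0", "7"}
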