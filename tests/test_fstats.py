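"""Blocks, f4-statistics and the weighted jackknife against closed-form
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixeval.fstats import (
    F4Workspace,
    SitePolicy,
    f4,
    f4_vector_with_cov,
    jackknife_estimate,
    make_blocks,
)
from admixeval.genotype import MISSING, allele_frequencies

from conftest import make_matrix


def snp_frame(gpos, chrom=None):
    n = len(gpos)
    chrom = chrom if chrom is not None else np.ones(n, dtype=int)
    pos = []
    counter = {}
    for c in chrom:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c])
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)], "chromosome": chrom,
        "genetic_pos": gpos, "physical_pos": pos, "ref": "A", "alt": "G",
    })


class TestBlocks:
    def test_large_block_size_gives_one_block_per_chromosome(self):
        snps = snp_frame(np.tile(np.linspace(0, 0.4, 50), 2),
                         chrom=np.repeat([1, 2], 50))
        blocks = make_blocks(snps, block_size=1.0)
        assert blocks.n_blocks == 2
        assert blocks.sizes.tolist() == [50, 50]

    def test_uniform_spacing_blocks_of_five(self):
        # 1 cM spacing, 0.05 M blocks -> 5 SNPs per block; a SNP exactly at
        # the boundary starts the next block
        snps = snp_frame(np.arange(30) * 0.01)
        blocks = make_blocks(snps, block_size=0.05)
        assert blocks.sizes.tolist() == [5] * 6

    def test_block_count_tracks_genetic_length(self):
        snps = snp_frame(np.linspace(0, 1.0, 2000))
        blocks = make_blocks(snps, block_size=0.05)
        assert blocks.n_blocks == pytest.approx(1.0 / 0.05, abs=1)

    def test_blocks_cover_all_sites_without_overlap(self):
        snps = snp_frame(np.sort(np.random.default_rng(1).uniform(0, 0.3, 200)))
        blocks = make_blocks(snps, block_size=0.02)
        covered = np.concatenate([np.arange(a, b) for a, b in
                                  zip(blocks.starts, blocks.stops)])
        np.testing.assert_array_equal(covered, np.arange(200))

    def test_non_monotone_positions_raise(self):
        snps = snp_frame(np.array([0.0, 0.2, 0.1]))
        with pytest.raises(ValueError):
            make_blocks(snps, 0.05)


class TestF4:
    def test_identical_first_pair_is_zero(self, standard_sim):
        est, _ = f4(standard_sim, "5", "5", "0", "13", block_size=1e-3)
        assert est == 0.0

    def test_antisymmetry_and_pair_swap(self, standard_sim):
        est1, se1 = f4(standard_sim, "5", "9", "0", "13", block_size=1e-3)
        est2, _ = f4(standard_sim, "9", "5", "0", "13", block_size=1e-3)
        est3, _ = f4(standard_sim, "0", "13", "5", "9", block_size=1e-3)
        assert est2 == pytest.approx(-est1)
        assert est3 == pytest.approx(est1)

    def test_matches_brute_force_on_hand_fixture(self):
        calls = np.array([
            [0, 2, 1, 1, 2, 2, 0, 0],
            [1, 1, 0, 2, 2, 0, 1, 1],
            [2, 2, 2, 0, 1, 1, 0, 2],
            [0, 0, 1, 1, 0, 2, 2, 2],
            [2, 0, 0, 0, 1, 2, 1, 0],
        ], dtype=np.int8)
        pops = ["A", "A", "B", "B", "C", "C", "D", "D"]
        G = make_matrix(calls, pops)
        est, _ = f4(G, "A", "B", "C", "D", block_size=1e-4)
        freq, _ = allele_frequencies(G, ["A", "B", "C", "D"])
        brute = np.mean((freq[0] - freq[1]) * (freq[2] - freq[3]))
        assert est == pytest.approx(brute)

    def test_linearity_in_first_slot(self, standard_sim):
        """f4(A,B;C,D) = f4(A,X;C,D) + f4(X,B;C,D) on identical sites."""
        ws = F4Workspace(standard_sim, ["1", "2", "3", "0", "13"], block_size=1e-3)
        def est(a, b):
            s, c = ws.f4_block_sums(a, b, "0", "13")
            return s.sum() / c.sum()
        assert est("1", "2") == pytest.approx(est("1", "3") + est("3", "2"))

    def test_zero_usable_sites_raises(self):
        G = make_matrix(np.array([[MISSING, 0, 1, 1]], dtype=np.int8),
                        ["A", "B", "C", "D"])
        with pytest.raises(ValueError):
            f4(G, "A", "B", "C", "D", block_size=1e-4)


class TestJackknife:
    def test_equal_identical_blocks_have_zero_se(self):
        est, se = jackknife_estimate(np.full(10, 3.0), np.full(10, 10.0))
        assert est == pytest.approx(0.3)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_equal_blocks_reduce_to_classical_formula(self, rng):
        vals = rng.normal(size=10)
        sums = vals * 7.0
        counts = np.full(10, 7.0)
        est, se = jackknife_estimate(sums, counts)
        # classical delete-one jackknife on the block means
        loo = np.array([(sums.sum() - sums[i]) / (counts.sum() - 7.0)
                        for i in range(10)])
        var = (10 - 1) / 10 * ((loo - loo.mean()) ** 2).sum()
        assert est == pytest.approx(vals.mean())
        assert se == pytest.approx(np.sqrt(var))

    def test_fewer_than_two_blocks_raises(self):
        with pytest.raises(ValueError):
            jackknife_estimate(np.array([1.0]), np.array([5.0]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_weighted_jackknife_estimate_is_ratio_of_totals(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.integers(2, 12)
        counts = rng.integers(1, 50, size=b).astype(float)
        sums = rng.normal(size=b) * counts
        est, se = jackknife_estimate(sums, counts)
        assert est == pytest.approx(sums.sum() / counts.sum())
        assert se >= 0


class TestF4Vector:
    QUADS = [("14", "5", "0", "7"), ("14", "5", "0", "13"),
             ("14", "9", "0", "7"), ("14", "9", "0", "13")]

    def test_policies_agree_on_complete_data(self, standard_sim):
        yes = f4_vector_with_cov(standard_sim, self.QUADS,
                                 SitePolicy.ALLSNPS_YES, block_size=1e-3)
        no = f4_vector_with_cov(standard_sim, self.QUADS,
                                SitePolicy.ALLSNPS_NO, block_size=1e-3)
        np.testing.assert_allclose(yes.estimates, no.estimates)

    def test_no_policy_collapses_usable_sites_under_missingness(self, rng):
        # one population missing at most sites shrinks the global
        # intersection but not the per-quadruple sites of other statistics
        calls = rng.integers(0, 3, size=(600, 10)).astype(np.int8)
        G = make_matrix(calls, ["A", "A", "B", "B", "C", "C", "D", "D", "E", "E"])
        ecols = G.population_columns("E")
        G.calls[:590, ecols] = MISSING
        quads = [("A", "B", "C", "D"), ("A", "B", "C", "E")]
        yes = f4_vector_with_cov(G, quads, SitePolicy.ALLSNPS_YES, block_size=1e-3)
        no = f4_vector_with_cov(G, quads, SitePolicy.ALLSNPS_NO, block_size=1e-3)
        assert yes.block_counts[0].sum() == 600
        assert no.block_counts[0].sum() <= 10

    def test_cov_diagonal_matches_componentwise_jackknife(self, standard_sim):
        vec = f4_vector_with_cov(standard_sim, self.QUADS,
                                 SitePolicy.ALLSNPS_YES, block_size=1e-3)
        for i in range(len(self.QUADS)):
            _, se = jackknife_estimate(vec.block_sums[i], vec.block_counts[i])
            assert np.sqrt(vec.covariance[i, i]) == pytest.approx(se)

    def test_covariance_is_psd(self, standard_sim):
        vec = f4_vector_with_cov(standard_sim, self.QUADS,
                                 SitePolicy.ALLSNPS_YES, block_size=1e-3)
        eig = np.linalg.eigvalsh(vec.covariance)
        assert eig.min() >= -1e-12 * eig.max()


def test_smaller_blocks_give_smaller_se(standard_sim):
    """The jackknife SE shrinks as blocks shrink (more, more-correlated
    blocks understate the long-range variance)."""
    ses = {}
    for bs in (2e-4, 2e-2):
        _, se = f4(standard_sim, "14", "5", "0", "13", block_size=bs)
        ses[bs] = se
    assert ses[2e-4] < ses[2e-2]


def test_f4_vector_frame_dump(standard_sim):
    vec = f4_vector_with_cov(standard_sim, [("14", "5", "0", "13"),
                                            ("14", "9", "0", "13")],
                             SitePolicy.ALLSNPS_YES, block_size=2e-3)
    frame = vec.to_frame()
    assert list(frame.columns) == ["A", "B", "C", "D", "f4", "se", "z", "n_sites"]
    assert np.allclose(frame["z"], frame["f4"] / frame["se"])


def test_clade_f4_consistent_with_zero(standard_sim):
    """Populations 5 and 6 are a clade: f4(5,6;X,Y) is within noise of 0
    for outside pairs."""
    z = []
    for c, d in [("0", "13"), ("7", "10"), ("9", "12")]:
        est, se = f4(standard_sim, "5", "6", c, d, block_size=1e-3)
        z.append(est / se)
    assert np.all(np.abs(z) < 4)
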