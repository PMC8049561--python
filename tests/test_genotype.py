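"""Genotype container, EIGENSTRAT I/O and population summaries."""

import numpy as np
import pandas as pd
import pytest

from admixeval.genotype import (
    MISSING,
    EigenstratFormatError,
    GenotypeMatrix,
    allele_frequencies,
    pairwise_fst,
    pca_projection,
    read_eigenstrat,
    shared_site_mask,
    write_eigenstrat,
)

from conftest import make_matrix


class TestEigenstratIO:
    def test_round_trip_is_lossless(self, tmp_path, random_matrix):
        G = random_matrix.take_sites(np.arange(50))
        G.calls[3, 2] = MISSING
        prefix = str(tmp_path / "data")
        write_eigenstrat(G, prefix)
        back = read_eigenstrat(prefix)
        np.testing.assert_array_equal(back.calls, G.calls)
        assert list(back.individuals["population"]) == list(G.individuals["population"])
        assert list(back.snps["physical_pos"]) == list(G.snps["physical_pos"])

    def test_missing_is_nine_on_disk(self, tmp_path):
        G = make_matrix([[0, 1], [2, MISSING], [1, 0]], ["A", "B"])
        prefix = str(tmp_path / "m")
        write_eigenstrat(G, prefix)
        rows = open(prefix + ".geno").read().splitlines()
        # disk stores reference-allele counts: alt 0 -> '2', alt 2 -> '0'
        assert rows == ["21", "09", "12"]
        back = read_eigenstrat(prefix)
        assert back.calls[1, 1] == MISSING

    def test_pseudohaploid_round_trip_chars(self, tmp_path):
        G = make_matrix([[0, 2], [2, MISSING]], ["A", "B"])
        prefix = str(tmp_path / "ph")
        write_eigenstrat(G, prefix)
        text = open(prefix + ".geno").read()
        assert set(text) <= {"0", "2", "9", "\n"}
        assert read_eigenstrat(prefix).is_pseudohaploid()

    def test_empty_matrix_round_trips(self, tmp_path):
        G = make_matrix(np.empty((0, 3), dtype=np.int8), ["A", "A", "B"])
        prefix = str(tmp_path / "empty")
        write_eigenstrat(G, prefix)
        back = read_eigenstrat(prefix)
        assert back.n_sites == 0 and back.n_individuals == 3

    def test_row_length_mismatch_raises(self, tmp_path):
        G = make_matrix([[0, 1], [2, 0]], ["A", "B"])
        prefix = str(tmp_path / "bad")
        write_eigenstrat(G, prefix)
        with open(prefix + ".geno", "w") as fh:
            fh.write("012\n01\n")
        with pytest.raises(EigenstratFormatError, match="characters"):
            read_eigenstrat(prefix)

    def test_invalid_genotype_char_raises(self, tmp_path):
        G = make_matrix([[0, 1]], ["A", "B"])
        prefix = str(tmp_path / "badchar")
        write_eigenstrat(G, prefix)
        with open(prefix + ".geno", "w") as fh:
            fh.write("0X\n")
        with pytest.raises(EigenstratFormatError, match="invalid genotype"):
            read_eigenstrat(prefix)

    def test_dimension_mismatch_names_file(self, tmp_path):
        G = make_matrix([[0, 1], [2, 0]], ["A", "B"])
        prefix = str(tmp_path / "dims")
        write_eigenstrat(G, prefix)
        with open(prefix + ".geno", "a") as fh:
            fh.write("00\n")
        with pytest.raises(EigenstratFormatError, match=r"\.snp"):
            read_eigenstrat(prefix)


class TestAlleleFrequencies:
    def test_single_het_gives_half(self):
        G = make_matrix([[1]], ["A"])
        freq, n = allele_frequencies(G, ["A"])
        assert freq[0, 0] == 0.5 and n[0, 0] == 2

    def test_all_missing_is_undefined(self):
        G = make_matrix([[MISSING, MISSING, 1]], ["A", "A", "B"])
        freq, n = allele_frequencies(G, ["A", "B"])
        assert np.isnan(freq[0, 0]) and n[0, 0] == 0
        assert freq[1, 0] == 0.5

    def test_matches_brute_force_count(self, random_matrix):
        freq, n = allele_frequencies(random_matrix, ["A", "B", "C"])
        calls = random_matrix.calls
        for p, pop in enumerate(["A", "B", "C"]):
            cols = random_matrix.population_columns(pop)
            for s in (0, 17, 1999):
                vals = [calls[s, j] for j in cols if calls[s, j] != MISSING]
                assert n[p, s] == 2 * len(vals)
                if vals:
                    assert freq[p, s] == pytest.approx(sum(vals) / (2 * len(vals)))

    def test_alt_plus_ref_equals_total(self, random_matrix):
        freq, n = allele_frequencies(random_matrix, ["A", "B"])
        alt = freq * n
        ref = (1 - freq) * n
        np.testing.assert_allclose(alt + ref, n)

    def test_unknown_population_raises(self, random_matrix):
        with pytest.raises(KeyError):
            allele_frequencies(random_matrix, ["Z"])


class TestSharedSiteMask:
    def test_complete_data_all_true(self, random_matrix):
        assert shared_site_mask(random_matrix, ["A", "B", "C"]).all()

    def test_fully_missing_population_clears_site(self):
        calls = np.array([[0, 1, 2, 0], [MISSING, MISSING, 1, 1]], dtype=np.int8)
        G = make_matrix(calls, ["A", "A", "B", "B"])
        mask = shared_site_mask(G, ["A", "B"])
        assert mask.tolist() == [True, False]

    def test_monotone_in_population_set(self, random_matrix, rng):
        G = random_matrix.take_sites(np.arange(500))
        drop = rng.random(G.calls.shape) < 0.4
        G.calls[drop] = MISSING
        m_two = shared_site_mask(G, ["A", "B"])
        m_three = shared_site_mask(G, ["A", "B", "C"])
        assert not (m_three & ~m_two).any()


class TestFst:
    def test_identical_populations_near_zero(self, rng):
        # two samples from the same frequency distribution
        p = rng.uniform(0.05, 0.95, size=5000)
        calls = rng.binomial(2, p[:, None], size=(5000, 40)).astype(np.int8)
        G = make_matrix(calls, ["A"] * 20 + ["B"] * 20)
        assert abs(pairwise_fst(G, "A", "B")) < 0.005

    def test_matches_manual_two_site_arithmetic(self):
        # pop A: genotypes (0,2) -> p1=0.5 at both sites; pop B: (2,2) -> p2=1
        G = make_matrix([[0, 2, 2, 2], [2, 0, 2, 2]], ["A", "A", "B", "B"])
        # per site: p1=0.5 (n1=4), p2=1.0 (n2=4)
        # num = 0.25 - 0.25/3 - 0 = 1/6 ; den = 0.5*0 + 1*0.5 = 0.5
        expected = (2 * (0.25 - 0.25 / 3)) / (2 * 0.5)
        assert pairwise_fst(G, "A", "B") == pytest.approx(expected)

    def test_no_usable_sites_raises(self):
        G = make_matrix([[MISSING, 0]], ["A", "B"])
        with pytest.raises(ValueError):
            pairwise_fst(G, "A", "B")


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        block = np.array([[0] * 5 + [2] * 5] * 30, dtype=np.int8)
        noise = np.zeros((30, 10), dtype=np.int8)
        noise[0, 0] = 1  # avoid exact degeneracy
        G = make_matrix(block + 0 * noise, ["A"] * 5 + ["B"] * 5)
        coords = pca_projection(G)
        a = coords[coords.population == "A"]["PC1"].to_numpy()
        b = coords[coords.population == "B"]["PC1"].to_numpy()
        assert a.max() < b.min() or b.max() < a.min()

    def test_matches_eigendecomposition_oracle(self, rng):
        calls = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
        G = make_matrix(calls, ["A"] * 3 + ["B"] * 3)
        coords = pca_projection(G)
        # oracle: dense eigendecomposition of the normalized covariance
        X = calls.astype(float)
        p = X.mean(axis=1) / 2
        keep = (p > 0) & (p < 1)
        Z = (X[keep] - 2 * p[keep][:, None]) / np.sqrt(p[keep] * (1 - p[keep]))[:, None]
        C = Z.T @ Z
        vals, vecs = np.linalg.eigh(C)
        for k, col in enumerate(["PC1", "PC2"]):
            expected = vecs[:, -1 - k] * np.sqrt(vals[-1 - k])
            got = coords[col].to_numpy()
            assert np.allclose(np.abs(got), np.abs(expected), atol=1e-8)

    def test_constant_input_raises(self):
        G = make_matrix(np.full((10, 4), 2, dtype=np.int8), ["A"] * 4)
        with pytest.raises(ValueError):
            pca_projection(G)


class TestInvariants:
    def test_calls_shape_must_match(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(
                snps=pd.DataFrame({"snp_id": ["a"], "chromosome": [1],
                                   "genetic_pos": [0.0], "physical_pos": [1],
                                   "ref": ["A"], "alt": ["G"]}),
                individuals=pd.DataFrame({"sample_id": ["x"], "sex": ["U"],
                                          "population": ["A"]}),
                calls=np.zeros((2, 1), dtype=np.int8),
            )

    def test_validate_rejects_unsorted_positions(self):
        G = make_matrix([[0], [1]], ["A"])
        G.snps.loc[1, "physical_pos"] = G.snps.loc[0, "physical_pos"]
        with pytest.raises(ValueError, match="physical"):
            G.validate()
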