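"""Mean-field DCA: reweighting, frequencies, inversion, direct information."""

import numpy as np
import pytest

from coevdock.alignment import encode_sequences
from coevdock.dca import (ConvergenceError, compute_frequencies,
                          compute_weights, direct_information,
                          invert_mean_field, rank_pairs, run_dca,
                          read_di_table, write_di_table)
from coevdock.synth import random_potts, sample_potts

from oracles import (di_two_state_oracle, frequencies_bruteforce,
                     mutual_information_counts, weights_bruteforce)


def small_msa(seed=0, m=12, l=3, q=21):
    rng = np.random.default_rng(seed)
    seqs = rng.integers(0, q, size=(m, l)).astype(np.int8)
    from coevdock.alignment import MSA
    return MSA(seqs, [f"s{i}" for i in range(m)], q=q)


class TestWeights:
    def test_duplicates_share_weight(self):
        msa = encode_sequences(["ACD", "ACD"], ["a", "b"])
        w, meff = compute_weights(msa, theta=0.8)
        assert np.allclose(w, [0.5, 0.5]) and meff == pytest.approx(1.0)

    def test_dissimilar_sequences_keep_unit_weight(self):
        msa = encode_sequences(["ACDEF", "GHKLM", "NPQRS"], list("abc"))
        w, meff = compute_weights(msa, theta=0.8)
        assert np.allclose(w, 1.0) and meff == pytest.approx(3.0)

    def test_matches_bruteforce_counting(self):
        msa = encode_sequences(
            ["ACDEF", "ACDEW", "ACDEF", "GHKLM", "GHKLA"],
            [f"s{i}" for i in range(5)])
        for theta in (0.6, 0.8, 1.0):
            w, _ = compute_weights(msa, theta)
            assert np.allclose(w, weights_bruteforce(msa.sequences, theta))

    def test_invalid_theta(self):
        msa = encode_sequences(["AC", "AD"], ["a", "b"])
        with pytest.raises(ValueError):
            compute_weights(msa, theta=0.0)


class TestFrequencies:
    def test_pseudocount_dominance(self):
        msa = small_msa(m=5, l=3)
        w, _ = compute_weights(msa, 0.8)
        freq = compute_frequencies(msa, w, lam=1e9)
        assert np.allclose(freq.f_i, 1.0 / msa.q, atol=1e-7)
        off = freq.f_ij[0, 1]
        assert np.allclose(off, 1.0 / msa.q ** 2, atol=1e-7)

    def test_zero_pseudocount_is_pure_counting(self):
        msa = encode_sequences(["ACD", "ACD"], ["a", "b"])
        freq = compute_frequencies(msa, np.array([0.5, 0.5]), lam=0.0)
        expected = np.zeros(msa.q)
        expected[1] = 1.0  # 'A'
        assert np.allclose(freq.f_i[0], expected)

    def test_matches_weighted_counting_oracle(self, tiny_msa):
        w, meff = compute_weights(tiny_msa, 0.8)
        freq = compute_frequencies(tiny_msa, w, lam=meff)
        f_i, f_ij = frequencies_bruteforce(tiny_msa.sequences, w, meff, tiny_msa.q)
        assert np.allclose(freq.f_i, f_i, atol=1e-12)
        assert np.allclose(freq.f_ij, f_ij, atol=1e-12)

    def test_normalization_and_marginalization(self, tiny_msa):
        w, meff = compute_weights(tiny_msa, 0.8)
        freq = compute_frequencies(tiny_msa, w, lam=0.5 * meff)
        assert np.allclose(freq.f_i.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(freq.f_ij[0, 1].sum(), 1.0, atol=1e-9)
        # marginalizing the pair table recovers the single-site table
        assert np.allclose(freq.f_ij[0, 1].sum(axis=1), freq.f_i[0], atol=1e-9)
        assert np.allclose(freq.f_ij[0, 1].sum(axis=0), freq.f_i[1], atol=1e-9)


class TestInversion:
    def test_independent_columns_give_zero_couplings(self):
        msa = small_msa(m=30, l=4)
        w, meff = compute_weights(msa, 0.8)
        freq = compute_frequencies(msa, w, lam=1e7)
        coup = invert_mean_field(freq)
        assert np.abs(coup.e_ij[0, 1]).max() < 1e-4

    def test_two_site_two_state_closed_form(self):
        # L=2, q=2: C is 2x2 and e_01 = -(C^-1)_01 = c01 / det(C)
        from coevdock.alignment import MSA
        seqs = np.array([[0, 0], [0, 0], [1, 1], [0, 1]], dtype=np.int8)
        msa = MSA(seqs, list("abcd"), q=2)
        w = np.ones(4)
        freq = compute_frequencies(msa, w, lam=1.0)
        coup = invert_mean_field(freq)
        c00 = freq.f_i[0, 0] * (1 - freq.f_i[0, 0])
        c11 = freq.f_i[1, 0] * (1 - freq.f_i[1, 0])
        c01 = freq.f_ij[0, 1, 0, 0] - freq.f_i[0, 0] * freq.f_i[1, 0]
        expected = c01 / (c00 * c11 - c01 ** 2)
        assert coup.e_ij[0, 1, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_coupling_symmetry(self):
        msa = small_msa(seed=3, m=20, l=4)
        w, meff = compute_weights(msa, 0.8)
        freq = compute_frequencies(msa, w, lam=meff)
        coup = invert_mean_field(freq)
        assert np.allclose(coup.e_ij[0, 2], coup.e_ij[2, 0].T, atol=1e-10)

    def test_singular_without_pseudocount(self):
        msa = encode_sequences(["ACD", "ACD", "ACD"], list("abc"))
        w = np.ones(3) / 3
        freq = compute_frequencies(msa, w, lam=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            invert_mean_field(freq)


class TestDirectInformation:
    def test_zero_couplings_give_zero_di(self):
        msa = small_msa(m=25, l=3)
        w, meff = compute_weights(msa, 0.8)
        freq = compute_frequencies(msa, w, lam=meff)
        coup = invert_mean_field(freq)
        coup.e_ij[:] = 0.0
        assert direct_information(coup, freq, 0, 2) == pytest.approx(0.0, abs=1e-9)

    def test_di_nonnegative(self):
        msa = small_msa(seed=9, m=20, l=4)
        ranking, _, _ = run_dca(msa, min_separation=1)
        assert all(di >= 0 for _, _, di in ranking.entries)

    def test_self_pair_rejected(self):
        msa = small_msa()
        _, freq, coup = run_dca(msa)
        with pytest.raises(ValueError):
            direct_information(coup, freq, 1, 1)

    def test_matches_two_state_grid_oracle(self):
        from coevdock.alignment import MSA
        rng = np.random.default_rng(5)
        seqs = rng.integers(0, 2, size=(20, 3)).astype(np.int8)
        msa = MSA(seqs, [f"s{i}" for i in range(20)], q=2)
        ranking, freq, coup = run_dca(msa, min_separation=1)
        for i, j, di in ranking.entries:
            expected = di_two_state_oracle(coup.e_ij[i, j, :2, :2],
                                           freq.f_i[i], freq.f_i[j])
            assert di == pytest.approx(expected, abs=1e-5)


class TestRanking:
    def test_min_separation_filter(self):
        msa = small_msa(m=15, l=3)
        _, freq, coup = run_dca(msa)
        ranking = rank_pairs(coup, freq, min_separation=2)
        assert ranking.pairs() == [(0, 2)]

    def test_ties_break_lexicographically(self):
        msa = small_msa(m=15, l=4)
        _, freq, coup = run_dca(msa)
        coup.e_ij[:] = 0.0  # all DI 0 -> pure tie
        ranking = rank_pairs(coup, freq, min_separation=1)
        assert ranking.pairs() == sorted(ranking.pairs())

    def test_planted_pair_ranks_first(self):
        model = random_potts(L=8, q=4, n_planted=1, coupling_strength=3.0, seed=2)
        msa = sample_potts(model, M=1500, seed=3)
        ranking, _, _ = run_dca(msa, min_separation=1)
        assert ranking.pairs()[0] == model.planted_pairs[0]


class TestInvariances:
    def test_sequence_permutation_leaves_di_unchanged(self):
        msa = small_msa(seed=11, m=18, l=4)
        ranking, _, _ = run_dca(msa, min_separation=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(msa.M)
        from coevdock.alignment import MSA
        permuted = MSA(msa.sequences[perm], [msa.labels[k] for k in perm], q=msa.q)
        ranking2, _, _ = run_dca(permuted, min_separation=1)
        for (i1, j1, d1), (i2, j2, d2) in zip(ranking.entries, ranking2.entries):
            assert (i1, j1) == (i2, j2)
            assert d1 == pytest.approx(d2, abs=1e-10)

    def test_alphabet_relabeling_leaves_di_unchanged(self):
        # any state permutation fixing the gauge (last) state
        from coevdock.alignment import MSA
        rng = np.random.default_rng(21)
        q = 5
        seqs = rng.integers(0, q, size=(40, 4)).astype(np.int8)
        msa = MSA(seqs, [f"s{i}" for i in range(40)], q=q)
        ranking, _, _ = run_dca(msa, min_separation=1)
        perm = np.array([2, 0, 3, 1, 4])  # fixes state q-1
        msa2 = MSA(perm[seqs].astype(np.int8), msa.labels, q=q)
        ranking2, _, _ = run_dca(msa2, min_separation=1)
        di1 = dict(((i, j), d) for i, j, d in ranking.entries)
        di2 = dict(((i, j), d) for i, j, d in ranking2.entries)
        for pair in di1:
            assert di1[pair] == pytest.approx(di2[pair], abs=1e-6)

    def test_di_rank_order_matches_mutual_information(self):
        # strong regularization, q=2, small L: DI ordering equals the
        # ordering of plug-in mutual information from exhaustive counting
        from coevdock.alignment import MSA
        rng = np.random.default_rng(8)
        base = rng.integers(0, 2, size=(60, 1))
        col2 = (base[:, 0] ^ (rng.random(60) < 0.15)).astype(np.int8)
        col3 = rng.integers(0, 2, size=60).astype(np.int8)
        seqs = np.column_stack([base[:, 0], col2, col3]).astype(np.int8)
        msa = MSA(seqs, [f"s{i}" for i in range(60)], q=2)
        ranking, _, _ = run_dca(msa, theta=1.0, min_separation=1)
        mi = {(i, j): mutual_information_counts(seqs, i, j, 2)
              for i, j, _ in ranking.entries}
        di_order = ranking.pairs()
        mi_order = sorted(mi, key=lambda p: -mi[p])
        assert di_order == mi_order


def test_di_table_roundtrip(tmp_path):
    msa = small_msa(seed=4, m=15, l=4)
    ranking, _, _ = run_dca(msa)
    path = tmp_path / "di.tsv"
    write_di_table(ranking, path)
    again = read_di_table(path)
    assert again.pairs() == ranking.pairs()
    assert again.meta["Meff"] == pytest.approx(ranking.meta["Meff"])
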