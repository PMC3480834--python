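import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_running_sum, naive_kmer_counts
from conftest import random_dna
from mirseed.io_formats import UTRRecord
from mirseed.word_enrichment import (
    RankedSequences,
    _dstat_for_orders,
    _permutation_orders,
    kmer_count_matrix,
    kmer_words,
    permutation_z,
    rank_sequences,
    rank_words,
    running_sum_profile,
    word_profile,
    _count_word,
)


def ranked_from(sequences, logfc=None):
    n = len(sequences)
    logfc = np.arange(n, dtype=float) if logfc is None else np.asarray(logfc, float)
    order = np.lexsort((np.array([f"g{i}" for i in range(n)]), logfc))
    return RankedSequences(
        gene_ids=tuple(f"g{i}" for i in order),
        sequences=tuple(sequences[i] for i in order),
        logfc=logfc[order],
    )


class TestKmerCounting:
    def test_overlapping_windows(self):
        counts = kmer_count_matrix(["ACGTACGT"], 4)
        words = kmer_words(4)
        got = {w: int(c) for w, c in zip(words, counts[0]) if c}
        assert got == {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}
        assert counts.sum() == 5

    def test_homopolymer_overlaps(self):
        counts = kmer_count_matrix(["AAAA"], 2)
        assert counts[0][kmer_words(2).index("AA")] == 3

    def test_n_windows_count_nothing(self):
        assert kmer_count_matrix(["ANA"], 2).sum() == 0

    def test_k_longer_than_all_sequences_rejected(self):
        with pytest.raises(ValueError):
            kmer_count_matrix(["ACG", "TT"], 4)

    def test_matches_naive_oracle(self, rng):
        seqs = [random_dna(rng, int(rng.integers(3, 60)), with_n=True) for _ in range(30)]
        for k in (1, 2, 3, 5):
            counts = kmer_count_matrix(seqs, k)
            words = kmer_words(k)
            for i, seq in enumerate(seqs):
                want = naive_kmer_counts(seq, k)
                got = {w: int(c) for w, c in zip(words, counts[i]) if c}
                assert got == want


class TestRunningSum:
    def test_hand_computed_profile(self):
        profile, d = running_sum_profile([2, 1, 0], [1000, 1000, 1000])
        assert profile == pytest.approx([0.001, 0.001, 0.0], abs=1e-12)
        assert d == pytest.approx(0.001)

    def test_equal_rates_flat_profile(self):
        profile, d = running_sum_profile([3, 3, 3], [500, 500, 500])
        assert np.allclose(profile, 0) and d == 0.0

    def test_reversed_order_kills_head_signal(self):
        profile, d = running_sum_profile([0, 1, 2], [1000, 1000, 1000])
        assert profile == pytest.approx([-0.001, -0.001, 0.0], abs=1e-12)
        assert d == 0.0

    def test_profile_ends_at_zero(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            counts = rng.integers(0, 10, n)
            lengths = rng.integers(50, 500, n)
            profile, _ = running_sum_profile(counts, lengths)
            assert abs(profile[-1]) < 1e-9

    def test_rate_invariance_under_common_rescaling(self, rng):
        counts = rng.integers(0, 8, 10)
        lengths = rng.integers(100, 400, 10)
        p1, d1 = running_sum_profile(counts, lengths)
        p2, d2 = running_sum_profile(counts * 3, lengths * 3)
        assert np.allclose(p1, p2) and d1 == pytest.approx(d2)

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 6, 25)
        lengths = rng.integers(60, 900, 25)
        profile, d = running_sum_profile(counts, lengths)
        want_profile, want_d = brute_running_sum(counts.tolist(), lengths.tolist())
        assert np.allclose(profile, want_profile) and d == pytest.approx(want_d)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            running_sum_profile([1, 2], [100, 0])


class TestPermutationZ:
    def test_absent_word_is_degenerate(self):
        score = permutation_z(np.zeros(10), np.full(10, 100), n_permutations=20, rng_seed=1)
        assert score.degenerate and score.z_score == 0.0
        assert score.d_stat == 0.0 and score.empirical_p == 1.0

    def test_seed_determinism(self, rng):
        counts = rng.integers(0, 5, 30)
        lengths = rng.integers(100, 500, 30)
        a = permutation_z(counts, lengths, n_permutations=50, rng_seed=9)
        b = permutation_z(counts, lengths, n_permutations=50, rng_seed=9)
        assert a == b

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            permutation_z([1, 2], [10, 10])

    def test_fixed_relabeling_leaves_d_obs_unchanged(self, rng):
        counts = rng.integers(0, 5, 20)
        lengths = rng.integers(100, 500, 20)
        _, d1 = running_sum_profile(counts, lengths)
        perm = rng.permutation(20)
        inv = np.argsort(perm)
        # permute the genes and undo it through the ranking: same list, same D
        _, d2 = running_sum_profile(counts[perm][inv], lengths[perm][inv])
        assert d1 == pytest.approx(d2)


class TestExhaustivePermutationNull:
    def test_sampled_null_matches_full_enumeration(self, rng):
        n = 5
        counts = np.array([4, 1, 0, 2, 0], float)
        lengths = np.array([200, 150, 300, 120, 260], float)
        rates = counts / lengths
        u = (rates - rates.mean()).astype(np.float32)[:, None]
        all_orders = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        d_full = _dstat_for_orders(np.ascontiguousarray(u), all_orders, False)[:, 0]
        sampled = _dstat_for_orders(
            np.ascontiguousarray(u), _permutation_orders(n, 2000, 4), False
        )[:, 0]
        se_mean = d_full.std() / np.sqrt(2000)
        assert abs(sampled.mean() - d_full.mean()) < 3 * se_mean
        # sd of the sample sd is ~ sd/sqrt(2(n-1))
        assert abs(sampled.std(ddof=1) - d_full.std(ddof=1)) < 3 * d_full.std() / np.sqrt(2 * 1999)


class TestRankWords:
    def test_identical_words_tie_lexicographically(self):
        # AA and CC have identical per-sequence counts, so identical z
        seqs = ["AAACCCG", "AACCGTG", "GACGTAC", "TTGTCAG"]
        df = rank_words(ranked_from(seqs), 2, n_permutations=20, rng_seed=5)
        sub = df.set_index("word").loc[["AA", "CC"]]
        assert sub["z_score"].nunique() == 1
        assert sub.loc["CC", "rank"] == sub.loc["AA", "rank"] + 1

    def test_vectorized_path_matches_single_word_path(self, rng):
        seqs = [random_dna(rng, int(rng.integers(30, 120))) for _ in range(40)]
        ranked = ranked_from(seqs, rng.normal(size=40))
        df = rank_words(ranked, 3, n_permutations=60, rng_seed=13).set_index("word")
        lengths = ranked.lengths
        for word in ("ACG", "TTT", "GAT"):
            counts = np.array([_count_word(s, word) for s in ranked.sequences])
            single = permutation_z(counts, lengths, n_permutations=60, rng_seed=13, word=word)
            assert df.loc[word, "d_stat"] == pytest.approx(single.d_stat, rel=1e-4, abs=1e-9)
            if not single.degenerate:
                assert df.loc[word, "z_score"] == pytest.approx(single.z_score, rel=1e-3, abs=1e-3)
            assert df.loc[word, "empirical_p"] == pytest.approx(single.empirical_p, abs=1e-9)

    def test_rank_column_is_a_permutation(self, rng):
        seqs = [random_dna(rng, 50) for _ in range(10)]
        df = rank_words(ranked_from(seqs), 2, n_permutations=10, rng_seed=2)
        assert sorted(df["rank"]) == list(range(1, 17))
        z = df.sort_values("rank")["z_score"].to_numpy()
        assert (np.diff(z) <= 1e-12).all()

    def test_adding_head_occurrences_never_decreases_d(self, rng):
        seqs = [random_dna(rng, 80) for _ in range(15)]
        ranked = ranked_from(seqs, np.arange(15, dtype=float))
        lengths = ranked.lengths
        word = "ACGTA"
        counts = np.array([_count_word(s, word) for s in ranked.sequences], float)
        _, d_before = running_sum_profile(counts, lengths)
        counts[0] += 3  # plant extra occurrences in the most down-regulated gene
        _, d_after = running_sum_profile(counts, lengths)
        assert d_after >= d_before


class TestRankedSequences:
    def test_ascending_logfc_with_gene_id_ties(self):
        utrs = [UTRRecord("b", "ACGT"), UTRRecord("a", "TTTT"), UTRRecord("c", "GGGG")]
        fc = pd.DataFrame({"gene_id": ["a", "b", "c"], "logFC": [0.5, -1.0, 0.5]})
        ranked = rank_sequences(utrs, fc)
        assert ranked.gene_ids == ("b", "a", "c")

    def test_genes_without_sequence_dropped(self):
        utrs = [UTRRecord("a", "ACGT"), UTRRecord("b", "TTTT")]
        fc = pd.DataFrame({"gene_id": ["a", "b", "zz"], "logFC": [0.1, -0.1, -2.0]})
        assert rank_sequences(utrs, fc).gene_ids == ("b", "a")


class TestWordProfile:
    def test_profile_table_shape_and_consistency(self, rng):
        seqs = [random_dna(rng, 60) for _ in range(8)]
        ranked = ranked_from(seqs)
        df = word_profile(ranked, "ACG", n_permutations=5, rng_seed=3)
        assert list(df.columns[:4]) == ["position", "gene_id", "logFC", "R"]
        assert len(df) == 8 and df.filter(like="perm_").shape[1] == 5
        counts = np.array([_count_word(s, "ACG") for s in ranked.sequences])
        want, _ = running_sum_profile(counts, ranked.lengths)
        assert np.allclose(df["R"], want)
        for col in df.filter(like="perm_"):
            assert abs(df[col].iloc[-1]) < 1e-9  # every trace conserves the centering
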