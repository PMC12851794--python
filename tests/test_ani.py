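import numpy as np
import pytest
from conftest import random_dna, substituted_copy

from prophagepop import ani
from prophagepop.io_formats import SequenceRecord
from prophagepop.simulate import insert_indels, plant_family_sequences


class TestOracle:
    @pytest.mark.parametrize("seq", ["ACGT", "A", "ACGTACGTACGTTTTT"])
    def test_self_identity_is_100(self, seq):
        assert ani.nw_identity_oracle(seq, seq) == 100.0

    def test_no_matches(self):
        assert ani.nw_identity_oracle("AAAA", "TTTT") == 0.0

    def test_planted_20_substitutions_give_98(self, rng):
        s = random_dna(1000, rng)
        s2 = substituted_copy(s, 20, rng)
        assert ani.nw_identity_oracle(s, s2) == pytest.approx(98.0, abs=1e-9)

    def test_n_positions_never_match(self):
        # 2 real matches out of 4+4 bases -> 100*2*2/8 = 50
        assert ani.nw_identity_oracle("AANN", "AANN") == 50.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            ani.nw_identity_oracle("", "ACGT")


class TestSeedMatches:
    def test_embedded_30mer_found_forward(self, rng):
        a = random_dna(500, rng)
        fragment = a[100:130]
        b = random_dna(200, rng) + fragment + random_dna(200, rng)
        matches = [m for m in ani.seed_matches(a, b) if m.orientation == "forward"]
        assert any(m.length >= 30 for m in matches)

    def test_reverse_complement_full_length(self, rng):
        a = random_dna(300, rng)
        matches = ani.seed_matches(a, ani.reverse_complement(a))
        rc = [m for m in matches if m.orientation == "reverse-complement"]
        assert any(m.length == 300 and m.pos_a == 0 for m in rc)

    def test_random_pairs_rarely_share_seeds(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a, b = random_dna(1000, r), random_dna(1000, r)
            hits += min(1, len(ani.seed_matches(a, b, k=15)))
        assert hits <= 1

    def test_small_k_raises(self):
        with pytest.raises(ValueError):
            ani.seed_matches("ACGTACGTACGT", "ACGTACGTACGT", k=4)


def _brute_force_chain(anchors):
    """Exhaustive maximum over all strictly-increasing chains with the
    same overlap-trimming rule as the DP."""
    anchors = sorted(anchors, key=lambda m: (m.pos_a, m.pos_b))

    def rec(prev_idx, weight):
        best = weight
        start = 0 if prev_idx is None else prev_idx + 1
        for i in range(start, len(anchors)):
            m = anchors[i]
            if prev_idx is None:
                gain = m.length
            else:
                p = anchors[prev_idx]
                if p.pos_a >= m.pos_a or p.pos_b >= m.pos_b:
                    continue
                gain = m.length - max(
                    0, p.pos_a + p.length - m.pos_a, p.pos_b + p.length - m.pos_b
                )
                if gain <= 0:
                    continue
            best = max(best, rec(i, weight + gain))
        return best

    return rec(None, 0)


class TestChaining:
    def test_single_match(self):
        m = ani.SeedMatch(10, 20, 40, "forward")
        assert ani.chain_seeds([m]) == 40

    def test_two_collinear_matches(self):
        ms = [
            ani.SeedMatch(0, 0, 30, "forward"),
            ani.SeedMatch(50, 60, 20, "forward"),
        ]
        assert ani.chain_seeds(ms) == 50

    def test_crossing_matches_keep_one(self):
        ms = [
            ani.SeedMatch(0, 100, 30, "forward"),
            ani.SeedMatch(50, 10, 30, "forward"),
        ]
        assert ani.chain_seeds(ms) == 30
        assert ani.chain_seeds(ms) == _brute_force_chain(ms)

    def test_matches_brute_force_on_random_anchor_sets(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 9))
            ms = [
                ani.SeedMatch(
                    int(rng.integers(0, 200)),
                    int(rng.integers(0, 200)),
                    int(rng.integers(15, 60)),
                    "forward",
                )
                for _ in range(n)
            ]
            assert ani.chain_seeds(ms) == _brute_force_chain(ms)

    def test_mixed_orientations_raise(self):
        ms = [
            ani.SeedMatch(0, 0, 20, "forward"),
            ani.SeedMatch(30, 30, 20, "reverse-complement"),
        ]
        with pytest.raises(ValueError):
            ani.chain_seeds(ms)


class TestTani:
    def test_self_is_100(self, rng):
        s = random_dna(800, rng)
        assert ani.tani(s, s).tani == 100.0

    def test_no_shared_seeds_is_zero(self):
        a = "A" * 500
        b = "C" * 500
        assert ani.tani(a, b).tani == 0.0

    def test_planted_98_percent_pair(self, rng):
        s = random_dna(1000, rng)
        s2 = substituted_copy(s, 20, rng)
        assert ani.tani(s, s2).tani == pytest.approx(98.0, abs=1.5)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = random_dna(600, rng)
            b = substituted_copy(a, int(rng.integers(0, 60)), rng)
            assert ani.tani(a, b).tani == pytest.approx(ani.tani(b, a).tani, abs=1e-9)

    def test_reverse_complement_orientation_used(self, rng):
        a = random_dna(700, rng)
        res = ani.tani(a, ani.reverse_complement(a))
        assert res.orientation_used == "reverse-complement"
        assert res.tani == pytest.approx(100.0, abs=0.5)

    def test_more_substitutions_never_increase_tani(self, rng):
        a = random_dna(1500, rng)
        values = []
        for n_sub in (0, 30, 90, 200):
            b = substituted_copy(a, n_sub, np.random.default_rng(5))
            values.append(ani.tani(a, b).tani)
        assert values == sorted(values, reverse=True)

    def test_tracks_oracle_on_high_identity_pairs(self, rng):
        agree = 0
        for i in range(10):
            length = int(rng.integers(1000, 2000))
            a = random_dna(length, rng)
            n_sub = int(rng.integers(0, int(0.15 * length)))
            b = substituted_copy(a, n_sub, rng)
            if abs(ani.tani(a, b).tani - ani.nw_identity_oracle(a, b)) <= 3.0:
                agree += 1
        assert agree >= 9

    def test_robust_to_short_indels(self, rng):
        a = random_dna(1500, rng)
        b = insert_indels(substituted_copy(a, 30, rng), n_events=4, max_length=10, seed=3)
        oracle = ani.nw_identity_oracle(a, b)
        assert ani.tani(a, b).tani == pytest.approx(oracle, abs=3.0)


class TestTaniMatrix:
    def test_identical_sequences_all_100(self, rng):
        s = random_dna(400, rng)
        records = [SequenceRecord(f"p{i}", s) for i in range(3)]
        m = ani.tani_matrix(records)
        assert np.allclose(m.values, 100.0)

    def test_permutation_invariance(self, rng):
        records = [
            SequenceRecord(f"p{i}", substituted_copy(random_dna(400, rng), 0, rng))
            for i in range(4)
        ]
        m1 = ani.tani_matrix(records)
        m2 = ani.tani_matrix(records[::-1]).reorder(m1.labels)
        assert np.allclose(m1.values, m2.values, atol=1e-9)

    def test_planted_block_structure_recovered(self):
        species = {f"s{b}_m{j}": f"sp{b}" for b in range(2) for j in range(3)}
        records, _ = plant_family_sequences(species, 1000, 97.0, 80.0, seed=9)
        m = ani.tani_matrix(records)
        within, between = [], []
        for i, a in enumerate(m.labels):
            for b in m.labels[i + 1 :]:
                (within if species[a] == species[b] else between).append(m.value(a, b))
        assert np.mean(within) > np.mean(between)
        assert min(within) > 95.0
        assert max(between) < 95.0

    def test_duplicate_ids_raise(self, rng):
        s = random_dna(300, rng)
        with pytest.raises(ValueError):
            ani.tani_matrix([SequenceRecord("p", s), SequenceRecord("p", s)])
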