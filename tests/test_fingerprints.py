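from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsarscreen import (
    FingerprintSet,
    SyntheticSpec,
    ValidationError,
    bit_frequency,
    differential_bits,
    generate_dataset,
    pairwise_similarity,
    tanimoto,
)
from qsarscreen.containers import N_MACCS_BITS


def fp(*on_bits):
    v = np.zeros(N_MACCS_BITS, dtype=np.uint8)
    v[list(on_bits)] = 1
    return v


def brute_force_tanimoto(x, y):
    """Exact rational bit-loop evaluation, independent of the vectorized path."""
    a = b = c = 0
    for i in range(N_MACCS_BITS):
        a += int(x[i])
        b += int(y[i])
        c += int(x[i]) and int(y[i])
    if a + b - c == 0:
        return Fraction(0)
    return Fraction(c, a + b - c)


class TestTanimoto:
    def test_hand_example(self):
        # |A| = 4, |B| = 6, shared = 2 -> 2 / (4 + 6 - 2) = 0.25
        x = fp(0, 1, 2, 3)
        y = fp(2, 3, 10, 11, 12, 13)
        assert tanimoto(x, y) == pytest.approx(0.25)

    def test_identical_nonempty_is_one(self):
        assert tanimoto(fp(5, 9), fp(5, 9)) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(fp(0, 1), fp(2, 3)) == 0.0

    def test_all_zero_pair_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto(fp(), fp()) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto(np.zeros(10, dtype=np.uint8), fp(0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_bounded_and_reflexive(self, seed):
        rng = np.random.default_rng(seed)
        x = (rng.random(N_MACCS_BITS) < 0.3).astype(np.uint8)
        y = (rng.random(N_MACCS_BITS) < 0.3).astype(np.uint8)
        if x.sum() == 0 or y.sum() == 0:
            return
        t = tanimoto(x, y)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(y, x)
        assert tanimoto(x, x) == 1.0


class TestPairwiseSimilarity:
    def test_self_similarity_matrix(self, dataset):
        sub = dataset.fingerprints.subset(dataset.fingerprints.compound_ids[:20])
        M = pairwise_similarity(sub, sub)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)

    def test_shape(self, rng):
        a = FingerprintSet([f"a{i}" for i in range(3)],
                           (rng.random((3, 166)) < 0.3).astype(np.uint8))
        b = FingerprintSet([f"b{i}" for i in range(5)],
                           (rng.random((5, 166)) < 0.3).astype(np.uint8))
        assert pairwise_similarity(a, b).shape == (3, 5)

    def test_matches_exact_rational_brute_force_on_100_random_pairs(self, rng):
        bits_a = (rng.random((100, 166)) < 0.3).astype(np.uint8)
        bits_b = (rng.random((100, 166)) < 0.3).astype(np.uint8)
        A = FingerprintSet([f"a{i}" for i in range(100)], bits_a)
        B = FingerprintSet([f"b{i}" for i in range(100)], bits_b)
        M = pairwise_similarity(A, B)
        for i in range(100):
            exact = brute_force_tanimoto(bits_a[i], bits_b[i])
            assert Fraction(M[i, i]).limit_denominator(10**6) == exact
            assert M[i, i] == float(exact)

    def test_agrees_with_rdkit_bit_vector_similarity(self, rng):
        DataStructs = pytest.importorskip("rdkit.DataStructs")
        from rdkit.DataStructs.cDataStructs import ExplicitBitVect

        for _ in range(25):
            x = (rng.random(166) < 0.3).astype(int)
            y = (rng.random(166) < 0.3).astype(int)
            bx, by = ExplicitBitVect(166), ExplicitBitVect(166)
            for i in np.flatnonzero(x):
                bx.SetBit(int(i))
            for i in np.flatnonzero(y):
                by.SetBit(int(i))
            if x.sum() == 0 and y.sum() == 0:
                continue
            assert tanimoto(x.astype(np.uint8), y.astype(np.uint8)) == pytest.approx(
                DataStructs.TanimotoSimilarity(bx, by), abs=1e-12
            )


class TestBitFrequency:
    def test_direct_percentage(self):
        bits = np.zeros((10, 166), dtype=np.uint8)
        bits[:7, 0] = 1
        fps = FingerprintSet([f"c{i}" for i in range(10)], bits)
        table = bit_frequency(fps, fps.compound_ids, "active")
        assert table.freq[0] == pytest.approx(70.0)
        assert table.freq[1] == 0.0
        assert table.n == 10

    def test_unknown_member_id_rejected_by_name(self, dataset):
        with pytest.raises(ValidationError, match="nope"):
            bit_frequency(dataset.fingerprints, ["nope"])

    def test_enriched_bit_frequency_near_planted_probability(self, dataset):
        active_ids = [c for c, l in zip(dataset.fingerprints.compound_ids,
                                        dataset.labels) if l == 1]
        table = bit_frequency(dataset.fingerprints, active_ids, "active")
        se = 100 * np.sqrt(0.8 * 0.2 / len(active_ids))
        for bit in dataset.enriched_bit_indices:
            assert abs(table.freq[bit] - 80.0) <= 3 * se

    def test_union_frequency_is_weighted_mean_of_classes(self, dataset):
        ids = dataset.fingerprints.compound_ids
        act = [c for c, l in zip(ids, dataset.labels) if l == 1]
        inact = [c for c, l in zip(ids, dataset.labels) if l == 0]
        fa = bit_frequency(dataset.fingerprints, act)
        fi = bit_frequency(dataset.fingerprints, inact)
        fu = bit_frequency(dataset.fingerprints, ids)
        weighted = (fa.freq * len(act) + fi.freq * len(inact)) / len(ids)
        assert np.allclose(fu.freq, weighted)


class TestDifferentialBits:
    def test_identical_tables_give_empty_list(self, dataset):
        table = bit_frequency(dataset.fingerprints, dataset.fingerprints.compound_ids)
        assert differential_bits(table, table) == []

    def test_planted_enriched_bits_ranked_first(self):
        ds = generate_dataset(
            SyntheticSpec(n_active=300, n_inactive=300, p_bit_active=0.8,
                          p_bit_inactive=0.4, n_enriched_bits=6, seed=17)
        )
        ids = ds.fingerprints.compound_ids
        act = [c for c, l in zip(ids, ds.labels) if l == 1]
        inact = [c for c, l in zip(ids, ds.labels) if l == 0]
        hits = differential_bits(
            bit_frequency(ds.fingerprints, act),
            bit_frequency(ds.fingerprints, inact),
            min_diff=10.0,
        )
        top = {h["bit"] - 1 for h in hits[: len(ds.enriched_bit_indices)]}
        assert top == set(ds.enriched_bit_indices)

    def test_zero_min_diff_bounded_by_bit_count(self, dataset):
        ids = dataset.fingerprints.compound_ids
        act = [c for c, l in zip(ids, dataset.labels) if l == 1]
        inact = [c for c, l in zip(ids, dataset.labels) if l == 0]
        hits = differential_bits(
            bit_frequency(dataset.fingerprints, act),
            bit_frequency(dataset.fingerprints, inact),
            min_diff=0.0,
        )
        assert len(hits) <= 166
        diffs = [h["diff"] for h in hits]
        assert diffs == sorted(diffs, reverse=True)
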