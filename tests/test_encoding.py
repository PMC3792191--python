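"""Pair-frequency tallies, propensity matrices and the feature encoding,
cross-checked against an independent brute-force tally."""

import random

import numpy as np
import pytest

from snopair import (
    PeptideWindow,
    encode,
    index_pair,
    pair_frequencies,
    psdp,
)
from snopair.encoding import encode_codes
from snopair.errors import (
    DimensionMismatchError,
    EmptyDatasetError,
    IncompatibleMatricesError,
)
from snopair.windows import windows_to_codes

from conftest import WINDOW_NEG, WINDOW_POS, random_window
from oracles import brute_encode, brute_pair_frequencies, brute_psdp

W1 = "ACDEFGHIKLCMNPQRSTVWY"


def test_single_window_gap0_frequencies_are_indicator_columns():
    f = pair_frequencies([PeptideWindow(W1)], gap=0)
    assert f.values.shape == (441, 20)
    col = f.values[:, 0]
    assert col[index_pair("A", "C") - 1] == 1.0
    assert col.sum() == 1.0
    assert f.counts.sum() == 20  # one pair per subsite


def test_single_window_gap1_pairs_skip_one_residue():
    f = pair_frequencies([PeptideWindow(W1)], gap=1)
    assert f.values.shape == (441, 19)
    assert f.values[index_pair("A", "D") - 1, 0] == 1.0


def test_two_windows_split_frequency_at_differing_position():
    w2 = "C" + W1[1:]
    f = pair_frequencies([PeptideWindow(W1), PeptideWindow(w2)], gap=0)
    assert f.values[index_pair("A", "C") - 1, 0] == 0.5
    assert f.values[index_pair("C", "C") - 1, 0] == 0.5


def test_empty_window_set_rejected():
    with pytest.raises(EmptyDatasetError):
        pair_frequencies([], gap=0)


def test_propensity_is_elementwise_difference_and_antisymmetric():
    rng = random.Random(3)
    a = [PeptideWindow(random_window(rng)) for _ in range(5)]
    b = [PeptideWindow(random_window(rng)) for _ in range(7)]
    fa, fb = pair_frequencies(a, 0), pair_frequencies(b, 0)
    z = psdp(fa, fb)
    np.testing.assert_array_equal(z.values, fa.values - fb.values)
    np.testing.assert_array_equal(psdp(fb, fa).values, -z.values)
    # identical classes carry no signal
    assert not psdp(fa, fa).values.any()


def test_gap_mismatch_rejected():
    a = pair_frequencies([PeptideWindow(W1)], 0)
    b = pair_frequencies([PeptideWindow(W1)], 1)
    with pytest.raises(IncompatibleMatricesError):
        psdp(a, b)


def test_disjoint_pair_training_encodes_to_all_plus_and_minus_one(toy_pair):
    """One positive and one negative window sharing no pair at any subsite:
    every feature component of the positive window is +1 (pair seen only in
    the positive class) and of the negative window is -1."""
    pos, neg = toy_pair
    # precondition: no shared pair at any subsite, either gap
    for gap in (0, 1):
        for j in range(21 - gap - 1):
            assert (
                pos.residues[j : j + gap + 2 : gap + 1]
                != neg.residues[j : j + gap + 2 : gap + 1]
            )
    z0 = psdp(pair_frequencies([pos], 0), pair_frequencies([neg], 0))
    z1 = psdp(pair_frequencies([pos], 1), pair_frequencies([neg], 1))
    np.testing.assert_array_equal(encode(pos, z0, z1).components, np.ones(39))
    np.testing.assert_array_equal(encode(neg, z0, z1).components, -np.ones(39))


def test_window_with_unseen_pairs_encodes_to_zero_vector(toy_pair):
    pos, neg = toy_pair
    z0 = psdp(pair_frequencies([pos], 0), pair_frequencies([neg], 0))
    z1 = psdp(pair_frequencies([pos], 1), pair_frequencies([neg], 1))
    third = PeptideWindow("GECAHDIFWG" + "C" + "AGEWCDKIFG")
    # `third` differs from both training windows at every non-center position,
    # so no pair of it occurs in either training window at the same subsite
    for i, ch in enumerate(third.residues):
        if i != 10:
            assert ch != pos.residues[i] and ch != neg.residues[i]
    psi = encode(third, z0, z1).components
    assert psi.shape == (39,)
    assert not psi.any()


def test_encoding_is_deterministic(toy_pair):
    pos, neg = toy_pair
    z0 = psdp(pair_frequencies([pos], 0), pair_frequencies([neg], 0))
    z1 = psdp(pair_frequencies([pos], 1), pair_frequencies([neg], 1))
    a = encode(pos, z0, z1).components
    b = encode(pos, z0, z1).components
    np.testing.assert_array_equal(a, b)


def test_window_length_must_match_matrices(toy_pair):
    pos, neg = toy_pair
    z0 = psdp(pair_frequencies([pos], 0), pair_frequencies([neg], 0))
    z1 = psdp(pair_frequencies([pos], 1), pair_frequencies([neg], 1))
    with pytest.raises(DimensionMismatchError):
        encode(PeptideWindow("ZZCZZ"), z0, z1)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("gap", [0, 1])
def test_frequencies_match_brute_force_on_random_small_datasets(seed, gap):
    rng = random.Random(seed)
    windows = [random_window(rng) for _ in range(rng.randint(1, 20))]
    f = pair_frequencies([PeptideWindow(w) for w in windows], gap)
    expected = np.asarray(brute_pair_frequencies(windows, gap))
    np.testing.assert_allclose(f.values, expected, atol=1e-12)
    # column stochasticity
    np.testing.assert_allclose(f.values.sum(axis=0), 1.0, atol=1e-12)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_full_encoding_matches_brute_force(seed):
    rng = random.Random(seed)
    pos = [random_window(rng) for _ in range(rng.randint(2, 12))]
    neg = [random_window(rng) for _ in range(rng.randint(2, 12))]
    z0 = psdp(
        pair_frequencies([PeptideWindow(w) for w in pos], 0),
        pair_frequencies([PeptideWindow(w) for w in neg], 0),
    )
    z1 = psdp(
        pair_frequencies([PeptideWindow(w) for w in pos], 1),
        pair_frequencies([PeptideWindow(w) for w in neg], 1),
    )
    bz0 = brute_psdp(pos, neg, 0)
    bz1 = brute_psdp(pos, neg, 1)
    np.testing.assert_allclose(z0.values, np.asarray(bz0), atol=1e-12)
    np.testing.assert_allclose(z1.values, np.asarray(bz1), atol=1e-12)
    query = random_window(rng)
    psi = encode(PeptideWindow(query), z0, z1).components
    np.testing.assert_allclose(psi, brute_encode(query, bz0, bz1), atol=1e-12)
    # boundedness
    assert np.all(np.abs(z0.values) <= 1)
    assert np.all(np.abs(psi) <= 1)


def test_smoothing_keeps_columns_stochastic():
    f = pair_frequencies([PeptideWindow(W1)], 0, smoothing=0.5)
    np.testing.assert_allclose(f.values.sum(axis=0), 1.0, atol=1e-12)
    assert np.all(f.values > 0)


def test_batch_encoding_agrees_with_single_window_path(separable_data):
    pos, neg = separable_data
    z0 = psdp(pair_frequencies(pos, 0), pair_frequencies(neg, 0))
    z1 = psdp(pair_frequencies(pos, 1), pair_frequencies(neg, 1))
    batch = encode_codes(windows_to_codes(pos[:5]), z0, z1)
    for i, w in enumerate(pos[:5]):
        np.testing.assert_array_equal(batch[i], encode(w, z0, z1).components)
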