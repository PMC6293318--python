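"""Unit tests for the truncated-signature engine: closed forms, Chen
concatenation, the quadrature oracle and the exact symbolic oracle."""

import itertools

import numpy as np
import pytest

from helpers import random_path, sympy_signature

from moodsig.signature import (
    TruncatedSignature,
    brute_force_signature,
    chen_concatenate,
    identity_signature,
    path_signature,
    segment_signature,
    shuffle_product,
    sig_dim,
    word_index,
    word_manifest,
    words,
)


@pytest.mark.parametrize(
    "d,n,expected", [(7, 2, 57), (1, 5, 6), (7, 4, 2801), (3, 0, 1), (2, 3, 15)]
)
def test_sig_dim(d, n, expected):
    assert sig_dim(d, n) == expected


@pytest.mark.parametrize("d", [1, 2, 3, 7])
@pytest.mark.parametrize("n", [0, 1, 2, 4])
def test_sig_dim_matches_word_enumeration(d, n):
    assert sig_dim(d, n) == sum(1 for _ in words(d, n))


@pytest.mark.parametrize("d,n", [(0, 2), (-1, 1), (3, -1)])
def test_sig_dim_rejects_bad_arguments(d, n):
    with pytest.raises(ValueError):
        sig_dim(d, n)


def test_word_index_is_graded_lex_position():
    for d, n in [(2, 3), (3, 2), (7, 2)]:
        for pos, w in enumerate(words(d, n)):
            assert word_index(w, d) == pos
    assert word_manifest(2, 1) == ["", "1", "2"]


def test_segment_signature_closed_form():
    sig = segment_signature([1.0, 2.0], 2)
    expected = {"": 1, "1": 1, "2": 2, "1.1": 0.5, "1.2": 1, "2.1": 1, "2.2": 2}
    assert sig.to_dict() == pytest.approx(expected)


def test_segment_signature_of_zero_increment_is_identity():
    sig = segment_signature(np.zeros(4), 3)
    assert sig.coeffs[0] == 1.0
    assert np.all(sig.coeffs[1:] == 0.0)


def test_segment_signature_word_coefficient_vs_quadrature(rng):
    inc = rng.normal(size=7)
    sig = segment_signature(inc, 3)
    assert sig.coefficient((3, 3, 3)) == pytest.approx(inc[2] ** 3 / 6, rel=1e-12)
    two_point = np.vstack([np.zeros(7), inc])
    bf = brute_force_signature(two_point, (3, 3, 3), 3000)
    assert bf == pytest.approx(sig.coefficient((3, 3, 3)), abs=1e-6)


def test_segment_signature_rejects_nonfinite():
    with pytest.raises(ValueError):
        segment_signature([np.nan, 1.0], 2)


def test_chen_identity_element():
    rng = np.random.default_rng(0)
    s = segment_signature(rng.normal(size=3), 3)
    e = identity_signature(3, 3)
    for combo in (chen_concatenate(s, e), chen_concatenate(e, s)):
        np.testing.assert_allclose(combo.coeffs, s.coeffs, atol=1e-12)


def test_chen_collinear_segments_merge():
    delta = np.array([0.5, -1.0, 2.0])
    c = 1.7
    combined = chen_concatenate(
        segment_signature(delta, 3), segment_signature(c * delta, 3)
    )
    np.testing.assert_allclose(
        combined.coeffs, segment_signature((1 + c) * delta, 3).coeffs, atol=1e-12
    )


def test_chen_rejects_mismatched_signatures():
    with pytest.raises(ValueError):
        chen_concatenate(identity_signature(2, 2), identity_signature(3, 2))
    with pytest.raises(ValueError):
        chen_concatenate(identity_signature(2, 2), identity_signature(2, 3))


def test_path_signature_single_segment(rng):
    path = random_path(rng, 2, 5)
    np.testing.assert_allclose(
        path_signature(path, 3).coeffs,
        segment_signature(path[1] - path[0], 3).coeffs,
        atol=1e-12,
    )


def test_path_signature_level_one_is_total_increment(rng):
    path = random_path(rng, 7, 4)
    sig = path_signature(path, 2)
    np.testing.assert_allclose(sig.level(1), path[-1] - path[0], atol=1e-12)


def test_path_signature_ignores_duplicate_points(rng):
    path = random_path(rng, 5, 3)
    dup = np.vstack([path[:3], path[2:3], path[3:]])
    np.testing.assert_allclose(
        path_signature(dup, 3).coeffs, path_signature(path, 3).coeffs, atol=1e-12
    )


def test_path_signature_rejects_degenerate_input(rng):
    with pytest.raises(ValueError):
        path_signature(np.zeros((1, 3)), 2)
    with pytest.raises(ValueError):
        path_signature(random_path(rng, 4, 3), 0)


def test_brute_force_empty_and_single_letter(rng):
    path = random_path(rng, 5, 3)
    assert brute_force_signature(path, (), 10) == 1.0
    for i in range(3):
        assert brute_force_signature(path, (i + 1,), 50) == pytest.approx(
            path[-1, i] - path[0, i], abs=1e-9
        )


def test_brute_force_unit_square_corner():
    corner = [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]
    assert brute_force_signature(corner, (1, 2), 500) == pytest.approx(1.0, abs=1e-9)
    assert brute_force_signature(corner, (2, 1), 500) == pytest.approx(0.0, abs=1e-9)
    reverse = [[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
    assert brute_force_signature(reverse, (1, 2), 500) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize(
    "u,v,expected",
    [
        ((1,), (2,), {(1, 2): 1, (2, 1): 1}),
        ((), (3, 1), {(3, 1): 1}),
        ((1, 2), (3,), {(3, 1, 2): 1, (1, 3, 2): 1, (1, 2, 3): 1}),
        ((1,), (1,), {(1, 1): 2}),
    ],
)
def test_shuffle_product_enumerates_interleavings(u, v, expected):
    import math
    from collections import Counter

    result = shuffle_product(u, v)
    assert Counter(result) == expected
    assert len(result) == math.comb(len(u) + len(v), len(u))


def test_signature_matches_exact_symbolic_oracle():
    """Closed-form engine vs exact iterated integration (sympy) on small
    rational paths, every word up to length 3."""
    paths = [
        [(0, 0), (1, "1/2"), ("1/3", 2), (1, 1)],
        [(0, 0, 0), (1, "1/2", "-1/2"), ("1/2", 1, "1/4"), ("3/2", 2, 1)],
    ]
    from fractions import Fraction

    for points in paths:
        d = len(points[0])
        numeric = np.array(
            [[float(Fraction(str(x))) for x in pt] for pt in points]
        )
        sig = path_signature(numeric, 3)
        for w in words(d, 3):
            exact = float(sympy_signature(points, w))
            assert sig.coefficient(w) == pytest.approx(exact, abs=1e-9), w


def test_truncated_signature_validation():
    with pytest.raises(ValueError):
        TruncatedSignature(2, 2, np.zeros(7))  # empty-word coefficient not 1
    with pytest.raises(ValueError):
        TruncatedSignature(2, 2, np.ones(5))  # wrong length
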