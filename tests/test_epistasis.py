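"""Epistasis measures, sign-motif classification, and map-induced transitions."""

import itertools
import math

import numpy as np
import pytest

from incon.epistasis import (
    SignMotif,
    Square,
    classify_sign_motif,
    congruence_probability,
    large_sigma_product,
    magnitude_epistasis,
    motif_transition_matrix,
    multiplicative_epistasis,
)
from incon.fitness_map import GaussianMap


def motif_by_cycle_extrema(square: Square) -> SignMotif:
    """Independent oracle: classify via local extrema of the 4-cycle 00-01-11-10.

    Reciprocal sign epistasis has two local maxima (the diagonal), the
    no-sign motif has its unique maximum and minimum on a diagonal, and the
    simple-sign motif has them adjacent.
    """
    cycle = [square.w00, square.w01, square.w11, square.w10]
    n_max = sum(
        cycle[i] > cycle[(i + 1) % 4] and cycle[i] > cycle[(i - 1) % 4] for i in range(4)
    )
    if n_max == 2:
        return SignMotif.RECIPROCAL_SIGN
    i_max = max(range(4), key=cycle.__getitem__)
    i_min = min(range(4), key=cycle.__getitem__)
    return SignMotif.NO_SIGN if abs(i_max - i_min) == 2 else SignMotif.SIMPLE_SIGN


def test_magnitude_and_multiplicative_examples():
    assert magnitude_epistasis(Square(0, 0.3, 0.5, 0.8)) == pytest.approx(0.0)
    assert magnitude_epistasis(Square(0, 0.3, 0.5, 1.0)) == pytest.approx(0.2)
    assert multiplicative_epistasis(Square(0.2, 0.3, 0.4, 0.6)) == pytest.approx(0.0)
    assert multiplicative_epistasis(Square(0.1, 0.2, 0.3, 0.9)) == pytest.approx(0.03)
    rng = np.random.default_rng(0)
    for _ in range(50):
        sq = Square(*rng.random(4))
        neg = Square(*(-v for v in sq))
        assert magnitude_epistasis(neg) == pytest.approx(-magnitude_epistasis(sq))


def test_sign_motif_examples():
    assert classify_sign_motif(Square(0, 0.3, 0.5, 0.8)) is SignMotif.NO_SIGN
    assert classify_sign_motif(Square(0.1, 0.4, 0.3, 0.2)) is SignMotif.RECIPROCAL_SIGN
    assert classify_sign_motif(Square(0.1, 0.4, 0.3, 0.35)) is SignMotif.SIMPLE_SIGN


def test_sign_motif_agrees_with_cycle_extrema_oracle_on_all_rank_orders():
    for perm in itertools.permutations((0.1, 0.35, 0.6, 0.9)):
        sq = Square(*perm)
        assert classify_sign_motif(sq) is motif_by_cycle_extrema(sq)


from hypothesis import assume, given, settings
from hypothesis import strategies as st

unit_floats = st.floats(0.001, 0.999, allow_nan=False)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(unit_floats, unit_floats, unit_floats, unit_floats, st.floats(0.05, 20), st.floats(-5, 5))
def test_sign_motif_invariant_under_affine_rescaling(w00, w01, w10, w11, scale, shift):
    values = (w00, w01, w10, w11)
    # keep effects well above rounding error so strict sign comparisons survive
    assume(min(abs(a - b) for i, a in enumerate(values) for b in values[i + 1 :]) > 1e-6)
    sq = Square(*values)
    rescaled = Square(*(scale * v + shift for v in sq))
    assert classify_sign_motif(rescaled) is classify_sign_motif(sq)


def test_sign_motif_invariant_under_monotone_transforms():
    rng = np.random.default_rng(3)
    transforms = [lambda x: x**3, np.exp, lambda x: 2 * x + 1, lambda x: x / (1 + x)]
    for _ in range(200):
        sq = Square(*rng.random(4))
        motif = classify_sign_motif(sq)
        for f in transforms:
            assert classify_sign_motif(Square(*(f(np.asarray(sq))))) is motif


def test_large_sigma_expansion_vanishes_for_additive_squares():
    # exactly representable values with w00 + w11 - w01 - w10 == 0 in floats
    assert large_sigma_product(Square(0.25, 0.5, 0.5, 0.75), w_opt=0.3, sigma=5.0) == 0.0


def exact_product(sq, w_opt, sigma):
    gmap = GaussianMap(w_opt=w_opt, sigma=sigma)
    F = gmap(np.asarray(sq))
    return (F[0] + F[3] - F[1] - F[2]) * magnitude_epistasis(sq)


def test_large_sigma_expansion_sign_and_convergence():
    rng = np.random.default_rng(11)
    squares = [Square(*rng.random(4)) for _ in range(500)]
    w_opt = 0.4
    agree = sum(
        np.sign(large_sigma_product(sq, w_opt, 100.0)) == np.sign(exact_product(sq, w_opt, 100.0))
        for sq in squares
    )
    assert agree / len(squares) > 0.99

    rel_err = []
    for sigma in (10.0, 20.0, 40.0):
        errs = [
            abs(large_sigma_product(sq, w_opt, sigma) - exact_product(sq, w_opt, sigma))
            / abs(exact_product(sq, w_opt, sigma))
            for sq in squares
        ]
        rel_err.append(np.median(errs))
    assert rel_err[0] > rel_err[1] > rel_err[2]


def test_congruence_probability_reproducible_and_increasing_at_large_sigma():
    grid = np.linspace(0, 1, 6)
    df1 = congruence_probability(grid, sigma=1.0, n_reps=8000, seed=4)
    df2 = congruence_probability(grid, sigma=1.0, n_reps=8000, seed=4)
    assert df1.equals(df2)
    p = df1["p_congruent"].to_numpy()
    assert p[-1] > p[0]
    assert np.all(np.diff(p) > -0.02)  # increasing up to Monte-Carlo noise
    assert np.all(df1["p_zero_fitness"] == 0.0)  # no underflow at sigma = 1


def test_congruence_probability_large_sigma_method_matches_exact():
    grid = [0.2, 0.8]
    exact = congruence_probability(grid, sigma=50.0, n_reps=20000, seed=9)
    approx = congruence_probability(grid, sigma=50.0, n_reps=20000, seed=9, method="large_sigma")
    np.testing.assert_allclose(
        exact["p_congruent"], approx["p_congruent"], atol=0.02
    )


def test_underflow_yields_zero_fitness_epistasis_at_small_sigma():
    df = congruence_probability([0.0], sigma=0.005, n_reps=4000, seed=2)
    assert df.loc[0, "p_zero_fitness"] > 0.5


def test_motif_transitions_rows_sum_to_one_and_forbidden_move_absent():
    grid = np.linspace(0, 1, 11)
    matrix, counts = motif_transition_matrix(grid, n_reps=4000, seed=8)
    sums = np.nansum(matrix, axis=2)
    np.testing.assert_allclose(sums[counts > 0], 1.0)
    # simple sign epistasis never becomes reciprocal under the map
    assert np.all(matrix[:, 1, 2][counts[:, 1] > 0] == 0.0)


def test_reciprocal_splits_evenly_and_retention_symmetric():
    grid = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
    matrix, counts = motif_transition_matrix(grid, n_reps=30_000, seed=15)
    # reciprocal -> no_sign vs reciprocal -> simple_sign: equal probabilities
    n_rec = counts[:, 2]
    to_no = matrix[:, 2, 0] * n_rec
    to_simple = matrix[:, 2, 1] * n_rec
    diff = np.abs(to_no - to_simple)
    assert np.all(diff <= 3 * np.sqrt(to_no + to_simple + 1))
    # retention curves symmetric about w_opt = 0.5 for each starting motif
    for motif in range(3):
        r = matrix[:, motif, motif]
        n = counts[:, motif]
        for i, j in [(0, 4), (1, 3)]:
            se = math.sqrt(
                r[i] * (1 - r[i]) / n[i] + r[j] * (1 - r[j]) / n[j]
            )
            assert abs(r[i] - r[j]) <= 4 * se


def test_extreme_optima_retain_motifs():
    matrix, counts = motif_transition_matrix([0.0, 1.0], n_reps=3000, seed=23)
    for k in range(2):
        for motif in range(3):
            if counts[k, motif] > 0:
                assert matrix[k, motif, motif] == 1.0
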