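"""Local incongruence: magnitude and sign epistasis of two-locus squares.

A *square* holds the four values (phenotype or fitness) of one locus pair in
one genetic background: ``w00, w01, w10, w11``. Magnitude epistasis is the
linear combination ``eps = w00 + w11 - w01 - w10`` (additive when zero,
positive/negative by sign). Sign-epistasis motifs are rank-based: a locus
"changes sign" when its effect has strictly opposite signs in the two
backgrounds of the other locus; no locus changing gives the no-sign motif,
exactly one the simple-sign motif, and both the reciprocal-sign motif.

The module also provides the large-``sigma`` expansion of the congruence
product ``eps_f * eps_gp`` and Monte-Carlo sweeps over random squares: the
probability of keeping the same magnitude-epistasis type after the Gaussian
map, and the 3x3 motif transition matrix.
"""

from __future__ import annotations

import enum
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._seeds import spawn_rng
from .fitness_map import GaussianMap

__all__ = [
    "Square",
    "SignMotif",
    "magnitude_epistasis",
    "multiplicative_epistasis",
    "classify_sign_motif",
    "large_sigma_product",
    "congruence_probability",
    "motif_transition_matrix",
]


class Square(NamedTuple):
    """Phenotype or fitness values of one locus pair in one background."""

    w00: float
    w01: float
    w10: float
    w11: float


class SignMotif(enum.IntEnum):
    NO_SIGN = 0
    SIMPLE_SIGN = 1
    RECIPROCAL_SIGN = 2


def magnitude_epistasis(square: Square) -> float:
    """``eps = w00 + w11 - w01 - w10``."""
    w00, w01, w10, w11 = square
    return w00 + w11 - w01 - w10


def multiplicative_epistasis(square: Square) -> float:
    """``eps_m = w00 * w11 - w01 * w10``."""
    w00, w01, w10, w11 = square
    return w00 * w11 - w01 * w10


def _motif_codes(w00, w01, w10, w11, tol=0.0) -> np.ndarray:
    """Vectorised motif code: 0 no-sign, 1 simple, 2 reciprocal.

    A locus changes sign when its two background effects are strictly
    opposite (each exceeding ``tol`` in magnitude).
    """
    d1_b0 = w10 - w00  # effect of locus 1 with locus 2 = 0
    d1_b1 = w11 - w01
    d2_b0 = w01 - w00
    d2_b1 = w11 - w10
    flip1 = (np.abs(d1_b0) > tol) & (np.abs(d1_b1) > tol) & (np.sign(d1_b0) != np.sign(d1_b1))
    flip2 = (np.abs(d2_b0) > tol) & (np.abs(d2_b1) > tol) & (np.sign(d2_b0) != np.sign(d2_b1))
    return flip1.astype(np.int8) + flip2.astype(np.int8)


def classify_sign_motif(square: Square, tol: float = 0.0) -> SignMotif:
    """Classify one square as no / simple / reciprocal sign epistasis."""
    w00, w01, w10, w11 = (np.asarray(v, dtype=float) for v in square)
    return SignMotif(int(_motif_codes(w00, w01, w10, w11, tol)))


def large_sigma_product(square: Square, w_opt: float, sigma: float) -> float:
    """Weak-selection expansion of ``eps_f * eps_gp``.

    ``(1/sigma^2) * [2 eps_m eps_gp + (2 w_opt - sum_i w_i) eps_gp^2]``;
    its sign predicts whether the magnitude-epistasis type survives the map
    when ``sigma`` is large.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    e_gp = magnitude_epistasis(square)
    e_m = multiplicative_epistasis(square)
    return (2.0 * e_m * e_gp + (2.0 * w_opt - sum(square)) * e_gp**2) / sigma**2


def _draw_squares(rng: np.random.Generator, n: int) -> tuple[np.ndarray, ...]:
    w = rng.random((n, 4))
    return w[:, 0], w[:, 1], w[:, 2], w[:, 3]


def congruence_probability(
    w_opt_grid,
    sigma: float,
    n_reps: int,
    seed: int | None = None,
    method: str = "exact",
) -> pd.DataFrame:
    """P(eps_gp * eps_f > 0) over random two-locus landscapes, per ``w_opt``.

    ``method="exact"`` evaluates the Gaussian map; ``method="large_sigma"``
    uses the sign of the weak-selection expansion instead. The returned
    frame also reports ``p_zero_fitness``, the fraction of replicates whose
    fitness epistasis is exactly zero because all four fitness values
    underflowed (the strong-selection regime).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if method not in ("exact", "large_sigma"):
        raise ValueError(f"unknown method {method!r}")
    w_opt_grid = np.atleast_1d(np.asarray(w_opt_grid, dtype=float))
    rows = []
    for k, w_opt in enumerate(w_opt_grid):
        rng = spawn_rng(seed, "congruence", k)
        w00, w01, w10, w11 = _draw_squares(rng, n_reps)
        e_gp = w00 + w11 - w01 - w10
        if method == "exact":
            gmap = GaussianMap(w_opt=w_opt, sigma=sigma)
            F00, F01, F10, F11 = (gmap(v) for v in (w00, w01, w10, w11))
            e_f = F00 + F11 - F01 - F10
            product = e_gp * e_f
            p_zero = float(np.mean(e_f == 0.0))
        else:
            e_m = w00 * w11 - w01 * w10
            total = w00 + w01 + w10 + w11
            product = (2.0 * e_m * e_gp + (2.0 * w_opt - total) * e_gp**2) / sigma**2
            p_zero = 0.0
        rows.append(
            {
                "w_opt": float(w_opt),
                "p_congruent": float(np.mean(product > 0)),
                "p_zero_fitness": p_zero,
            }
        )
    return pd.DataFrame(rows)


def motif_transition_matrix(
    w_opt_grid,
    n_reps: int,
    seed: int | None = None,
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Motif transition probabilities under the Gaussian map.

    For each ``w_opt`` in the grid, draws ``n_reps`` random squares,
    classifies the sign motif before and after the map, and returns

    * ``matrix``: shape ``(len(grid), 3, 3)``; ``matrix[k, i, j]`` is the
      probability that a square with motif ``i`` in the phenotype landscape
      has motif ``j`` in the fitness landscape (rows sum to 1);
    * ``counts``: shape ``(len(grid), 3)``; occurrences of each phenotype
      motif.

    The result is independent of ``sigma`` (the classification is
    rank-based) as long as no fitness values underflow.
    """
    w_opt_grid = np.atleast_1d(np.asarray(w_opt_grid, dtype=float))
    G = len(w_opt_grid)
    matrix = np.zeros((G, 3, 3))
    counts = np.zeros((G, 3), dtype=np.int64)
    for k, w_opt in enumerate(w_opt_grid):
        rng = spawn_rng(seed, "motif", k)
        w00, w01, w10, w11 = _draw_squares(rng, n_reps)
        gp = _motif_codes(w00, w01, w10, w11)
        gmap = GaussianMap(w_opt=w_opt, sigma=sigma)
        F00, F01, F10, F11 = (gmap(v) for v in (w00, w01, w10, w11))
        f = _motif_codes(F00, F01, F10, F11)
        joint = np.zeros((3, 3), dtype=np.int64)
        np.add.at(joint, (gp, f), 1)
        row_tot = joint.sum(axis=1)
        counts[k] = row_tot
        with np.errstate(invalid="ignore"):
            matrix[k] = np.where(row_tot[:, None] > 0, joint / row_tot[:, None], np.nan)
    return matrix, counts
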