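"""Global incongruence: plateau-aware peak detection and peak-count change.

Two neighboring genotypes are *indistinguishable* when their score
difference is at most the larger of their two noise thresholds. Plateaus
are the connected components of the indistinguishability graph (its
transitive closure, since indistinguishability itself is not transitive),
and a plateau is a *peak* when no member has a neighbor outside the plateau
with distinguishably higher score. With zero noise this reduces to the
classical definition: maximal connected sets of equal-score genotypes with
no strictly fitter neighbor.

The replicate sweeps compare the number of peaks before (``p_gp``) and
after (``p_f``) the Gaussian phenotype-to-fitness map and report the mean
absolute change ``<|p_f - p_gp|>`` together with the probabilities that the
count changes, increases, or decreases. Because peak counts are rank
statistics, the sweeps evaluate the map through the monotone surrogate
``-(w - w_opt)**2``, making them independent of ``sigma`` by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import beta as beta_fn
from scipy.special import betainc

from ._seeds import spawn_rng
from .genotype_space import Landscape, hamming_neighbor_index

__all__ = [
    "PeakSet",
    "IncongruenceSummary",
    "find_peaks",
    "peak_count",
    "batch_peak_counts",
    "incongruence_sweep",
    "nk_incongruence_sweep",
    "hoc_incongruence_sweep",
    "hoc_mean_peak_count",
    "hoc_peak_count_variance",
    "hoc_peak_count_covariance",
    "hoc_large_L_mean_abs_change",
    "sufficient_squares",
    "total_squares",
]


@dataclass
class PeakSet:
    """Plateaus of a landscape with peak flags, heights, and widths."""

    peaks: list[np.ndarray]  # member indices of each peak plateau
    heights: np.ndarray  # score of each peak (max over the plateau)
    widths: np.ndarray  # genotype count of each peak
    global_height: float  # maximum score anywhere in the landscape
    component_of: np.ndarray  # plateau id per genotype
    is_peak_component: np.ndarray  # bool per plateau id
    height_of_component: np.ndarray = field(repr=False, default=None)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def peak_genotypes(self, landscape: Landscape) -> list[list[str]]:
        return [[landscape.genotypes[i] for i in members] for members in self.peaks]


def find_peaks(landscape: Landscape, delta_mode: str = "noise") -> PeakSet:
    """Detect peak plateaus of a landscape.

    ``delta_mode="noise"`` uses the per-genotype noise thresholds;
    ``"zero"`` forces exact-score comparison (``delta = 0``).
    """
    if delta_mode not in ("noise", "zero"):
        raise ValueError(f"delta_mode must be 'noise' or 'zero', got {delta_mode!r}")
    n = len(landscape)
    if n == 0:
        raise ValueError("cannot find peaks of an empty landscape")
    s = landscape.scores
    I, J = landscape.edge_arrays()
    if delta_mode == "noise" and landscape.has_noise:
        thr = np.maximum(landscape.noise[I], landscape.noise[J])
    else:
        thr = 0.0
    diff = s[J] - s[I]
    indist = np.abs(diff) <= thr

    graph = sparse.csr_matrix(
        (np.ones(int(indist.sum()), dtype=np.int8), (I[indist], J[indist])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)

    # a plateau is disqualified when any member sees a distinguishably
    # higher score across an edge
    has_higher = np.zeros(n_comp, dtype=bool)
    higher = diff > thr
    has_higher[comp[I[higher]]] = True
    is_peak = ~has_higher

    comp_height = np.full(n_comp, -np.inf)
    np.maximum.at(comp_height, comp, s)

    order = np.argsort(comp, kind="stable")
    bounds = np.searchsorted(comp[order], np.arange(n_comp + 1))
    peaks = [order[bounds[c] : bounds[c + 1]] for c in np.flatnonzero(is_peak)]
    return PeakSet(
        peaks=peaks,
        heights=comp_height[is_peak],
        widths=np.array([len(p) for p in peaks], dtype=np.int64),
        global_height=float(s.max()),
        component_of=comp,
        is_peak_component=is_peak,
        height_of_component=comp_height,
    )


def peak_count(landscape: Landscape, delta_mode: str = "noise") -> int:
    return find_peaks(landscape, delta_mode).n_peaks


def batch_peak_counts(scores: np.ndarray, neighbor_index: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Strict peak counts for many score vectors on one neighbor graph.

    ``scores`` is ``(R, n)``; ``neighbor_index`` is ``(n, deg)``. A genotype
    is a peak when its score strictly exceeds all neighbors' (the zero-noise
    rule for landscapes with distinct scores). Processes replicates in
    chunks to bound memory.
    """
    scores = np.asarray(scores)
    R = scores.shape[0]
    out = np.empty(R, dtype=np.int64)
    for lo in range(0, R, chunk):
        s = scores[lo : lo + chunk]
        out[lo : lo + chunk] = np.all(s[:, :, None] > s[:, neighbor_index], axis=2).sum(axis=1)
    return out


@dataclass
class IncongruenceSummary:
    """Per-``w_opt`` aggregate of the peak-count change across replicates."""

    w_opt: float
    mean_abs_change: float
    se_abs_change: float
    p_change: float
    p_increase: float
    p_decrease: float
    mean_p_gp: float
    mean_p_f: float
    n_reps: int


def incongruence_sweep(
    sampler,
    neighbor_index: np.ndarray,
    w_opt_grid,
    n_reps: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Peak-count incongruence of random landscapes across a ``w_opt`` grid.

    ``sampler(rng, n_reps)`` must return an ``(n_reps, n)`` phenotype score
    matrix; fresh replicates are drawn per grid point from named substreams
    of ``seed``.
    """
    w_opt_grid = np.atleast_1d(np.asarray(w_opt_grid, dtype=float))
    rows = []
    for k, w_opt in enumerate(w_opt_grid):
        rng = spawn_rng(seed, "sweep", k)
        w = sampler(rng, n_reps)
        p_gp = batch_peak_counts(w, neighbor_index)
        p_f = batch_peak_counts(-((w - w_opt) ** 2), neighbor_index)
        d = p_f - p_gp
        ad = np.abs(d)
        rows.append(
            IncongruenceSummary(
                w_opt=float(w_opt),
                mean_abs_change=float(ad.mean()),
                se_abs_change=float(ad.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0,
                p_change=float(np.mean(d != 0)),
                p_increase=float(np.mean(d > 0)),
                p_decrease=float(np.mean(d < 0)),
                mean_p_gp=float(p_gp.mean()),
                mean_p_f=float(p_f.mean()),
                n_reps=n_reps,
            ).__dict__
        )
    return pd.DataFrame(rows)


def nk_incongruence_sweep(L, K, w_opt_grid, n_reps, seed=None) -> pd.DataFrame:
    from .generators import nk_scores_batch

    nbr = hamming_neighbor_index(L, 2)
    return incongruence_sweep(
        lambda rng, R: nk_scores_batch(rng, R, L, K), nbr, w_opt_grid, n_reps, seed
    )


def hoc_incongruence_sweep(L, w_opt_grid, n_reps, seed=None) -> pd.DataFrame:
    from .generators import uniform_scores_batch

    nbr = hamming_neighbor_index(L, 2)
    return incongruence_sweep(
        lambda rng, R: uniform_scores_batch(rng, R, L), nbr, w_opt_grid, n_reps, seed
    )


# -- House-of-Cards closed forms ------------------------------------------


def hoc_mean_peak_count(L: int) -> float:
    """Expected number of peaks of a random (House-of-Cards) landscape: 2^L/(L+1)."""
    return 2.0**L / (L + 1)


def hoc_peak_count_variance(L: int) -> float:
    """Exact variance of the House-of-Cards peak count.

    From the pairwise peak-indicator covariances on the hypercube: the
    distance-0 and distance-1 terms cancel exactly and the distance-2 pairs
    (two shared neighbors) leave ``2^(L-1) (L-1) / (L+1)^2``.
    """
    return 2.0 ** (L - 1) * (L - 1) / (L + 1) ** 2


def hoc_peak_count_covariance(L: int) -> float:
    """Exact covariance of the peak counts before and after the map at ``w_opt = 1/2``.

    The peak indicators of the phenotype landscape and of the fitness
    landscape (scores folded around the optimum) interact only for genotype
    pairs at Hamming distance at most 2. Each contribution is an explicit
    order-statistics integral over the shared uniform scores:

    * distance 0: P(top score and closest-to-optimum simultaneously)
      ``= 2^-L / (L+1)``;
    * distance 1: the pair's own scores are shared between both
      neighborhoods (incomplete-beta integral);
    * distance 2: the two common neighbors are shared (polynomial
      integral, evaluated by quadrature).
    """
    if L < 2:
        raise ValueError("L must be at least 2")
    q = 1.0 / (L + 1)

    p_a = 2.0**-L / (L + 1)

    # distance 1: (1/L) [ int_{1/2}^1 x^{L-1} dx - 2^L int_{1/2}^1 x^{L-1}(1-x)^L dx ]
    tail = beta_fn(L, L + 1) * (1.0 - betainc(L, L + 1, 0.5))
    p_b = ((1.0 - 2.0**-L) / L - 2.0**L * tail) / L

    # distance 2: shared pair must lie below the phenotype peak and outside
    # the fitness peak's fold window; Q(t) below is the per-shared-neighbor
    # overlap probability squared, integrated over the fold half-width t
    def Q(t: float) -> float:
        lo, hi = 0.5 - t, 0.5 + t
        term1 = lo ** (L + 1) / (L + 1)
        term2 = lo**2 * (hi ** (L - 1) - lo ** (L - 1)) / (L - 1)

        def anti(x: float) -> float:
            return (
                x ** (L + 1) / (L + 1)
                - 4 * t * x**L / L
                + 4 * t * t * x ** (L - 1) / (L - 1)
            )

        return term1 + term2 + anti(1.0) - anti(hi)

    p_c = 2.0 * integrate.quad(lambda t: (1 - 2 * t) ** (L - 2) * Q(t), 0, 0.5, limit=200)[0]

    return 2.0**L * (
        (p_a - q * q) + L * (p_b - q * q) + math.comb(L, 2) * (p_c - q * q)
    )


def hoc_large_L_mean_abs_change(L: int, finite_L_correction: bool = True) -> float:
    """Closed-form ``<|p_f - p_gp|>`` for House-of-Cards landscapes.

    The peak-count change is asymptotically normal with mean zero, so
    ``<|Delta|> = sqrt(2 Var(Delta) / pi)``. With
    ``finite_L_correction=False`` the variance uses independent peak counts
    with the exact single-landscape variance, giving the leading-order form
    ``sqrt(2^(L+1) (L-1) / pi) / (L + 1)``; the default additionally
    subtracts the exact finite-``L`` covariance between the two counts
    (evaluated at ``w_opt = 1/2``), which matters at moderate ``L``.
    """
    if L < 2:
        raise ValueError("L must be at least 2")
    var_p = hoc_peak_count_variance(L)
    var_d = 2.0 * var_p
    if finite_L_correction:
        var_d -= 2.0 * hoc_peak_count_covariance(L)
    return math.sqrt(2.0 * var_d / math.pi)


# -- square bookkeeping on the hypercube ----------------------------------


def sufficient_squares(L: int) -> int:
    """Number of two-locus squares sufficient to determine all motifs: 2^(L-2) (L-1)."""
    if L < 2:
        raise ValueError("L must be at least 2")
    return 2 ** (L - 2) * (L - 1)


def total_squares(L: int) -> int:
    """Total number of square faces of the L-dimensional hypercube: 2^(L-2) C(L, 2)."""
    if L < 2:
        raise ValueError("L must be at least 2")
    return 2 ** (L - 2) * math.comb(L, 2)
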