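"""Model genotype-phenotype landscape families.

Three random-landscape families are provided:

* two-locus biallelic landscapes with i.i.d. uniform(0, 1) phenotypes;
* NK landscapes with the cyclic adjacency interaction scheme, spanning the
  additive Mt. Fuji case (``K = 0``) through the fully random House-of-Cards
  case (``K = L - 1``); phenotypes are rescaled to span [0, 1] exactly;
* the mismatch model of transcription factor-DNA binding, where a genotype
  with ``m`` mismatches to the consensus sequence has phenotype
  ``A_m = 1 - m * e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seeds import as_rng
from .genotype_space import DNA_ALPHABET, GenotypeSpace, Landscape, enumerate_genotypes

__all__ = [
    "NKConfig",
    "MismatchConfig",
    "gen_two_locus",
    "gen_nk",
    "gen_house_of_cards",
    "gen_mismatch",
    "count_mismatch_class",
    "mismatch_class_sizes",
    "nk_scores_batch",
    "uniform_scores_batch",
]

_BINARY = ("0", "1")


@dataclass
class NKConfig:
    """Configuration for one NK landscape realisation.

    ``K`` loci to the right of each locus (cyclic) interact with it; the
    contribution table holds one uniform(0, 1) draw per locus per
    configuration of its ``K + 1``-locus neighborhood, drawn once per
    landscape replicate.
    """

    L: int
    K: int
    seed: int | None = None
    contributions: np.ndarray | None = None  # shape (L, 2**(K+1))

    def __post_init__(self) -> None:
        if not 0 <= self.K <= self.L - 1:
            raise ValueError(f"K must satisfy 0 <= K <= L-1, got K={self.K}, L={self.L}")
        if self.contributions is not None:
            expected = (self.L, 2 ** (self.K + 1))
            c = np.asarray(self.contributions, dtype=float)
            if c.shape != expected:
                raise ValueError(f"contribution table must have shape {expected}, got {c.shape}")
            if np.any(c < 0) or np.any(c > 1):
                raise ValueError("contributions must lie in [0, 1]")
            self.contributions = c


@dataclass
class MismatchConfig:
    """Mismatch-model parameters: per-mismatch penalty ``e`` and a consensus."""

    L: int
    a: int = 4
    e: float = 0.05
    consensus: str | None = None
    alphabet: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError(f"per-mismatch penalty e must be positive, got {self.e}")
        if self.alphabet is None:
            if self.a == 4:
                self.alphabet = DNA_ALPHABET
            elif self.a <= 10:
                self.alphabet = tuple(str(i) for i in range(self.a))
            else:
                raise ValueError("provide an explicit alphabet for a > 10")
        if len(self.alphabet) != self.a:
            raise ValueError("alphabet size must equal a")
        if self.consensus is None:
            self.consensus = self.alphabet[0] * self.L


def gen_two_locus(seed=None) -> Landscape:
    """A random two-locus biallelic phenotype landscape, scores i.i.d. uniform(0, 1)."""
    rng = as_rng(seed)
    space = GenotypeSpace(L=2, alphabet=_BINARY)
    return Landscape(space, enumerate_genotypes(space), rng.random(4), label="phenotype")


def _nk_locus_indices(L: int, K: int) -> np.ndarray:
    """Neighborhood configuration index of each locus for every genotype code."""
    n = 2**L
    codes = np.arange(n)
    bits = (codes[:, None] >> np.arange(L - 1, -1, -1)[None, :]) & 1  # (n, L), leftmost first
    idx = np.zeros((n, L), dtype=np.int64)
    for i in range(L):
        cols = [(i + j) % L for j in range(K + 1)]
        for c in cols:
            idx[:, i] = idx[:, i] * 2 + bits[:, c]
    return idx


def gen_nk(config: NKConfig) -> Landscape:
    """One NK landscape; raw scores are min-subtracted and range-divided to span [0, 1]."""
    rng = as_rng(config.seed)
    contrib = config.contributions
    if contrib is None:
        contrib = rng.random((config.L, 2 ** (config.K + 1)))
    idx = _nk_locus_indices(config.L, config.K)
    raw = np.zeros(2**config.L)
    for i in range(config.L):
        raw += contrib[i, idx[:, i]]
    raw -= raw.min()
    mx = raw.max()
    if mx > 0:
        raw /= mx
    space = GenotypeSpace(L=config.L, alphabet=_BINARY)
    return Landscape(space, enumerate_genotypes(space), raw, label="phenotype")


def gen_house_of_cards(L: int, seed=None) -> Landscape:
    """A House-of-Cards landscape: i.i.d. uniform(0, 1) score per genotype.

    Rank-equivalent to ``gen_nk`` with ``K = L - 1`` (whose raw scores are
    i.i.d. sums of uniforms); all peak and motif statistics used here are
    rank-based.
    """
    rng = as_rng(seed)
    space = GenotypeSpace(L=L, alphabet=_BINARY)
    return Landscape(space, enumerate_genotypes(space), rng.random(2**L), label="phenotype")


def gen_mismatch(config: MismatchConfig) -> Landscape:
    """The mismatch-model landscape: score ``1 - e * hamming(g, consensus)``.

    With ``L * e >= 1`` the farthest classes get non-positive phenotypes;
    this is permitted but unusual for the binding-affinity interpretation.
    """
    space = GenotypeSpace(L=config.L, alphabet=config.alphabet)
    genotypes = enumerate_genotypes(space)
    cons = config.consensus
    space.validate(cons)
    geno_arr = np.frombuffer("".join(genotypes).encode(), dtype="S1").reshape(len(genotypes), config.L)
    cons_arr = np.frombuffer(cons.encode(), dtype="S1")
    mismatches = (geno_arr != cons_arr[None, :]).sum(axis=1)
    scores = 1.0 - config.e * mismatches
    land = Landscape(space, genotypes, scores, label="phenotype")
    land.meta["mismatch_class"] = mismatches
    land.meta["consensus"] = cons
    return land


def count_mismatch_class(L: int, a: int, m: int) -> int:
    """Number of genotypes at Hamming distance ``m`` from a fixed sequence.

    ``N_m = (a-1)^m * C(L, m)``; the asymmetric binomial class-size law.
    """
    if not 0 <= m <= L:
        raise ValueError(f"mismatch class m must satisfy 0 <= m <= L, got {m}")
    return (a - 1) ** m * math.comb(L, m)


def mismatch_class_sizes(L: int, a: int) -> np.ndarray:
    """``N_m`` for m = 0..L; sums to ``a ** L``."""
    return np.array([count_mismatch_class(L, a, m) for m in range(L + 1)], dtype=np.int64)


# -- batch samplers for replicate sweeps ----------------------------------


def uniform_scores_batch(rng: np.random.Generator, n_reps: int, L: int) -> np.ndarray:
    """``(n_reps, 2**L)`` i.i.d. uniform score matrix (House-of-Cards replicates)."""
    return rng.random((n_reps, 2**L))


def nk_scores_batch(rng: np.random.Generator, n_reps: int, L: int, K: int) -> np.ndarray:
    """``(n_reps, 2**L)`` NK phenotype matrix, each row rescaled to span [0, 1]."""
    idx = _nk_locus_indices(L, K)
    contrib = rng.random((n_reps, L, 2 ** (K + 1)))
    raw = np.zeros((n_reps, 2**L))
    for i in range(L):
        raw += contrib[:, i, idx[:, i]]
    raw -= raw.min(axis=1, keepdims=True)
    mx = raw.max(axis=1, keepdims=True)
    np.divide(raw, mx, out=raw, where=mx > 0)
    return raw
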