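"""The Gaussian phenotype-to-fitness map and its noise propagation.

Fitness is ``F(w) = exp(-((w - w_opt) / sigma)**2)``: maximal (1) at the
optimal phenotype ``w_opt`` and symmetric around it. ``sigma`` sets the
strength of selection -- smaller ``sigma`` means fitness falls off faster
away from the optimum. Fitness values below the smallest positive double
(5e-324) underflow to exactly zero; such genotypes are counted and flagged
on the resulting landscape because a fitness plateau of exact zeros behaves
qualitatively differently (no magnitude epistasis, giant neutral plateaus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_space import Landscape

__all__ = ["UNDERFLOW_LIMIT", "GaussianMap", "apply_map", "propagate_noise"]

#: Smallest positive (subnormal) double; fitness below this is exactly 0.
UNDERFLOW_LIMIT = 5.0e-324


@dataclass(frozen=True)
class GaussianMap:
    """Gaussian fitness function ``F(w) = exp(-((w - w_opt)/sigma)^2)``."""

    w_opt: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def fitness(self, w) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        with np.errstate(under="ignore"):
            return np.exp(-(((w - self.w_opt) / self.sigma) ** 2))

    __call__ = fitness

    def noise_gain(self, w) -> np.ndarray:
        """|dF/dw| = 2 F(w) |w - w_opt| / sigma^2, the error-propagation factor."""
        w = np.asarray(w, dtype=float)
        return 2.0 * self.fitness(w) * np.abs(w - self.w_opt) / self.sigma**2


def apply_map(landscape: Landscape, gmap: GaussianMap) -> Landscape:
    """Apply the Gaussian map genotype-wise, propagating noise thresholds.

    Returns a fitness-labelled landscape on the same domain. The number of
    genotypes whose fitness underflowed to exactly zero is recorded in
    ``meta["n_underflow"]``.
    """
    if landscape.label != "phenotype":
        raise ValueError("apply_map expects a phenotype-labelled landscape")
    F = gmap.fitness(landscape.scores)
    n_underflow = int(np.count_nonzero(F < UNDERFLOW_LIMIT))
    F = np.where(F < UNDERFLOW_LIMIT, 0.0, F)
    dF = propagate_noise(landscape, gmap) if landscape.has_noise else None
    out = landscape.with_scores(F, noise=dF, label="fitness")
    out.meta["n_underflow"] = n_underflow
    out.meta["map"] = gmap
    return out


def propagate_noise(landscape: Landscape, gmap: GaussianMap) -> np.ndarray:
    """Per-genotype fitness noise magnitude ``dF = 2 F |w - w_opt| / sigma^2 * delta``."""
    return gmap.noise_gain(landscape.scores) * landscape.noise
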