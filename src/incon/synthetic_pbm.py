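"""Synthetic protein-binding-microarray (PBM) style landscapes.

Emulates the statistical structure of transcription-factor binding-affinity
landscapes measured on universal PBMs: all DNA 8-mers scored with an
enrichment-score-like value in [-0.5, 0.5], merged with reverse
complements, thresholded at a specificity cut-off (0.35 by default, the
conventional high-confidence E-score cut-off), connected under point
mutations plus single-base shifts, and annotated with a per-landscape
noise threshold ``delta``.

The score surface mixes an additive per-position energy model (which makes
neighboring sequences highly correlated, as observed for real TFs) with
i.i.d. noise; the ``energy_ruggedness`` knob interpolates from perfectly
additive (0) to uncorrelated House-of-Cards-like (1). This generator is a
synthetic stand-in for empirical PBM data -- it reproduces the qualitative
features the downstream analyses rely on (bounded scores, thresholding,
broad low-affinity classes, correlated neighborhoods), not any particular
transcription factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import spawn_rng
from .genotype_space import (
    DNA_ALPHABET,
    GenotypeSpace,
    Landscape,
    neighbors,
    reverse_complement,
    reverse_complement_class,
)

__all__ = ["PBMConfig", "gen_pbm_landscape", "gen_pbm_collection", "dominant_component"]


@dataclass
class PBMConfig:
    """Knobs of the synthetic PBM landscape generator.

    ``energy_ruggedness`` is the mixing weight of the i.i.d. noise component
    (0 = purely additive energies, 1 = pure noise); ``delta_scale`` is the
    per-landscape noise threshold attached to every genotype, mirroring the
    one-threshold-per-TF convention of PBM reproducibility analyses.
    """

    L: int = 8
    n_landscapes: int = 1
    energy_ruggedness: float = 0.2
    escore_threshold: float = 0.35
    delta_scale: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.energy_ruggedness <= 1.0:
            raise ValueError("energy_ruggedness must lie in [0, 1]")
        if not -0.5 < self.escore_threshold < 0.5:
            raise ValueError("escore_threshold must lie within (-0.5, 0.5)")
        if self.delta_scale < 0:
            raise ValueError("delta_scale must be non-negative")


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def gen_pbm_landscape(config: PBMConfig, index: int = 0, max_tries: int = 100) -> Landscape:
    """One synthetic PBM landscape (the dominant component above threshold).

    Scores all ``4^L`` sequences with a mixed additive/noise surface,
    rescales affinely (rank-preserving) into [-0.5, 0.5], merges reverse
    complements (canonical member keeps its score), retains scores at or
    above the threshold, and returns the largest connected component under
    the point-mutation + single-base-shift neighbor rule. Redraws (up to
    ``max_tries``) if thresholding empties the landscape.
    """
    space = GenotypeSpace(L=config.L, alphabet=DNA_ALPHABET, neighbor_rule="pbm_style")
    n = space.size
    codes = np.arange(n)
    digits = np.stack(
        [(codes // 4 ** (config.L - 1 - i)) % 4 for i in range(config.L)], axis=1
    )
    for attempt in range(max_tries):
        rng = spawn_rng(config.seed, "pbm", index, attempt)
        energy = rng.random((config.L, 4))
        additive = energy[np.arange(config.L)[None, :], digits].sum(axis=1)
        noise = rng.random(n)
        mix = config.energy_ruggedness
        raw = (1.0 - mix) * _standardise(additive) + mix * _standardise(noise)
        lo, hi = raw.min(), raw.max()
        scores = -0.5 + (raw - lo) / (hi - lo)  # affine, rank-preserving

        # merge reverse-complement pairs; the canonical strand's score stands
        # for the pair
        canon: dict[str, float] = {}
        from .genotype_space import enumerate_genotypes

        for g, s in zip(enumerate_genotypes(space), scores):
            c = reverse_complement_class(g)
            if c == g:
                canon[c] = float(s)
            else:
                canon.setdefault(c, float(s))
        retained = sorted(g for g, s in canon.items() if s >= config.escore_threshold)
        if retained:
            break
    else:
        raise RuntimeError(
            f"thresholding at {config.escore_threshold} emptied the landscape "
            f"{max_tries} times; lower the threshold or the ruggedness"
        )
    land = Landscape(
        space,
        retained,
        [canon[g] for g in retained],
        noise=np.full(len(retained), config.delta_scale),
        label="phenotype",
        merged_revcomp=True,
        meta={"energy_ruggedness": mix, "attempt": attempt},
    )
    return dominant_component(land)


def gen_pbm_collection(config: PBMConfig) -> list[Landscape]:
    """``config.n_landscapes`` independent synthetic PBM landscapes."""
    return [gen_pbm_landscape(config, index=i) for i in range(config.n_landscapes)]


def dominant_component(landscape: Landscape) -> Landscape:
    """The largest connected component of a landscape's neighborhood graph.

    The returned landscape records the retained fraction of genotypes in
    ``meta["dominant_fraction"]``. Idempotent; connected inputs come back
    unchanged (up to that annotation).
    """
    adj = landscape.adjacency()
    n = len(landscape)
    comp = np.full(n, -1, dtype=np.int64)
    n_comp = 0
    for root in range(n):
        if comp[root] >= 0:
            continue
        stack = [root]
        comp[root] = n_comp
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if comp[j] < 0:
                    comp[j] = n_comp
                    stack.append(int(j))
        n_comp += 1
    sizes = np.bincount(comp, minlength=n_comp)
    keep = np.flatnonzero(comp == int(np.argmax(sizes)))
    out = landscape.subset(keep, meta=dict(landscape.meta))
    out.meta["dominant_fraction"] = float(len(keep) / n)
    return out
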