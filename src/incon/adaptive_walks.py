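"""Greedy adaptive walks with plateau traversal.

A walk starts at a genotype and repeatedly moves to the distinguishably
fittest neighbor (ties broken uniformly at random). When no neighbor is
distinguishably fitter but the current plateau is not a peak, the walk
steps uniformly at random to an unvisited neighbor of indistinguishable
fitness until the plateau is traversed. The walk terminates when the
current plateau is a peak (or when a non-peak plateau offers no unvisited
indistinguishable neighbor, which can only happen under noise). Reversion
to any genotype already on the path is disallowed, which guarantees
termination; walk length counts every step, including plateau steps.

For the mismatch model the average walk length over all starting genotypes
has the closed form ``<l> = sum_m N_m |m_opt - m| / a^L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import spawn_rng
from .generators import count_mismatch_class
from .genotype_space import Landscape
from .peaks import PeakSet, find_peaks

__all__ = ["WalkResult", "greedy_walk", "mean_walk_length", "walk_ensemble", "mismatch_walk_length"]


@dataclass
class WalkResult:
    path: list[int]  # genotype indices, start through terminus
    length: int  # steps taken (== len(path) - 1)
    terminal_peak: int  # plateau id of the terminus
    terminal_is_peak: bool  # False only for noise-induced dead ends
    terminal_height_fraction: float  # terminal plateau height / global height

    def path_genotypes(self, landscape: Landscape) -> list[str]:
        return [landscape.genotypes[i] for i in self.path]


def greedy_walk(
    landscape: Landscape,
    start,
    rng=None,
    peakset: PeakSet | None = None,
    delta_mode: str = "noise",
) -> WalkResult:
    """One greedy adaptive walk from ``start`` (genotype string or index)."""
    if landscape.label != "fitness":
        raise ValueError("greedy walks run on fitness-labelled landscapes")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if peakset is None:
        peakset = find_peaks(landscape, delta_mode)
    s = landscape.scores
    noise = landscape.noise if (delta_mode == "noise" and landscape.has_noise) else None
    adj = landscape.adjacency()
    i = landscape.index_of(start) if isinstance(start, str) else int(start)

    path = [i]
    visited = {i}
    # every step either strictly increases fitness or visits a new plateau
    # member, so the path length is bounded by the landscape size
    for _ in range(len(landscape)):
        nbrs = adj[i]
        sn = s[nbrs]
        thr = np.maximum(noise[i], noise[nbrs]) if noise is not None else 0.0
        fitter = sn > s[i] + thr
        if np.any(fitter):
            cand = nbrs[fitter]
            cs = sn[fitter]
            best = cand[cs == cs.max()]
            i = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
            path.append(i)
            visited.add(i)
            continue
        if peakset.is_peak_component[peakset.component_of[i]]:
            break
        flat = np.abs(sn - s[i]) <= thr
        cand = [int(j) for j in nbrs[flat] if j not in visited]
        if not cand:
            break  # noise-induced dead end; report the plateau as terminal
        i = cand[rng.integers(len(cand))] if len(cand) > 1 else cand[0]
        path.append(i)
        visited.add(i)
    comp = int(peakset.component_of[i])
    return WalkResult(
        path=path,
        length=len(path) - 1,
        terminal_peak=comp,
        terminal_is_peak=bool(peakset.is_peak_component[comp]),
        terminal_height_fraction=float(peakset.height_of_component[comp] / peakset.global_height)
        if peakset.global_height != 0
        else float("nan"),
    )


def walk_ensemble(
    landscape: Landscape,
    starts="all",
    n_sims: int = 1,
    seed: int | None = None,
    delta_mode: str = "noise",
) -> list[WalkResult]:
    """Walks from every start, ``n_sims`` replicates each.

    ``starts`` is ``"all"`` (every genotype), ``"nonpeak"`` (genotypes
    outside peak plateaus), or an explicit list of genotypes/indices.
    """
    peakset = find_peaks(landscape, delta_mode)
    if starts == "all":
        start_idx = range(len(landscape))
    elif starts == "nonpeak":
        start_idx = np.flatnonzero(~peakset.is_peak_component[peakset.component_of])
    else:
        start_idx = [landscape.index_of(g) if isinstance(g, str) else int(g) for g in starts]
    results = []
    for i in start_idx:
        for sim in range(n_sims):
            rng = spawn_rng(seed, "walk", i, sim)
            results.append(greedy_walk(landscape, int(i), rng, peakset, delta_mode))
    return results


def mean_walk_length(
    landscape: Landscape,
    starts="all",
    n_sims: int = 1,
    seed: int | None = None,
    delta_mode: str = "noise",
) -> float:
    """Average greedy walk length over starts and simulations.

    Returns 0.0 for a landscape whose every genotype lies in a peak (the
    ``"nonpeak"`` start set is then empty).
    """
    results = walk_ensemble(landscape, starts, n_sims, seed, delta_mode)
    if not results:
        return 0.0
    return float(np.mean([r.length for r in results]))


def mismatch_walk_length(L: int, a: int, m_opt: int) -> float:
    """Closed-form mean greedy walk length on the mismatch-model fitness landscape.

    ``<l> = sum_m (a-1)^m C(L, m) |m_opt - m| / a^L``: with zero noise every
    walk descends the mismatch-class ladder one class per step, so its
    length is exactly ``|m_opt - m|``. The sum is accumulated in integers
    and divided once, so the result is exact.
    """
    if not 0 <= m_opt <= L:
        raise ValueError(f"m_opt must satisfy 0 <= m_opt <= L, got {m_opt}")
    total = sum(count_mismatch_class(L, a, m) * abs(m_opt - m) for m in range(L + 1))
    return total / a**L
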