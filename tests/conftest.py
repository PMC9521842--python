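"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from incon.genotype_space import GenotypeSpace, Landscape, enumerate_genotypes


def naive_peak_count(landscape: Landscape) -> int:
    """Strict no-fitter-neighbor scan (independent of the plateau machinery).

    Valid oracle for zero-noise landscapes with distinct scores.
    """
    from incon.genotype_space import neighbors

    count = 0
    for g in landscape.genotypes:
        s = landscape.score_of(g)
        if all(
            landscape.score_of(h) < s
            for h in neighbors(landscape.space, g)
            if h in landscape
        ):
            count += 1
    return count


def iter_squares(landscape: Landscape):
    """All two-locus squares of a complete biallelic landscape.

    Yields ``(w00, w01, w10, w11)`` for every locus pair and background,
    with the pair's alleles at 00/01/10/11.
    """
    L = landscape.space.L
    assert landscape.space.a == 2
    score = {g: landscape.score_of(g) for g in landscape.genotypes}
    for i, j in itertools.combinations(range(L), 2):
        others = [k for k in range(L) if k not in (i, j)]
        for bg in itertools.product("01", repeat=len(others)):
            def build(ai, aj):
                chars = [""] * L
                chars[i] = ai
                chars[j] = aj
                for k, c in zip(others, bg):
                    chars[k] = c
                return "".join(chars)

            yield (
                score[build("0", "0")],
                score[build("0", "1")],
                score[build("1", "0")],
                score[build("1", "1")],
            )


@pytest.fixture
def binary_space_3():
    return GenotypeSpace(3, ("0", "1"))


@pytest.fixture
def random_binary_landscape():
    """Factory for complete biallelic landscapes with i.i.d. uniform scores."""

    def make(L: int, seed: int = 0) -> Landscape:
        rng = np.random.default_rng(seed)
        space = GenotypeSpace(L, ("0", "1"))
        return Landscape(space, enumerate_genotypes(space), rng.random(2**L))

    return make
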