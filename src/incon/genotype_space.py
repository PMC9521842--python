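"""Genotype universes, neighborhood graphs, and landscape I/O.

A genotype is a length-``L`` string over an ``a``-letter alphabet. The
:class:`GenotypeSpace` fixes the universe and the mutational neighborhood
rule: plain Hamming neighbors (single-position substitutions), or the
``pbm_style`` rule used for transcription-factor binding sites, which adds
single-base shift neighbors (the last ``L-1`` symbols of one genotype equal
the first ``L-1`` symbols of the other) and supports merging each DNA
genotype with its reverse complement.

A :class:`Landscape` attaches a real-valued score (phenotype or fitness) and
an optional non-negative noise threshold to every genotype in its domain.
The domain may be the full space (model landscapes) or a subset (synthetic
protein-binding-microarray landscapes after thresholding).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DNA_ALPHABET",
    "CapacityError",
    "GenotypeSpace",
    "Landscape",
    "enumerate_genotypes",
    "neighbors",
    "reverse_complement",
    "reverse_complement_class",
    "merge_reverse_complements",
    "hamming_neighbor_index",
    "read_landscape",
    "write_landscape",
]

DNA_ALPHABET = ("A", "C", "G", "T")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Hard cap on enumerable genotype universes; everything studied here
#: needs at most 4**8 = 65,536 genotypes.
MAX_GENOTYPES = 10_000_000


class CapacityError(ValueError):
    """Raised when a genotype universe is too large to enumerate."""


@dataclass(frozen=True)
class GenotypeSpace:
    """The set of length-``L`` strings over an alphabet, plus a neighbor rule.

    Parameters
    ----------
    L:
        Number of loci (string length), positive.
    alphabet:
        Ordered tuple of distinct single-character symbols; its length is the
        number of alleles per locus ``a`` (at least 2).
    neighbor_rule:
        ``"hamming"`` (single-position substitutions; every genotype has
        exactly ``(a - 1) * L`` neighbors) or ``"pbm_style"`` (substitutions
        plus single-base shift neighbors).
    """

    L: int
    alphabet: tuple[str, ...] = DNA_ALPHABET
    neighbor_rule: str = "hamming"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be a positive integer, got {self.L}")
        alphabet = tuple(self.alphabet)
        object.__setattr__(self, "alphabet", alphabet)
        if len(alphabet) < 2:
            raise ValueError("alphabet must contain at least two symbols")
        if len(set(alphabet)) != len(alphabet):
            raise ValueError("alphabet symbols must be distinct")
        if any(len(s) != 1 for s in alphabet):
            raise ValueError("alphabet symbols must be single characters")
        if self.neighbor_rule not in ("hamming", "pbm_style"):
            raise ValueError(f"unknown neighbor rule {self.neighbor_rule!r}")

    @property
    def a(self) -> int:
        """Number of alleles per locus."""
        return len(self.alphabet)

    @property
    def size(self) -> int:
        """Number of genotypes in the universe, ``a ** L``."""
        return self.a**self.L

    @property
    def is_dna(self) -> bool:
        return set(self.alphabet) == set(DNA_ALPHABET)

    def validate(self, g: str) -> None:
        if len(g) != self.L:
            raise ValueError(f"genotype {g!r} has length {len(g)}, expected {self.L}")
        bad = set(g) - set(self.alphabet)
        if bad:
            raise ValueError(f"genotype {g!r} uses symbols outside the alphabet: {sorted(bad)}")

    def encode(self, g: str) -> int:
        """Integer code of ``g`` in lexicographic (alphabet-order) enumeration."""
        self.validate(g)
        idx = {s: i for i, s in enumerate(self.alphabet)}
        code = 0
        for ch in g:
            code = code * self.a + idx[ch]
        return code

    def decode(self, code: int) -> str:
        symbols = []
        for _ in range(self.L):
            symbols.append(self.alphabet[code % self.a])
            code //= self.a
        return "".join(reversed(symbols))


def enumerate_genotypes(space: GenotypeSpace) -> list[str]:
    """All genotypes of ``space`` in lexicographic order over its alphabet."""
    if space.size > MAX_GENOTYPES:
        raise CapacityError(
            f"universe has {space.size} genotypes, exceeding the cap of {MAX_GENOTYPES}"
        )
    return ["".join(t) for t in itertools.product(space.alphabet, repeat=space.L)]


def neighbors(space: GenotypeSpace, g: str) -> set[str]:
    """Mutational neighbors of ``g`` under the space's neighbor rule.

    Hamming: all single-position substitutions. ``pbm_style``: substitutions
    plus shift neighbors ``g'`` such that ``g[1:] == g'[:-1]`` or
    ``g'[1:] == g[:-1]`` (a single-base shift of the whole site, with any
    incoming symbol). The genotype itself is never its own neighbor.
    """
    space.validate(g)
    out: set[str] = set()
    for i, ch in enumerate(g):
        for s in space.alphabet:
            if s != ch:
                out.add(g[:i] + s + g[i + 1 :])
    if space.neighbor_rule == "pbm_style":
        for s in space.alphabet:
            out.add(g[1:] + s)  # site shifts left, s enters on the right
            out.add(s + g[:-1])  # site shifts right, s enters on the left
        out.discard(g)
    return out


def reverse_complement(g: str) -> str:
    """Reverse complement of a DNA genotype."""
    bad = set(g) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(
            f"reverse complement requires a DNA genotype; {g!r} contains {sorted(bad)}"
        )
    return g.translate(_DNA_COMPLEMENT)[::-1]


def reverse_complement_class(g: str) -> str:
    """Canonical representative of ``{g, revcomp(g)}``: the lexicographically smaller."""
    return min(g, reverse_complement(g))


def hamming_neighbor_index(L: int, a: int) -> np.ndarray:
    """Neighbor index array for the complete Hamming space.

    Returns an ``(a**L, (a-1)*L)`` integer array whose row ``c`` lists the
    codes of the Hamming neighbors of the genotype with lexicographic code
    ``c`` (leftmost locus varies slowest).
    """
    n = a**L
    if n > MAX_GENOTYPES:
        raise CapacityError(f"universe has {n} genotypes, exceeding the cap of {MAX_GENOTYPES}")
    codes = np.arange(n)
    cols = []
    for pos in range(L):
        weight = a ** (L - 1 - pos)
        digit = (codes // weight) % a
        for other in range(1, a):
            new_digit = (digit + other) % a
            cols.append(codes + (new_digit - digit) * weight)
    return np.stack(cols, axis=1)


class Landscape:
    """A genotype-to-score map with optional per-genotype noise thresholds.

    Parameters
    ----------
    space:
        The genotype universe and neighbor rule.
    genotypes:
        The domain, as a list of genotype strings (no duplicates). May be a
        subset of the universe.
    scores:
        Finite real score per genotype (phenotype or fitness, per ``label``).
    noise:
        Non-negative noise threshold per genotype; defaults to zero. Two
        neighboring genotypes are *indistinguishable* when their score
        difference is at most the larger of their two noise thresholds.
    label:
        ``"phenotype"`` or ``"fitness"`` -- a bookkeeping tag only.
    merged_revcomp:
        True when each genotype stands for the merged pair
        ``{g, revcomp(g)}``; adjacency then considers the neighbors of both
        strands, mapped back to canonical representatives.
    """

    def __init__(
        self,
        space: GenotypeSpace,
        genotypes: Sequence[str],
        scores: Iterable[float],
        noise: Iterable[float] | None = None,
        label: str = "phenotype",
        merged_revcomp: bool = False,
        meta: dict | None = None,
    ) -> None:
        if label not in ("phenotype", "fitness"):
            raise ValueError(f"label must be 'phenotype' or 'fitness', got {label!r}")
        self.space = space
        self.genotypes = list(genotypes)
        if not self.genotypes:
            raise ValueError("landscape must contain at least one genotype")
        self.scores = np.asarray(list(scores), dtype=float)
        if self.scores.shape != (len(self.genotypes),):
            raise ValueError("scores must align one-to-one with genotypes")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("all scores must be finite")
        if noise is None:
            self.noise = np.zeros(len(self.genotypes))
        else:
            self.noise = np.asarray(list(noise), dtype=float)
            if self.noise.shape != self.scores.shape:
                raise ValueError("noise must align one-to-one with genotypes")
            if np.any(self.noise < 0) or not np.all(np.isfinite(self.noise)):
                raise ValueError("noise thresholds must be finite and non-negative")
        self.label = label
        self.merged_revcomp = bool(merged_revcomp)
        self.meta = dict(meta or {})
        self._index: dict[str, int] = {}
        for i, g in enumerate(self.genotypes):
            space.validate(g)
            if g in self._index:
                raise ValueError(f"duplicate genotype {g!r}")
            self._index[g] = i
        self._adjacency: list[np.ndarray] | None = None
        self._edges: tuple[np.ndarray, np.ndarray] | None = None

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.genotypes)

    def __contains__(self, g: str) -> bool:
        return g in self._index

    def index_of(self, g: str) -> int:
        try:
            return self._index[g]
        except KeyError:
            raise KeyError(f"genotype {g!r} is not in the landscape") from None

    def score_of(self, g: str) -> float:
        return float(self.scores[self.index_of(g)])

    @property
    def has_noise(self) -> bool:
        return bool(np.any(self.noise > 0))

    def is_complete_hamming(self) -> bool:
        """True when the domain is the full universe in lexicographic order."""
        if self.space.neighbor_rule != "hamming" or len(self) != self.space.size:
            return False
        cached = self.meta.get("_complete_hamming")
        if cached is None:
            cached = self.genotypes == enumerate_genotypes(self.space)
            self.meta["_complete_hamming"] = cached
        return cached

    # -- adjacency --------------------------------------------------------

    def adjacency(self) -> list[np.ndarray]:
        """Per-genotype arrays of neighbor indices, restricted to the domain."""
        if self._adjacency is not None:
            return self._adjacency
        if self.is_complete_hamming():
            nbr = hamming_neighbor_index(self.space.L, self.space.a)
            self._adjacency = list(nbr)
            return self._adjacency
        adj = []
        for g in self.genotypes:
            cand = set(neighbors(self.space, g))
            if self.merged_revcomp:
                cand |= set(neighbors(self.space, reverse_complement(g)))
                cand = {reverse_complement_class(h) for h in cand}
                cand.discard(g)
            idx = sorted(self._index[h] for h in cand if h in self._index)
            adj.append(np.asarray(idx, dtype=np.int64))
        self._adjacency = adj
        return adj

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edges ``(I, J)`` of the neighborhood graph, both orientations."""
        if self._edges is None:
            adj = self.adjacency()
            if self.is_complete_hamming():
                nbr = np.stack(adj)
                deg = nbr.shape[1]
                I = np.repeat(np.arange(len(self)), deg)
                J = nbr.ravel()
            else:
                lens = [len(a) for a in adj]
                I = np.repeat(np.arange(len(self)), lens)
                J = np.concatenate(adj) if sum(lens) else np.empty(0, dtype=np.int64)
            self._edges = (I, J)
        return self._edges

    def subset(self, indices: Sequence[int], meta: dict | None = None) -> "Landscape":
        idx = np.asarray(indices, dtype=int)
        return Landscape(
            self.space,
            [self.genotypes[i] for i in idx],
            self.scores[idx],
            self.noise[idx],
            label=self.label,
            merged_revcomp=self.merged_revcomp,
            meta=meta,
        )

    def with_scores(
        self, scores: np.ndarray, noise: np.ndarray | None = None, label: str | None = None
    ) -> "Landscape":
        """Copy of this landscape with new scores (domain and adjacency shared)."""
        out = Landscape(
            self.space,
            self.genotypes,
            scores,
            noise if noise is not None else self.noise,
            label=label or self.label,
            merged_revcomp=self.merged_revcomp,
        )
        out._adjacency = self._adjacency
        out._edges = self._edges
        out.meta["_complete_hamming"] = self.meta.get("_complete_hamming")
        return out


def merge_reverse_complements(landscape: Landscape, tol: float = 1e-12) -> Landscape:
    """Merge each DNA genotype with its reverse complement.

    The canonical (lexicographically smaller) member represents the pair and
    keeps its score. If both members are present their scores must agree
    within ``tol``.
    """
    if not landscape.space.is_dna:
        raise ValueError("reverse-complement merging requires a DNA alphabet")
    keep: dict[str, int] = {}
    for i, g in enumerate(landscape.genotypes):
        canon = reverse_complement_class(g)
        if canon in keep:
            other = keep[canon]
            if abs(landscape.scores[i] - landscape.scores[other]) > tol:
                raise ValueError(
                    f"genotype {g!r} and its reverse complement carry scores that differ "
                    f"by more than {tol}"
                )
        elif g == canon:
            keep[canon] = i
        else:
            keep[canon] = i  # only the non-canonical strand present; keep its score
    order = sorted(keep)
    out = Landscape(
        landscape.space,
        order,
        [landscape.scores[keep[g]] for g in order],
        [landscape.noise[keep[g]] for g in order],
        label=landscape.label,
        merged_revcomp=True,
    )
    return out


# -- TSV I/O --------------------------------------------------------------


def read_landscape(
    path,
    space: GenotypeSpace | None = None,
    label: str = "phenotype",
    merged_revcomp: bool = False,
) -> Landscape:
    """Read a landscape from a TSV file.

    The file has header columns ``genotype`` and ``score`` and optionally
    ``noise``; lines starting with ``#`` are ignored. When ``space`` is not
    given it is inferred: the DNA alphabet if all symbols are in ACGT,
    otherwise the sorted set of symbols seen.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"genotype": str}, float_precision="round_trip"
    )
    required = {"genotype", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    genotypes = df["genotype"].tolist()
    if any(not isinstance(g, str) or not g for g in genotypes):
        raise ValueError(f"{path}: empty or missing genotype entries")
    dupes = df["genotype"][df["genotype"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate genotypes {list(dupes[:5])}")
    try:
        scores = df["score"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric score ({exc})") from exc
    noise = None
    if "noise" in df.columns:
        noise = df["noise"].astype(float).to_numpy()
    if space is None:
        lengths = {len(g) for g in genotypes}
        if len(lengths) != 1:
            raise ValueError(f"{path}: genotypes have differing lengths {sorted(lengths)}")
        symbols = set().union(*(set(g) for g in genotypes))
        if symbols <= set(DNA_ALPHABET):
            alphabet = DNA_ALPHABET
        else:
            alphabet = tuple(sorted(symbols))
        space = GenotypeSpace(L=lengths.pop(), alphabet=alphabet)
    return Landscape(space, genotypes, scores, noise, label=label, merged_revcomp=merged_revcomp)


def write_landscape(landscape: Landscape, path) -> None:
    """Write a landscape as TSV; round-trips scores at full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        if landscape.has_noise:
            fh.write("genotype\tscore\tnoise\n")
            for g, s, d in zip(landscape.genotypes, landscape.scores, landscape.noise):
                fh.write(f"{g}\t{float(s)!r}\t{float(d)!r}\n")
        else:
            fh.write("genotype\tscore\n")
            for g, s in zip(landscape.genotypes, landscape.scores):
                fh.write(f"{g}\t{float(s)!r}\n")
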