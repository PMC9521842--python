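"""Mutation-selection dynamics: class recursion and genotype-level eigenmode."""

import numpy as np
import pytest

from incon.evo_dynamics import (
    class_equilibrium,
    class_mutation_matrix,
    genotype_equilibrium,
    mismatch_class_fitness,
    mutation_step,
    optimal_mismatch_class,
    phase_diagram,
    selection_step,
)
from incon.fitness_map import GaussianMap, apply_map
from incon.generators import MismatchConfig, gen_mismatch
from incon.genotype_space import GenotypeSpace, Landscape, enumerate_genotypes


def test_selection_step_examples():
    X = np.array([0.25, 0.25, 0.5])
    np.testing.assert_allclose(selection_step(X, np.ones(3)), X)
    one_hot = selection_step(X, np.array([0.0, 1.0, 0.0]))
    np.testing.assert_allclose(one_hot, [0.0, 1.0, 0.0])
    with pytest.raises(ValueError, match="degenerate"):
        selection_step(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


@pytest.mark.parametrize("L,a,mu", [(8, 4, 0.1), (5, 2, 0.3), (10, 3, 0.05)])
def test_mutation_kernel_conserves_frequency(L, a, mu):
    T = class_mutation_matrix(L, a, mu)
    np.testing.assert_allclose(T.sum(axis=0), 1.0, atol=1e-14)
    rng = np.random.default_rng(0)
    X = rng.dirichlet(np.ones(L + 1))
    assert abs(mutation_step(X, L, a, mu).sum() - 1.0) < 1e-12


def test_mutation_kernel_identity_at_zero_and_class0_flow():
    np.testing.assert_array_equal(class_mutation_matrix(6, 4, 0.0), np.eye(7))
    X = np.zeros(9)
    X[0] = 1.0
    out = mutation_step(X, 8, 4, 0.1)
    assert out[0] == pytest.approx(0.9)
    assert out[1] == pytest.approx(0.1)
    assert np.all(out[2:] == 0.0)
    with pytest.raises(ValueError):
        class_mutation_matrix(8, 4, 1.5)


def test_class_equilibrium_selection_only_fixes_optimum():
    res = class_equilibrium(L=8, a=4, e=0.05, m_opt=3, sigma=0.5, mu=0.0)
    assert res.mean_fitness == pytest.approx(1.0, abs=1e-9)
    assert int(np.argmax(res.frequencies)) == 3


def test_class_equilibrium_start_independent():
    rng = np.random.default_rng(4)
    kwargs = dict(L=8, a=4, e=0.05, m_opt=5, sigma=1.0, mu=0.1, tol=1e-12)
    ref = class_equilibrium(**kwargs)
    for _ in range(2):
        alt = class_equilibrium(**kwargs, x0=rng.dirichlet(np.ones(9)))
        assert np.max(np.abs(alt.frequencies - ref.frequencies)) < 10 * 1e-12
        assert alt.mean_fitness == pytest.approx(ref.mean_fitness, abs=1e-10)


def test_frequency_conservation_along_trajectory():
    F = mismatch_class_fitness(8, 0.05, 6, 1.0)
    T = class_mutation_matrix(8, 4, 0.1)
    X = np.full(9, 1 / 9)
    for _ in range(200):
        X = T @ selection_step(X, F)
        assert abs(X.sum() - 1.0) < 1e-12


def test_optimal_mismatch_class_reference_point():
    best, gains = optimal_mismatch_class(8, 4, 0.05, sigma=1.0, mu=0.1)
    assert best == 6
    assert gains[0] == 0.0
    assert np.all(gains[1:] > 0)  # any m_opt > 0 beats selecting for the consensus


def test_phase_diagram_trends():
    df = phase_diagram(range(9), sigma_grid=[0.05, 0.3, 1.0], mu_grid=[0.1], e=0.05)
    by_sigma = df.sort_values("sigma")["best_m_opt"].tolist()
    assert by_sigma[0] == 8  # strong selection favors the broadest peak
    assert by_sigma[-1] == 6  # weak selection favors the most peak genotypes
    assert all(a >= b for a, b in zip(by_sigma, by_sigma[1:]))
    # a larger mismatch penalty strengthens selection: argmax weakly increases
    strong_e = phase_diagram(range(9), [1.0], [0.1], e=0.2).best_m_opt.iloc[0]
    weak_e = phase_diagram(range(9), [1.0], [0.1], e=0.025).best_m_opt.iloc[0]
    assert strong_e >= 6 >= weak_e or strong_e >= weak_e


def uniform_two_genotype_landscape(mu):
    space = GenotypeSpace(1, ("0", "1"))
    land = Landscape(space, ["0", "1"], [0.5, 0.5], label="fitness")
    return genotype_equilibrium(land, mu)


def test_genotype_equilibrium_symmetry_and_validation():
    res = uniform_two_genotype_landscape(0.2)
    np.testing.assert_allclose(res.frequencies, [0.5, 0.5])
    space = GenotypeSpace(1, ("0", "1"))
    land = Landscape(space, ["0", "1"], [0.0, 0.0], label="fitness")
    with pytest.raises(ValueError, match="degenerate"):
        genotype_equilibrium(land, 0.1)
    land2 = Landscape(space, ["0", "1"], [0.5, 1.0], label="fitness")
    with pytest.raises(ValueError):
        genotype_equilibrium(land2, 0.0)


@pytest.mark.parametrize("L,seed", [(5, 0), (7, 1)])
def test_leading_eigenvalue_equals_mean_fitness(L, seed):
    rng = np.random.default_rng(seed)
    space = GenotypeSpace(L, ("0", "1"))
    land = Landscape(space, enumerate_genotypes(space), rng.random(2**L), label="fitness")
    res = genotype_equilibrium(land, mu=0.05)
    assert res.leading_eigenvalue == pytest.approx(res.mean_fitness, abs=1e-10)


def test_small_mu_concentrates_on_global_peak():
    rng = np.random.default_rng(6)
    space = GenotypeSpace(5, ("0", "1"))
    scores = rng.random(32)
    land = Landscape(space, enumerate_genotypes(space), scores, label="fitness")
    means = []
    for mu in (1e-2, 1e-3, 1e-4):
        res = genotype_equilibrium(land, mu)
        means.append(res.mean_fitness)
        assert int(np.argmax(res.frequencies)) == int(np.argmax(scores))
    assert means[0] < means[1] < means[2] <= scores.max()


def exact_class_kernel(land, mu):
    """Aggregate the genotype-level mutation matrix over mismatch classes.

    The mismatch landscape is permutation-symmetric, so the genotype chain
    lumps exactly onto classes: T[m', m] sums mu^d (1-mu)^(L-d) over the
    genotypes of class m' for any representative of class m.
    """
    L = land.space.L
    classes = land.meta["mismatch_class"]
    geno = np.array([list(g) for g in land.genotypes])
    d = (geno[:, None, :] != geno[None, :, :]).sum(axis=2)
    M = mu**d * (1.0 - mu) ** (L - d)
    T = np.zeros((L + 1, L + 1))
    for m in range(L + 1):
        rep = int(np.flatnonzero(classes == m)[0])
        for mp in range(L + 1):
            T[mp, m] = M[classes == mp, rep].sum()
    return T


def test_genotype_mode_lumps_exactly_onto_classes_and_eq_matches():
    # the genotype-level equilibrium, summed by class, must equal the class
    # chain driven by the exactly aggregated kernel
    e, m_opt, sigma, L = 0.05, 4, 0.5, 6
    land = gen_mismatch(MismatchConfig(L=L, a=2, e=e))
    fit = apply_map(land, GaussianMap(w_opt=1 - e * m_opt, sigma=sigma))
    classes = land.meta["mismatch_class"]
    F = mismatch_class_fitness(L, e, m_opt, sigma)
    for mu in (0.1, 0.01):
        geno = genotype_equilibrium(fit, mu)
        by_class = np.bincount(classes, weights=geno.frequencies, minlength=L + 1)
        T = exact_class_kernel(land, mu)
        X = np.bincount(classes, minlength=L + 1) / 2**L
        for _ in range(100_000):
            Xn = T @ (F * X)
            Xn /= Xn.sum()
            if np.max(np.abs(Xn - X)) < 1e-15:
                X = Xn
                break
            X = Xn
        assert np.max(np.abs(by_class - X)) < 1e-6


def test_single_mutation_kernel_approximates_exact_aggregation_at_small_mu():
    # the nearest-class kernel (total single-mutation probability
    # L mu (1-mu)^(L-1)) deviates from the exact aggregation at O(mu^2)
    L = 6
    land = gen_mismatch(MismatchConfig(L=L, a=2, e=0.05))
    errs = []
    for mu in (0.02, 0.005):
        exact = exact_class_kernel(land, mu)
        near = class_mutation_matrix(L, 2, L * mu * (1 - mu) ** (L - 1))
        errs.append(np.max(np.abs(exact - near)))
    ratio = errs[0] / errs[1]
    assert 8 < ratio < 32  # quadratic scaling: (0.02/0.005)^2 = 16
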