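# Methods

## Landscapes and neighborhoods

Genotypes are length-`L` strings over an `a`-letter alphabet. Two
neighborhood rules are supported. The *Hamming* rule connects genotypes that
differ by one substitution, so every genotype has `(a-1)*L` neighbors. The
*pbm_style* rule, used for transcription-factor binding sites, adds shift
neighbors: `g'` neighbors `g` when the last `L-1` symbols of one equal the
first `L-1` symbols of the other, i.e. a single-base shift of the whole
site with an arbitrary incoming base (all `a` incoming bases are admitted;
the genotype itself is excluded). DNA landscapes may merge each genotype
with its reverse complement; the lexicographically smaller member is the
canonical representative and carries the score, and the adjacency of a
merged genotype is the union of both strands' neighborhoods mapped back to
canonical representatives.

A `Landscape` attaches to each genotype a finite score and a non-negative
noise threshold `delta` (default 0). Scores are labelled `phenotype` or
`fitness`; the label is bookkeeping only — every measure is defined on the
scores.

## Phenotype-to-fitness map

`F(w) = exp(-((w - w_opt)/sigma)^2)` with `sigma > 0`. The map is maximal
at `w_opt`, symmetric, and monotone on either side of the optimum, so all
rank-based measures (sign motifs, peak counts) depend on `w_opt` but not on
`sigma`. Fitness below the smallest positive double (5e-324) is clamped to
exactly 0 and counted in `meta["n_underflow"]`; in the strong-selection
regime (very small `sigma`) whole squares can collapse to zero fitness, and
the fraction of such replicates is reported separately by the
magnitude-epistasis sweep. Phenotype noise propagates to fitness by first-
order error propagation, `dF = 2 F(w) |w - w_opt| / sigma^2 * delta`,
stored as a magnitude.

## Epistasis measures

For a locus pair in a fixed background, magnitude epistasis is
`eps = w00 + w11 - w01 - w10`, classified additive / positive / negative by
sign; congruence of a random square under the map is measured by
`P(eps_gp * eps_f > 0)`. The weak-selection expansion
`eps_f * eps_gp = (1/sigma^2) [2 eps_m eps_gp + (2 w_opt - sum_i w_i) eps_gp^2]`,
with `eps_m = w00*w11 - w01*w10`, is implemented for comparison; its sign
agrees with the exact product in the large-`sigma` limit.

Sign motifs are rank-based: a locus "changes sign" when its effect has
strictly opposite signs in the two backgrounds of the other locus; zero,
one, or two changing loci give the no-sign, simple-sign, and
reciprocal-sign motifs. For model landscapes with continuous scores the
comparison tolerance is 0 (ties have probability zero); for noisy
landscapes effects within the propagated noise count as zero-sign. The
transition sweep draws fresh uniform squares per `w_opt` grid point and
tabulates the 3x3 motif transition matrix before/after the map.

## Peaks and plateaus

Neighbors `g, h` are *indistinguishable* when
`|s(g) - s(h)| <= max(delta_g, delta_h)`. Indistinguishability is not
transitive; plateaus are defined as connected components of the
indistinguishability graph (its transitive closure). A plateau is a peak
when no member has a neighbor outside the plateau with a distinguishably
higher score. Peak width is the plateau's genotype count; peak height is
the maximum member score (members agree within the noise thresholds along
plateau edges). With `delta = 0` exact score ties form plateaus — this is
what makes the mismatch model's same-class clusters single broad peaks
(e.g. 70 peaks of width 81 at `L = 8, a = 4` when selecting for mismatch
class 4) rather than thousands of singleton peaks.

Replicate sweeps count peaks before and after the map. Because peak counts
are rank statistics, the sweeps score fitness with the monotone surrogate
`-(w - w_opt)^2`, which avoids underflow and makes `sigma`-independence
explicit. Replicates use a strict vectorised counter (valid for continuous
scores with `delta = 0`) that is tested against the plateau-aware detector.

## House-of-Cards closed form

For a fully random landscape the peak count `p` has mean `2^L/(L+1)`. Its
exact variance follows from pairwise peak-indicator covariances on the
hypercube: same-genotype and distance-1 terms cancel and distance-2 pairs
(two shared neighbors) leave `Var(p) = 2^(L-1) (L-1) / (L+1)^2`. The
peak-count change `Delta = p_f - p_gp` is asymptotically normal with mean
zero, so `<|Delta|> = sqrt(2 Var(Delta) / pi)`. Treating the two counts as
independent gives the leading-order form
`sqrt(2^(L+1) (L-1) / pi) / (L+1)`, accurate to a few percent by `L = 10`.
At moderate `L` the two counts are weakly positively correlated; the
default implementation subtracts the exact covariance, evaluated at
`w_opt = 1/2` from three order-statistics integrals (same genotype,
distance-1 pair, distance-2 pair; the last by numerical quadrature of a
polynomial integrand). Each integral was verified against direct
Monte-Carlo simulation of the corresponding local configuration before
being frozen. At `L = 8` the corrected form is 3.62 versus 3.75 for the
leading-order form; simulation at 40,000 replicates gives 3.635 +- 0.014.

## Greedy adaptive walks

From a start genotype, the walk moves to the distinguishably fittest
neighbor (ties uniform at random, seeded). On a non-peak plateau it moves
uniformly at random to an *unvisited* indistinguishable neighbor until the
plateau is traversed; "unvisited" excludes every genotype already on the
path (stronger than one-step backtracking), which guarantees termination
within the landscape size. The walk stops when the current plateau is a
peak; a non-peak plateau with no unvisited indistinguishable neighbor and
no fitter neighbor (possible only under noise) also terminates the walk and
is reported with `terminal_is_peak = False`. Length counts all steps,
including plateau steps. On the zero-noise mismatch model every walk
descends the class ladder, so its length is `|m_opt - m|` and the mean over
all starts is `sum_m (a-1)^m C(L,m) |m_opt - m| / a^L`, computed in integer
arithmetic so that the exhaustive simulation reproduces it exactly.

## Mutation-selection dynamics

*Class recursion* (mismatch model): frequencies `X_m` over classes
`0..L` alternate a selection step `X_m <- F_m X_m / sum_i F_i X_i` with
`F_m = exp(-((A_m - A_mopt)/sigma)^2)` and a single-point-mutation step
with total probability `mu`: up `mu (L-m)/L`, within-class
`mu (a-2) m / ((a-1) L)`, down `mu m / ((a-1) L)` (the kernel is
column-stochastic — the three streams balance exactly). Iteration starts
from the neutral distribution `N_m / a^L` and stops when the estimated
distance to the fixed point (step size divided by one minus the observed
contraction ratio) falls below `tol = 1e-12`, capped at 1e6 iterations.
The fixed point is start-independent (the kernel is irreducible for
`mu > 0`). The headline statistic is the mean-fitness gain relative to
selecting for the consensus (`m_opt = 0`).

*Genotype-level eigenmode*: for small landscapes the equilibrium is the
leading eigenvector of `M . S`, `M_ij = mu^d(i,j) (1-mu)^(L-d(i,j))`,
`S = diag(f)`, with `d` the Hamming distance, minimised over the neighbor's
reverse complement for merged DNA landscapes. Here `mu` is a *per-locus*
rate; the class recursion's total-probability `mu` corresponds to
`L * mu * (1-mu)^(L-1)` at leading order, and on the permutation-symmetric
mismatch landscape the genotype chain lumps exactly onto classes (tested
against the exactly aggregated kernel). For biallelic spaces `M` is
column-stochastic and the leading eigenvalue equals the equilibrium mean
fitness; for `a > 2` the per-locus model inflates every column sum by the
constant `(1 + (a-2) mu)^L`, which rescales the eigenvalue but not the
eigenvector. A sensitivity helper re-solves the equilibrium under Gaussian
fitness perturbations with standard deviation `dF/3` (clipped at zero).

## Synthetic PBM landscapes

The synthetic generator stands in for empirical protein-binding-microarray
data, which this package deliberately does not require. Each landscape
scores all `4^L` sequences as a mixture
`(1 - mix) * additive + mix * noise` of a standardised additive
per-position energy surface and standardised i.i.d. noise, rescaled
affinely (hence rank-preserving) into the E-score range [-0.5, 0.5];
`mix = energy_ruggedness` interpolates from perfectly additive (one peak,
strongly correlated neighbors) to uncorrelated. Reverse complements are
merged, scores below the specificity threshold (default 0.35) are dropped,
and the largest connected component under the pbm_style rule is returned
with a constant per-landscape noise threshold `delta_scale` (default 0.01,
a small fraction of the retained score range; real per-TF thresholds are
empirical quantities and are not modelled). What passing tests on these
landscapes show about real data is qualitative only: the generator
reproduces bounded scores, thresholding, broad low-affinity classes and
correlated neighborhoods, but not TF-specific motif structure, position
interdependence, or array-specific biases.

## Numerical conventions and problem sizes

All randomness flows from one master seed through named substreams
(seed sequence spawned per stage, grid point, and replicate), so results
are reproducible and independent of execution order. Genotype universes
are capped at 1e7 (everything here needs at most `4^8 = 65,536`). NK
phenotypes are rescaled per landscape by subtracting the minimum and
dividing by the post-subtraction maximum, so each replicate spans [0, 1]
exactly. Default sweep sizes follow the study conditions (10,000 replicates
per `w_opt`, grid step 0.01); the test suite uses smaller replicate counts
chosen to keep three-standard-error Monte-Carlo bands tight enough for the
properties asserted.

## Limitations

Single phenotype, symmetric (Gaussian) map only; no asymmetric maps, no
multi-phenotype fitness. No finite-population (Wright-Fisher/Moran)
dynamics. No accessibility-path enumeration or basin partitioning beyond
walk statistics. The empirical PBM corpus and its per-TF statistics are out
of scope; all conclusions about such data rest on the synthetic stand-in
described above.
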