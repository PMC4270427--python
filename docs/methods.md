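# Methods

## The model

A collective of total mass `M` distributes itself between two identical
options (for the plasmodium of *Physarum polycephalum*, two equal food
sources; `M` is identified with the plasmodium diameter in cm).  `X1` and
`X2` are the masses committed to the options, `M − X1 − X2` the uncommitted
pool, and

    dXi/dt = k (M − X1 − X2) F(Xi) − d Xi,    F(x) = xⁿ / (Tⁿ + xⁿ)

Commitment is recruited from the pool at flux rate `k`, amplified by a
sigmoidal quorum response `F` of the mass already committed to the *same*
option (information is purely local: tube growth toward one food source
does not inhibit growth toward the other), and decays at rate `d`.  The
pool factor is a passive negative feedback: recruitment stops when the
pool is exhausted, which makes the simplex `{X1, X2 ≥ 0, X1+X2 ≤ M}`
forward-invariant.

Parameters, with units and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `k` | commitment flux rate | 1/time | — (strain-specific) |
| `d` | commitment decay rate | 1/time | 1 (time-unit rescaling) |
| `T` | quorum threshold, `F(T) = 1/2` | mass | — (strain-specific) |
| `n` | sigmoid exponent | — | 2 (results robust for n ≥ 2) |
| `M` | total mass / plasmodium diameter | mass (cm) | — |

`d = 1` is a normalization, not an assumption: time can always be
rescaled by the decay rate, and the fitted quantities (`k`, `T`) are then
expressed in decay-time units.  Strain best-fit values used throughout:
Japan (k=2.5, T=1.5), Australian (k=1.5, T=0.9), American (k=1.5, T=1.2).

## Equilibria and bifurcation structure

Setting the derivatives to zero yields four families (closed forms for
n = 2; for n > 2 the same branches are found by bracketed scalar
root-finding on the reduced equilibrium conditions, the asymmetric family
via a one-dimensional solve on the committed sum S = X1 + X2):

* trivial `(0,0)` — always stable, double eigenvalue `−d`;
* semi-trivial `(X,0)`/`(0,X)` with `(k+d)X² − kMX + dT² = 0` — born at a
  saddle-node at `M1 = (2T/k)√(d(k+d))`; upper branch stable, lower unstable;
* homogeneous `(X,X)` with `(2k+d)X² − kMX + dT² = 0` — born at a
  saddle-node at `M2 = (2T/k)√(d(2k+d))`; the upper branch is unstable
  until the pitchfork and stable beyond it;
* non-homogeneous `(X1,X2)`, `X1 ≠ X2`, with `X1X2 = T²` and
  `X1 + X2 = kM/(k+d)` — exist for `M > M3 = 2T(k+d)/k`, always unstable,
  and merge with the homogeneous upper branch at exactly `(T,T)` when
  `M = M3` (a subcritical, symmetry-restoring pitchfork).

`M1 < M2 < M3` always, since `(k+d)² > d(2k+d) > d(k+d)`.  The regime
sequence in `M` is therefore: no decision only (`M < M1`); no decision or
one option (`M1 < M < M3`); tristability — none, one, or both options —
past the pitchfork.  For the three strains `M3` is 4.2 (Japan),
3.0 (Australian) and 4.0 (American): the Japanese strain, which builds
few thick tubes, needs the largest mass before exploiting both sources.

Numerical choices: eigenvalues come from the closed 2×2 characteristic
quadratic (exact at the trivial state); quadratic roots use the
numerically stable pairing; a vanishing discriminant (relative 1e-12) is
reported as a single degenerate "limit point" state so sweeps see
unambiguous branch counts; the trajectory integrator is LSODA at
rtol 1e-7 / atol 1e-9, well below every 1e-6 comparison tolerance; `F′(0)`
for n = 2 is taken as its analytic limit 0.  Bifurcation masses in mass
sweeps are located by bisection on branch-count changes between grid
cells (tolerance 1e-6), not by continuation — closed forms make tangent
prediction unnecessary.  Basin probes draw initial conditions uniformly
on the feasible triangle (respecting conservation), integrate to
`t = 500/d` or until the derivative norm falls below 1e-8, and count
unsettled runs separately.

## Monte Carlo simulator

Mass moves in discrete units `δ` (default `M/1000`).  Each step selects
one of four events — add/remove a unit to/from option 1 or 2 — with
probabilities proportional to the propensities `A_i = k(M−X1−X2)F(X_i)`
and `R_i = dX_i`, normalized by their current sum (the only
normalization under which the four probabilities sum to one at every
state).  Boundary clipping (an add-event transfers at most the remaining
pool; a remove-event at most the remaining commitment) keeps positivity
and conservation exact at every step; the kernel tracks the worst
violation observed and tests assert it is exactly zero.  A realisation
runs 70 000 steps (ample to reach the stationary regime at `δ = M/1000`)
or until the pool drops below `δ`; the exactly-uncommitted state, where
all propensities vanish, is absorbing and detected.

Initial commitments are drawn uniformly on `[0, M/2]` per option.  This
choice matters and was made deliberately: the embedded jump chain is
biased toward the no-decision state wherever the quorum is sub-threshold,
so starts confined near zero commitment are absorbed at `(0,0)` for every
experimental mass and the model would predict no decision always.
Spreading the starts over the feasible simplex lets realisations sample
the coexisting attraction basins — the stochastic counterpart of the
plasmodium's variable initial exploration — and reproduces the reported
model behaviour (for the Australian rates at `M = 4` the simulator gives
p(two) ≈ 0.72, against the reported experimental 75%).

Outcome classification of a final state: "none" if less than half of the
total mass has moved; otherwise "one" if at least 60% of the *moved* mass
sits on a single option, else "two".  The majority rule is taken relative
to the moved mass because the stationary pool is generically nonzero
(decay continually returns mass to it): at the semi-trivial equilibrium
the committed fraction tends to `k/(k+d)` for large `M`, which equals 0.6
exactly at `k = 1.5, d = 1` — under a total-mass reading the Australian
and American strains could essentially never register a one-option
choice, contradicting their fitted behaviour.  The three classes are
exhaustive and mutually exclusive.

Two implementations share these semantics: a pure-Python reference
realisation runner (can record full trajectories for invariant checks)
and a numba-compiled batch kernel used wherever many realisations are
needed; tests compare their outcome distributions statistically.
Reproducibility: every stage derives per-realisation 32-bit seeds from a
single `SeedSequence`, so identical configurations give bit-identical
results.

## Synthetic experiments and fitting

The synthetic generator emulates the experimental design exactly: ten
diameters (4, 3.2, 2.6, 2.3, 2, 1.8, 1.7, 1.3, 1, 0.8 cm), 65 replicates
per strain and size (650 rows per strain, 1950 over three strains).  For
each mass it estimates the simulator's outcome distribution, mixes it
with the uniform distribution over the three outcomes with weight λ, and
draws replicates as independent categorical samples — the exact sampling
counterpart of the model the fitter assumes.  What it does *not* emulate:
real trials are photographs of a living organism scored by hand; any
mass-dependent scoring bias, temporal correlation between replicates, or
deviation of real variability from the uniform-contamination form is
absent, so passing recovery tests validate the inference machinery, not
the biological adequacy of the mixture.  An optional overdispersion knob
(off by default) perturbs the per-mass mixture probabilities with a
Dirichlet draw of concentration `(1−ρ)/ρ`, for robustness checks beyond
the exact-multinomial design.

Fitting minimizes the summed squared error between mixture predictions
`λ p_sim,j(M) + (1−λ)/3` and observed outcome proportions, over an
exhaustive grid: `k` from 0.5 to 3.5 and `T` from 0.5 to 2.0 in steps of
0.1, `λ` from 0 to 1 in steps of 0.01, 1000 realisations per (k, T) and
mass at full scale.  λ enters the objective linearly, so each (k, T)
cell's λ-scan is closed-form; simulator distributions are cached per
(k, T, M) and every cell reuses one common stream of realisation seeds
per mass (common random numbers), which removes seed-to-seed jitter from
the comparison between neighbouring cells.  Fits are per strain; no
pooling.

## Identifiability of (k, T) from outcome data — a known limitation

The desk-scale recovery experiment (truth k=2.5, T=1.5, λ=0.9; the full
65-replicate design; reduced grid k ∈ [2.0, 3.0], T ∈ [1.0, 2.0];
200 realisations per cell) does *not* recover the truth to one grid step
reliably, and the failure is structural, not a bug: outcome probabilities
constrain (k, T) almost entirely through the mass scale of the
bifurcation structure.  Pairs that preserve that scale — e.g. (3.0, 1.7)
against (2.5, 1.5), whose noise-free outcome profiles over all ten masses
differ by only ~0.02 in L2 — are indistinguishable at 65 replicates per
mass (sampling noise ~0.06 per proportion), leaving a near-flat ridge in
the objective along which the fitted (k, T) wanders by several grid
steps.  For the Japanese-like truth the both-options probability carries
almost no additional signal because its pitchfork mass (4.2) exceeds the
largest experimental size (4 cm).  The rate ratio that would break the
degeneracy (the stationary committed fraction `k/(k+d)`) is coarse-grained
away by the three-outcome classification.  The mixture weight λ and the
ridge-aligned combination of (k, T) are recovered well; the fitted point
estimates of `k` and `T` individually should be read with this flatness
in mind — a caveat that applies equally to grid fits on real outcome
tables.

## Problem sizes used in the test suite

Sweeps, oracle comparisons and stability checks run at full precision
(they are cheap).  Monte Carlo checks use 200–1000 realisations of the
full 70 000-step protocol; the statistical comparison between the
reference and compiled simulators uses 250 realisations at 6 000 steps;
the recovery study uses 10 data seeds against one shared 121-cell
simulator cache at 200 realisations per cell.  These sizes put every
assertion's statistical power well above its threshold while keeping the
suite runnable on a laptop.
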