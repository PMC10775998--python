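# Methods

This note documents the models, estimators and design choices behind
`idpdesign`: a desk-scale active-learning framework for designing short
intrinsically disordered protein (IDP) sequences that trade off condensate
thermodynamic stability against condensed-phase dynamics.

## Physical model

Sequences are represented in a residue-level coarse-grained (CG) model:
each amino acid is one bead with a hydropathy scaling factor λᵢ ∈ [0, 1], a
van der Waals diameter σᵢ (Å), a point charge qᵢ (e) and a mass mᵢ (g/mol).
The packaged table carries the published HPS-Urry parameter set of this
model family (histidine neutral by default, configurable). Pair energies:

- bonded: k_b (r − b₀)², k_b = 10 kcal/(mol Å²), b₀ = 3.82 Å;
- van der Waals (Ashbaugh–Hatch): the shifted repulsive LJ branch
  φ_LJ + (1 − λᵢⱼ)ε for r ≤ 2^{1/6}σᵢⱼ and λᵢⱼ φ_LJ beyond, with
  ε = 0.2 kcal/mol, λᵢⱼ and σᵢⱼ arithmetic means; continuous at the
  crossover by construction;
- electrostatics (Debye–Hückel): C qᵢqⱼ e^{−r/κ}/(D r) with D = 80,
  κ = 10 Å (≈ 0.1 M ionic strength at 300 K), and the Coulomb constant
  folded into C = 332.0637 kcal·Å/(mol·e²) so energies are kcal/mol.

No cutoffs are applied: these are analytic pair energies, not an MD engine.

## Property definitions and estimators

**Second virial coefficient.** B₂ = 2π ∫₀^∞ r² [1 − e^{−βu(r)}] dr from a
potential of mean force u(r) between two chains' centers of mass; negative
B₂ means net attraction and is the stability proxy. Quadrature runs on a
0.2 Å grid to r_max = 100 Å (tail treated as u = 0). Non-finite u marks a
hard core located at the grid node; segments inside the core plateau use the
exact cubic antiderivative of r², the segment leaving the core uses the
finite branch value across the whole bin (the wall is a step, not a ramp),
and smooth segments use the trapezoid rule. This keeps hard-sphere and
square-well references accurate to ≲0.1% (machine precision for the
hard sphere) on the default grid.

**Two-chain PMF at desk scale.** For chains of up to 10 residues,
`two_chain_pmf_mc` estimates u(r) by reference-ensemble reweighting:
conformations of both chains are drawn from the bonded-only ensemble (bond
lengths Gaussian about b₀ with variance kT/2k_b, isotropic directions;
common random numbers across all separations), and
u(r) = −kT ln ⟨w e^{−βU_inter}⟩/⟨w⟩ with w = e^{−βU_intra}. For
one-residue chains the estimator is exact with zero variance — the COM PMF
*is* the pair potential — which provides the oracle-equivalence check for
the quadrature pipeline. Per-bin standard errors come from the weighted
delta method; bins with vanishing Boltzmann weight are flagged as hard-core.

**Phase separation and condensed-phase density.** A pressure–density
equation of state from a finite system shows a van der Waals loop when the
state point is inside coexistence. A cubic spline is fitted to the
(ρ, p) points; phase separation is called iff the fitted pressure dips
below zero, and ρ_c is the highest zero crossing (the coexistence pressure
is approximated as exactly zero, appropriate for a dilute low-density
phase). Uncertainty: the per-point pressures are resampled from Gaussians
with their standard errors 50 times and the spread of the recomputed ρ_c is
reported. An all-negative curve is flagged as an unresolved condensed
branch rather than assigned a density.

**Self-diffusion.** D = slope/6 of the chain center-of-mass MSD, averaged
over chains and time origins (FFT-based). The fit window is configurable;
the default caps lags at 10% of the trajectory and fits the upper half of
that range — long enough to be diffusive, short enough that time-origin
averaging retains statistics (MSD values at lags comparable to the
trajectory length are noise-dominated). A log–log slope diagnostic flags
sub-linear (caged) or super-linear (ballistic) MSD. Parameter-recovery
tests use 100-chain Brownian trajectories of 5000 frames with a 1–2% lag
window, where the estimator's spread is ≈2%; the 10% default is the
sensible choice for real trajectories whose short-time regime must be
excluded.

**Reference scales.** Properties are reported relative to
V₀ = (4π/3) b₀³ (N/6)^{3/2} with b₀ = 3.8 Å and N = 50 (pervaded volume of
an ideal chain, 5529 ų) and D₀ = τ k_B T/(N M̄) with τ = 1 ps and the mean
residue mass M̄ ≈ 118.9 g/mol (ideal Rouse chain, 0.42 × 10⁻⁹ m²/s at
300 K). The bonded equilibrium length is 3.82 Å; the reference-volume
formula uses the rounded 3.8 Å, and both constants are kept where they are
used. `homopolymer_scaling` regresses log(D/D₀) on log(−N^{1/2}B₂/V₀), the
Rouse-melt prediction that chain friction is proportional to the number of
interacting neighbours times the pair-cohesion scale, and reports the
correlation with and without the N^{1/2} factor.

## Featurization

A sequence maps to a 30-dimensional vector: 20 composition fractions plus
10 descriptors — N, mean hydropathy λ̄, sequence hydropathy decoration
SHD = (1/N) Σ_{m>n} (λ_m + λ_n)(m − n)^{−1}, charged fractions q̄₊ and q̄₋,
absolute net charge per residue |q̄|, sequence charge decoration
SCD = (1/N) Σ_{m>n} q_m q_n (m − n)^{1/2}, a mean-field virial coefficient
B₂^MF, Shannon entropy of the composition (natural log), and mean residue
mass. The SHD/SCD kernel exponents follow the literature-standard
definitions and are config-exposed. B₂^MF is the composition-weighted
single-bead pair virial, f ᵀ M f with M_ab the pair virial integral of the
CG potential for residue types a and b (cached per parameter table); it is
an orientation-free mean-field surrogate for the chain-level B₂, cheap
enough for the genetic algorithm's inner loop, and deliberately *not* a
substitute for the chain-level calculation.

Descriptors are min–max scaled to [0, 1] with fixed physical bounds
(length bounds 20–50; patterning bounds from extremal constructions —
all-W, all-E, charge diblock, alternating charges — at N = 50, with a 10%
margin) rather than dataset-dependent scaling, so feature vectors are
comparable across active-learning iterations. Out-of-bound values are
clamped with a warning. Implementation notes: the SHD pair sum is
separable into per-position harmonic-number coefficients (cached per
length) and SCD touches only charged positions, so featurization costs
~50 µs per sequence inside the design loop.

## Surrogate models

Two Gaussian-process regressors predict the standard-normalized second
virial coefficient B̃₂ (trained on all sequences) and diffusivity D̃
(trained on phase-separating sequences only, since D is undefined
otherwise); a random-forest classifier predicts the phase flag and gates D
predictions in the acquisition. The GP uses a squared-exponential kernel
with unit prior variance on standardized targets; the isotropic length
scale (grid anchored at the median pairwise distance), the observation
noise, and a two-point relevance weight on the composition block (1.0 or
0.3 relative to the descriptors) are selected by maximizing the log
marginal likelihood. The weight grid is a cheap stand-in for full ARD that
lets the model discover that the descriptor block carries most of the
signal without the O(d) hyperparameter optimization cost that would
dominate per-iteration refits. Predictive sd shrinks toward √noise at
training points and reverts to the prior far away; a mean-only path skips
the variance solve in the purely exploitative fitness stages. The GP is
validated against scikit-learn's reference implementation at fixed
hyperparameters. The classifier defaults to 500 trees (50 in the
desk-scale loop configuration); its hard label aggregates the fitted trees
directly, bypassing scikit-learn's per-tree dispatch overhead, and is
tested to agree exactly with `RandomForestClassifier.predict`.

## Acquisition

Objectives are (−B̃₂, D̃), both maximized. The exact two-objective expected
hypervolume improvement for independent Gaussian predictions is computed by
a strip decomposition over the front augmented with sentinel endpoints:
with the front sorted by descending first objective (a₁ > … > a_n,
b₁ < … < b_n), reference point (r₁, r₂), and E_i[c] = E[(Y_i − c)⁺],

EHVI = Σ_{k=0}^{n} (E₁[a_{k+1}] − E₁[a_k]) · E₂[b_k],  a₀ = ∞,
a_{n+1} = r₁, b₀ = r₂.

Each term is the expected dominated area of the vertical strip between
consecutive front abscissae. The closed form is validated against
Monte-Carlo EHVI (10⁵ Gaussian draws per instance) and its Ψ helper
(Gaussian partial expectation) against numerical quadrature. The reference
point is the componentwise minimum of the observed standardized objectives
minus a 10% range margin, recomputed each iteration.

The similarity penalty α is the harmonic mean of the cosine
dissimilarities (1 − cos)/2 between a candidate's feature vector and every
previously simulated or proposed sequence; the harmonic-mean form makes α
collapse to zero as soon as the candidate closely matches even one history
entry, and α = 1 for an empty history. The staged fitness is: iteration 0,
−B̃₂ (mean prediction); iterations 1–7, EHVI × classifier label × α;
final iteration, −B̃₂ + D̃ (pure exploitation).

## Sequence design (genetic algorithm)

Children derive from a parent pool through four moves applied
independently in fixed order with fixed probabilities — crossover 0.5
(single cut-and-swap at the same relative position in both parents, so
identical parents reproduce themselves), point mutation 0.8 (one site, a
different residue), segment deletion 0.2, and segment growth 0.5
(duplicating a contiguous block in place). Moves that cannot respect the
20–50 length bounds fall back to the identity after bounded resampling.
Each proposal trial is a greedy keep-if-better local search over a fixed
number of steps; a batch of independent trials (per-trial RNG streams
derived from the master seed) runs per child and the best trial wins.
Duplicate children are retried, with retry waves starting one move away
from their parents so that even a flat (fully classifier-gated) fitness
landscape yields distinct children. Fitness functions are batched (a list
of sequences in, an array out), which lets all concurrent trials share one
surrogate evaluation per step; the `wave_size` option additionally
co-optimizes several children per batch, trading the strict
child-by-child growth of the α history for much larger surrogate batches.

## Active-learning loop

Each iteration refits the surrogates on all data, proposes a batch of
children with the stage fitness, evaluates them through the property
oracle, and updates the archive and convergence metrics. Iteration 0
minimizes B₂ only (it exists to create phase-separating training data);
if an EHVI round is reached without enough separators (default ≥4) or
without both classifier classes, the B₂-only stage repeats. Parents are
the previous iteration's Pareto set (fallback: negative-B₂ sequences).
EHVI operates in the per-iteration standardized plane; convergence metrics
(hypervolume and the fraction of newly added Pareto points relative to the
current front size, plus both restricted to the weakly-interacting regime
−B₂/V₀ ≤ 50) are computed in the fixed raw plane (−B₂/V₀, D/D₀) with a
fixed reference point at the origin, so the hypervolume trace is
nondecreasing by construction — the standardized plane rescales every
iteration and cannot support a monotone trace. Every sequence is evaluated
at most once; duplicates short-circuit to cached records.

## Synthetic oracle

The oracle replaces molecular simulation for closed-loop testing. Its
ground truth is an explicit smooth map from descriptors to properties:

- attraction A = λ̄ + 0.3 tanh(−SCD/4): hydropathy plus a saturating bonus
  for blocky charge patterning;
- B₂ = −V₀ · 40 · (N/50)(A − 0.62): more negative for longer, more
  hydrophobic, better-patterned chains. The offset 0.62 sits at the mean
  hydropathy of disorder-like random sequences, so typical seeds do not
  phase separate (≈1%, mirroring the role of the seed round), while 30 of
  the 80 homopolymers at N = 20–50 do;
- phase separation iff −B₂/V₀ > 2; ρ_c rises smoothly with −B₂;
- D = D_free · (1 + 2 tanh(fc/0.35)) / (1 + 2.5 (−B₂/V₀)√(N/50)) with
  D_free = D₀·(50/N) the free Rouse value and fc the charged fraction. In
  the strong-attraction limit this follows the melt scaling
  D ∼ (−N^{1/2}B₂)^{−1}; near the phase boundary D stays bounded by the
  free-chain value (an earlier unbounded 1/(−B₂) form put the front's
  high-D supremum exactly on the phase boundary — both unphysical and an
  infinitely sharp design target). The saturating polyampholyte bonus means
  near-optimal dynamics are achievable over a broad band of charged
  fractions, reproducing the degeneracy of near-optimal sequences that
  characterizes this design problem;
- measurements carry 5% relative Gaussian noise on B₂ and D (typical of
  well-converged simulation estimates); the phase flag derives from the
  noise-free B₂, modelling the more robust equation-of-state call.

The planted reference front is the brute-force Pareto front of the
noise-free map over the documented two-block family E^{m/2} W^w K^{m/2}
(20 ≤ m + w ≤ 50): oppositely charged blocks flanking a hydrophobic block
span the whole trade-off from barely-separating fast polyampholytes to
strongly attracting slow hydrophobes. The family is enumerable (≈600
members), its front is recomputed on demand, and the design loop is free
to — and occasionally does — exceed it, since the search space is all
sequences.

What the oracle does *not* emulate: sequence-specific conformational
effects, many-body condensed-phase structure, composition dependence beyond
the descriptor set, and correlated or heteroscedastic measurement noise.
Closed-loop tests therefore certify the learning and acquisition machinery
against a known ground truth, not the CG model's physics.

## Problem sizes and study conditions

The desk-scale closed-loop study uses 128 disorder-like seed sequences and
the full nine-iteration schedule with 32 children per iteration, 8 trials
of 120 greedy steps per child (eight children co-optimized per surrogate
batch), a 50-tree classifier, and the two-point composition-weight GP
grid. Under these conditions the archive's hypervolume reaches a median
≥90% of the planted front's (20 seeds), each trace is nondecreasing, and
the fraction of new Pareto points collapses by the exploitation round. For
context, a direct-oracle genetic search with the same evaluation budget
and perfect information recovers only ≈55–60% — the surrogate-guided
acquisition, not raw search, does the heavy lifting.

## Numerical conventions and degenerate inputs

Exact objective ties in Pareto extraction keep the first-seen point.
Hypervolume excludes (with a warning) points not dominating the reference
point. Ψ at σ = 0 degenerates to a step function. α returns exactly zero
when any dissimilarity falls below 10⁻¹² (round-off guard). The B₂
integrand treats non-finite PMF values as hard core. Standardization
refuses constant inputs. All stochastic components draw from explicit
seeds; a run is reproducible end-to-end from its master seed.

## Known limitations

The MC PMF sampler's bonded-only reference becomes inefficient for chains
much longer than ~10 residues (importance weights degenerate); real
chain-level B₂ values at design lengths require an external simulation
backend implementing the oracle interface. The GP's two-point relevance
grid is coarser than full ARD. The 2-D EHVI decomposition does not extend
to three or more objectives. Counterfactual selection depends on the
z-scored property plane of the analyzed dataset, so reports are relative
to that dataset's spread.
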