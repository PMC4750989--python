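# Methods

## Model and rationale

`glvtypes` studies how compositional categories ("community types") arise
among microbial communities assembled from a shared species pool, using
generalized Lotka–Volterra (GLV) dynamics

    ẋ = diag(x)(r + A x),

with the interaction matrix decomposed off-diagonally as A = N H ∘ G s and
A_ii = −1.  The decomposition separates four causes of structure: nominal
pairwise strengths (N, i.i.d. normal with s.d. σ), per-species outgoing
interaction scale (diagonal H, power-law distributed, normalized to mean 1),
network topology (binary G), and a global scaling s that provides the
stability margin.  The object of study is interaction-strength
heterogeneity: when the distribution of H_jj is heavy-tailed, a few
strongly interacting species (SISs) exist, and which of them a local
community happens to contain dictates where its steady state lies.  The
assumptions worth keeping in mind: interactions are host-independent
(a single universal A), local communities differ only in species
membership (uniform random p-subsets), and measured microbiome samples
correspond to steady states.

When A is invertible the interior fixed point is x* = −A⁻¹r; feasibility
and stability are checked numerically, not analytically — the package
integrates every community and filters on a steadiness statistic rather
than certifying stability by theorem.

## Power-law heterogeneity: the sampling convention

"Power law with exponent α" is ambiguous, and the choice matters more than
any other numerical decision here.  We sample

    h = U^(−1/α),  U ~ U(0,1),

i.e. a Pareto variable on [1, ∞) with *survival* exponent α (density
∝ x^(−(α+1))), computed in log space and mean-normalized by log-sum-exp so
that draws near α = 1 stay finite in double precision.  Two facts motivate
this convention over the density-exponent alternative U^(−1/(α−1)).
First, its phenomenology matches the regimes the model is meant to produce:
the mean is finite for all α > 1, single-draw dominance (exactly one SIS
after mean normalization) appears as α → 1, and at α ≈ 1.6–2 a handful of
comparable SISs coexist.  Second, under the alternative the α ∈ {1.6, 2}
study conditions put several enormous columns into A simultaneously and
roughly half of all 80-species communities diverge in finite time
(mutualistic blow-up), which contradicts the intended regime where fewer
than 1% of integrations fail.  The sweep default α ∈ {7, 3, 2, 1.6, 1.01}
runs from near-homogeneous interactions to the single-SIS regime.

Default scalings: s = 0.07 for the complete graph (σ = 1), s = 0.1 for the
Erdős–Rényi digraph (link probability 0.1) and for the power-law out-degree
digraph (mean out-degree 10; out-degrees reuse the heterogeneity draws, so
high-H species are also high-out-degree — the structurally confounded case
that the H = identity variant disentangles).

## Simulation protocol and steadiness

Each local community (default: 500 communities of 80 species from a
100-species pool) integrates from U(0,1) initial abundances with adaptive
RK45 (rtol 1e−6, atol 1e−9) for 100 time units, sampled on a 0.1 grid.
Steadiness uses the discrete terminal derivative ‖(x(T) − x(T−0.1))/0.1‖₂
≤ 0.01; solver failure, non-finite states, or negative excursions beyond
−1e−9 (GLV preserves the nonnegative orthant, so larger violations signal
numerical failure; tiny ones are clipped) mark a community unstable, and
unstable communities are excluded from all downstream analysis.  Note the
criterion bounds a *rate*: a community passing at 0.01 can still drift
visibly over hundreds of time units, which is why control scenarios
integrate longer (below).

Robustness variants replace the deterministic law: an Itô disturbance
dx = diag(x)(r dt + A x dt + c dw) simulated by Euler–Maruyama with step
0.01 and states clipped at zero (c ∈ {0.1, 0.5, 1} are the conventional
levels), and a migration term ẋ = λ(t) + diag(x)(r + Ax) with λ redrawn
uniformly from [0, λ_high]^n every 0.01 time units (RK4 within intervals).
Under persistent disturbance the terminal derivative never falls below the
disturbance floor, so these runs take the terminal state directly and flag
only non-finite runs as unstable.

## Community typing

Steady states are embedded in the 100-species pool frame (absent species
at zero), row-normalized, and compared by the Jensen–Shannon distance —
the square root of the Jensen–Shannon divergence with base-2 logarithms
(0·log 0 := 0), bounding distances in [0, 1].  The base is a convention
the silhouette is insensitive to, but raw distances are not, so it is
stated here.  Clustering is PAM k-medoids (greedy BUILD plus nine random
seeded restarts, best-improvement swaps, total distance-to-medoid cost,
ties to the lexicographically smallest medoid set) for k = 2..10; the
cluster number is the silhouette argmax (ties to smaller k), with the
Calinski–Harabasz variance-ratio criterion available as an alternative,
computed on the full positive-eigenvalue PCoA embedding of the chosen
distance so that Euclidean dispersion is faithful to it.  k = 1 cannot be
scored by silhouette; instead a winning silhouette below 0.1 is reported
as "no clustering".  Ordination is classical scaling with negative
eigenvalues dropped and their mass reported (JSD matrices are mildly
non-Euclidean); axis signs are fixed by making the largest-magnitude
loading positive.

## Open-loop control

The control experiments run against a clustered background generated at
α = 1.6 (Euclidean metric on relative abundances, so the ordination is a
PCA and trajectories can be projected into it).  Because a random draw is
not guaranteed to produce two clusters distinguished by disjoint SIS sets,
`find_control_background` scans metacommunity draws — and, within each
draw, the k = 2..4 partitions, since the SIS-combination structure is
sometimes resolved only at a finer partition than the silhouette optimum —
until a valid swap plan exists: among the top-6 species by H, a nonempty
set present in ≥90% of the source cluster and ≤10% of the target, and vice
versa.  In our draws roughly one background in twenty-five qualifies, so
the search dominates the control demo's runtime; the conditioning mirrors
the premise of the experiment rather than tuning its outcome.

Scenario mechanics: removed species leave the dynamics entirely (the
community is re-extracted from the pool, keeping zeros structural);
SIS-swap additions enter at U(0,1) abundances; dominant-swap additions are
copied at exactly the donor's steady abundances, overwriting the abundance
of species present in both; the FMT protocol removes the community's two
strongest-H members plus its 18 most abundant remaining species, settles
to the depleted "CDI" state, then adds 1% of the donor's steady abundance
for every donor species (incrementing residents, introducing absentees) —
optionally withholding the donor's own two SISs, the designed failure
control.  Post-intervention integrations run 500 time units: interventions
can trigger transients far slower than assembly from random abundances,
and the depleted CDI community in particular converges slowly.  Success is
membership of the declared target cluster at the endpoint, assigned by the
nearest background *sample* (1-NN under the background's own metric and
partition; ties to the lower cluster id).  Nearest-medoid assignment is
available but brittle here: when clusters overlap, a community that has
acquired the target type's SIS signature can still sit marginally closer
to another cluster's medoid, because a medoid is a central prototype and
says little about the boundary.  Growth rates of introduced species are their pool values —
the only self-consistent choice — and the default donor is the target
cluster's medoid community.

## System identification

With samples on integer days and the state held constant over each
interval, GLV dynamics discretize to
log x_i(t_{k+1}) − log x_i(t_k) = r_i + Σ_j a_ij x_j(t_k) + e_i(k), fitted
jointly for all taxa by Tikhonov-regularized least squares.  The closed
form Y Φᵀ(ΦΦᵀ + λI)⁻¹ is evaluated through the equivalent stacked
least-squares problem (QR/SVD), which avoids squaring the condition
number; λ = 0 demands full row rank of Φ.  The penalty covers the
growth-rate column as the closed form implies.  Preprocessing follows the
real-data conventions: zero counts become one read, relative abundances
are computed per sample before logarithms, and only consecutive-day pairs
enter.  Regressing on relative abundances rescales the interaction
estimates by the unobserved total abundance; rankings are unaffected, and
for recovery studies the regression can instead run on counts divided by a
known scale.  λ is chosen on a 50-point log grid in [1e−4, 10] by
chronological hold-out: per subject, the first two thirds of usable pairs
train and the final third tests (a chronological rather than random split
avoids temporal leakage; the alternative was genuinely open), errors
summed over subjects, ties to the smaller λ.  SIS scores are the standard
deviation of each taxon's column of Â, ranked descending.

The synthetic generator samples a local community daily and converts each
day's composition to counts — multinomially at a given read depth, or by
deterministic rounding for noise-free studies.  Its "euler" scheme iterates
x(t+1) = x(t)·exp(r + A x(t)), exactly the generative model the regression
assumes, so noiseless recovery is exact and the remaining error isolates
count noise, dropout, disturbance (Gaussian noise added to log-increments)
or day permutation; the "ode" scheme samples the continuous trajectory and
so carries genuine discretization error.  A noise-free trajectory parks at
the fixed point and loses identifiability, so the generator can
re-randomize the state every so many samples (emulating repeated large
perturbations), skipping one calendar day at each restart so the jump pair
is excluded by the consecutive-day rule.  The day-permutation control
shuffles sample columns against fixed dates; notably, column-s.d. scores
remain heterogeneous on permuted data, and over-regularizing permuted data
biases the ranking toward the most abundant taxa — both reported, as
cautions against reading SIS rankings off real data uncritically.

## What the synthetic data do and do not emulate

Generated tables have daily sampling, multinomial read noise, missing
days, and zero counts, like real longitudinal gut surveys.  They do not
reproduce heavy-tailed abundance profiles (GLV steady states from this
generator are not heavy-tailed), compositional coupling from fixed
sequencing depth acting on *varying* total biomass, taxonomic aggregation
effects, or host-specific dynamics.  Passing recovery tests therefore
demonstrates correctness of the estimator under its own assumptions, not
identifiability on real stool series.

## Problem sizes and determinism

Full-scale runs (the acceptance script) use the study conditions: 500
communities of 80 species, five heterogeneity levels, one fresh
metacommunity per level.  The test suite exercises the same pipeline at
500 communities for the regime checks and 200 communities, three
metacommunity re-draws, for the trend and topology-null properties —
enough for the medians to be stable while keeping the default suite fast.
All randomness flows from one master seed through named CRC32-keyed
`SeedSequence` substreams ("N", "h", "G", "r", per-community "lc"/"x0",
"replicate", ...), so any single component can be regenerated in
isolation and every run replays bitwise.

## Known limitations

* The power-law convention is a reconstruction; the regimes match, but
  printed silhouette values need not coincide with any particular
  realization elsewhere.  The optimal cluster count at intermediate
  heterogeneity (α ≈ 2) is draw-sensitive: two clusters (split on the
  single strongest SIS) are the modal outcome here, with three appearing
  when the second SIS is comparably strong.
* PAM with ten restarts is a heuristic; it matches exhaustive search on
  small instances (tested) but global optimality at q = 500 is not
  guaranteed.
* The steadiness criterion bounds a rate, not a distance to equilibrium;
  slowly drifting communities can pass it.
* Control conclusions are demonstrated on backgrounds satisfying the
  SIS-separation premise, which only a minority of draws produce; the
  separation observed is single-SIS and partial (exclusivity margins
  0.8–0.95), never the full two-SIS characterization of the reference
  experiment.  Consequences: SIS swaps steer reliably (80% of
  background × initial-condition replicates) and dominant-species swaps
  reliably fail, but the transplant *failure* control is weaker — on some
  backgrounds an FMT that withholds the donor's SISs still ends nearest
  the target cluster, because the remaining donor species suffice to move
  the composition there when clusters overlap.  The withheld-SIS failure
  appears to require strongly SIS-characterized, well-separated types.
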