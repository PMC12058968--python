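# Methods

## Model

Two-dimensional overdamped active Brownian particles (ABPs) with diameter
σ interact through (i) WCA repulsion (Lennard-Jones truncated and shifted
at its minimum r_c = 2^{1/6}σ; energy scale ε = 100 k_BT), (ii) a
reciprocal alignment torque 𝒯_A sin(φ_j − φ_i), and (iii) a non-reciprocal
cohesive torque −𝒯_C sin θ(u_i, r̂_ij) that rotates particle i toward
neighbor j. Both torques act inside the same radius R; their competition
(alignment wants a common heading, cohesion wants to point at neighbors)
is the mechanism behind every emergent state. The ratio 𝒯_A/𝒯_C defaults
to 2; ratios below 1 produce clusters that cohere but fail to co-move, so
2 is kept fixed while 𝒯₀ = 𝒯_A and R are swept.

**Sign conventions.** r_ij = r_i − r_j (minimum image); θ is the
counterclockwise signed angle in (−π, π] from u_i to r̂_ij, with
sin θ = u_x r̂_y − u_y r̂_x. With these conventions the cohesive fixed point
u_i = −r̂_ij points straight at the neighbor, and positive torque is
counterclockwise. The Heaviside support is strict (interaction iff
distance < R); the boundary has measure zero in the dynamics but the
convention is fixed for reproducibility.

**Units.** σ = k_BT = 1 and time is measured in the reorientation time
τ_R = 1/D_R. Taking μ_R = 1 and the rigid-disk relation μ/μ_R = σ²/3
gives μ = D = 1/3 and v₀ = Pe·D/σ = Pe/3 ≈ 26.67 at the standard Pe = 80.
The box side follows from the packing fraction, L = √(Nπσ²/4Φ); R is
configured in units of r_c and converted internally.

## Integration

Explicit Euler–Maruyama:

    r ← r + [v₀u + μΣF] dt + √(2D dt) ξ,   φ ← φ + μ_R ΣT dt + √(2D_R dt) η,

with fresh standard-normal draws per particle per step from a single
counter-based stream (numpy PCG64); the master seed is split into
independent initialization and thermal-noise streams, and equilibration
and collection share the noise stream, so runs are bit-reproducible.
Positions are rewrapped into [0, L) with integer image counters (needed to
unwrap for the MSD); φ is wrapped to (−π, π].

The default step dt = 5·10⁻⁵ τ_R keeps the WCA displacement at the
steepest guarded separation, μ·24ε·dt/σ, below 0.05 σ; a startup check
warns above 0.1 σ. Scaled-down validation runs use dt = 10⁻⁴ with the
same guard. Pairs closer than 0.5 σ abort the run with an overlap error
(the step is then too large for ε = 100); forces and torques are not
capped. Neighbor search inside the integrator is a linked-cell grid with
cell side ≥ max(R, r_c), falling back to an all-pairs scan when the box
is smaller than three cells; the grid is capped at ~2√N cells per side so
clearing it stays O(N). The public `build_pairs` uses a periodic k-d tree
and is cross-checked against an O(N²) minimum-image scan, as is the
integrator's torque kernel against a double-loop oracle.

## Initial conditions

Four families probe the multistability: (1) random orientations on a
triangular lattice spanning the box; (2) a hexagonally close-packed disk
(spacing r_c, i.e. contact at the potential minimum, avoiding initial
force spikes) with inward orientations — the aster initialization — or
(3) with random orientations; (4) a hex-packed worm strip aligned with +x
with Gaussian orientation jitter (std 0.1 rad). The worm's width defaults
to the narrowest strip (≥ 5 particles) whose length fits the box; width
and jitter are free geometry parameters not constrained by the model, and
both are exposed in the configuration.

## Observables

* **Polar order** Ψ = |Σu_i|/N per frame, time-averaged over collection.
* **Clustering**: DBSCAN (scikit-learn) with cutoff 1.5 σ and minimum
  samples 1 on the full minimum-image distance matrix — with min_samples=1
  this equals connected components of the proximity graph, with no noise
  label. The distance-matrix route (not a tree) keeps the periodic metric
  exact; at N ≤ a few thousand correctness beats speed.
* **Periodic center of mass**: each coordinate is mapped to the unit
  circle, the embedded mean gives a reference point, and the arithmetic
  mean of minimum-image displacements about that reference is added back.
  This equals the plain mean for any cluster narrower than half the box,
  wherever it sits; a mass-balanced antipodal configuration (undefined
  circular mean) falls back to the arithmetic mean with a warning.
* **Cluster size** S_c: mean over clusters of the farthest member's
  distance to the cluster's periodic center of mass; **system size** S is
  the same with all N particles as one cluster. The per-frame *line
  criterion* is a largest-cluster extent above L/2: the all-particle S is
  also reported, but for multi-worm configurations scattered across the
  box it exceeds L/2 without any line existing, so intermittency detection
  uses the largest single cluster.
* **Asymmetry** A = |I₁−I₂|/(I₁+I₂) from the eigenvalues of the 2×2
  second-moment (gyration) tensor about the periodic center of mass. Any
  planar inertia-tensor variant differing by a trace shift gives the same
  A because the eigenvalue gap and sum normalize identically. Clusters
  with a zero tensor return NaN and are excluded from averages.
* **MSD / OCF** with averaging over all time origins at the frame spacing
  and over particles; quoted errors are standard errors over particles
  (independent for free particles; for interacting runs they understate
  correlations and are used only qualitatively). Lag 0 is pinned to
  MSD = 0, OCF = 1. Closed-form free-ABP baselines:
  MSD = 4Dt + (2v₀²/D_R²)(D_R t − 1 + e^{−D_R t}), OCF = e^{−D_R t}.
* **Neighbor turnover**: fraction of particles within R of a tagged
  particle at t₀ no longer within R at t₁, plus the particle's front/back
  rank along its cluster's mean orientation (leadership tracking).

## State classification

Static split (thresholds configurable): Ψ_lo = 0.3, Ψ_hi = 0.6,
S_lo = 5 σ. These numeric boundaries are this package's own construction —
the state groupings in the (Ψ, S_c) plane are visually separated but no
published numbers exist — chosen midway between the observed groupings:
disperse sits at Ψ ≲ 0.1 (the N^{−1/2} floor) and S_c ≲ 1σ, worm families
at Ψ ≳ 0.8, so the rule is insensitive to factor-of-two threshold changes.

* aster: Ψ < Ψ_lo, S_c > S_lo, and mean outward radial order < −0.5
  (orientations point at the cluster center);
* disperse: Ψ < Ψ_lo, S_c ≤ S_lo;
* line: Ψ ≥ Ψ_hi and ⟨S_c⟩ > L/2;
* multiple-worm ↔ line transition: Ψ ≥ Ψ_hi and the per-frame line
  criterion holds intermittently (fraction in (0.05, 0.95));
* multiple worm: Ψ ≥ Ψ_hi, S_c ≤ S_lo;
* otherwise the worm family, split by dynamics: **persistent** if the MSD
  crossover exists and is later than the standard ABP's (computed from the
  analytic baseline with the same estimator, for a self-consistent
  comparison); **rotary** if no crossover and the oscillation flag is set;
  **transition** if a crossover exists but is earlier than the ABP's or
  coexists with oscillations. Records matching no rule raise and are
  flagged for manual review, never silently labeled.

**Crossover estimator**: local log-log slope by centered differences after
thinning the curve to ≤ 16 log-spaced points per decade (on a uniform lag
grid the late-time log spacing vanishes and centered differences amplify
sampling noise). The crossover is the first lag with slope < 1.5 that
stays below 1.5 for a full decade of confirming data; lags whose decade
window extends past the curve cannot be confirmed and yield none. The
curve must span ≥ 2 decades.

**Oscillation detector**: flag when the OCF dips below −0.1 and its
spectrum (uniform-lag grid, quadratically interpolated peak) has a
dominant nonzero-frequency peak ≥ 3× the median background, or when the
MSD shows ≥ 2 local maxima of prominence ≥ 10% of the plateau after the
plateau onset. The depth/ratio/prominence values are package choices,
exposed in `ClassifierThresholds`.

Synthetic records (`cohesim.synthetic`) realize each label's defining
signature with margins from the thresholds and 1% multiplicative curve
noise; the crossover/oscillation flags are then computed by the real
estimators, so label recovery exercises the full decision path. They
validate the rule's internal consistency, not the simulator.

## Sheet-edge stability analysis

The probe torque is the continuum integral (uniform sheets; polar
Gauss–Legendre product quadrature, default order 64×64, doubling changes
results < 10⁻⁶ relative) or triangular-lattice sum (hex sheet) of the
pair torque over the sheet region within R, with all sheet particles
oriented along the edge (or wedge axis). The stable orientation is the
torque root with negative slope (Brent, xtol 10⁻¹⁰). Because 𝒯₀ factors
out, the tilt depends only on the alignment/cohesion ratio — verified to
10⁻⁸ rad over three decades of 𝒯₀.

For the uniform half-plane the integral is elementary,
T(α) ∝ −π sin α − (2/ratio) cos α, giving the closed-form inward tilt
−atan(2/(π·ratio)) ≈ −0.308 rad at ratio 2; the quadrature path is tested
against it. Lattice sums use the closed disk (distance ≤ R): lattice
shells sit exactly at rational multiples of the spacing, so the open-disk
convention used in the dynamics would make the nominal radii k·r_c
degenerate. The hex-sheet tilt is inward and non-decreasing in magnitude
over R ∈ {1, 1.5, 2, 2.5, 3}·r_c; on finer R grids the trend carries
small non-monotonic steps where new lattice shells enter the disk — the
monotonicity statement is about the standard radii, not arbitrary R. The
uniform-sheet density is set to the hex-packing density at spacing r_c
for comparability.

## Problem sizes for validation

All in-suite and acceptance-script simulations run at reduced size, chosen
so each check still probes the intended physics: the free-ABP limit at
N = 500, Φ = 10⁻³, 10 τ_R (the closed forms are exact at any N); aster
stability at N = 100 for 50 τ_R (strong-torque R = 2 r_c asters are stable
at this size); multiple-worm persistence at N = 100–200 over 200 τ_R; the
coarse census at N = 100 with 25 + 25 τ_R windows. Oracle equivalences are
exact and size-independent.

## What reduced-scale runs do and do not show

The reduced census realizes disperse, multiple-worm, rotary-worm, aster,
and the worm↔line transition states. Two states are systematically harder
at N = 100: the **line** state is a finite-size effect that requires the
cluster to span the box and lock in — at N = 100 box-spanning lines form
but break again (they appear as the transition state); and **persistent
worms** reorient so slowly that their ballistic-to-diffusive crossover
falls beyond affordable collection windows, leaving the dynamic split
unconfirmed (such runs are flagged rather than mislabeled). The
full-scale state diagram, including both states, is produced by
`scripts/full_census.py`, which runs the standard N = 1000,
1000 + 1000 τ_R protocol and is a multi-day single-CPU computation.
Passing reduced-scale checks therefore validates the kernels, estimators,
and classifier logic; they do not by themselves reproduce the full-scale
state diagram.

## Known limitations

* Euler–Maruyama is first-order; time-scale-sensitive quantities (exact
  transition torques, crossover times) shift slightly with dt.
* Error bars on MSD/OCF of interacting runs ignore inter-particle
  correlations.
* The classifier thresholds are calibrated for the standard conditions
  (Pe = 80, Φ = 0.025); strongly different densities or activities may
  need re-tuned boundaries.
* No hydrodynamics, no vision cones, 2D only, equal ranges for both
  torques.
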