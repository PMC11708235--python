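# Methods

## Model and assumptions

A haploid monoecious population at uniform density `ρ` occupies
`d`-dimensional continuous space (`d = 1, 2, 3`).  A biallelic locus A/a
has log-fitness `s1 > 0` (allele A) inside "environment-1" patches —
a target patch of radius `R` centred at the origin and, in the
immigration scenario, a source patch of radius `Rs` at centre distance
`D` — and `−s2 < 0` elsewhere.  Offspring disperse by an isotropic
Gaussian step, per-axis variance `σ²` per generation.  Environments are
constant in time.  Fitness is additive, so diploids are handled exactly
by substituting `ρ → 2ρ` (no dominance parameter is offered).  Distances
are dimensionless (the natural choice is `R = 1`), time is in
generations, and all rates are per generation.

Two regimes make the analytic machinery valid:

* **Branching regime** — while rare, the descendants of one allele copy
  behave as an independent branching process.  This requires density
  high enough that a wandering deleterious lineage stays locally rare;
  a surviving lineage carries on the order of `1/s2` members spread over
  `~1/β₂`, so the package warns when `ρ (1/β₂)^d < 1/s2`.
* **Diffusion regime** — `s1, s2 ≪ 1` and `σ ≪` all geometric scales,
  so discrete generations are well approximated by a diffusion with the
  per-generation moments.

The decay constant `β₂ = √(2 s2/σ²)` is computed once on the validated
parameter container and read from there by every module; its inverse is
the characteristic spatial scale of all results.

## Establishment profile u_d(r)

The establishment probability of a single copy born at radius `r`
satisfies

    u²/2 = s(r) u + (d−1)σ²/(2r) u′ + (σ²/2) u″ ,   u′(0) = 0,  u(∞) = 0.

Numerics (all choices are the package's own; the scheme is validated by
self-consistency and by the independent branching Monte Carlo):

* **Discretization** — second-order central finite differences on a
  uniform grid with spacing `h = min(R, 1/β₂)/refine`, `refine = 400` by
  default.  A node sits exactly at `r = R`; there the solution is C¹ but
  not C², so that node carries the matching condition
  `u′(R⁺) − u′(R⁻) = 0` built from one-sided second-order stencils.
* **Origin** — the radial drift `(d−1)σ²/(2r) u′` is regularized by the
  symmetry `u′(0) = 0`, giving `u²/2 = s1 u + (σ² d/2) u″(0)` with a
  ghost-node second difference; this keeps `r = 0` on the grid, which
  the origin-distance density needs.
* **Truncation** — `u(r_max) = 0` at `r_max = R + 20/β₂` stands in for
  the condition at infinity; the neglected tail is `O(e⁻⁴⁰)` relative at
  `r_max` and `O(e⁻²⁰)` in the profile integrals.  The multiplier is
  configurable (the critical-distance search uses 32).
* **Nonlinear solve** — damped Newton (line search halving) on the
  discrete system, sparse direct linear solves, converged to residual
  `< 10⁻¹²`.  The initial guess glues the exact interior fixed point
  `2 s1` to the tail shape `2 s1 e^{−β₂(r−R)}` and converges in 5–7
  iterations over the whole explored parameter range.  Failure raises;
  no partial profile is ever returned.
* **Evaluation** — downstream integrals interpolate the grid with PCHIP
  (shape-preserving, never outside the hull of neighbouring nodes);
  radii beyond `r_max` evaluate to 0, negative radii are rejected.

Refinement checks: doubling `refine` moves `u(0)` by `< 10⁻⁶` relative
and the rate integrals by `~10⁻⁵` (second-order convergence, asserted in
the suite).

Exterior closed form (d = 1): `u₁ = 6 s2/(cosh(β₂ r + α₂) − 1)` solves
the exterior equation exactly (verified symbolically in the suite).  The
constant `α₂` has no explicit formula; it is fitted by minimizing the
maximum relative deviation from the numerical profile on
`r > R + 0.1/β₂`, staying `4/β₂` clear of the truncation node.  Fitted
values are negative for all four benchmark sets (e.g. `−2.161` for
`β₂ = √10`), consistent with the profile's value at the patch edge.

Far field: `u_d ≈ C r^{(2−d)/2} K_{|2−d|/2}(β₂ r)`.  The amplitude `C`
is fitted in log space on a window starting at
`max(R + 6/β₂, 5/β₂)` — the exterior solution deviates from the
linearized tail by `~u/(6 s2)`, which drops below 1% only once
`β₂(r − R) ≳ 6`.  For d = 1 the Bessel form reduces to a pure
exponential (`K_{1/2}(z) = √(π/2z) e^{−z}`); the equivalent exponential
amplitude `C′` is exposed as a property.

## Mutation-driven adaptation

`κ(r)` weighs `u_d` by the habitat at distance `r` (`2`, `2πr`, `4πr²`)
and normalizes; it is reported as a density over distance, not volume.
`λ_mut = μ ρ_eff ∫ u_d dx` uses the same weights.  Quadrature is
composite trapezoid on the solver grid — the integrand's only kink (at
`R`) lies on a node, and the grid already resolves `1/β₂`.

## Migration-driven adaptation

`λ_mig = N(Δx) · ū_d · P(Δx)`:

* **Outflux** `N = n(Δx) σ²/(2Δx²)` from a boundary layer of thickness
  `Δx` with inter-layer migration rate matched to the dispersal variance
  (`2 m Δx² = σ²`); `n = {2ρΔx, 2πRsρΔx, 4πRs²ρΔx}`.  The layer
  must satisfy `Δx ≤ 0.1/β₂` (the closed forms are `O(β₂Δx)` accurate).
* **Mean boundary probability** `ū_d` — d = 1: the average of `u₁` at
  the two emigration points `D ± Rs`; d = 2, 3: the uniform average over
  the boundary circle/sphere, evaluated with 64-node Gauss–Legendre in
  the polar angle (quadrature error far below the 0.1% consistency
  budget the cross-checks enforce).
* **No-return probability** `P` — a lineage destined to establish must
  not be double-counted across repeated emigrations, so only lineages
  that never re-enter the source count.  The lineage is a killed
  Brownian motion (killing rate `s2`); its reach probability `q_d(r)`
  has closed forms `cosh(β₂r)`, `I₀(β₂r)`, `sinh(β₂r)/r` (normalized at
  `R′`).  Conditioning on reaching `R′` gives drift
  `a* = (d−1)σ²/(2r) + σ² q′/q`, and the scale density
  `G(x) = exp(−∫2a*/b*) = x^{1−d} q_d(x)⁻²` yields

      P(Δx) ≈ G(Rs)Δx / ∫_{Rs}^{R′} G
            = {2β₂Δx/(1+e^{−2β₂Rs}), Δx/(K₀I₀(β₂Rs)Rs), 2β₂Δx/(1−e^{−2β₂Rs})}.

  `G` is implemented twice — from the closed form and by numerically
  accumulating `∫2a*/b*` — and the suite asserts the two routes agree to
  `10⁻⁹`, guarding the derivation.  `P` is independent of `R′` once
  `R′ ≥ Rs + 10/β₂` (enforced; an explicit `exact` route evaluates the
  defining ratio at finite `R′` without the thin-layer approximation for
  Monte-Carlo comparison).  `Δx` cancels between `N` and `P`: the
  production `λ_mig` path is the Δx-free combined formula, and an
  explicit product route at two values of `Δx` must reproduce it to
  `10⁻⁶` (asserted).

**Waiting time**: `T_wait = 1/λ_mig + (D − R − Rs)/(β₂σ²)`; the second
term is the travel time of the successful lineage, which approaches the
target at mean speed `β₂σ²`.  This correction matters when patches are
close; it can still misestimate when back-and-forth travel is heavy, and
no finer correction is attempted.

**Partition and critical distance**: the probability that adaptation,
once evolved, was mutation-driven is `λ_mut/(λ_mut+λ_mig)`.  `D*` solves
`λ_mig(D*) = λ_mut` by Brent's method on
`[R+Rs+0.1, R+Rs+30/β₂]` (unique root: `λ_mig` is strictly decreasing);
`ρ` cancels between the rates, so `D*` is density-invariant (asserted to
`10⁻⁹`).  Under the benchmark conditions with `μ = 10⁻⁶` all twelve
`(parameter set, d)` combinations give `D*` between 3.4 and 9.3 patch
radii — the headline number `scripts/acceptance.py` recomputes (its
reported value is the minimum, 3.41).

The log-slope of `λ_mig` in `D` tends to `−β₂` with a curvature
correction `−(d−1)/(2D)`; the correction exceeds 2% of `β₂` for d = 3 at
any desk-scale `D`, so the suite tests the corrected slope.

## Stepping-stone simulator

Validation engine, not an approximation the analytics depend on.  Demes
of `K = round(ρ dx^d)` individuals on a lattice of spacing `dx`;
per-neighbour migration `m = σ²/(2dx²)` (variance-matched to the
Gaussian kernel; calibration asserted to 2% over 100 generations);
nearest neighbours only; reflecting boundaries with the domain extended
`10/β₂` beyond every patch edge so the edge frequency is negligible.
Life cycle: migration → selection → binomial Wright–Fisher resampling.
A deme belongs to a patch iff its centre lies inside, boundary included
(half-open convention); this shifts the effective patch edge by up to
`dx/2`, a bias visible only in far-tail comparisons.  Establishment is
scored when allele A's frequency over the target-patch demes exceeds
0.5.  Constraints (each raises a named error): `dx ≤ (1/β₂)/5`,
`2dm ≤ 0.5`, `K ≥ 2`.

Reproducibility: replicates are processed in fixed batches of 512 with
per-batch seeds spawned from the run seed; the same (seed, replicate
count) is bit-identical.  Timed-out replicates are always reported,
never dropped; waiting-time means are reported only when ≥ 90% of
replicates established, else flagged censored.

**What the generator emulates, and what it does not.**  The lattice at
adequate density reproduces the continuous-space model's diffusion
limit; it does not emulate continuous positions (validation on a lattice
is the standard route for this model class), overlapping generations,
density regulation, fat-tailed dispersal, or temporally varying
selection.  The
migration-probability constraint bounds `dx` from below
(`dx ≥ σ/√(0.5)`), so at `ρ = 216` the 1-D demes hold only ~14
individuals — inside the low-density regime where local fixation of the
deleterious allele weakens selection and inflates establishment beyond
the branching theory (the simulator warns; measured: +45% at
`u ~ 0.005`, and waiting times ~6× shorter than predicted at `D = 4`).
Validation runs therefore use `ρ = 2160` (deme sizes ~100), safely in
the branching regime the theory assumes; at that density the simulated
waiting times sit within 10–30% of the prediction.  Passing tests
demonstrate agreement of lattice dynamics with the theory in its stated
regime — they do not probe the low-density breakdown, which is exposed
but not modelled.

Problem sizes in the suite (the package's scaling choices): 1e5
branching replicates per oracle point (six points across all d),
2,000–20,000 lattice replicates per establishment point, 20 replicates
per waiting-time point at `D ∈ {3, 4}` in d = 1 — the multi-dimensional
waiting-time sweep at large `D` (waiting times `~10⁵` generations on 2-D/3-D
grids) is replaced by the Δx-invariance, slope, and oracle property
checks plus the d = 1 spot checks.

## Monte-Carlo oracles

Independent of the analytic modules (they import only the parameter
container; geometry and dynamics are written inline):

* **Spatial branching** — Poisson(`e^{s(x)}`) offspring, Gaussian
  displacement.  Establishment proxy: ≥ 500 descendants with the
  majority inside the patch (doubling the threshold moves the estimate
  by < 1 SE, asserted); replicates hitting the 10⁵-individual cap
  without an inside majority are flagged, never counted.  Note the exact
  Poisson-offspring fixed point `1 − π = e^{−e^{s1}π}` lies ~2.4% below
  the diffusion value `2 s1` at `s1 = 0.05`; oracle–BVP comparisons are
  made at tail radii where 3 Monte-Carlo SEs exceed this
  offspring-distribution bias.
* **Killed Brownian walkers** — per-generation survival `e^{−s2}`,
  Gaussian step; first passages monitored discretely with the
  Broadie–Glasserman–Kou barrier shift (0.5826 step-SDs) to recover the
  continuous probability.
* **Conditioned no-return walkers** — the layer thickness `Δx` is far
  below the per-generation step `σ`, so the walk is advanced in Euler
  sub-steps sized to at most `Δx/4` with killing applied per sub-step.
  Conditioning is by rejection; fewer than 100 conditioned events is an
  error.  The comparison configuration uses a finite `R′ = Rs + 3/β₂`
  (where conditioning events are affordable) against the exact
  finite-`R′` scale-density ratio; the asymptotic closed forms are
  checked separately against the quadrature route.

## Known limitations

* Only the two-environment pocket geometry: one target patch in the
  BVP, one source patch in the rates; no arbitrary `s(r)` landscapes,
  multiple sources, or asymmetric patches.
* The low-density breakdown is detected and warned about, not modelled.
* `T_wait` ignores repeated back-and-forth travel beyond the mean-speed
  correction.
* Diploids only via `ρ → 2ρ` (additivity); no dominance.
* Dispersal is Gaussian; results should be only mildly
  kernel-dependent in the diffusion regime, but no kernel-robustness
  analysis is attempted.
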