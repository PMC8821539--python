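# Methods

## Scope and data model

`dfekit` implements the analysis half of a dissociation-metadynamics
workflow.  Its inputs are, per replica, a *kernel sequence* (one row per
deposited Gaussian: time, CV center, width σ, height h) and a *CV
trajectory* (time, D).  Everything downstream — primitive and averaged
free-energy surfaces (FES), run auditing, the dissociation free energy
(DFE), convergence, calibration — consumes only these two artifacts, which
is why the bundled 1-D simulator is a sufficient test bed: the analysis
never sees the dimensionality of the system that produced the records.

Units are fixed globally: Å, ps (ns for durations), kcal/mol, kelvin, with
k = 1.987204259 × 10⁻³ kcal mol⁻¹ K⁻¹ and a default temperature of 310 K
(also used for the K_d → ΔG_e conversion).  All three text formats carry a
mandatory units declaration and round-trip at full precision.

## FES reconstruction

The primitive FES of a replica is the negative image of its accumulated
bias, g(D) = −Σᵢ hᵢ exp(−(D−dᵢ)²/2σᵢ²), tabulated on 80 uniformly spaced
points whose endpoints are the minimum and maximum kernel centers.  Eighty
*points* (spacing = range/79), endpoints included: the tabulation is defined
by its row count.  The grid is defined by the deposited kernels, not the CV
trace, because the FES estimate is a functional of the bias alone and
trajectories may be absent.

Averaging N primitive profiles uses a common grid spanning the union of the
member ranges.  The number of intervals is ceil(range / finest member
spacing), so the spacing is uniform, hits both endpoints exactly, and is
never coarser than the finest member.  Members are resampled by linear
interpolation inside their own range and contribute **zero** outside it —
an unvisited region received no bias, so its accumulated Gaussian energy is
identically zero.  Per-point summation uses exact (`fsum`) accumulation, so
the average is bit-identical under any permutation of the member list.

## DFE

    Q = (b − a)⁻¹ ∫_a^b exp(−g(D)/kT) dD,      DFE = −kT ln Q

evaluated by composite trapezoidal quadrature on the native averaged grid,
with linearly interpolated values at a and b when they fall between grid
points.  The window defaults to the full tabulated range (in a standard
campaign: zero to the wall); because the integrand is dominated by the
bottom of the bound-state minimum, the exact choice of b is immaterial for
wells that sit well below their surroundings (the property suite checks
< 0.1 kcal/mol sensitivity at fixed normalization width, and < 0.2 kcal/mol
under clipping everything above g_min + 4 kcal/mol).  Two exact algebraic
properties are enforced by tests: DFE(g + c) = DFE(g) + c, and
monotonicity in well depth.

The DFE-vs-N convergence trace recomputes DFE from the first N replicas in
launch (seed) order; the campaign is converged when at least five entries
exist and the spread (max − min) of the last five is below 1 kcal/mol.
The reported uncertainty is a delete-one jackknife over replicas: the
deposition records are the replicas' independent random draws, so
resampling them is the natural error model.  (For two members with constant
offsets c and c+δ the jackknife standard error is δ/2, which the tests pin
down.)

## The correction process (run audit)

Landmarks are read off the averaged FES: r₀ is the grid point of the global
minimum (ties toward smaller CV); r_b is the first point right of r₀ that
is a maximum of the moving-average-smoothed profile over a ±window
neighborhood *and* rises at least 1 kcal/mol above the minimum — the
neighborhood and rise requirements keep grid-scale noise from masquerading
as the barrier.  If no such maximum exists the boundary falls back to the
first point within 0.1 kcal/mol of the terminal plateau.  A profile that is
monotone, or decreases to the grid end, has no bound state and is an error.

Classification of a replica trajectory:

* **one-way** (keep): the CV exceeds r_b and never afterwards drops below
  r_b − hysteresis.  The hysteresis margin (default 0.5 Å, configurable)
  absorbs jitter exactly at the boundary.
* **multi-trip** (reject): exceeds r_b, then returns below r_b − hysteresis.
* **invasion** (reject): never exceeds r_b and drifts more than 4 Å below
  r₀ — motion opposite to dissociation.  A companion diagnostic reports the
  fraction of the replica's bias deposited left of the *inner wall* (the
  first CV left of r₀ where the averaged FES rises 4 kcal/mol above the
  minimum); it is informational only, since no quantitative threshold for
  "significant invasion" of the primitive FES is established.
* **incomplete** (extend): never exceeds r_b but stays near the well; the
  run needs more time.

Because rejecting replicas changes the average, and the landmarks with it,
the audit iterates — filter, re-average, re-locate — until the kept set is
stable (at most 5 iterations; in practice 2–3).  A run that has been
extended the maximum number of times and still is not a one-way trip is
rejected.  Classification depends only on the sequence of CV values, never
on absolute times, so it is invariant to uniform time rescaling.

## The toy simulator

The generator is overdamped Langevin dynamics on the CV itself:

    D ← D + (D_c/kT)·F(D)·dt + √(2·D_c·dt)·ξ,   ξ ~ N(0,1)

with F = −d/dD (model potential + accumulated bias + wall term), reflection
at D = 0 and a half-harmonic wall (spring 100 kcal mol⁻¹ Å⁻²) at the wall
position.  Deposition follows the standard dissociation-metadynamics
settings: σ = 0.05 Å, h = 0.01 kcal/mol, τ_G = 0.09 ps, T = 310 K.
Integrator defaults: dt = 0.002 ps (45 steps per deposition),
D_c = 0.1 Å² ps⁻¹.  The bias potential/force is accumulated on a 0.005 Å
grid and linearly interpolated; kernels are spread over ±8σ (the dropped
tails are < 10⁻⁶ kcal/mol).  The CV trace is recorded at the deposition
cadence, so each kernel center is verifiably the CV value at its deposition
time.  The inner loop is numba-compiled when numba is available, with an
identical pure-Python fallback.

Noise is a pure function of the replica seed, so identical inputs give
bit-identical outputs, and `extend_run` reproduces a continuation by
deterministic replay: an extended run is bit-identical to a single longer
run with the same seed, and a supplied history that does not match the
replay is reported as a state mismatch.

### Model potentials and the one-way-trip emulation

Three analytic forms are provided: an unbounded harmonic well (for
equilibrium-statistics checks), a truncated harmonic well on a flat
background (`piecewise_well_flat`), and a double well.  Two optional terms
emulate, in one dimension, the physics that makes real dissociation runs
one-way:

* **Radial entropy** (`radial_entropy_power`, default off): an additive
  −p·kT·ln(D/wall) with p = 2, the Jacobian of a three-dimensional distance
  coordinate.  It gives the free region a gentle outward tilt (the growing
  phase space of a separated pair).  The force p·kT/D is clamped below
  0.2 Å for integrator stability.
* **Release step** (`release`, default 0): the outer flat region sits
  `release` kcal/mol below the well rim, reached over a `ramp`-Å slope.  It
  stands in for the orientational/translational freedom gained the moment
  the native contacts break.  Without it, a 1-D walker re-enters the filled
  basin during the late-fill window and most replicas classify as
  multi-trip, which is not how higher-dimensional dissociation behaves.

The default benchmark (`benchmark_potential` / `benchmark_config`): well at
r_w = 2.5 Å, depth 12 kcal/mol, curvature 24 kcal mol⁻¹ Å⁻² (half-width
1 Å), release 5 kcal/mol (~8 kT, the low end of rigid-body entropy loss on
protein association) over a 1 Å ramp, radial entropy p = 2, wall at 33.5 Å
(30 Å beyond the bound-state rim, mirroring the complex-size-plus-30-Å
placement rule), 3 ns per replica, 50 replicas seeded 2007–2056.  Under
these conditions roughly 80–100% of replicas are one-way trips depending on
the seed batch, wells fill in ~1 ns, and a full campaign takes well under a
minute on one CPU.  The problem sizes here (ns-scale 1-D runs) are the
package's chosen desk-scale regime; the analysis stages are size-agnostic.

The analytic reference for benchmark validation is the *effective*
landscape the walker samples — model potential plus entropy terms
(`effective_free_energy`) — tabulated and pushed through the same Q/DFE
machinery.  A converged campaign recovers this reference to a few tenths of
a kcal/mol; the residual offset is the stochastic overfill of the well at
the moment of escape (order kT) plus averaged-grid effects.

### What the generator does not emulate

No solvent, no conformational degrees of freedom, no pressure coupling (no
1-D analogue), no equilibration protocol (the walker starts at the well
bottom), and no orientation-dependent re-binding: the release step is a
mean-field stand-in for it.  Passing tests therefore demonstrate the
correctness of the *analysis* — reconstruction, auditing, integration,
convergence, calibration — under controlled conditions, not the fidelity of
any molecular force field.

## Calibration

ΔG_e = kT·ln(K_d) at 310 K (K_d in molar, 1 M standard state).  The
calibration is an ordinary least-squares fit of ΔG_e on DFE — residuals in
the experimental quantity, consistent with the line's use for prediction —
with R² = 1 − SSR/SST and the residual standard error on n − 2 degrees of
freedom (the definition uniquely consistent with the published pair
R² = 0.84, SE = 1.61 on the bundled panel).  Outlier handling is explicit
by identifier only; there is no automatic outlier detection.  Panel
aggregation over ligand-series targets is an unweighted mean of per-target
R² and SE, with an optional substitution map for outlier-excluded variants.

Two fixture tables ship with the package at printed precision: the
19-complex protein–protein panel (DFE with sampling errors, pre-correction
DFE, calibrated and experimental free energies, K_d, run counts and applied
corrections) and the eight-target protein–ligand panel (per-target R², SE,
and fitted relationships).  Regression tests on these printed values accept
rounding-induced slack (±0.002 on the slope, ±0.01–0.02 elsewhere).

## Pipeline

`run_campaign` executes simulate → primitive FES → average → audit (with
extensions, then rejection of persistent failures) → re-average → DFE +
jackknife → convergence trace; if the trace has not converged, another
batch of the same size is launched (fresh consecutive seeds) up to a
configurable batch limit, after which the campaign honestly reports
`unconverged` (CLI exit status 3) with the manifest still written.  The
manifest records both the post-correction DFE and the pre-correction DFE
(all replicas at their original durations), per-run verdicts with evidence,
extension counts, seeds, file paths, a config hash, and the tool version;
re-running an identical configuration reproduces it bit-for-bit except the
timestamp.  Replica seeds must be unique; launch order for the convergence
trace is seed order, so results are independent of any execution
interleaving.

## Known limitations

* The audit's boundary detection assumes a single dominant bound-state
  minimum; multi-basin surfaces get the leftmost credible boundary.
* The invasion rule is trajectory-based; the primitive-FES invasion
  diagnostic is reported but not used for rejection, for lack of a defined
  threshold.
* The jackknife treats replicas as i.i.d.; it does not capture within-run
  time correlation.
* The kernel-sequence dialect is this package's own; adapters for specific
  MD engines' native deposition formats are future work.
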