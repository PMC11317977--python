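# Methods

## Scope and model

pmfkit implements the free-energy side of a QM/MM umbrella-sampling
mechanism study: reconstructing 2D potentials of mean force from biased
window samples, locating and book-keeping stationary points and paths,
applying level-of-theory corrections, and decomposing QM-region/environment
interaction energies over residues.  The quantum and molecular-dynamics
engines that produce real inputs are deliberately out of scope; the package
consumes their outputs as plain data (coordinate time series, state energy
tables, PDB geometries with partial charges) and provides synthetic
generators with analytically known ground truth in their place.

Units are fixed package-wide: kcal/mol, Å, elementary charges, kelvin;
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹ and k_e = 332.0637 kcal·Å·mol⁻¹·e⁻².
There is no unit autodetection anywhere.

## Synthetic data

**Surfaces.**  Three analytic families with closed-form gradients, each
shifted so its global minimum is exactly zero:

- `harmonic_well` — ½k₁x² + ½k₂y²; curvature default 2 kcal·mol⁻¹·Å⁻².
- `double_well_2d` — a quartic double well along axis 1,
  h·((x²−a²)²/a⁴) + tilt·x, plus a harmonic term along axis 2.  With zero
  tilt the saddle energy equals the `barrier` parameter exactly; with tilt
  the stationary points come from the cubic derivative (numpy roots) and
  the metadata barrier is saddle minus deeper well.  Defaults: wells at
  ±1 Å, y-curvature 10 kcal·mol⁻¹·Å⁻², domain [−2, 2] × [1, 3] Å — the
  same window ranges used for the motivating enzyme system.
- `muller_brown_scaled` — the classic four-Gaussian benchmark scaled by
  0.05 so its ~147-unit depth becomes ~7 kcal/mol; the minimum offset is
  located numerically at construction from the known basin.

**Sampler.**  The real windows are restrained QM/MM MD; here a Metropolis
random walker moves directly in the two collective coordinates under
surface energy plus harmonic bias.  WHAM consumes only the biased
coordinate distributions, which the walker reproduces exactly in the long
run — this is what makes the substitution valid, and also what it does
*not* emulate: no dynamics, no autocorrelation structure of real MD, no
orthogonal degrees of freedom.  Passing tests therefore validate the
estimators, not any claim about a real protein.  Defaults mirror the
production design: 20 000 relaxation + 20 000 production steps (the equal
equilibration/production split of the umbrella protocol), Gaussian
proposals of σ = 0.05 Å (30–60% acceptance under a 50 kcal·mol⁻¹·Å⁻² bias
at 300 K), seed mandatory, default 2024.  Proposals leaving the surface
domain are rejected, which preserves detailed balance for symmetric
proposals.  `sample_windows` advances all windows in lockstep from a single
seeded generator (one Gaussian pair and one uniform per window per step),
so a full 1600-window design samples in seconds and is bit-reproducible;
`sample_biased` is the single-window case.  A window that never accepts a
move raises rather than returning a frozen series.

**Toy complexes.**  A compact QM cluster at the origin surrounded by 1–5
atom MM residues on 6–20 Å shells, per-atom charges uniform on
[−0.6, 0.6] e, minimum inter-atom separation 1 Å enforced by bounded
rejection.  Ground-truth per-residue energies are computed by a deliberately
naive atom-by-atom double loop, independent of the vectorized decomposition
module they validate.

## WHAM

Standard binned 2D WHAM with per-window harmonic biases evaluated at bin
centers (the usual grid-WHAM convention; documented, since sample-position
evaluation is the other common choice).  Direct iteration of the coupled
equations; convergence when max|Δf_i| < tol (default 10⁻⁷ kcal/mol, cap
10⁵ iterations); hitting the cap returns an explicit `converged=False`,
never a silent success.  The first window's offset is gauged to zero.
Probabilities convert to free energies at the run temperature, the unmasked
minimum is normalized to zero, and bins with zero counts are masked with
NaN — never a large finite sentinel.  Samples outside the grid are counted
and reported, not dropped silently.  Windows whose histograms share no bins
with the rest are detected by union–find and reported as disconnected
groups.  Equal sample weights throughout: no statistical-inefficiency or
autocorrelation correction (a known limitation, acceptable for the
walker-generated fixtures); single temperature, no reweighting.

`overlap_report` gives the histogram-intersection fraction
Σ min(ĥ_i, ĥ_j) for adjacent window pairs (grid neighbors when the centers
form a regular grid, nearest neighbors otherwise), flagging pairs below a
configurable floor (default 0.1).

## Surface analysis

**Minima** are unmasked nodes strictly below all unmasked 8-neighbors;
equal-value plateaus that are collectively below their rim are reduced to
the lexicographically lowest index.  **Saddles** combine three
finite-difference criteria: the gradient norm is locally minimal among
8-neighbors, the 2×2 Hessian has one eigenvalue < −10⁻⁶ and one > +10⁻⁶
kcal·mol⁻¹·Å⁻², and the least-squares quadratic fitted to the 3×3
neighborhood has its stationary point inside that neighborhood.  The last
test is the ridge guard: on surfaces with curved ridges (Müller–Brown being
the canonical offender) gradient-norm minima appear along the ridge with no
stationary point nearby, and the fit rejects them.  Touching candidate
nodes are merged, keeping the smallest-gradient representative.

Both kinds of stationary point carry a sub-bin refinement from the same
quadratic fit (position and energy), since mechanism energetics are
conventionally quoted to 0.1 kcal/mol — finer than typical bin widths.  Raw
grid values are retained alongside.

**MFEP.**  The minimum free-energy path is defined as the minimax (widest)
path on the 8-connected grid graph: among all unmasked routes between two
basins it minimizes the maximum node energy.  This is computed exactly by a
Dijkstra-style search ordered by (max energy, summed energy) with
lexicographic node order as the final tie-break — deterministic and free of
step-size or interpolation parameters, unlike steepest-descent tracing, and
it is precisely the property that makes the path's top the effective
barrier.  `main_basins` picks the global minimum and the minimum of
greatest prominence (minimax-path top minus own energy), which makes basin
selection robust to shallow sampling-noise minima on reconstructed
surfaces.  `grid_barrier` reports the MFEP top minus the deeper basin on
raw grid values, directly comparable to an analytic barrier at grid
resolution.

**Profiles.**  `EnergyProfile` holds ordered labeled states (RS, TS1, TI1,
…, PS), each a minimum or TS, optionally tagged with a mechanism branch so
alternative routes can live in one object.  `barriers` reports every state
relative to RS and every TS relative to its preceding intermediate on the
same branch, plus the rate-limiting TS under each convention; the identity
rel_RS(TS) − rel_prev(TS) = rel_RS(preceding intermediate) holds by
construction.  Multi-step mechanisms are stitched by shifting each step so
shared state labels coincide (free-energy continuity at shared states is
assumed — the natural reading of composed per-step surfaces, though a
stitching rule is rarely stated explicitly in mechanism papers);
inconsistent duplicate labels are an error.

## Corrections

A correction table maps state labels to (e_low, e_high) pairs; each state's
free energy becomes G + (e_high − e_low).  Only differences of the
correction between states matter — uniform shifts cancel in every barrier,
which the tests assert exactly.  Two modes: stationary-points-only (default)
and whole-path, where a table covering a subset of path nodes is linearly
interpolated in arc length (constant beyond the outermost covered nodes)
with interpolated nodes flagged.  One conformation per state; no ensemble
averaging over TS-like snapshots.  The module never runs quantum chemistry;
tables are inputs.

## Decomposition

With a nonpolarizable fixed-charge environment, the interaction energy
between the QM selection and everything else reduces to the bare Coulomb
sum over QM–MM pairs, and it partitions exactly over MM residues — the
additivity Σ_r E_r = E_int is checked to 10⁻¹⁰ relative in the tests.  No
distance cutoff and no periodic images (per-residue magnitudes of interest
are large bare-Coulomb terms); electrostatics only by default.  The QM mask
is entirely caller-controlled, so catalytic residues can be included or
excluded from either side.  QM–MM contacts under 1.8 Å are flagged in the
output (a covalently bound nucleophile makes that residue's Coulomb term
physically meaningless); pairs under 10⁻³ Å are rejected as overlapping
atoms.  Difference profiles (state A − state B) require identical residue
key sets — a missing residue is an error, never an implicit zero — and use
the sign convention that positive values destabilize state A.

## Numerical and design choices

- Biases in WHAM's denominator underflow harmlessly to zero for distant
  bins (double-precision exp); window offsets stay O(10 kcal/mol).
- `Window` accepts zero force constants (unbiased reference runs reduce
  WHAM to direct Boltzmann inversion — the solver's exact oracle); the
  window-grid generator and the metadata reader require strictly positive
  values.
- Atoms are addressed by PDB serial, not (residue, atom-name); name
  resolution belongs to the I/O layer.  No minimum-image convention for
  reaction coordinates: they are intra-active-site distances of a few Å.
- PDB reading (Biopython) is restricted to one geometry per state: altLoc
  other than blank/'A' is rejected.  Charges live in a separate TSV table
  because the PDB format has no adequate charge column; occupancy/B-factor
  are never repurposed.
- Text writers use repr-exact (`%.17g`) floats, so write→read round trips
  are bit-faithful and pipeline reruns are byte-identical.
- The walker initializes at the window center (how real studies seed
  windows from neighbors is protocol-dependent and not modeled).

## Problem sizes in tests and the acceptance script

The production design (40×40 windows × 20 000 production steps, 60×60
bins) is used for the double-well barrier-recovery checks; the harmonic
closed-form check uses 9×9 windows × 20 000 steps with the quadratic fit
restricted to the window-covered region, where every bin is densely
sampled (tail bins carry large free-energy noise and no design coverage);
reduced designs (20×20 windows, a few thousand steps) back the faster unit
tests.  The Müller–Brown comparisons run against an exhaustive
gradient-norm search on a 2001² analytic grid.

## Known limitations

- Equal sample weights in WHAM (no autocorrelation correction) make the
  masked-bin pattern and convergence rate fixture-specific.
- Saddle refinement is quadratic-local; strongly anharmonic saddles at
  coarse resolution keep only their raw grid value.
- The decomposition is the semiclassical fixed-charge limit: QM-side
  polarization is not modeled, and charges for the QM region must be
  supplied (e.g. pre-fitted ESP charges).
- The minimax MFEP is a grid path; it is not a continuous-space string or
  NEB path, and its geometry (unlike its maximum) depends on bin layout.
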