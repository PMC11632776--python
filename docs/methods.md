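# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one convention was defensible.

## Data model and units

All analyses consume three containers: `TimeSeriesTable` (ordered numeric
records, first column the strictly increasing independent variable),
`ConfigurationFrame` (atom identities, positions and an orthorhombic
periodic box) and `PropertyResult` (named scalar, unit, optional
uncertainty, and a provenance map recording every window/threshold that
influenced the value).  Canonical units are nm, ns, K, g/cm³, GPa and
cm²/s; pressure arrives in bar and is converted as 1 bar = 10⁻⁴ GPa.
Only orthorhombic boxes are supported — minimum-image arithmetic is then a
single componentwise rounding — and triclinic input raises an explicit
"unsupported" error rather than a wrong number.  GRO I/O is delegated to
MDAnalysis (Å↔nm conversion at the module boundary); extended XYZ with a
`Lattice="..."` comment is parsed directly, as no installed library reads
that lattice convention.

## Glass transition

Specific volume, not density, is regressed on temperature, with free
intercepts in both windows (the changepoint is estimated by two *free*
lines, not a continuity-constrained hinge, because the glassy and rubbery
branches are fitted only to points clearly away from the transition).
Window endpoints are inclusive.  T_g is the exact intersection abscissa of
the two stored lines; slopes closer than 10⁻¹² cm³/(g·K) raise a
"parallel fits" error instead of returning an enormous T_g.  T_g is
invariant under affine transformations of the volume axis, which both fits
share.

Error budget worth knowing: with 6 points per window, 25 K spacing and
volume noise of 5×10⁻⁴ cm³/g, each branch is extrapolated ~190 K to the
intersection and the resulting T_g standard deviation is ≈ 5.7 K.  Recovery
statements at this noise level are therefore made about means over seeds,
not individual realisations.

## Thermal expansion

α_V uses the finite difference of V(T) over one 25 K cooling step,
normalised by the lower-temperature volume; the normalisation reference
(lower vs midpoint) changes the result only at order α·ΔT ~ 0.3 %, far
below reporting precision, and is switchable and recorded in provenance.
For exponentially growing V(T) the finite difference overestimates α by
α·ΔT/2 to leading order.

## Hydrogen bonds

Geometric criterion: donor-oxygen to acceptor-oxygen minimum-image distance
strictly below r_max = 0.35 nm *and* the angle at the donor oxygen between
its hydrogen and the acceptor strictly below 30°.  Boundary values are
excluded.  Donors are oxygens with an attached hydrogen (same molecule,
O–H < 0.12 nm) matching configurable name patterns; acceptors are all
matching oxygens.  An explicitly named donor without an attached hydrogen
is an error, not a silent skip.

Kinetics use the *intermittent* indicator autocorrelation with multiple
time origins, normalised per lag:
C(t) = Σ_b Σ_{t₀} h_b(t₀)h_b(t₀+t) / Σ_b Σ_{t₀} h_b(t₀)².  The intermittent
form (a bond that re-forms still counts) is the convention compatible with
long-lived bonds making the lifetime effectively infinite in rigid glasses.
The two-term decay is fitted by bounded trust-region least squares
(K₁, K₂ ≥ 0; τ₁, τ₂ ∈ [10⁻⁶, 10⁴]·t_max) from a deterministic grid of 12
starts (three amplitude splits × four decade-spaced timescale pairs); the
best converged start wins and τ₁ ≤ τ₂ is canonicalised.  A fit whose curve
has not decayed below 99 % of C(0) by the end of the window is flagged
"no decay" and refused downstream.

Lifetime is the full integral K₁τ₁ + K₂τ₂.  The half-life is by default the
time where the *fitted* C crosses 0.5 (bracketed Brent root); an alternative
"partial integral up to the crossing" convention is implemented behind a
mode flag because the defining phrase ("integrate until it reaches 0.5") is
ambiguous.  For K₁, K₂ ≥ 0 the survival mixture is completely monotone, so
half-life ≤ lifetime always; this is asserted property-style in the tests.

## Deformation mechanics

Stress is σ(ε) = −P_z(ε) with bar→GPa conversion; strain is engineering
strain (L_t − L₀)/L₀.  Smoothing is an unweighted mean over a ±2.5 %-strain
window (the kernel is a design choice; mean was adopted), with the data
odd-reflected around ε = 0 so windows that dip below zero strain use
(−ε′, −σ′) points — this pins the smoothed curve to (0, 0).  Near the upper
data edge the half-width shrinks symmetrically (h′ = min(h, ε_max − ε)) so
every window stays centred; this keeps the smoother exactly
linearity-preserving on uniform grids, which a one-sided truncation would
not.  A sample recorded at exactly ε = 0 is treated as σ = 0, the only
value consistent with odd symmetry.

Young's modulus is the zero-intercept least-squares slope Σσε/Σε² over
0.3–3 % strain — zero intercept because the reflection already forces the
curve through the origin, and a free intercept would fight that
construction.  Maximum tensile strength is the largest smoothed stress on
[3 %, 97 %], ties broken to the smaller strain.  Poisson's ratio is minus
the OLS slope of transverse vs axial strain over 1–2 %, with the transverse
reference length taken at zero axial strain (not a time average); the two
transverse directions are coupled and equal in semi-isotropic deformation,
and a single supplied direction is accepted with a warning flag.  The bulk
modulus K = E/(3(1 − 2ν)) degenerates as ν → 0.5; within |1 − 2ν| < 10⁻³
the result is flagged "near-incompressible: K unreliable" rather than
reported bare, and ν > 0.5 is an error.  Direction aggregation over the
three orthogonal pulls reports mean ± population standard deviation.

Recovery-test design: the paper-style 0.3–3 % window is the default for
real, eventually-nonlinear curves.  For noisy *linear* synthetic sweeps the
information bound for the slope is noise/√(Σε²); restricted to ε ≤ 3 % of a
400-point sweep this bound alone exceeds 2.5 %, so the noisy-recovery tests
fit the full linear range (where the bound is ~0.15 %) and the narrow-window
convention is exercised on noiseless and lightly smoothed data.

## Free volume

Free volume is operationalised as the probe-insertion fraction: the share
of box volume where a probe centre lies strictly outside every atom's
(van der Waals radius + probe radius) sphere, minimum-image.  A point
exactly on an exclusion surface counts as excluded.  The production
estimator samples a regular grid commensurate with the box (default
spacing 0.02 nm, at which discretisation error stays below 1 % against a
10⁶-sample Monte-Carlo cross-check on ≤100-atom packings); periodic
nearest-atom queries use a boxed k-d tree.  The Monte-Carlo estimator is
retained as an independent brute-force path (uniform insertions, direct
minimum-image distances, no spatial index) for cross-validation.  Van der
Waals radii default to a bundled Bondi-style table and are
config-replaceable; unknown elements are an error naming the element.
Accessible fractions are non-increasing in probe radius (nested exclusion
sets) — asserted per frame.

## Diffusion

Wrapped frames are unwrapped by accumulating minimum-image steps; a step of
half a box edge or more is ambiguous and raises.  MSD is averaged over all
particles and, by default, all time origins, computed with the standard FFT
decomposition MSD(m) = (S₁(m) − 2S₂(m))/(N − m) (identical to the direct
double loop to ~10⁻¹⁴, verified in tests).  D = slope/6 of a free-intercept
OLS fit over the central 10–90 % of the lag range, which on a 10 ns trace
reproduces a 1–9 ns fit window; the intercept is free because the window
deliberately excludes the short-time regime.  1 nm²/ns = 10⁻⁵ cm²/s.

Two split-half uncertainty conventions are implemented.
`diffusivity_from_msd` splits the *lag window* of one MSD curve and fits
each half.  `diffusivity_with_split_half` instead splits the *sampled
trajectory* into halves, computes each half's own MSD and fit, and takes
|D_first − D_second|; because the halves are near-independent realisations,
this tracks the true sampling error better (measured 2σ coverage over
Brownian replicates: ~75 % for the lag split vs ~81–84 % for the
trajectory split).  Per-chain diffusivities apply the same window to each
chain's centre-of-mass MSD and report mean ± population std; single-chain
fits on a 10 ns window carry large correlated-lag errors (relative sd well
over 50 %), so cross-chain means should be compared at a few standard
errors, not a fixed percentage.

## Synthetic generators

Every generator is a pure function of its parameters and a seeded
`GeneratorSpec`; identical inputs give bit-identical output.  Noise is
additive i.i.d. Gaussian everywhere — real MD observables carry correlated
thermostat/barostat fluctuations, so passing recovery tests demonstrates
estimator correctness, not robustness to correlated noise.  Specifics:

- V–T curves are exact two-line hinges; the default hinge (T_g 400 K,
  slopes 1×10⁻⁴/3×10⁻⁴ cm³/(g·K), V(T_g) = 0.54 cm³/g, noise
  5×10⁻⁴ cm³/g, 25 K grid 150–600 K) mirrors a dense amorphous polymer
  cooling schedule.
- Bond events are two-state Markov chains (per-step break probability
  1 − e^(−k·dt)) starting formed, so C(0) = 1 and, with no reformation,
  C(t) = e^(−kt) exactly in expectation.
- Stress sweeps are linear at slope E with a cubic-Hermite knee onto a
  plateau; below the knee the sweep is exactly linear, so noiseless
  recovery is exact.
- Transverse box response defaults to the linear convention
  ε_t = −ν·ε_a (Poisson's ratio is a derivative definition); the
  finite-strain volume-preserving variant L_t = L₀(1+ε)^(−1/2) is an
  explicit flag and yields ν ≈ 0.489 over the 1–2 % window.
- Brownian walks draw per-coordinate increments with variance 2D·dt,
  unwrapped.
- Packings are rejection-sampled with minimum-image separation ≥ 2r and a
  configurable placement budget.

None of the generators attempt chemically realistic conformations,
force-field energies or equilibration histories; they reproduce only the
statistical structure each estimator consumes.

## Problem sizes and determinism

Default test/acceptance sizes — 19-point cooling curves, 10⁴ bonds ×
1000 frames, 400-point deformation sweeps, ≤100-atom packings with 10⁶
grid/MC samples, 100-particle × 10 ns Brownian ensembles, 50-replicate
coverage checks — were chosen so each stage's Monte-Carlo error sits well
inside its assertion band while the full pipeline completes in seconds.
All randomness flows through explicit integer seeds; analyses themselves
are deterministic given their inputs.

## Known limitations

Triclinic boxes, binary trajectory formats, velocity/force records,
Green–Kubo diffusivities, finite-size hydrodynamic corrections, cavity
connectivity/percolation analysis and energetic hydrogen-bond definitions
are out of scope.  The 2σ-coverage property of the split-half error bar is
intrinsically marginal around its 80 % line (expected ≈ 84 %, binomial sd
≈ 5 % at 50 replicates): an unlucky replicate block can land just below it
without indicating a defect.
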