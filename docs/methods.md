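# Methods

This note records the models implemented in `pdccore`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic-data tests do and do not demonstrate.

## Synthetic dodecahedral core generator

The generator (`pdccore.assembly`) is a *forward* model: it produces
bead models with the known architecture of the PDC core rather than
reconstructing shapes from data (no simulated-annealing shape search is
included or intended).

Geometry.  Trimer centroids sit on the 20 vertices of a regular
dodecahedron at `inner_radius` from the centre; the three monomers of a
trimer form an equilateral triangle of circumradius `trimer_radius` in
the tangent plane.  The dodecahedron is constructed as the exact dual of
the reference icosahedron (face centroids of the icosahedral hull), so
the 12 pentagonal face axes are by construction 37.38° from the nearest
trimer axis — this guarantees the hollow centre and open pentagonal
faces that distinguish the substitution stoichiometry, and gives the
addition model well-defined face positions for its 12 extra E3BP
clusters.  Each monomer is one bead by default (`bead_radius` 14 Å);
multi-bead monomers use a deterministic Fibonacci-shell layout.

Calibration.  Defaults (`inner_radius` 130 Å, `trimer_radius` 25 Å,
bead radius 14 Å) place the truncated-core maximum dimension at ≈293 Å,
matching the ≈300 Å envelope of the truncated core.  This is a
calibration constant of the generator, not a measurement.

Stoichiometry.  `substitution_48_12` replaces one E2 with one E3BP in 12
of the 20 trimers (chosen by the seeded generator); `addition_60_12`
keeps 60 E2 and adds 12 E3BP clusters on the face axes; `E2_only_60` is
the homomeric control.  Chain identity is tracked per bead
(`chain_ids`), so the census is in chains regardless of beads per
monomer.

Flexible arms.  Full-length chains carry disordered N-terminal lipoyl
domains, subunit-binding domains and Ala-Pro-rich linkers.  Arms are
modelled as jittered outward random walks anchored at well-spread
surface beads (greedy farthest-point selection, seeded).  Defaults —
60 arms (one per chain) of 12 beads, 9.5 Å spacing, 8 Å bead radius —
were set so that (a) arms contribute ≈40% of the armed maximum dimension
(≈480 Å armed vs ≈293 Å core), the proportion reported for the
full-length assemblies, and (b) the arm *mass* fraction (~43% of the
scattering weight) approaches the roughly-half-of-total that the
flexible regions represent in the full-length chains, so that the p(r)
tail carries realistic weight.  Arms are self-avoiding only step-to-step
(they are disordered in reality; full excluded volume would buy nothing
at this resolution).

Mass bookkeeping.  The per-chain masses shipped as
`SUBUNIT_MASSES_TABLE1` solve the printed core totals exactly
(60·m_E2 = 3,741,780 Da and 48·m_E2 + 12·m_E3BP = 3,551,100 Da giving
m_E2 = 62,363 Da, m_E3BP = 46,473 Da; the truncated total 1,671,348 Da
split evenly across 60 chains, since the individual truncated chain
masses are not resolved by the available data).  The published
monomer-level numbers are not mutually consistent to better than a few
percent, so masses are always explicit inputs; the package never bakes
in a reconciliation.

## Scattering

Debye curves.  I(q) = Σᵢⱼ fᵢ(q)fⱼ(q) sin(qrᵢⱼ)/(qrᵢⱼ) with fᵢ the
uniform-sphere amplitude times weight × volume (point-scatterer mode
available).  The q → 0 limit is analytic; the pair sum is chunked over q
to bound memory.  The curve is exactly invariant under rigid motion.

Guinier analysis.  The fit window is the largest low-q stretch with
q·Rg ≤ 1.3 (the standard validity cutoff), iterated to self-consistency.
By default the regression of ln I on q² carries an additional q⁴ term
and Rg is taken from the q² coefficient: a purely linear fit on a
qRg ≤ 1.3 window overestimates Rg by 2–2.5% for compact hollow shapes
(the ln I curvature is systematic, not noise), while the second-order
fit is unbiased to <0.2% on all fixture shapes and exact for a true
Guinier exponential.  `curvature_correction=False` restores the textbook
linear fit.  Curves whose low-q intensity rises with q raise an
aggregation error rather than returning a meaningless Rg.

p(r) and IFT.  The direct pair-distance histogram uses left-closed bins
and weights wᵢVᵢwⱼVⱼ (point mode; a sampled-sphere mode approximates the
bead-pair kernel with deterministic quasi-uniform interior points).  The
IFT solves I(q) = 4π∫p(r)sinc(qr)dr on an n_r-point trapezoid grid by
bounded-variable least squares with p(0) = p(Dmax) = 0, non-negativity,
and a second-difference curvature penalty of weight λ (default 1e-3)
scaled by the design-matrix norm so λ is dimensionless.  Misfit is
monotone non-decreasing in λ.

Dmax estimation.  Candidates (default 1.6–5 × Guinier Rg) are scanned
at fixed n_r; the estimate is the smallest candidate whose misfit is
within a documented tolerance factor (1.05) of the best.  n_r is held
fixed across candidates deliberately: with a fixed grid-point count the
misfit has a clear minimum near the true dimension, whereas a fixed
grid *spacing* lets larger Dmax values fit monotonically better and
defeats the parsimony rule.  A quality warning fires when undersized
candidates do not visibly degrade the fit (no plateau contrast).

NSD superposition.  NSD² = ½[⟨minⱼ|aᵢ−bⱼ|²⟩/d_b² + ⟨minᵢ|bⱼ−aᵢ|²⟩/d_a²]
with d the mean nearest-neighbour spacing of each model.  Orientation
search: centroid alignment, then candidate rotations (identity,
principal-axis alignments, seeded quasi-random grid), each polished by
iterative-closest-point Kabsch updates.  The raw NSD landscape is only
piecewise smooth and its value ranks proximity poorly, so every
candidate is polished by default (ICP is cheap at bead-model sizes);
gradient descent on the metric itself stalls in local minima.  Exact
recovery of an arbitrary rotation needs a grid dense enough to land in
an ICP basin (~0.3 rad); for the 60-bead core ≈500 orientations suffice.

## Hydrodynamics

Constants: N_A = 6.02214076e23 mol⁻¹, k_B = 1.380649e-16 erg/K; water at
20 °C ρ = 0.99823 g/mL, η = 1.002 cP.  Internal computation is cgs; all
interfaces use Å, Da, S, cm²/s.

The Svedberg set: f = M(1−v̄ρ)/(N_A·s); R₀ = (3Mv̄/4πN_A)^⅓;
f₀ = 6πηR₀; Rs = f/6πη; Ds = 2Rs; Dt = k_BT/f.  Standardization uses
s20,w = s_obs·(η_exp/η_20,w)·((1−v̄ρ)_20,w/(1−v̄ρ)_exp).  Infinite-
dilution extrapolation is a weighted linear fit of s on c (the 1/s form
is available behind a flag); two points give the exact line with
infinite standard error.

Bead friction.  The supermatrix method builds the 3N×3N
Rotne–Prager–Yamakawa mobility matrix (unequal radii supported), solves
for forces under unit uniform velocity and averages the total force over
the three axes.  Overlapping beads are uniformly shrunk to the largest
non-overlapping scale (with a warning) because the plain RPY tensor
assumes non-overlap; a reject policy is available.  The Kirkwood method
is the orientation-averaged double sum (f = N²/H with
H = Tr ΣᵢⱼMᵢⱼ/3), typically within ~10% of the supermatrix.
Rotation–translation coupling is neglected (no centre-of-resistance
search) — a ≤ few-percent bias for near-spherical assemblies like these.

Coarse-graining lays a cubic grid over the bounding box, collapses each
occupied cell to a bead at the weighted centroid with volume
proportional to the cell mass, and sets radii so the total bead volume
equals the anhydrous particle volume M·v̄/N_A exactly.

Hydration.  Computed bead-model sedimentation coefficients are anhydrous
by construction; they are converted with F = (v̄/(v̄+δ₁v₁⁰))^⅓.  The
default hydration δ₁ = 0.4 g water/g protein (F ≈ 0.87 at v̄ ≈ 0.745) is
used because bead-model programs "see" only surface hydration — solvent
in the hollow centre and open faces does not add friction — so the
appropriate δ₁ is far below what the frictional ratio alone would
suggest.

## Sedimentation equilibrium

signal(r) = baseline + Σᵢ aᵢ exp[σᵢ(r²−r_ref²)/2] with
σᵢ = Mᵢ(1−v̄ρ)ω²/RT.  Fitting is nonlinear least squares over baseline
plus per-species (amplitude, mass) with bounds (amplitudes ≥ 0, masses
within 10²–10⁹ Da); the first species is seeded from the log-linear
slope of the upper third of the profile, a second species at 2× and 4×
that mass.  The global fit shares masses across loading concentrations
with per-dataset amplitudes and baselines (interference offsets are
arbitrary).  Mw⁰ comes from a linear fit of 1/M_app on c with
first-order error propagation of the intercept.  Bottom-of-cell material
and approach-to-equilibrium effects are outside the model: profiles are
treated as at equilibrium.  Discrete species only; no mass-action
self-association models — trace aggregates are represented as a second
discrete species, and model comparison reports residuals without a hard
accept/reject rule.

Default simulation conditions mirror a long-column low-speed run on a
megadalton particle: 3000 rpm, 4 °C, 6.8–7.25 cm radial window, 80
points, Gaussian optical noise 0.005 signal units on ~0.3-unit loading
amplitudes.

## Chemical unfolding

Linear-extrapolation two-state model: ΔG(c) = ΔG⁰ − m·c,
fU = 1/(1+exp(ΔG/RT)), y = (1−fU)(aN+bN·c) + fU(aU+bU·c);
R = 8.314 J/mol·K, T = 298.15 K by default.  The six-parameter fit
multi-starts on the midpoint across the concentration window; standard
errors come from the Gauss–Newton covariance.  Cm = ΔG⁰/m is an exact
identity of the returned parameters.  Percent-change normalization uses
fitted linear baselines by default (endpoint mode available) and reports
out-of-range values without clamping.  Emission spectra yield a
parabolic-refined peak wavelength (multi-modal spectra flagged) and an
always-defined barycentric mean wavelength.

The published stability numbers are used as *fixture parameters* for
recovery tests — (ΔG⁰, Cm) = (17.0 kJ/mol, 2.70 M), (23.6, 3.19),
(11.0, 2.88) for the full-length mixed, E2-only and truncated cores —
not as quantities re-derivable from raw spectra, which are unavailable.
The implied m-values differ per construct and are used as-is.
Multimeric linkage (concentration-dependent stability of a 60-mer) is
deliberately ignored, matching the monomolecular-style reporting of the
source values; fitted ΔG⁰ should be read accordingly.

## What the synthetic tests show — and what they do not

The generator emulates architecture (20 vertex trimers, hollow centre,
open or occupied faces, flexible arms with realistic mass and length),
1D equilibrium profiles with Gaussian optical noise, and two-state
unfolding signals with linear baselines.  It does not emulate:
instrument smearing or beam geometry, concentration-dependent
interparticle interference, the "breathing" size heterogeneity of real
cores, proteolytic degradation during long runs, radial dilution or
bottom-of-cell buildup in the centrifuge, or unfolding intermediates
(trimeric species) beyond the two-state approximation.  Passing tests
therefore demonstrate that the analysis chain is internally consistent
and recovers known ground truth from data of the stated form — not that
it would be unbiased against every artefact of real beamline or AUC
data.

Known quantitative gaps, kept visible rather than tuned away: the
hydration-corrected sedimentation coefficient of the default
truncated-core model computes ≈24 S against the experimental 27.5 S
(−13%; within the 15% band expected when the true reconstructed envelope
is replaced by a regular synthetic one), and the single-bead-per-monomer
core is smoother than a real protein surface, which lowers its friction
slightly.

## Numerical choices and degenerate inputs

* Histograms use left-closed bins; r grids include both endpoints.
* A single bead is a valid model everywhere (its p(r) is a point mass
  at r = 0 in point mode; its friction is Stokes' law exactly).
* Zero-arm specs return the input model object unchanged.
* Buoyancy (1−v̄ρ) ≤ 0 raises a dedicated error in every route that
  would otherwise divide by or take the sign of it.
* Two-point linear fits return the exact line with infinite standard
  error instead of a spurious covariance.
* All stochastic stages (substitution placement, arm growth, simulated
  noise) draw from explicit integer seeds; the pipeline refuses to run
  without one, and its JSON report is byte-identical across reruns.
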