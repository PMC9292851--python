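# Methods

`mbrtplan` implements robust direct aperture optimization (DAO) for
mixed-beam radiotherapy (MBRT) — combined intensity-modulated 6 MV photon
beams and intensity/energy-modulated electron beams (6–22 MeV), both
collimated by the photon MLC, electrons at shortened SSD — at desk scale:
synthetic phantoms and analytic dose kernels replace CT data and Monte
Carlo transport, while the optimizer itself is implemented in full.

## Phantom and structures

The synthetic case emulates a cranial/head-and-neck geometry: an
ellipsoidal body contour (default semi-axes 80 × 90 × 92 mm on a 48³ grid
at 4 mm isotropic spacing), a spherical CTV of 15 mm radius centered 20 mm
below the anterior surface (shallow enough for clinical electron ranges), a
2–6 mm bony shell (relative density 1.5) under the skin, three spherical
OARs at graded distance from the CTV (abutting, near, distant), and a
normal-tissue structure holding everything else.  Air is assigned density
0.001 so depth integrals never divide by zero.  Margin operations
(CTV→PTV expansion, PRV generation, body cropping) use the Euclidean
distance transform in millimetres, which preserves isotropic margin
semantics under anisotropic spacing.  Masks of analytic shapes are
voxelized by voxel-center inclusion.

What the phantom does *not* emulate: real contours (irregular targets
wrapping around OARs), density heterogeneity beyond a single bone shell,
couch/immobilization hardware, and CT noise.  Passing tests on this phantom
demonstrate the optimizer's behaviour (robustness trade-offs, modality
selection), not clinical dosimetric accuracy.

## Dose engines

Beamlets are 5 × 5 mm² at the isocenter plane (SAD 1000 mm).  Both engines
share one geometry path; doses are linear in aperture weight and
non-negative.

* **Photon (6 MV)**: D = PDD(d) · (SAD/(SAD+z))² · Gᵤ·Gᵥ, with a quadratic
  build-up to d_max = 15 mm followed by exponential attenuation
  (μ_eff = 0.005/mm), and a lateral profile equal to the difference of
  error functions of a depth-broadened Gaussian (σ = 3 mm + 0.02·d) over
  the 5 mm beamlet width.  d is the radiological depth (density line
  integral, ray step = half the minimum voxel spacing).
* **Electron (6–22 MeV)**: plateau to 0.8·R_p, linear falloff to zero at
  the practical range R_p = E/2 cm water-equivalent, plus a 2%
  bremsstrahlung tail for E ≥ 15 MeV; broader lateral spread
  (σ = 4 mm + 0.1·d) modelling in-air and in-tissue scatter at shortened
  SSD; no inverse-square term.  Beam divergence for electron fields is
  neglected; the configured SSD is provenance only.

These kernels preserve the dosimetric contrast the optimizer exploits —
sharp photon penumbra versus finite electron range with broad penumbra —
without claiming dosimetric accuracy.

**Setup-error scenarios.** A scenario is a systematic patient translation
`s`; the default robust set is nominal ± 5 mm along LR, AP and SI (7
scenarios, equal importance 1/7).  A shift is applied under the
isocenter-shift (static dose cloud) approximation: the scenario dose is
the nominal dose field evaluated at translated points, D_s(r) = D_0(r+s)
exactly.  This is a deliberate modelling choice: dose deformation by
surface curvature or heterogeneity under a shift (which a per-scenario
transport recalculation would capture) is not modelled, making translation
consistency of the scenario dose exact by construction.

**Voxel sampling.** Objectives are evaluated on every voxel of every
non-body structure; the normal-tissue mask is subsampled by a fixed stride
(default 3 per axis, recorded in the run summary) for tractability.
Dose-influence matrices (one CSC matrix per field and scenario) drop
entries below 10⁻⁴ of each beamlet's maximum before sparse storage.

## Objective

A weighted sum of one-sided quadratic penalties with per-structure
voxel-count normalization — the de-facto standard in DAO:

F(D) = Σ_t (w_t/|V_t|) Σ_{i∈A_t} (D_i − d_t)²,

with active sets for minimum-dose, maximum-dose and dose-volume terms (the
hottest allowed fraction is exempted by DVH sorting, stable order), and
w·(mean−d)₊² for mean-dose terms.  The robust objective is the
importance-weighted expectation of F over scenarios; with a nominal-only
set it reduces bit-for-bit to the plain objective (one shared code path).
Dose-volume active sets are frozen during each weight-optimization pass and
refreshed between passes, keeping each inner problem smooth, convex and
deterministic.

The default term template encodes the clinical priority ordering: target
coverage outranks OAR sparing.  Target window 0.98–1.05 of prescription
at weights 100/50; per-OAR mean/max tolerances graded by the OAR's gap to
the target, computed from the mask geometry (gap < 5 mm: 0.35/0.95 of
prescription; 5–20 mm: 0.20/0.70; ≥ 20 mm: 0.12/0.50; weight 8 each) —
an organ abutting a full-dose target cannot be held to a low mean dose
without sacrificing coverage, so nearby organs get lenient, achievable
levels; loose normal-tissue caps (max 0.80, mean 0.06 of prescription).
All values are configuration, not claims.

## Hybrid DAO loop

Each outer iteration: (1) price every beamlet at the current pool dose
(price = gradient of the robust objective with respect to an aperture
weight at zero); (2) per field, build the most promising aperture — per
MLC row the contiguous interval of minimum summed price (Kadane), rows
with non-negative best interval closed; no inter-row connectivity or
interdigitation constraints; (3) add each candidate to a copy of the pool
and run deterministic weight optimization (projected L-BFGS-B on w ≥ 0
with analytic gradients), zero-weight pruning (ε = 10⁻⁸ of the maximum
weight), simulated annealing over shapes and weights, and a second weight
optimization; (4) keep the candidate pool with the lowest robust objective
(ties break toward the earlier field in configuration order).  The loop
stops at the aperture budget or when no field offers a negative price
(logged as convergence).  Photon and electron fields run through the
identical code path, keyed only by their dose-influence columns.

Simulated annealing moves: shift one leaf edge by one column (possibly
opening a closed row by one beamlet or closing a one-beamlet row), or
multiply one weight by exp(N(0, σ)).  Metropolis acceptance with geometric
cooling (default α = 0.95, σ = 0.1); T₀ defaults to half the |ΔF| of a
calibration move.  The best-visited state is returned, so the objective
never increases.  Seeds fully determine the trajectory: each candidate's
RNG is derived from (config seed, iteration, field index), so the outcome
is independent of how many other candidates exist.

The logged objective after every outer iteration is non-increasing: weight
optimization keeps the incumbent if the solver fails to improve, annealing
returns the best-visited state, and adding a candidate at zero weight is
always feasible.

## Finalization, normalization, evaluation

The final aperture dose adds MLC transmission through closed-but-in-jaw
beamlets (1.5% for photon fields; 0 for electron apertures, configurable),
which recreates the structural discrepancy between beamlet-sum and final
dose that the final robust weight re-optimization corrects.  Plans are then
normalized by a single MU scale factor so the nominal-scenario D_50% (or
D_95%) of the prescription structure equals the prescription level
(default 60 Gy to the CTV in robust mode, to the PTV in PTV mode);
normalization is exactly linear and idempotent.

Point metrics (D_x%, V_x, D_mean, HI_95/107 = V95% − V107%) are computed
on raw voxel doses; D_x% uses the nearest-rank quantile — exact and
bin-free; binned cumulative DVHs are for plotting only.  Scenario spread is
reported as mean ± population SD over all scenarios including the nominal.
Gamma analysis follows TG-218 defaults: global normalization to the
reference maximum, 10% low-dose threshold excluded from the passing-rate
denominator, the continuous minimum approximated on a 0.5 mm bilinear
resampling of the evaluated plane within a 3×DTA search radius, and the
calculation as the default reference (configurable).

## Planning modes

*Robust*: prescription and optimization on the CTV, scenario expectation
over the 7-scenario set, normal tissue = body minus CTV and OARs, no PRVs.
*PTV-based*: CTV + 5 mm margin cropped 3 mm from the body surface, PRVs =
OAR + 5 mm, optimization on the nominal scenario only (deleting the error
scenario matrices provably does not change the optimized weights), normal
tissue = body minus PTV and OARs.  Both modes share the identical beam
arrangement and are evaluated on all seven scenarios post hoc.

## Numerical choices and problem sizes

The default study case uses 7 photon fields plus 3 electron directions × 6
energies (25 fields), a 20-aperture budget, normal-tissue stride 3
(≈ 2000 sampled voxels), and a short annealing schedule (10 moves × 10
temperatures) per candidate — the package's scaled-down working point for
the robust-vs-PTV comparison; all knobs are configuration.  The aperture
budget follows an aperture-count convergence run (the standard protocol):
on this case the robust objective improves by less than 0.5% per added
aperture beyond roughly 20 apertures.  Weight
optimization uses ftol 10⁻¹⁶ / projected-gradient tolerance 10⁻⁸ by
default; KKT conditions are verified in tests at 10⁻⁶.  Degenerate inputs
are defined: an empty aperture pool has the zero-dose objective; a fully
closed candidate is skipped; empty normalization structures raise.

## Known limitations

Static-dose-cloud scenario model (above); no random (non-systematic) error
sampling; no leaf-end/tongue-and-groove or interdigitation physics; no
delivery-time or MU-constraint modelling; electron divergence neglected;
single-interval-per-row apertures (annealing cannot split a row into two
openings); no biological objectives; no minimax robust mode (stochastic
expectation only).

A consequence of the static-dose-cloud model worth stating explicitly:
under rigid dose translation, a PTV margin equal to the shift magnitude
retains CTV coverage *by construction* — the classical margin argument
holds exactly.  On this phantom the robust plan's advantage therefore
shows up as per-scenario dominance of the homogeneity index, a higher HI
mean, substantially lower OAR mean doses and lower normal-tissue V10%,
rather than as a large gap in the HI scenario-to-scenario spread; models
that recompute transport per scenario (capturing dose deformation at
surfaces and heterogeneities) additionally degrade PTV-based plans and
widen that spread.  With only ~230 CTV voxels the homogeneity index is
also quantized in steps of ~0.44 percentage points, which makes spread
statistics coarse.
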