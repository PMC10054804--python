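# Methods

`aerodep` is a desk-scale model of micro-aerosol transport in the human
upper airway: prescribed analytic duct flows, Lagrangian particle
tracking with slip-corrected Stokes drag, and deposition bookkeeping.
This note records the model, its assumptions, the numerical choices, and
what the synthetic test cases do and do not demonstrate.

## Particle model

Particles are rigid spheres of density ρ_p (default 1000 kg/m³),
one-way coupled to the carrier gas (valid below volume fractions of
~10⁻⁶; no particle–particle interaction, no feedback on the flow, no
resuspension).  The force balance per particle is drag plus gravity:

    dv/dt = f/τ_p (u − v) + g,     f = C_d Re_p / 24,
    τ_p = ρ_p d_p² C_c / (18 μ),   Re_p = ρ d_p |u − v| / μ.

The drag group *f* equals 1 in the Stokes regime (Re_p < 1, including
the Re_p = 0 singularity of C_d itself, which is why the code exposes
`drag_factor` and never divides 24 by zero) and 1 + 0.15 Re_p^0.687 for
1 ≤ Re_p ≤ 10³.  As printed, the piecewise law jumps from f = 1 to
f = 1.15 at Re_p = 1; it is implemented and tested with that jump rather
than smoothed, and requests beyond Re_p = 10³ raise (outside the
correlation's validity).  The slip correction uses the two-parameter
exponential form with the mean free path λ; defaults are air at 20 °C
(ρ = 1.204 kg/m³, μ = 1.81×10⁻⁵ Pa·s, λ = 65 nm), overridable in the
run configuration.  Brownian diffusion, lift, thermophoresis and
hygroscopic growth are deliberately absent from the force balance.

The Stokes number is defined as Stk = τ_p U_mean / D with the bulk mean
velocity and tube diameter as references — the convention of the
bend-deposition literature; the bend oracle uses the same convention.

## Flow fields

No 3D flow is solved.  Fields are analytic and satisfy continuity
exactly:

* uniform field (settling and harness tests), laminar Poiseuille pipe;
* the 90° bend: velocity tangent to the circular-arc centerline, plug
  (default) or parabolic cross-profile.  No secondary (Dean) flow: the
  benchmark validates impaction deposition, and both the working run and
  its fine-step oracle see the same field;
* the airway streamtube field: axial speed U(s) = Q_branch/A(s) (half
  the flow per nostril, the sum past the merge), with the radial
  component u_r = U (dr/ds)(d/r)/h implied by the wall taper so that
  inertia-free tracers follow the contracting/expanding streamtube
  exactly.  The factor h is the bend metric (arc length per unit
  centerline s at the particle's in-plane radius, h = 1 on straight
  segments).  Without h, tracers on the outer side of a tapering bend
  acquire a spurious wall-ward drift of order (dr/ds)·(d/R_c) per unit
  length — this was measurable as a false ~4 % tracer deposition before
  the correction and ~0.1–0.5 % after (the remainder is genuine
  inertial drift at the bends plus near-wall injection).

Turbulence enters only through the pointwise SST low-Reynolds closure
coefficients α*(Re_t), α(Re_t) and μ_t = α*ρk/ω.  The printed form of
the α relation is ambiguous about whether α* multiplies or divides; the
division form — the standard low-Reynolds k-ω correction, with the same
Re_t → ∞ limit of 0.52 either way — is implemented.  The airway field
carries a flat k = (3/2)(I·U)² with intensity I = 5 % only at stations
whose duct Reynolds number ρUD/μ exceeds the pipe-transition threshold
2300, with ω = √k/(0.07 D) from a mixing-length estimate.  On the
default geometry every station is laminar at 5–15 L/min (k ≡ 0) and the
constrictions transition at 30–45 L/min, which is the regime structure
the model is meant to emulate.

## Geometry

The synthetic airway is a union of tubes around piecewise
straight/arc centerlines with a C¹ radius profile (monotone cubic
through the radius knots — a slope kink in r(s) would act as an
artificial particle-capture wedge at the knot):
two mirror-image nostril branches (3.5 cm vertical vestibule + valve,
1.5 cm-radius bend posterior, turbinate passage, bend down) merging at
the nasopharynx 11 cm from the nostrils into a 14 cm vertical trunk
(nasopharynx, oropharynx, larynx with glottal contraction, trachea);
25 cm in total.  Regions tile the centerline without gaps; analysis
planes sit at 0.53 cm then every 1.11 cm (nasal segment) and 0.822 cm
below the nasopharynx roof then every 1.32 cm (pharyngeal segment).
The trunk entrance radius always covers the two branch-exit circles, so
the interior is simply connected across the merge; in the short overlap
a point belongs to the component in which it sits deepest.

Cross-sections are circular — a stated idealization (real nasal
passages are slit-like); the area series, not the section shape, carries
the one-dimensional physics.  Defaults make the nasal valve the
narrowest single passage (r = 3.6 mm per side) and the glottis the
smallest combined section (0.69 cm², vs 0.80 cm² for both valves), so
the two "dramatic change" sites of real upper airways — nasal valve and
glottis — are both present, the laryngeal jet forms at the glottis, and
the posterior segment dominates the total pressure drop at rest, as in
vivo.  The glottal radius (4.7 mm) is the largest value that keeps the
glottis the dominant constriction while remaining laminar at 15 L/min
(Re ≈ 2250 < 2300).  An optional multiplicative jitter on the radius
knots generates geometry variants; the jitter never breaks the
merge-coverage invariant (the nasopharynx radius is floored at the
required coverage).

The validation bend is a 90° arc of curvature ratio (bend centerline
radius / tube radius) 5.6 — tube radius 4 mm by default — with straight
extensions of four tube radii.

## Tracking numerics

Default scheme: *semi-analytic exponential*.  Over one step the drag
coefficient group f/τ_p and the sampled fluid velocity are frozen and
the then-linear ODE is integrated exactly (implemented with `expm1` for
small exponents).  The scheme is A-stable, so the step size is set by
the geometry, not by τ_p: dt = min(dt_max, 0.2 r_local/|v|), with
dt_max = 1 ms.  The frozen coefficients are refreshed at the step
midpoint (sample at the half-step position, then redo the full step),
which makes the advection second-order in field curvature; without the
refresh, chord-stepping through bends drifts tracers outward by
≈ (π/4)·(dt |v|) per quarter turn, enough to corrupt the tracer limit of
the bend benchmark.  The geometric step is additionally refined by the
factor 1 + 4|dr/ds| + 6 r/R_c where the wall tapers steeply or the
centerline bends, so local features (valve and glottal tapers, the
turbinate bends) are resolved by many chords; step-halving checks on
1 µm tracers show the surviving sub-percent deposition is converged,
i.e. genuine near-wall impaction rather than discretization.  The rk4 scheme (classical, velocity resampled at
stage positions) is the cross-check; being explicit it additionally
requires dt ≤ 0.2 τ_p, which is why it is not the default for micrometre
particles (τ_p ~ 10⁻⁶–10⁻⁴ s would force ~10⁵ steps per particle).
The geometric cap also bounds every chord to a fifth of the local duct
radius, which is what keeps endpoint wall-crossing detection (ensemble
path) reliable; the scalar path additionally probes interior points of
each chord.  Wall contact is trap-on-first-contact (the standard
discrete-phase assumption), located by bisection to 10⁻⁹ m; the fate
records the region and arc length at the hit.  Particles crossing the
trachea outlet plane are `escaped` (lung delivery); particles exceeding
max_time = 10 s (or a step ceiling) are `time_expired` and counted as
*unresolved* — never silently folded into deposition or escape.

Ensembles advance as numpy arrays with per-particle adaptive dt, which
is what makes 10⁴-particle cells affordable (seconds per cell).  The
scalar `track` is the readable reference implementation of the same
update.

Injection: uniform over the inlet disk(s) by default (flow-weighted
parabolic sampling available), initial velocity matched to the inlet
flow, particles split round-robin across nostrils (counts differ by at
most one).  Per-particle RNG substreams are spawned from the run seed
(`SeedSequence`), so fate tables are bit-identical across re-runs and
independent of how many particles remain active at any step.

Eddy-interaction dispersion: fluctuation components are Gaussian with
σ = √(2k/3); the eddy lifetime is τ_e = 0.15 k/ε with ε = β*kω and
β* = 0.09 (the standard closure constant); the interaction time is
min(τ_e, eddy crossing time L_e/|u−v|) with L_e = τ_e σ.  Where k = 0
the fluctuation is exactly zero and no random numbers are consumed, so
laminar runs are bit-identical with dispersion on or off.  A particle
entering a turbulent zone starts a fresh eddy immediately.

Gravity defaults to −z, the trachea axis, at 9.81 m/s² (configurable).
The bend benchmark runs with gravity off: it isolates inertial
impaction, as the validation experiments it mirrors were oriented to do.

## 1D station model

The quasi-1D module is an emulation layer (the corresponding quantities
in a CFD study come from the 3D solution): mean speed from continuity,
gauge pressure from an extended Bernoulli balance with Darcy–Weisbach
friction (f = 64/Re laminar, 0.316 Re^−1/4 past 2300) and minor losses
charged once per abrupt area feature — K = 0.5 for a contraction whose
overall ratio exceeds 1.3, Borda–Carnot K = (1 − A_small/A_big)² for an
expansion — on the higher velocity head.  Charging per *feature* rather
than per station pair keeps the loss independent of station resolution.
Elevation head is neglected (air, centimetre heights).  On a uniform
laminar tube the model reduces to Hagen–Poiseuille within discretization
error (< 1 %).

## What the synthetic cases show — and what they do not

The bend benchmark checks the impaction physics end to end: DE(Stk)
rises monotonically from ~0 (tracers follow the turning flow) to 1
(stopping distance exceeds the bore), cross-checked against a 20×
finer-timestep oracle on the same field.  The airway sweep reproduces
the qualitative dosimetry structure: deposition non-decreasing in both
particle size and flow rate, fine aerosols (≤3 µm) reaching the lungs
almost entirely, coarse aerosols (16–30 µm) filtered in the nasal
passages with a growing anterior share.  None of this calibrates to a
specific patient: the synthetic geometry has circular sections, no
secondary flows, and plug axial profiles, so region-resolved
percentages are indicative only and patient-specific values (which
depend on CT geometry) are out of scope.  Problem sizes used by the
shipped studies — 20 Stokes-number points × 2000 particles for the bend,
six sizes × five flow rates × 10⁴ particles for the sweep — were chosen
so that Monte-Carlo standard errors are small against the effects being
demonstrated.

## Known limitations

* No Dean vortices in the bend and no secondary flows in the airway;
  deposition from swirl-driven transport is absent.
* The turbulence indicator is a threshold proxy, not a transition model;
  k is flat across a station.
* Circular cross-sections underestimate near-wall surface area relative
  to slit-like nasal passages, hence diffusional/interception effects
  (absent anyway) and per-region splits differ from anatomical truth.
* The drag correlation's printed discontinuity at Re_p = 1 introduces a
  (physically negligible) kink in particle response around slip
  velocities where Re_p ≈ 1.
* `time_expired` fates are possible for neutrally settling particles in
  near-stagnant corners; they are reported as unresolved rather than
  guessed.
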