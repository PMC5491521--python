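# Methods

## Model

A rigid sphere of radius *a* (the adhering particle) moves in a viscous
fluid above a flat substratum at *z* = 0.  `n_tethers_total` anchor
directions are placed quasi-uniformly on the sphere with a Fibonacci spiral
lattice (deterministic for a given count; for 256 anchors the lattice
centroid norm is < 2e-4 and the minimum pairwise angle exceeds 1.5x the
ideal equal-area angle).  Each tether is a pull-only Hookean spring of rest
length L₀ and stiffness k connecting its anchor tip (rotation is neglected,
so tips translate rigidly with the center) to a fixed attachment point on
the plane.  Bound tethers exert |F| = k·max(0, d − L₀) toward their
attachment point; slack tethers exert nothing.  A compression branch
(two-sided spring) exists behind `allow_compression` but is off by default:
polymeric tethers buckle rather than push.

The center obeys the overdamped Langevin equation, integrated by
Euler–Maruyama:

    Δr = (ΣF_tether / γ) Δt + ξ,   γ = 6πηa,   ξ_i ~ N(0, 2 (k_BT/γ) Δt)

Gravity and buoyancy are omitted (negligible for a near-density-matched
micron sphere), and the sphere is reflected at *z* = *a* (non-penetration).
The momentum relaxation time m/γ of a micron particle (~1e-7 s at the
shipped drag) is far below every observable timescale, so inertia is
irrelevant to the physics; an inertial integrator (Grønbech-Jensen/Farago
Langevin velocity-Verlet, exact free diffusion at finite Δt) is provided
behind `integrator="inertial"` for fidelity checks.

Binding kinetics, applied once per step after the position update,
detachments first and then attachments in ascending tether index:

* a bound tether detaches when its elastic force **strictly exceeds** the
  tether adhesion force F_adh (a tether loaded exactly at threshold stays
  bound);
* an unbound tether whose anchor tip height is ≤ L₀ attaches at the
  perpendicular projection of its tip onto the plane (deterministically by
  default; `attach_probability` < 1 makes attachment Bernoulli per step).

Initialization rests the sphere on the plane (center at *z* = *a*) and binds
the `n_tethers_initial_bound` anchors closest to the surface (ties broken by
index) at their tip projections; a rest length too short to reach that many
anchors is a configuration error.  With the default geometry more anchors
are within reach at *z* = *a* than the 12 initially bound, so the bound
count rises over the first moments of a run and — with detachment inhibited
— is non-decreasing, mirroring the recruitment of additional tethers by an
adhering cell.

Frames are sampled at the integration step nearest each multiple of the
frame interval; `floor(duration × frame_rate)` frames in total (33 s at
60 Hz → 1980 frames; setting `duration=2000/60` reproduces the 2000-frame
convention).  One seeded generator drives each run; trajectories are
bit-reproducible for a fixed (config, seed).

## Default parameters and calibration

| parameter | default | why |
|---|---|---|
| particle diameter | 1.0 µm | coccal cell scale |
| particle mass | density-matched | gravity/buoyancy neglected anyway |
| temperature | 298 K | room temperature |
| tether spring constant k | 1.2e-5 N/m | mean value measured for adhering bacteria by vibration spectroscopy |
| tethers (total / initially bound) | 256 / 12 | model convention for this system |
| tether rest length L₀ | 150 nm | calibrated, see below; fibril/EPS strands are 0.1–0.3 µm |
| effective fluid viscosity η | 0.45 Pa·s | calibrated, see below |
| tether adhesion force F_adh | 3.8e-13 N | calibrated sweep midpoint; +inf = non-detachable |
| force sweep | (1, 2, 3.8, 8, 20)e-13 N | spans free-creep → pinned regimes |
| timestep | 2e-4 s | ≪ tether relaxation γ/k ≈ 0.35 s; per-step noise 0.8 nm resolves the ~30 nm rupture scale |

Not every physical input of the model is independently measurable, so the
free geometry/medium parameters were calibrated **once** against the four
published simulation observables for this system — no-detachment vibration
amplitude 33 nm, long-time exponent α ≈ 0.15 with dynamic tethers, α ≈ 0
with detachment inhibited, initial α ≈ 1 — and frozen; they are ordinary
config fields and every value is overridable.

Two calibration points deserve explanation:

* **Effective viscosity.**  With bulk-water drag, a 1 µm sphere confined to
  σ ≈ 33 nm decorrelates in ~2 ms: its track would be fully plateaued at the
  first 60 Hz lag, contradicting both the measured autocorrelation
  half-times of adhering bacteria (0.02–0.4 s) and the diffusive initial MSD
  regime.  Those measurements imply an effective friction 10²–10³ times the
  Stokes value — physically, unresolved near-wall lubrication and
  tether-internal/EPS friction.  The model folds this into a single
  effective viscosity; η = 0.45 Pa·s reproduces tenth-of-second positional
  relaxation at the 33 nm amplitude.  Tests of bulk transport (Stokes–
  Einstein, equipartition) set η = 1e-3 Pa·s explicitly.
* **Rest length.**  At the resting height, anchor tip heights reach ~45 nm
  for the 12th-closest anchor of 256, so L₀ must exceed ≈ 45 nm for 12 bound
  tethers; amplitude grows slowly with L₀ (slack width and the
  tension-mediated lateral "pendulum" stiffness both scale with it), and
  L₀ = 150 nm lands the no-detachment amplitude at 33 nm.

The relaxation time of the confined motion is pinned by the amplitude
through τ = γσ²/k_BT ≈ 1.1 s at these defaults: a single lever (η) controls
both how diffusive the first half second looks (wants τ large) and how many
independent long-lag samples a 33 s track holds (wants τ small).  The
shipped η sits at the crossing point where both long- and short-time
exponent checks hold on average; individual 6-particle ensembles scatter by
±0.1 in fitted α (see "statistical precision" below).

## Track statistics

* **Vibration amplitude** = mean of the per-axis population SDs about the
  track mean, minus a fixed-marker amplitude (linear subtraction, floored at
  0).  For circular position-maps this equals the single-axis SD.
* **Autocorrelation** uses the biased estimator
  R(h) = Σ x(n)x(n+h) / Σ x(n)², x mean-relative, computed on the
  x-coordinate (a `axis="y"` flag exists for anisotropy checks); |R(h)| ≤ 1
  by Cauchy–Schwarz.  The 50% time is the first R ≤ 0.5 crossing, linearly
  interpolated, +inf if never crossed.
* **MSD**: MSD(i) = (1/M) Σ_k |r(j_k+i) − r(j_k)|² over M = 10 starting
  frames spaced 100 apart, N = 1000 lags (16.7 s at 60 Hz), 2D positions;
  ensembles are pointwise means of per-track curves.  The printed form of
  this estimator carries an inner 1/N that only yields a function of lag
  time under this multi-start reading, which is the one implemented.
* **Power-law fit**: OLS on (log t, log MSD) within a window — log-log OLS
  weights all decades of lag equally, the standard choice in single-particle
  tracking.  α is reported for t > 1 s and t > 5 s (both conventions in
  use), and for the first 0.5 s as the initial-diffusion check; the window
  is always recorded in the fit object.
* **Cross-strain correlation**: OLS of amplitude on adhesion force with the
  two-tailed t-test on Pearson r (n − 2 d.o.f.).  The built-in eight-strain
  reference dataset gives r² = 0.718, p = 0.0079.

### Statistical precision of the exponent

With M = 10 starts, each lag of a single-track MSD carries only 10
displacement samples, and neighboring lags share starts, so fitted long-lag
exponents of 6-particle/33 s ensembles have an intrinsic seed-to-seed SD of
≈ 0.05–0.12 — even exactly plateaued Ornstein–Uhlenbeck tracks at matched
(σ, τ) give ensemble-fit α with SD 0.03–0.07 and a small positive mean bias
≈ +0.03.  Acceptance-level checks therefore average several independent
ensembles (12 in the test suite, 10 in `scripts/acceptance.py`), which
tightens the estimate of the expected exponent without touching any
tolerance.  A single ensemble's α should be quoted ±0.1.

## AFM force-distance analysis

Attractive forces are stored negative; metrics are reported as positive
magnitudes.  The baseline is the median force of the final 10% of retract
points and the noise SD is 1.4826×MAD of the same tail (the acquisition
never states its baseline convention, so a robust estimate is used).
Adhesion force is the magnitude of the most-negative baseline-subtracted
retract force.  Adhesion peaks are local minima found on a 5-sample
boxcar-smoothed trace with depth and prominence ≥ 3×noise SD (noise floor
1e-3 nN so noiseless synthetic curves retain a finite threshold), snapped to
the deepest raw sample nearby; smoothing suppresses single-sample noise
excursions (a bare 3σ threshold over ~500 samples would false-positive on
half of pure-noise curves) while rupture peaks, which sit on ramps many
samples wide, pass unchanged.  Rupture length is the separation where the
force last returns within threshold of baseline after the final peak — full
detachment of the entire bond.  Adhesion energy is the trapezoidal area of
the sub-baseline region of the retract curve from contact to the rupture
length, reported in J and k_BT.

The synthetic generator superposes parallel Hookean tethers engaging at
given offsets and snapping at given rupture forces, with optional Gaussian
noise, and returns an analytic ledger (per-tether rupture separations,
deepest total force, Σ F²/2k elastic energy) used as the round-trip oracle:
noiseless curves must reproduce peak count exactly, rupture length within
one or two sample spacings, and energy within 2%.

## What the synthetic generators do and do not emulate

The track generators (OU-confined, free diffusion, drift, white noise, with
5 nm measurement noise by default — the spatial resolution of
marker-corrected centroid tracking) reproduce the second-order statistics
that the analysis pipeline measures, which is what validating the pipeline
requires.  They do not emulate heavy-tailed displacement bursts from
discrete rupture events, drift of the experimental stage beyond a constant
marker, anisotropic position-maps, or frame-to-frame localization
correlation; passing tests on them therefore validates the estimators, not
the biological realism of any particular track.  Likewise the simulator
itself omits particle rotation (second-order for a center-of-mass observable
with short tethers), hydrodynamic wall corrections to drag, DLVO surface
forces, EPS production dynamics, and flagellar propulsion (non-motile
strains only).

## Numerical choices and degenerate inputs

* Euler–Maruyama stationary variance carries an O(kΔt/γ) bias; the
  equipartition oracle corrects it with the exact discrete-OU factor
  (1 − θ/2), θ = k_lat Δt/γ, and compares at 3 standard errors over 1e5
  near-independent samples against the finite-difference Hessian of the
  tether potential at the numerically minimized equilibrium.  The oracle
  configuration pre-tensions the bound tethers (attachments displaced
  radially outward) because projection-attached tethers are slack, giving a
  flat-bottomed, non-harmonic trap to which equipartition does not apply.
* Detachment uses a strict inequality; attachment uses tip height ≤ L₀.
* Zero-variance tracks: autocorrelation raises a data error (undefined
  normalization); amplitude returns 0.
* Power-law fits require ≥ 3 positive MSD values inside the window; a
  perfectly flat log-MSD fits α = 0 with r² conventionally 0.
* Seeds below 2³¹ are derived from a base seed via `SeedSequence`; the
  stepping kernel uses numba's NumPy-compatible MT19937.

## Known limitations

* The confinement at default geometry is a slack "box" with
  tension-mediated soft walls, not a harmonic trap; its heavy-tailed
  excursions make long-lag MSD estimates noisier than an OU model of equal
  amplitude.
* The effective-viscosity treatment lumps all unresolved friction into one
  scalar; it cannot capture frequency-dependent (viscoelastic) memory.
* Attachment is immediate and deterministic within reach; there is no bond
  maturation or attachment-rate physics beyond the optional per-step
  probability.
* AFM metrics assume a single approach/retract cycle per curve and do not
  fit worm-like-chain models to individual peaks.
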