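# Methods

This note documents the models, parameter choices and numerical
conventions behind `triaxmeg`, and what the synthetic studies can and
cannot show about real recordings.

## Sensor readout model

The OPM is modelled at the level of its demodulated response. For a
field *B* perpendicular to a beam, the photodetector signal at the
modulation frequency has amplitude proportional to the dispersive
Lorentzian r(B) = gain0·γBτ/(1+(γBτ)²). The constants:

| parameter | default | meaning |
|---|---|---|
| γ | 4.397×10¹⁰ rad s⁻¹ T⁻¹ | ⁸⁷Rb ground-state gyromagnetic ratio (≈7 Hz/nT) |
| τ | 3 ms | polarisation relaxation (coherence) time |
| f_mod | 1 kHz | modulation frequency |
| B₁ | 140 nT | modulation amplitude (sets the Bessel-factor argument ≈1) |
| gain0 | 1 (dimensionless) | lumped constant absorbing the equilibrium polarisation and the J₀·J₁ Bessel factors |
| noise | 13.5 / 9.9 / 14.9 fT/√Hz (x/y/z) | white output-noise densities of the emulated sensor |

The simulator synthesises both photodetector traces as superpositions of
the in-phase (y) and quadrature (x or z) responses, demodulates with
reference sinusoids at 0° and 90°, low-passes with a 4th-order
Butterworth at f_mod/5 applied forward–backward (zero phase; the lock-in
bandwidth is not prescribed by the physics, so a conventional value was
fixed once), and inverts the small-signal slope gain0·γτ. The two y
estimates are averaged with equal weights (no reason to prefer either
beam). White noise is added to the three outputs at the configured
densities; noisy simulations refuse to run without a seed.

Simplifications: the cell is a point (the beams' spatial offset is a
forward-model concern, below); no Bloch-equation dynamics, light shifts,
spin-exchange effects or closed-loop operation. At 100 pT the readout is
linear to ~0.02 % (γBτ ≈ 0.013), so the linear inversion is exact for
the field scales simulated here.

Crosstalk between sensors is handled as a static linear perturbation:
three test pulses measure the 3×3 axis response, and the software
correction is its inverse (rejected if the condition number exceeds
10⁶).

## Head and array geometry

Heads are concentric spheres: scalp radius = circumference/2π (58, 50,
47 cm for adult, 4-year-old, 2-year-old), brain radius 15, 10, 5 mm
smaller. Sensor arrays start from a 77-point golden-angle (Fibonacci)
lattice on the best-fit sphere, projected radially to the scalp with the
sensitive volume 6 mm above it. Points with polar angle beyond 115° are
removed as "underside" positions; on a sphere this keeps 55 of 77,
matching the ~50-sensor scale of a practical helmet. The exact retained
count is lattice-dependent and not treated as meaningful; where a
57-sensor array is needed (the adult coverage and forward-error
configurations) the cut is 118.5°. Source shells sit 5 mm beneath the
brain surface — for spherical brains the voxel-erosion construction
reduces exactly to radius shrinkage — with quasi-uniform spacing set by
the 4πr²/spacing² area estimate, and tangential frames (θ̂ₛ, φ̂ₛ) from
the best-fit sphere.

Coordinates are right-handed, metres, head-centred; polar angle from +z,
azimuth from +x; sample indices 0-based; all quantities SI except
spectral densities (fT/√Hz, factor 10¹⁵).

## Forward model

The conductor is the analytic homogeneous sphere (closed-form dipole
field including volume currents). This replaces a realistic single-shell
mesh correction deliberately: for the spherical synthetic heads used
throughout it is exact, mesh-free and fast. Its two structural
properties — radial dipoles are externally silent, and volume currents
contribute nothing to the radial field — are asserted in tests, and the
full field is cross-checked against an independent numerical oracle that
reconstructs the external field from the magnetic scalar potential
(radial integration of the primary-current radial component plus
numerical differentiation). Consequences carried through the analyses:
source reconstruction uses only the two tangential orientations, and
tangential-dipole silence is what creates the radial-array blind spots
the coverage study quantifies.

### Beam displacement

The two laser beams measure at slightly different points. With the cell
mounted stem-radial, the model evaluates beam 1 (carrying the θ and one
y channel) at the cell centre +0.65 mm along the radial axis and beam 2
(carrying the r and the other y channel) at the centre −0.65 mm along
the tangential θ axis; the φ (y) channel averages the two points. The
forward-error study compares lead-field columns with and without these
displaced evaluation points for tangential dipoles under the array
(polar angle ≤ 115°): the median column-norm error is ≈1.8 % at average
cortical depth (15 mm below the brain surface) and ≈2.4 % for shallow
sources (5 mm), on the adult sphere with 57 sensors and ~500 dipoles.
The intra-cell beam geometry is not fully constrained — a strictly
minimal-overlap construction separates the beam centroids by only
0.65 mm along the shared y axis and yields errors ≈3× smaller — so the
convention above (each beam offset along its own propagation axis) is a
documented modelling choice, and the error magnitudes should be read as
order-of-magnitude guidance for when displacement-aware forward models
become worthwhile.

## Synthetic datasets

*Phantom.* 25 triaxial slots quasi-uniform over the upper hemisphere of
a 5.5-cm sphere (6 mm standoff); a 2-µA·m dipole (2 V through 10 kΩ
across 1 cm) 3 cm deep in the upper-left octant, oriented along the
local azimuth; 7-Hz sinusoidal drive, 5 s at 1200 Hz. Placement error:
positions jittered by an isotropic Gaussian of 2 mm total rms and frames
rotated 2° about a random axis — the stated slot tolerances — and white
sensor noise at 15 fT/√Hz. Fields are evaluated at the *perturbed* poses
and projected on the perturbed axes (the sensor genuinely sits there);
the fitting stage uses the nominal layout, so placement error acts as a
systematic measurement bias, as it does in hardware.

*Cardiac grid.* A free-space dipole 10 cm behind a 20×20 cm board,
driven by a five-Gaussian PQRST template (relative amplitudes P 0.15,
Q −0.15, R 1, S −0.25, T 0.35; R-peak moment 20 µA·m — ~200 pT at the
nearest grid point), dominant current along the grid's x axis with a
small fixed tilt. Twenty 4×5 grid positions are "visited" sequentially
(12 beats each, 1.2 Hz with 10 ms timing jitter); a stationary reference
channel spans the session and carries the R-peak events used for
realignment. Environmental noise 100 fT/√Hz puts the best-channel QRS
SNR at order 10²: the free-space, torso-free model is a synthesis
stand-in, not a cardiac conductor model.

*Beta epochs.* A single cortical source (default 10 nA·m rms, 5 mm below
the brain surface, azimuthally oriented) emits band-limited (13–30 Hz)
Gaussian noise shaped by a deterministic envelope — 1 at baseline, 0.5
during the movement window (0.2–1.2 s), 1.5 during the rebound
(1.5–2.5 s), smoothed with a 0.1-s Gaussian — plus bursts at Poisson
rate 0.4 s⁻¹ (Gaussian window σ = 50 ms, amplitude uniform 3–5× the
baseline envelope). Trials run −1 to 4 s at 1200 Hz, 50 per experiment;
sensor noise 15 fT/√Hz. Ground truth (source pose, envelopes, source
time courses, burst times) is returned with the epochs.

What these generators do **not** emulate: correlated background brain
activity, environmental interference and its spatial structure, head
movement, co-registration error beyond the phantom slot tolerance,
non-spherical anatomy, and beat-to-beat cardiac variability. Passing
tests therefore demonstrate internal consistency of the pipeline and the
geometry-driven effects (coverage, displacement, orientation), not
performance on real noise.

## Analysis conventions

*Spectra.* Noise floors: non-overlapping 10-s windows, flattop
periodogram, median across windows with the χ² median-bias correction
(`scipy.signal.welch(average="median")`), reported as ASD = √PSD in
fT/√Hz over 0–100 Hz at 0.1-Hz resolution. The bias correction keeps the
median estimate unbiased for white noise (a raw median sits √ln2 ≈ 0.83
low) while retaining its robustness to transient windows.

*Extrema extraction.* The recording is bandpassed an octave around the
drive frequency, reduced to its first principal component, and peaks and
troughs are located there but refined on the unfiltered component
(filtfilt edge transients otherwise bias extrema near the record ends);
extrema within half a drive period of either boundary are discarded. A
7-Hz, 5-s, 1200-Hz record retains 68 of 70.

*Dipole fit.* Correlation = Pearson across the channel vector (centred;
scale- and offset-invariant, so calibration gain does not bias the fit).
At any trial position the optimal tangential orientation is the
least-squares combination of the two tangential lead-field columns — a
closed-form 2×2 solve — so the search is 3-dimensional: a deterministic
interior grid (Fibonacci shells, ~10³ points, radius ≤ 90 % of the
search sphere) seeds Nelder–Mead refinements from the best 5 points;
ties break toward higher correlation then smaller radius. Peaks and
troughs are fitted independently; orientations are sign-normalised to a
positive θ̂ component before cloud statistics. Degenerate inputs: a
numerically zero snapshot (e.g. a radial source) raises a fit error; a
fit converging to the boundary sets a warning flag.

*Beamformer.* Covariance from all samples of all trials in-band (no
window restriction), Tikhonov-regularised at 5 % of λ_max. The pseudo-T
contrast is the bounded symmetric form (P_act−P_con)/(P_act+P_con),
chosen for scale invariance; a noise-normalised alternative
(P_act−P_con)/P_con sits behind the same switch since the literature
also uses that form. Per-source value: the tangential orientation with
the larger |T|. Radial time courses are not reconstructed (silent in the
sphere model).

*Bursts.* Threshold mean + 3 sd of the envelope (the mean offset makes
the statistic location-invariant); bursts are maximal strictly-supra-
threshold runs; a constant envelope (sd = 0) yields no bursts by
convention. Alignment uses the analytic-signal phase on the cosine
convention (phase 0 at a local maximum): the zero crossing nearest the
envelope peak, searched within the burst ± the 0.3-s half-window;
bursts without a crossing or with windows leaving the data are dropped
and counted. Burst statistics default to the φ̂ₛ source time course.

## Problem sizes and determinism

The test and acceptance runs use reduced but structurally faithful
sizes, chosen once: 21–57 sensors, 120–500 sources, 10–50 trials, 2–12
fitted extrema per phantom run, 10–25 seeds per Monte-Carlo statement.
Cloud statistics and medians converge quickly in these regimes; the
full-scale configurations (77-point lattice, 50 trials, 68 extrema)
remain the generator defaults. All stochastic stages take explicit
seeds; given a seed, every generator is bit-reproducible, and the
fitting and beamforming pipelines are deterministic.

## Known limitations

- The spherical conductor and parametric heads cannot reproduce
  mesh-dependent quantities (sensor counts per head, source counts,
  realistic depth distributions); such numbers are configuration-scale,
  not anatomy.
- The beam-displacement error depends on an under-constrained intra-cell
  geometry (see above).
- The cardiac model is kinematic (field synthesis only).
- Burst detection operates on a single source envelope; no burst-shape
  modelling or cross-region analysis is attempted.
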