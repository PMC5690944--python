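# Methods

This note records the models implemented in `dirqa`, the numerical choices
behind them, and what the synthetic fixtures do and do not establish about
behaviour on real scans.

## Conventions

Voxel arrays are indexed (z, y, x); `spacing` and `origin` are world-order
(x, y, z) millimetre vectors, with the origin at the centre of voxel
(0, 0, 0). Displacement vectors are mm with (x, y, z) components — mm rather
than voxels so fields survive resampling metadata changes. Volumes with
non-identity direction matrices are rejected rather than silently
reoriented: a silent axis flip would corrupt displacement-component signs,
which is worse than an error. Vector fields carry a `"FROM->TO"` direction
tag; comparisons refuse fields whose targets differ instead of guessing a
sign convention.

## NPS estimation

ROIs are sampled on a circle around the slice centre (equal angular spacing
starting at the +x axis, counter-clockwise; patch corners rounded to integer
pixels). The default geometry — 16 ROIs of 40 px per slice at radius 80 px
over 20 slices, 512² matrix at 0.475 mm — mirrors standard CBCT
head-protocol phantom analyses. Adjacent ROIs at this geometry overlap
slightly; overlap correlates patches and inflates estimator variance but
does not bias the mean, so no overlap check is made.

Detrending removes deterministic structure so the periodogram sees only
stochastic noise. Two routes:

* `poly2d` — subtract the least-squares 2D polynomial surface of total
  order 2 (6 coefficients on coordinates normalized to [−1, 1]). Order 2 is
  enough for cupping-like bowls without eating noise power; the residual is
  exactly zero-mean by construction.
* `subtraction` — (ROI − paired repeat-scan ROI)/√2. The difference of two
  independent scans doubles noise power; √2 restores single-scan units.

The estimator is `(Δx Δy / (Nx Ny)) · mean |DFT|²`, DC-centred. No taper
window is applied; for a detrended stationary patch the resulting bin
leakage is negligible next to the annular averaging that follows. The radial
collapse uses annular bins one DFT bin wide. Each annular mean is assigned
to the **actual mean radius** of its contributing grid points and then
interpolated onto the uniform k·Δf axis: at small k the mean radius deviates
from k·Δf by tens of percent (bin 1 mixes radii Δf and √2·Δf), and labelling
those means with k·Δf measurably biases the ramp-up region of the profile —
this surfaced as a systematic error on the fitted ramp-up rate before the
correction. The profile spans 0 to the axis Nyquist in ⌊N/2⌋+1 points.

`nps_variance` integrates the radially symmetric spectrum in polar
coordinates, σ² = 2π ∫ f·NPS(f) df (trapezoid). For a spectrum that is flat
all the way to Nyquist (the white-noise fixture) the last annulus straddles
the edge of the frequency disc, giving a deterministic ≈3–4 % low bias of
the recovered variance; bell-shaped spectra that decay before Nyquist do not
show this edge effect (the worked example recovers σ² within ~1 %).

## Spectral model and fitting

f(x) = a1·exp(−((x−a2)/a3)²)·(1−exp(−a4·x)), with a1 ≥ 0 (HU²·mm²), a2 the
peak frequency (mm⁻¹), a3 > 0 the bell width (mm⁻¹), a4 > 0 the ramp-up
rate (mm). Fitting uses bounded trust-region least squares (max 2000
evaluations per pass, tolerances 1e-10), initialized from the data: a2 at
the peak frequency, a1 at the peak power, a3 from the half-width at half
maximum, a4 = 5/a2.

Residuals are **relative**, iteratively reweighted by the fitted model
(three passes, weight = model + 1e-3·peak). Periodogram scatter is
multiplicative — its standard deviation is proportional to the spectral
power — so relative residuals are the statistically matched objective.
Uniform weighting was tried first and rejected: the model has a soft ridge
(a larger a1 with a slower a4 fits almost as well near the peak), and with
uniform weights a 2 % multiplicative perturbation of the profile can move
the minimum very far along that ridge while changing the residual RMS only
marginally. Weighting by the model rather than by the noisy data avoids the
classic downward bias of data-weighted least squares.

A limit worth knowing: at 2 % multiplicative profile noise on a 64-point
axis, the sampling σ of the fitted a4 is ≈4 % even for an ideally weighted
estimator (Cramér–Rao); occasional double-digit percentage deviations of a4
are therefore expected and are not a fitting defect. a1–a3 are an order of
magnitude better determined. Profiles re-estimated from synthesized noise
(the texture round trip) carry far less noise than that, and there all four
parameters come back within ~2 %.

`scale_to_sigma` multiplies a1 by target-σ²/current-variance, with the
current variance computed from a 512-point model profile out to
a2 + 12·a3 (the bell has decayed to numerical zero there, so the truncation
is irrelevant).

## Noise synthesis

The 2D spectrum on the synthesis grid takes the profile/model value at each
bin's radial frequency (linear interpolation; zero beyond the profile
range). The complex spectrum has magnitude √(P·NxNy/(ΔxΔy)) and random
phases with Hermitian symmetry enforced exactly via the antisymmetrized
phase field φ(k) = θ(k) − θ(−k), so the inverse DFT is real and
self-conjugate bins get phase 0. The DC bin is forced to zero: realizations
are exactly zero-mean and noise injection cannot shift HU calibration.

Spectral **amplitudes are fixed**, not Rayleigh-distributed as for true
Gaussian noise: every realization then carries exactly the prescribed power
in every bin, which makes texture checks sharp (a single periodogram equals
the target spectrum bit for bit) at the cost of mildly non-Gaussian
single-voxel statistics. The Gaussian alternative would multiply each
amplitude by an independent Rayleigh variate and only match in ensemble
average.

When a target σ is requested, the *discrete* grid spectrum is renormalized
so that Σ P·Δu·Δv = σ² after DC removal. Combined with fixed amplitudes
this makes the per-slice sample variance exactly σ² — there is no
polar-vs-grid discretization slack to budget for. (Rescaling through the
continuous polar integral instead would land within a percent or two but
not exactly; the CLI `nps-scale` command exposes that continuous rescale
for parameter files.)

Slices receive independent realizations (seed + slice index); no
inter-slice correlation is modelled because the measurement and synthesis
chain is deliberately 2D. No HU clipping is applied after addition —
clipping would distort the noise distribution in air and bone.

## Registration-error metrics

The DVF comparison assumes the two fields share start points on one grid,
so the error is the plain vector-difference norm; the direction-tag check
is the only guard against comparing fields with incompatible conventions.
The percentage-below-threshold statistic uses a strict `<` (an error of
exactly 2 mm does not count as "below 2 mm"). The median for even sample
sizes defaults to the lower central order statistic — deterministic and
exactly reproducible on integer-valued fixtures — with the midpoint
convention available as an option.

Landmark propagation uses trilinear interpolation of the displacement at
the point's position. Trilinear interpolation reproduces any field that is
affine in world coordinates exactly (to float round-off), which the tests
exploit as an oracle. Points outside the grid are an error, not an
extrapolation case.

## Box alignment and locks

The refinement search is translation-only over integer-voxel offsets,
exhaustive within ±search_radius, minimizing the **mean** squared
intensity difference of the box contents (monotone-equivalent to the sum
for a fixed box, but comparable across box sizes). Exhaustive search makes
the returned minimum provably global within the range, and ties are broken
deterministically: smallest translation norm, then lexicographic (z, y, x).
Rotation and subvoxel refinement are out of scope. `apply_locks` performs
the literal vector replacement (later locks win at duplicate positions);
propagating a lock's influence through a deformable solver is left to the
external registration engine by design.

## Synthetic fixtures

Phantom stacks are a flat background plus an optional order-2 polynomial
trend (emulating cupping) plus spectrum-matched noise; repeat scans share
the trend and differ in the noise stream (second scan's seed offset by
2²⁰), mimicking the scan-twice protocol that enables subtraction
detrending. Synthetic DVFs are sums of closed-form components (constant,
affine, Gaussian bump — widths are e-folding lengths, so a bump with peak
vector d attains ‖d‖ exactly at its centre), giving every voxel and every
off-grid point an analytic truth. The default bump scale (14 mm) matches a
large-deformation breathing case; 7 mm is typical otherwise.

Registration cases perturb the ground truth by a constant bias b plus
i.i.d. N(0, σ²I₃) jitter, so the error magnitude follows ‖b + ε‖: exactly
‖b‖ when σ = 0, σ·χ₃ when b = 0, and √(σ²·χ'²₃(‖b‖²/σ²)) in general. The
expected mean/median/fraction-below-threshold come from these closed forms
(the noncentral mean via quadrature of the χ'²₃ density); the expected
maximum is reported as the median of the max order statistic,
F⁻¹(0.5^(1/n)) — deterministic, and within the sampling spread of an
observed maximum. Agreement between these expectations and the measured
statistics of the evaluation module is the toolkit's end-to-end self-test.

What the fixtures do **not** establish: behaviour on real CBCT artifacts
(cupping, streaking, ringing, aliasing, scatter-induced HU shift are not
synthesized), anisotropic or 3D-correlated noise, non-axis-aligned
geometry, and the response of any particular deformable algorithm — the
toolkit measures registrations, it does not produce them.

## Problem sizes

Default test and acceptance sizes are chosen for desk-scale runtimes while
keeping the statistics meaningful: the Parseval check runs the full
512²×20-slice, 320-ROI geometry; the texture round trip uses 500 slices of
256² (the 2D spectrum is fully resolved there — at 128² the coarser
frequency axis visibly degrades the a4 recovery); the magnitude ladder runs
at 512²×20; closed-form DVF checks use 64³ grids (≈2.6·10⁵ samples, enough
to pin the χ₃ mean to ±0.3 %).
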