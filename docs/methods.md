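# Methods

This note documents the models, estimators, numerical choices and
limitations behind `pcmrheo`. Units: lengths µm at the interface (SI
internally where kT enters), times s, frequencies rad/s, moduli Pa.

## Media models and the generative oracle

A tracer bead of radius *a* in a homogeneous medium at temperature *T*
obeys the generalized Stokes–Einstein relation (GSER) in creep form,
⟨Δr²(t)⟩₃D = (kT/πa)·J(t), with J the creep compliance. In-plane
tracking observes 2/3 of the 3D MSD. Two media are implemented:

- **Newtonian**, viscosity η: J(t) = t/η, so MSD₂D = 4Dt with
  D = kT/(6πηa).
- **Maxwell**, zero-shear viscosity η₀ and relaxation time τ (plateau
  modulus G₀ = η₀/τ): J(t) = 1/G₀ + t/η₀. Moduli
  G′ = G₀ω²τ²/(1+ω²τ²), G″ = G₀ωτ/(1+ω²τ²); the single crossover at
  ω_c = 1/τ has G′ = G″ = G₀/2, and η(ω) = G″/ω plateaus at η₀.

These closed forms (`pcmrheo.media`) are the oracle every stochastic
stage is tested against.

### Trajectory generator

The Maxwell MSD is an offset plus a linear ramp, so it is realized
*exactly* (for every lag ≥ one frame) as free diffusion at
D = kT/(6πη₀a) plus i.i.d. per-frame Gaussian cage jitter of per-axis
variance kT/(6πaG₀): the sampled MSD is 4Dt + (2/3)kT/(πaG₀) by
construction. This was chosen over a generalized-Langevin integrator
because it is exact at the observable timescales and orders of
magnitude faster; the price is that sub-frame dynamics and any memory
in the increments are not modelled (irrelevant for MSD-based
inference, which only sees pairwise displacement variances, but this
generator should not be used to study, e.g., displacement
autocorrelations at sub-frame resolution).

Defaults mirror the acquisition: dt = 15 ms, 10 000 frames, a = 50 nm
(100 nm bead diameter), T = 303.15 K (samples equilibrated at 30 °C in
the imaging chamber; the temperature assumed for kT is configurable
since acquisition protocols do not always state it). Reflecting
confinement in a disk is available but off by default — analyses keep
only beads near the condensate centre precisely to minimize
confinement, and the recovery benchmarks run unconfined.

Rendering (`render_video`) draws beads as 2D Gaussians (PSF width in
px), applies Poisson photon noise plus Gaussian read noise, and
retains ground-truth positions. Condensate fields render PSF-blurred
disks with per-object ground truth (centre, radius, pixel-counted
area, injected integrated intensity, touching-pair chain labels).
FRAP traces follow I(t) = m(1 − e^(−kt)) + ε and persistence traces
I(t) = s + (1−s)e^(−t/τ_d) + ε, on the assay sampling grids (every
20 s to 140 s; every 2 min for 1 h).

What the generator does *not* emulate: bead–bead and bead–interface
hydrodynamics, spatial heterogeneity inside condensates, photophysics
(blinking, bleaching within VPT movies), detector nonlinearity, stage
drift. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every artefact of
real microscopy.

## Tracking

Classic centroid tracking: Gaussian/boxcar bandpass (clipped at zero),
local maxima above an intensity percentile, iterative
intensity-weighted centroid refinement in a circular window (cap 10
iterations, window re-centred when the offset exceeds 0.5 px), then
frame-to-frame linking. Sub-pixel refinement uses centroids rather
than Gaussian fits to match the standard lineage of these codes.

Linking is globally optimal per frame (Hungarian algorithm on squared
displacements, with birth/death costs at max_disp²) rather than
greedy; a track missing a detection survives up to `memory` frames.
This removes the need for a candidate cap — ambiguities are resolved
by the global optimum, and unmatched detections start new
trajectories.

Known bias: the bandpass clip truncates spot tails, which pulls
centroids toward the nearest integer pixel by up to ~0.07 px when the
refinement window is tight. With a diameter ~7σ window the RMS
localization error at SNR ≥ 10 is ≈ 0.05 px. Localization noise adds a
constant 4σ_loc² to the MSD; `static_msd_offset` measures it on
stationary-bead fixtures, `analyze_trajectories` flags it when it
exceeds 10% of the shortest-lag MSD, and subtraction before GSER is
available but off by default.

Defaults (diameter 7 px, max_disp 5 px, memory 3, min_length 100) are
declared choices for the rendered fixtures, not values inferred from
any acquisition; all are exposed in the run configuration.

The recovery benchmarks run the rheology chain on simulated
trajectories directly, bypassing rendering: at η₀ ≈ 30 Pa·s the
per-frame displacement is ~1–2 nm (~0.02 px), far below any realistic
localization noise, so tracked videos at that stiffness would measure
the noise floor, not the medium. The tracking stage is validated
separately at low viscosity and high SNR, where the tracked ensemble
MSD matches the simulation's ground-truth MSD to < 1% (tolerance 10%)
for lags ≥ 5 frames.

## MSD estimation and smoothing

`ensemble_msd` snaps a log-spaced lag grid (20 points/decade,
0.015–100 s by default) to integer frame lags, computes every
overlapping displacement pair per trajectory, and pools pairs across
trajectories (pair-count weighting — equivalent to maximizing the
number of samples, as the standard codes do). `n_obs` records total
pairs; `n_eff` approximates independent samples (non-overlapping
windows) and drives standard-error checks in tests. Smoothing is a
centred moving average over grid indices (= log-lag space) with a span
kept below 10% of the number of points; endpoint windows shrink
symmetrically so lags are unchanged.

## GSER inversion (Mason's method)

For each lag t: ω = 1/t, α(ω) = d ln MSD/d ln t by centred finite
differences in log-log (one-sided at the ends), clamped to [0, 1];
MSD converted to 3D-equivalent (×3/2 for d = 2; the dimensionality
convention is configurable because published analyses are often silent
about it); then

|G*(ω)| = kT/(πa·MSD₃D(t)·Γ[1+α]), G′ = |G*|cos(πα/2),
G″ = |G*|sin(πα/2).

This first-order local power-law estimate is exact for pure power-law
MSDs but errs near sharp transitions — for a Maxwell fluid by −20% on
both moduli at the crossover and up to ±36% on the minor modulus at
0.1 or 10 ω_c. The default therefore adds the second-order term of
the same expansion: writing β = d²ln MSD/d(ln t)² (clamped to [0, 1];
creep MSDs have β ≥ 0) and expanding the one-sided Fourier transform
of a log-quadratic MSD gives

G*(ω) = G*_first-order(ω) / (1 + C),
C = (β/2)·[(ψ(1+α) − iπ/2)² + ψ₁(1+α)],

with ψ and ψ₁ the di- and trigamma functions. For Maxwell media this
brings the complex modulus within ~2% across 0.1–10 ω_c (the minor
modulus can still deviate ~15% at the band edge where it is a tenth of
|G*|). `curvature_correction=False` restores the plain first-order
form.

A useful identity: for any offset-plus-linear MSD, α(t) = t/(t+τ)
crosses 1/2 exactly at t = τ, where cos = sin — so the estimated
moduli cross exactly at the true crossover under the first-order form,
and τ_rel recovery is limited only by sampling noise and
interpolation.

## Scalar material constants

- **Viscosity spectrum**: η = G″/ω pointwise over measured
  frequencies.
- **Zero-shear viscosity**: the lowest-frequency run of ≥ 3
  consecutive points with |d ln η/d ln ω| < 0.1 is the plateau; η₀ is
  its mean. The 0.1 threshold operationalizes "the plateau at low
  frequency"; for a Maxwell fluid it admits ω < 0.23/τ, where η is
  within ~5% of η₀. Points with η = 0 (α clamped to 0 at the elastic
  end) are excluded. If no plateau exists in the measured band the
  Maxwell fit's η₀ = G₀τ is substituted and flagged.
- **Crossover / terminal relaxation time**: lowest-frequency sign
  change of log(G′/G″), interpolated linearly in log ω; τ_rel = 1/ω_c.
  If the measured band contains no crossing, the Maxwell fit's
  crossover is returned flagged as extrapolated (mirroring
  measured-vs-extrapolated line styles in standard figures). A second
  crossing, if present, is reported but no model beyond Maxwell is
  fitted.
- **Maxwell fit**: joint least squares of log G′ and log G″ against
  the Maxwell forms in (log G₀, log τ), robust soft-L1 loss
  (f_scale 0.3) because the minor modulus near the terminal-flow end
  scatters over orders of magnitude in log space. The fit is flagged
  `ok=False` when the worse per-modulus median absolute log residual
  exceeds 0.35 (≈ 40% typical miss) — a Newtonian input either fails
  outright (G′ ≡ 0 leaves < 6 usable points) or is flagged. The fit is
  applied in moduli space; fitting the MSD directly is equivalent for
  a Maxwell medium (offset/slope = τ) and the offset/slope identity is
  verified in tests.

## FRAP

Normalization modes: `in_vitro_reference` divides by a far-away
reference condensate *before* anchor rescaling (the reference exists
to cancel acquisition photobleaching, and division must precede
anchoring for the drift to cancel), then maps pre-bleach mean → 1 and
first post-bleach → 0; `in_vivo_minmax` maps the pre-bleach mean to 1
and the cytoplasmic level to 0. The bleach frame is auto-detected as
the largest single-step drop and can be overridden. Bleach depth
< 20% of pre-bleach triggers a "weak bleach" warning; a non-positive
reference is an error.

The one-phase fit I(t) = plateau·(1 − e^(−kt)) fixes I(0) = 0 (both
normalizations force the first post-bleach sample to the floor, so a
free offset is not identifiable). CIs are percentile intervals from
500 seeded residual-bootstrap refits; resampled residuals are
re-inflated by √(n/(n−2)) because raw fit residuals under-disperse on
short traces (without this, 95% intervals covered only ~87% in
calibration). Degenerate guard: when the recovery achieved within the
record is indistinguishable from noise (the optimizer can then trade
plateau → bound against k → 0), the reported plateau is the
data-supported recovery level and k is flagged unidentifiable. On the
140 s in vivo grid rates below ~0.005 s⁻¹ are fundamentally
unidentifiable (k·t_max ≈ 0.7 — only plateau·k is constrained); the
recovery-grid tests assert accuracy at k ∈ {0.02, 0.1} s⁻¹ and flag
degradation at slow rates instead. Both the fitted plateau and the
last-timepoint mean are reported, since descriptive "recovery"
percentages can mean either.

Partial-bleach line scans read intensities at the fixed landmarks
(maximum 1.82 µm, minimum 2.6 µm along the 5 µm line), normalized to
the maximum of the t = 0 post-bleach profile, averaged over replicate
stacks.

## Image quantification

Segmentation: Otsu on a 3 px median-filtered image (robustness to
shot noise), or a fixed threshold for exact reproducibility. A noise
guard requires the Otsu threshold to clear median + 3·1.4826·MAD of
the filtered image; otherwise the mask is empty (without it, an
object-free field percolates into large spurious components).
Optional distance-transform watershed splits touching chains; objects
below `min_size` px are removed and labels are contiguous.

Statistics: area (µm²), mean intensity, integrated density
(= mean × pixel count) and centroid per object, with the across-object
mean area ± 95% CI. The per-frame median of non-object pixels is
subtracted by default (robust to uneven illumination). On synthetic
fixtures (radius 16 px disks, PSF σ 0.8 px) Otsu-based integrated
density recovers the injected totals to −4% — the PSF pushes ~0.8σ/r
of each object's flux outside the half-maximum contour; a lower fixed
threshold recovers to < 1%.

Partition coefficients divide each object's mean intensity by the
dilute-phase mean, excluding a 2 px dilated rim around every object
(PSF bleed); the same edge bias makes disks at 10× contrast read ~5%
low. Persistence curves normalize integrated density to the pre-event
sample and report fraction remaining at 10 and 60 min and the 0.5
crossing time if reached; association of objects across frames uses
nearest-centroid matching with a 5 µm maximum jump. Stacks are
maximum-intensity projected before 2D analysis (summation is available
for integrated densities, since either convention appears in
published quantifications).

## Recovery benchmarks and problem sizes

`pcmrheo.benchmarks` parameterizes Maxwell media to the two published
conditions (η₀ = 31.8 Pa·s, τ = 4.6 s; η₀ = 3.8 Pa·s, τ = 1.03 s),
simulates 300 beads × 10 000 frames at 15 ms/frame per seed — the
stated acquisition scale, ~3×10⁶ bead-frames per condition over three
seeds — and reports median recovered η₀ (plateau mean) and τ_rel
(measured crossover; the crossover frequencies, 0.22 and 0.97 rad/s,
sit comfortably inside the measured band 0.01–67 rad/s). Typical
recovery is within ~5% of the generative values; the residual deficit
is finite sampling at the longest lags plus the local power-law
approximation. FRAP benchmarks fit 50 traces at mobile fraction 0.20,
k = 0.02 s⁻¹, noise SD 0.01 on the 20–140 s grid. Module tests use
smaller simulations (≤ 300 beads × 3000 frames) sized so that the
statistical tolerance being asserted is several standard errors wide.

## Known limitations

- One-point passive microrheology only: no two-point analysis, no
  confinement-corrected GSER, no active rheology, no inertia or
  hydrodynamic memory.
- The GSER inversion assumes a locally smooth MSD; heavy smoothing of
  very noisy curves biases α near sharp transitions.
- No drift correction beyond what linking tolerates; no 3D tracking.
- FRAP modelling is purely empirical one-phase recovery — no
  reaction–diffusion decomposition or bleach-geometry correction.
- Segmentation is 2D on projections; overlapping objects in z are not
  resolved.
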