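# Methods

This note documents the models, parameter choices and numerical decisions
behind `prismtrack`, and what the simulator-based validation does and does
not demonstrate about real data.

## Imaging model

Two synchronized cameras view the same focal plane. The **spatial** path
(160 nm/px by default, 16 µm camera pixels at ×100) carries a cylindrical
lens, so a point emitter images as an elliptical Gaussian whose widths
encode its axial position z. The **spectral** path (178 nm/px at ×90)
carries a low-dispersion prism that displaces each emitter's image along
one camera axis (+y here) in proportion to its mean emission wavelength;
because the dispersion is deliberately low, the image stays a compact,
near-diffraction-limited spot rather than a smeared spectrum, so ordinary
localization algorithms apply in both channels and usable emitter densities
stay high.

The channels are related by a full two-dimensional 3rd-order polynomial
(10 coefficients per output coordinate). The model is linear in its
coefficients, so the least-squares optimum is computed in closed form by
SVD-based linear least squares; an iterative Levenberg–Marquardt
minimization of the same residual converges to the identical optimum, which
a test verifies by recovering known coefficients to 1e-6 relative. The
transform is calibrated on a raster-scanned fiducial grid (7×7 positions,
49 paired centroids) and is implicitly centered at the fiducial's emission
wavelength λ₀: an emitter at λ₀ has pair distance d = 0.

Wavelength assignment is the affine law λ = λ₀ + α·d. The dispersion
coefficient α is the slope of an unweighted regression of known bead
emission peaks on their measured displacements; slope *and* intercept are
fitted, and the intercept is kept as a QC check on λ₀ rather than forced
through it. On the three-peak reference data (683/607/514 nm at
0/9.69/20.90 px) this yields α = −8.09 ± 0.13 nm/px.

## Detection and fitting

Spots are detected on plane 2 of the undecimated à-trous B3-spline wavelet
transform, which suppresses constant background and (away from borders)
linear gradients while passing PSF-sized structure. The detection threshold
is `threshold_k` (default 1.5) times a robust noise scale, 1.4826 × MAD
measured on wavelet plane 1 — the noise-dominated plane — rather than on
the already-smoothed detection plane; referencing the threshold to raw
pixel noise is what keeps false positives rare (well below 0.02/frame at
SNR ≥ 8) at this k. Seeds closer than `min_separation_px` (default 4)
merge to the brighter one.

Sub-pixel fitting minimizes unweighted least squares of
A·exp(−(x−x₀)²/2σx² − (y−y₀)²/2σy²) + b over a 7×7 ROI with an analytic
Jacobian, initialized from the centroid and second moments of the
background-subtracted ROI. Photons are the integrated amplitude above
background, 2πAσxσy, divided by the camera gain; the goodness-of-fit is the
coefficient of determination clipped to [0, 1]. Fits whose ROI clips the
border, or that fail, return records flagged invalid instead of raising.

z is assigned by matching (√σx, √σy) against calibration curves on a 1 nm
grid over [−500, 500] nm (no root finding); boundary minima or residuals
above 0.35 (√px units) leave z unset. The default calibration derives from
the standard cylindrical-lens defocus model σ(z) = σ₀√(1+((z∓Δ)/zR)²) with
σ₀ = 1.3 px, focal-plane split Δ = 250 nm, depth zR = 400 nm, refit as
4th-order polynomials exactly as a measured bead z-stack would be.

## Pairing and species assignment

Per frame, transformed spatial localizations are matched to spectral
localizations inside a rectangular zone: |Δx| ≤ dx_px (default 2)
perpendicular to the dispersion axis and displacement d within a window
along it. The window defaults to the full physically plausible emission
range (400–800 nm via the calibration) but should be narrowed to the imaged
palette when known — the zone's area bounds the density of simultaneously
emitting molecules that can be paired unambiguously, and at
≳0.002 molecules/px² with the full window, consistent mispairing of
coincidentally x-aligned emitters becomes the dominant wavelength error.
Conflicts are resolved by minimum-cost one-to-one assignment (cost =
squared perpendicular offset; a greedy fallback handles >200 candidate
links per frame). Pairing only ever *adds* wavelength information: spatial
coordinates pass through bit-identical.

## Spectrally-informed multi-Gaussian fitting

Two emitters closer than ~200 nm merge into one spatial spot. If their
wavelengths differ enough (≥2 px along the dispersion axis, ~16 nm at
−8.1 nm/px), the spectral channel still resolves them, giving both the
component count (capped at two; with three or more candidates the two
brightest are used) and an initialization for the coordinate perpendicular
to the dispersion axis, mapped back through a locally Newton-inverted field
transform.

Decision logic per frame: spatial seeds are first pre-paired one-to-one
with spectral candidates, so two partially split seeds of the same pair
cannot both claim two candidates; a seed (or group of adjacent seeds —
seeds within 2·roi+1 px are fitted jointly, since a bright neighbour's tail
otherwise biases independent single fits by tens of nanometres) with an
additional unclaimed candidate in its zone triggers the two-component fit.
A second candidate dimmer than 0.3× the primary is treated as a spurious
detection, which is what holds the over-counting rate on single-emitter
frames at zero across 1000 simulated frames.

The two-component fit itself is deliberately constrained. Both components
share widths fixed to the PSF model (the in-focus astigmatism widths):
freeing four width parameters on an unresolved pair is statistically
degenerate, and measurement showed it roughly doubles the error. The
perpendicular coordinate is bounded within ±1 px of its spectral
initialization (a ~5σ allowance at the spectral channel's localization
precision), and the along-axis coordinate within ±1.5 px of the seed —
justified because the two-component fit only triggers for emitters
overlapping inside one PSF. Free parameters: two amplitudes (initialized
proportional to the spectral candidates' photons), two positions, one
common offset. z is not refit for the overlapped pair; records inherit the
width model. Non-convergence falls back to a single fit.

The blind baseline ("systematic" mode) fits two free elliptical Gaussians
everywhere, initializing the second component at the maximum of the
single-fit residual, and keeps poorly converged components — emitting two
localizations per spot unconditionally is precisely the policy whose
over-counting pathology the comparison quantifies.

## Tracking and diffusion

Linking minimizes total squared displacement per frame pair by exact
one-to-one assignment, with per-link cap `max_disp_px` (scaled by gap
length when bridging up to `max_gap` = 2 dark frames, the quantum-dot
blinking scale). A simulated-annealing solver (greedy init, geometric
cooling 0.95, 10⁴ proposals, seeded) is provided as an alternative and
matches the exact optimum on small instances. MSD is the time-averaged mean
over all pairs at each lag, 2-D or 3-D as z availability allows; D is the
slope of an unweighted line through MSD points 1–4 (common SPT practice)
divided by 2·dim, clamped at zero and flagged when negative. Species
summaries report per-label median and IQR of D; a track's species is the
majority vote of its records' wavelength-window labels.

## The simulator and what passing tests mean

The simulator renders both channels from ground-truth trajectories through
the same models the analysis calibrates: sampled astigmatic Gaussians on the
spatial camera; the transform-then-displace mapping with a compact Gaussian
on the spectral camera (an explicit simplification of the true few-pixel
spectral smear, with the spectral path collecting 0.7× the spatial photon
budget to reflect its lower-NA objective); and an EMCCD surrogate of
Poisson shot noise on signal plus background flux, linear gain, constant
baseline and Gaussian readout noise. Defaults — 800 photons/frame,
10 background photons/px/frame, gain 2 counts/photon, baseline 100,
readout 3 counts — are calibrated so an isolated in-focus emitter localizes
to ~15 nm laterally, the bright-quantum-dot regime. Rendering is bit-exact
reproducible per seed and conserves photon flux to <0.5% without noise.

What this does *not* emulate: EMCCD excess-noise factor, emitter blinking
and photobleaching kinetics, the wavelength dependence of the field
transform away from λ₀, spectral-shape asymmetries, vectorial/aberrated
PSFs, and sample autofluorescence structure. Closed-loop results therefore
demonstrate correctness and internal consistency of the algorithms under a
realistic noise budget, not instrument-level accuracy on any particular
microscope.

## Benchmark problem sizes and headline numbers

The two-emitter crossing benchmark follows the reference protocol: one
705 nm emitter static at field center, one 655 nm emitter sweeping at
10 nm/frame for 320 frames over a 64×64 px field, both at z = 0; errors are
evaluated against ground truth by per-frame one-to-one matching within
2000 nm (generous enough that grossly mis-fitted components register as fit
error rather than vanishing as unmatched) and averaged over the 101 frames
with true separation ≤500 nm, as well as over all frames. Under these
conditions blind two-component fitting averages ≈220 nm in-window and the
spectrally-informed policy ≈61 nm (≈3.6× reduction); seed-to-seed scatter
is a few percent, and the acceptance script averages five seeds. The
residual informed-mode error is concentrated below 100 nm separation, where
amplitude trade-off between nearly coincident components is genuinely
ambiguous.

Registration quality is exercised on a 7×7 grid spanning a 512×512 px field
mapped through a mild cubic warp with 7 nm/axis localization jitter on both
channels: the fitted transform leaves a median 2-D residual of ≈6.5 nm
(the Rayleigh-statistics expectation after the 20-parameter model absorbs
its share of the 98 jittered degrees of freedom), comfortably inside the
12 nm channel-registration budget.

Test problem sizes are scaled for a single-CPU run: the over-counting guard
uses 1000 single-emitter frames (tolerance zero), the √N-precision slope
150 Monte-Carlo repeats per photon level, diffusion recovery 50 tracks of
1000 steps, and the acceptance-test crossing runs one seed per policy while
the acceptance script recomputes five.

## Known limitations

* Two overlapping emitters at most; three-emitter spots are fitted as the
  two brightest spectral candidates with a warning-level merge.
* Overlapped pairs inherit the in-focus width model, so their z is not
  independently refined (single-emitter records carry full astigmatic z).
* Wavelength accuracy degrades with emitter density through mispairing;
  narrow the pair-search window to the imaged palette whenever it is known.
* Drift estimation requires fiducials localized in ≥80% of frames;
  correlation-based (fiducial-free) drift correction is out of scope.
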