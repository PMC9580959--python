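# prismtrack

Multidimensional **(x, y, z, t, λ)** single-molecule localization and tracking
for dual-channel spectral SMLM.

## The problem

Single-molecule localization microscopy (SMLM) localizes sparse fluorophores
to a few tens of nanometres, and single-particle tracking (SPT) follows them
over time. Watching *several* molecular species at once normally costs
photons (dichroic splitting) or time (sequential imaging). A dual-objective
spectral design avoids both: a second detection path views the same focal
plane through a low-dispersion prism, which shifts each emitter's image along
one camera axis in proportion to its mean emission wavelength. Pairing each
direct ("spatial") localization with its displaced ("spectral") counterpart
turns that shift into a per-molecule wavelength — at no photon cost to the
spatial localization, whose precision is untouched.

`prismtrack` implements the complete analysis side of such an instrument,
plus a physics-based simulator of the instrument itself, so every stage can
be validated closed-loop against ground truth without microscope data:

1. **Detection & fitting** — à-trous B3-spline wavelet filtering for robust
   spot detection, elliptical-Gaussian least-squares fitting for sub-pixel
   coordinates, and astigmatism-based z assignment from the σx/σy asymmetry.
2. **Registration & drift** — the spatial→spectral field mapping is a full
   2-D 3rd-order polynomial with 10 coefficients per output coordinate,

       x′ = a₁x³ + a₂y³ + a₃x²y + a₄xy² + a₅x² + a₆y² + a₇xy + a₈x + a₉y + a₁₀,

   fitted by linear least squares to a raster-scanned 7×7 fiducial grid
   (median residual ≲ 12 nm); per-channel drift is corrected from fiducial
   trajectories, and session-to-session shifts touch only the zero-order
   coefficients a₁₀.
3. **Spectrally displaced localization** — localizations are paired frame by
   frame inside a rectangular search zone around the transformed spatial
   position (conflicts resolved by minimum-cost one-to-one assignment), and
   the wavelength follows the linear dispersion law **λ = λ₀ + α·d** with
   d = y_spectral − y′_spatial. On the reference instrument α = −8.1 nm/px
   with λ₀ = 683 nm.
4. **Spectrally-informed multi-Gaussian fitting** — when two spectrally
   distinct emitters overlap inside one diffraction-limited spot, the
   spectral channel still shows two localizations. Their count selects
   single- vs two-component fitting, and their coordinates initialize the
   fit perpendicular to the dispersion axis — removing both the
   under-counting of blind single fitting and the over-counting of blind
   multi-fitting.
5. **Tracking & diffusion** — optimal per-frame-pair assignment linking
   (simulated annealing available as an alternative solver), time-averaged
   MSD curves, and diffusion coefficients from MSD(τ) = 2·dim·D·τ.

## Worked example

Simulate a dual-camera acquisition of two spectrally distinct quantum dots
(655 / 705 nm) crossing paths, then compare blind two-component fitting with
the spectrally-informed policy:

```bash
$ prismtrack benchmark --mode both --seed 1
systematic: mean error  226.8 nm (|separation| <= 500 nm),   92.8 nm (all frames)
  informed: mean error   59.8 nm (|separation| <= 500 nm),   40.2 nm (all frames)
```

While the two emitters are within ±500 nm of each other they merge into one
spot on the spatial camera. Blind ("systematic") two-Gaussian fitting then
over-counts and mis-places components, averaging ~230 nm of localization
error; using the spectral channel to fix the emitter count and initialize
the fit cuts this to ~60 nm, a ~4× reduction. Away from the crossing the two
policies converge (all-frames means are dominated by easy, well-separated
frames).

A full pipeline run on simulated data:

```bash
prismtrack simulate --scenario multispecies --out-dir sim --seed 2
prismtrack localize --stack sim/spatial.tif  --out sim/spatial_locs.csv
prismtrack localize --stack sim/spectral.tif --out sim/spectral_locs.csv
prismtrack spectral --spatial-csv sim/spatial_locs.csv \
    --spectral-csv sim/spectral_locs.csv \
    --transform transform.txt --dispersion dispersion.txt \
    --out sim/paired.csv
prismtrack track --localizations sim/paired.csv --out sim/tracks.csv \
    --summary sim/diffusion.csv
```

Every command logs its full parameter set to a `*.params.txt` sidecar, and
localization tables are plain CSV with a fixed header
(`frame,x,y,sigma_x,sigma_y,photons,background,goodness,z,wavelength,pair_distance,track_id,species`),
coordinates in channel pixels (160 nm/px spatial, 178 nm/px spectral by
default), frames 0-based.

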