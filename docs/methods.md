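# Methods

## Scope and model

`hsical` models two intraoperative hyperspectral acquisition geometries and
the calibration chain that makes their outputs comparable:

* **Filter-wheel microscope** — narrowband *illumination* (Gaussian band
  filter in front of a broadband xenon source), panchromatic sensor, one
  frame per band.  19 bands: 400–700 nm in 20 nm steps (FWHM 10 nm) plus
  750/800/850 nm (FWHM 25 nm).
* **Mosaic snapshot cameras** — broadband illumination, per-pixel narrowband
  filters in a periodic 4×4 or 5×5 sensor tile.  16 bands at 463–638 nm and
  25 bands at 693–966 nm, with per-band FWHMs of 4–25 nm taken from the
  packaged instrument tables (`src/hsical/data/band_tables.json`).

All spectral quantities are `SpectralCurve`s: sampled, nonnegative functions
of wavelength.  Internal response/illumination arithmetic uses a common
390–1000 nm grid at 1 nm (band FWHMs go down to 4 nm, so sub-FWHM sampling
is required); reference-chart I/O stays on the chart's native 10 nm grid
(62 samples).  Band order inside cubes is always ascending center
wavelength; the mosaic cell position of each band (`sensor_index`,
row-major within the pattern period, 0-based, anchored at the top-left
pixel) is a fixed packaged permutation shared by the simulator and the
demosaicer — physically arbitrary, but any fixed convention is sufficient
because both sides agree on it.

## Forward simulator

The simulator exists to give every calibration stage a ground truth; it
reproduces the effects the chain corrects and deliberately nothing else.

* **Scene** — a label map with one reflectance spectrum per label.  The
  24-tile chart generator produces 18 colored tiles (random mixtures of 2–4
  Gaussian bumps, scaled into [0.03, 0.95]) and 6 gray tiles at fixed levels
  0.90/0.59/0.36/0.19/0.09/0.03.  Per-tile SD envelopes rise sigmoidally
  from 0.002 in the visible to ≈0.11 in the NIR, mimicking
  spectroradiometer chart calibrations.  Gray tiles are seed-independent.
* **Illumination** — `xenon`: flat from 400 nm with two narrow emission
  peaks at 818/838 nm and a gentle roll-off beyond 850 nm; `led`: strong
  460 nm peak, 525–680 nm plateau, rapid decay above 680 nm (NIR power
  < 10 % of the blue peak); `flat`: unity (for tests).  Both lamps are
  clipped to zero below 400 nm (UV protection).
* **Sensor responses** — unit-peak-scaled Gaussians at the packaged
  center/FWHM values.  Peak heights ≈ 0.2 for the 4×4 camera (one band at
  0.1) and ≈ 0.1 / 0.05 for the central / outer 5×5 bands, reproducing the
  per-band response gaps of real mosaic sensors.  Secondary response peaks
  are additive Gaussians; by default two 5×5 bands (872 and 932 nm) carry a
  secondary at 30 % relative height roughly 150 nm below the primary.  The
  secondary center snaps to the nearest band center (732 and 784 nm) and
  takes that band's FWHM: a second-order leak passes through the same
  interference structure as the band it overlaps, so the contamination is a
  true band-space mixing.  This choice is what makes the contamination
  correctable at all — a leak at a wavelength no band senses provides no
  independent signal from which a linear correction could subtract it.
* **Pixel model** — counts = exposure · gain · Σ_λ illumination ·
  reflectance · response · Δλ, attenuated by a radial quartic vignetting
  profile (1 − strength·r⁴, r = 1 at the corners), plus a constant dark
  offset, optional Poisson shot noise and Gaussian read noise, clipped to a
  12-bit full well (4095 counts).  Defaults: dark offset 100 counts,
  vignetting strength 0.3 in pipeline runs, noise off so round-trip
  accuracy can be asserted exactly.  Exposures default to the packaged
  per-configuration table (42 / 65 / 0.5 / 110 / 7.5 ms); the gain is set
  automatically so the brightest white-board band reaches 80 % of the
  usable well depth.
* Not modeled: optical PSF/defocus, chromatic aberration, thermal drift,
  scattered light, and sub-pixel or view-angle misalignment.  Passing tests
  therefore say nothing about those effects on real data.

## Calibration chain

* **Flat field** — gain = I_ref/I_meas per band from a dark-subtracted
  render of the uniform white board, I_ref being the mean over the
  (2·10+1)² center window (window auto-shrinks on small test images;
  requesting a window larger than the image is an error).  Near-zero pixels
  (< 10⁻³ of I_ref) are masked to gain 1 rather than producing unbounded
  gains; ≥ 5 % masked pixels triggers a warning.
* **Reflectance** — the one-point formula is applied literally; the white
  board's own 0.95 reflectance is *not* divided out by default, so the
  result carries a uniform 1/0.95 factor that the α step absorbs (an
  opt-in flag divides it out for absolute reflectance).  Pixels with a
  nonpositive white denominator become NaN; negative reflectance (noise
  below dark) is kept, not clipped, so region averages stay unbiased.
  Per-band σ_noise is the spatial median of the dark series' per-pixel
  temporal SD; a single-frame dark series has no SD and SNR is undefined.
* **Crosstalk correction** — measured responses R and ideal Gaussian
  targets T are normalized to unit integral (matching the white-reference
  normalization every reflectance band has already received, which also
  means a flat spectrum maps to the unit vector).  Because scene
  reflectance is smooth on the scale of the band spacing, the
  deconvolution is solved on a smooth scene-spectrum basis Φ — one
  Gaussian per band center, width set by the local band gap — rather than
  over raw wavelength space: with A = RΦ, B = TΦ,
  C = (AAᵀ + ridge·tr(AAᵀ)/n · I)⁻¹ABᵀ, followed by a column rescaling so
  a flat input maps exactly to a flat output.  Solving in the smooth basis
  is essential: over raw wavelength space no combination of narrow
  primaries can cancel a secondary lobe they barely overlap, and the
  measured suppression was nil.  Default ridge 1e-4; ridge 0 with an
  ill-conditioned band-overlap Gram matrix raises an error advising
  regularization.  Demosaicing is plane extraction (one sample per pattern
  cell, output size input/pattern, no interpolation).
* **Registration** — exhaustive integer-shift search maximizing NCC on the
  valid-overlap region (no zero padding), ties broken by smallest shift
  norm then row-major order.  Assembly registers every band to the first
  cube's mid-wavelength band (typically the best SNR), crops to the common
  valid region, and merges bands sorted by center wavelength with
  per-band source tags (41 bands for the dual-camera cube).  Translation
  only; the simulated single-setup pipeline skips registration because its
  frames are co-registered by construction — cross-band NCC on scenes
  whose band images are weakly correlated could otherwise *introduce*
  shifts.  Rotation, affine and parallax correction are out of scope.
* **Intensity correction** — α = Σ m·r / Σ m², pooled over all 24 tiles
  and all wavelengths ≤ 850 nm (the configurable NIR cutoff; reference SDs
  and SNR above it are too poor to constrain a scale).  The fit is
  scale-equivariant and exact under noiseless injection; validation
  reports per-tile differences d = reconstructed − reference at the band
  centers, within-SD flags against the chart envelope, and RMSE split at
  680 and 850 nm (visible / red-NIR / deep-NIR).

## Visualization

RGB rendering uses the CIE 1931 2° standard observer via the multi-lobe
Gaussian analytic approximation (piecewise-σ lobes; accurate to a few
parts in 10³ of the tabulated observer, far below the sampling error of a
41-band cube).  Tristimulus sums use trapezoid weights over the uneven
band-center spacing (band shapes are narrow, FWHM ≤ 25 nm, relative to the
smoothness of the observer curves, so sampling at centers suffices);
normalization maps unit reflectance to Y = 1, and a von Kries channel
scaling maps the rendering illuminant (default equal-energy, i.e. neutral
reflectance rendering) to exactly R = G = B = 1.  Values are clipped to
[0, 1] only at the final gamma encode, with the clipped fraction reported.

Enhancement follows the minor-component reconstruction
J = W Σ_{i>m} γᵢ Aᵢ: per pixel, the residual spectrum carried by the
components after the first m, weighted by a diagonal matrix W that is
nonzero (= gain) exactly on the bands inside the selected interval.  The
per-pixel weighted residual spectrum is reduced to a scalar by summing
over bands, then min–max normalized to [0, 1] — the reduction to a single
map is this package's choice, consistent with adding one image to the
blue channel.  m = N or W = 0 give all-zero maps.

Choosing m: the helper `m_for_variance(0.95)` (smallest m whose leading
components explain ≥ 95 % of variance) is the default in the CLI, but it
is a heuristic — when the contrast of interest is itself among the
leading components it gets excluded and the map carries no signal.  On
the two-region synthetic (one global shading mode), the analyst's correct
choice is m = 1, and that is what the tests use.  The two-region
generator draws a low-order polynomial shading field (the dominant
variance, as in real surgical scenes), mean-equalized across the two
regions so the label carries no brightness information, adds the stated
contrast (default 0.05) to the bands inside the interval in region B
only, and iid Gaussian noise (default 0.01).

## Numerical choices and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| working grid | 390–1000 nm, 1 nm | sub-FWHM sampling of 4 nm bands |
| full well | 4095 counts | 12-bit readout |
| dark offset | 100 counts | typical small offset, well below full well |
| ridge | 1e-4 (× tr(G)/n) | stabilizes C under response noise without visible bias |
| α cutoff | 850 nm | NIR reference/SNR cannot constrain a scale factor |
| validation breaks | 680, 850 nm | visible / red-NIR / deep-NIR quality regimes |
| center window | ±10 px | flat-field reference region |
| chart scene | 4×6 tiles, 40–50 px tiles | keeps pipeline runs in ~0.1 s while leaving ≥ 3 cube px per tile after demosaicing |

Problem sizes in tests and the acceptance script (chart scenes of
80×120–200×300 px, 50-trial registration Monte Carlo, 40×40 two-region
cubes) were chosen so the whole suite runs in seconds on one CPU while
every statistical assertion retains comfortable margin.

## Known limitations

* The crosstalk model treats the sensor as a purely spectral mixer; spatial
  neighbor-pixel crosstalk is folded into C rather than modeled separately.
* Registration is global integer translation; deformable or multi-view
  alignment must happen upstream.
* The chart is a synthetic stand-in with the same structure as a real
  24-tile chart (tile count, grid, SD envelope), not measured tile spectra.
* SNR figures from the simulator reflect the configured synthetic noise
  only; they are not predictions for any physical sensor.
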