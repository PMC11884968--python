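# Methods

This note documents the models, parameter defaults, and numerical choices
behind `mmspec`, and what the synthetic test bench does and does not
demonstrate about real tissue data.

## Data model

A `Spectrum` is a strictly increasing axis (wavelength nm, Raman shift
cm⁻¹, or raw pixel) plus intensities and acquisition metadata. Axis kinds
are checked on every binary operation; mismatches raise a `UnitError`
rather than silently coercing. Intensities must be free of infinities; NaN
appears only as an explicit masked-channel marker (reflectance channels
whose denominator was not strictly positive are masked and counted in the
result metadata).

CCD fiber regions are inclusive 0-indexed row ranges (rows 22–92 are 71
rows), binned by **summation** rather than averaging so Poisson counting
statistics are preserved. The shipped defaults (lensed rows 22–92, offset
rows 93–201 on a 256-row detector) mirror a typical alignment of the probe
fibers on the spectrograph slit; vendor row-indexing conventions vary, so
the split is configuration, not law.

## Reflectance calibration

Relative reflectance is the background-subtracted sample divided by the
background-subtracted measurement of an 80% diffuse standard. Choices:

- The standard's nominal reflectivity is stored but **not** folded into the
  ratio by default (`absolute=True` multiplies by it); displayed
  reflectance from such instruments is conventionally relative to the
  standard, and both conventions appear in practice.
- A neutral-density filter in the standard arm (OD 0.6 in the reference
  configuration) can be compensated with `od_correction`, which multiplies
  the ratio by `10^(−OD)`. Off by default: the plain ratio formula carries
  no compensation, and comparisons between spectra are unaffected by a
  global factor.
- The reporting band defaults to 475–600 nm (the useful band of the DRS
  spectrometer plus excitation short-pass filter); workflows that track the
  635/730 nm dye ratio pass a wider band explicitly.
- Channels with a nonpositive denominator are masked with NaN and counted
  (`n_masked`), not clipped — a silent clip would bias trough statistics.

## Wavenumber calibration

The pixel → cm⁻¹ map is a least-squares polynomial (degree ≤ 3, default 2)
through the pixel positions of calibrant peaks paired, in ascending order,
with the standard acetaminophen Raman shifts (651.6, 797.2, 857.9, 1168.5,
1236.8, 1323.9, 1648.4 cm⁻¹ — the community-standard solid-calibrant
positions). Peak pixel positions use 3-point parabolic refinement, which is
accurate here because calibrant bands are intense and narrow. The fitted
map must be strictly monotone over the pixel range; residual RMS is
reported. Calibration fails loudly if fewer peaks are detectable than the
polynomial needs or if detections cannot be paired 1:1 with the reference
list.

## Raman preprocessing chain

Execution order: despike → crop to fingerprint → baseline → vector
normalize. Despiking runs first so spikes cannot distort the polynomial
fit; cropping precedes the fit so the polynomial covers only the analyzed
band. The order of a prose list of steps is not an algorithm; this ordering
is standard practice.

**Despiking** is detect-and-replace, not blanket smoothing: a channel is
replaced by its running median (window 5, `scipy.ndimage.median_filter`,
edge mode "nearest") only when its deviation from that median exceeds 5×
the robust scale (1.4826 × MAD) of the residuals. Two details matter:

- Detection/replacement iterates to a fixpoint (clusters of spikes shield
  each other from a single pass); this also makes the operation idempotent.
- The scale is floored at 1% of the intensity range
  (`despike_scale_floor`). On (near-)noiseless spectra the residual MAD
  collapses toward zero and the tiny deviation of a genuine peak top from
  its running median would otherwise be flagged; real cosmic spikes exceed
  the spectral range by construction, so a 5% -of-range threshold never
  hides one.

**Baseline removal** is the iterative peak-excluding polynomial fit: fit a
degree-5 polynomial (`numpy.polynomial.Polynomial.fit`, internally scaled
domain for conditioning), clip points above the fit down to it, refit;
stop when the maximum baseline change per iteration falls below `poly_tol`
(10⁻⁴) of the intensity range or after `poly_max_iter` (100) iterations.
On noisy spectra the clipping step keeps descending through the noise
floor at a slowly decaying rate, so reaching the iteration cap is routine
and benign; the outcome is recorded as `baseline_converged` in the result
metadata instead of raising. The subtracted spectrum plus the returned
baseline reconstructs the input exactly.

**Vector normalization** divides by the Euclidean norm, making the full
chain invariant to global multiplicative intensity changes (laser-power
drift); an all-zero spectrum is a degenerate-input error.

`preprocess_raman` returns every intermediate stage (`PreprocessResult`)
so each step can be audited after the fact.

## Analysis statistics

**Peak detection** uses `scipy.signal.find_peaks` with a prominence
threshold relative to the spectrum maximum and a minimum separation in
axis units. Centers are refined by fitting a quadratic over the channels
within half the estimated FWHM of the maximum, degenerating to the classic
3-point parabola for narrow peaks. The wide symmetric fit averages channel
noise down by roughly the square root of the number of points used; with
tissue-like bands (FWHM 10–18 cm⁻¹, amplitude-to-noise 10) it brings the
mean center error from ≈1.4 cm⁻¹ (3-point) to ≈0.4 cm⁻¹, which is what
makes sub-wavenumber recovery achievable at realistic noise.

**Assignment** matches detected peaks to the shipped vibrational-mode
library greedily by ascending |Δcenter| within a tolerance of ±8 cm⁻¹
(half the closest spacing in the library); each library row is used at
most once. The same greedy matching classifies peaks from the lensed vs
offset configurations into common / lensed-only / offset-only sets.

**SNR** of a peak across replicates is the mean of the per-replicate peak
heights (maximum intensity within ±window/2 of the nominal center) divided
by their **sample** (n−1) standard deviation — replicate counts of ~5 are
typical, where the n−1 convention matters. Heights are read from
baseline-subtracted but **non**-vector-normalized spectra: normalization
would divide out exactly the across-replicate intensity variation the SNR
is supposed to measure. Identical replicates (zero variance) are an error,
not an infinite SNR.

**Trough location** smooths the reflectance with a 5-channel moving
average, takes the global minimum in the search band (default 550–700 nm),
and refines with a quadratic fit over ±10 channels; dye absorption bands
are tens of nm wide, so the wide fit is appropriate and a band-edge
minimum (monotone spectrum) is reported as "no trough" rather than a
wavelength. `reflectance_ratio` interpolates point values by default and
can average over ±2 nm bands.

**Depth curves** average replicates per thickness, evaluate a probe value
(peak height or reflectance ratio), and normalize by the thickness-0
value, which must be present.

## Laser safety

Only continuous-wave skin rules in 400–1400 nm are implemented: the
wavelength correction `C_A` (1 below 700 nm, `10^{0.002(λ−700)}` to
1050 nm, 5 above), the radiant-exposure limit `1.1·C_A·t^{0.25}` J/cm² for
10⁻⁷ s ≤ t ≤ 10 s, and the `0.2·C_A` W/cm² average-irradiance limit for
longer exposures. At exactly t = 10 s the short-exposure branch applies;
the branches agree there within 3%. MPE comparisons use the beam power
averaged over the **3.5 mm limiting aperture**, the measurement aperture
the skin standard prescribes: a 1 mm spot at 40 mW has a raw irradiance of
5.09 W/cm², far above any skin MPE, yet the aperture-averaged 0.416 W/cm²
is below the 5 s limit of 0.487 W/cm² — which is the arithmetic that makes
a 5 s, 40 mW skin exposure permissible, with a maximum permissible
duration of 6.17 s from the closed form `(1.1·C_A/E)^{4/3}`. The raw-beam,
aperture-averaged, and MPE figures are all reported side by side rather
than collapsed into one number, since published summaries quote different
ones.

## Forward simulator

The simulator produces the statistical structure the pipeline assumes, not
tissue physics:

- **Raman**: sum of Gaussian/Lorentzian bands plus a smooth polynomial
  autofluorescence background (coefficients over the normalized axis
  coordinate, so they stay O(counts)), Gaussian read noise, optional
  Poisson shot noise, and Poisson-count single-channel cosmic spikes with
  uniform amplitude in 500–5000 counts. Replicate r draws from a stream
  seeded `seed XOR r`; everything is bit-reproducible.
- **Fixture libraries**: muscle = protein bands (1002, 1339, 1645 cm⁻¹);
  fat = lipid bands (1448 dominant, 1736 cm⁻¹).
- **Two-layer weighting**: the bottom (fat) layer contributes
  `w(d) = exp(−d/δ)` under d mm of muscle — a phenomenological monotone
  stand-in for layered radiative transport, *not* a photon-transport
  model. Default sensing depths are back-computed so that 2 mm of muscle
  leaves 64% of the fat signal in the offset configuration
  (δ = −2/ln 0.64 ≈ 4.48 mm) and 49% in the lensed configuration
  (δ = −2/ln 0.49 ≈ 2.80 mm); these retention figures are therefore
  construction identities of the defaults, not predictions.
- **DRS**: a halogen-like smooth lamp profile, dark level of 30 counts,
  and layer reflectances sharing one gently sloped spectral shape with
  different albedos (muscle 0.35, fat 0.58), the fat layer multiplied by
  `exp(−dye_strength·B(λ))` with B a unit-height Gaussian band at 635 nm
  (FWHM 50 nm, strength 1.5 — a deep but not saturated trough for a fat
  layer soaked in concentrated dye). Sharing the shape makes the
  `R635/R730` ratio exactly thickness-independent when the dye is absent,
  isolating the dye as the only ratio signal. The DRS depth weight uses
  the offset-fiber sensing depth, matching the instrument's offset DRS
  collection geometry. The simulated standard is the lamp times 0.8 plus
  dark, so the triplet feeds the calibration unchanged.
- **CCD frames**: each fiber ROI carries the spectrum scaled by its gain,
  split across its rows so that vertical binning returns gain × spectrum;
  read noise everywhere. A brighter lensed block is just a larger gain.
- **Acetaminophen**: calibrant peaks rendered on the pixel axis through
  the inverse of a chosen true wavenumber map, for closed-loop calibration
  tests. Default integration times (0.5 s DRS / 5 s Raman), laser power
  (40 mW) and probe throughput (45% of source power at the sample) follow
  the reference instrument's operating point.

**What passing tests show — and don't.** The synthetic bench validates the
*software*: algebraic identities, parameter recovery under known noise,
monotone depth trends, reproducibility. It does not validate tissue
claims: real autofluorescence is not polynomial, real layered transport is
not single-exponential, chicken-tissue optics differ from human tissue,
and the in vivo SNR figures (≈10 lensed, ≈5.8 offset at 1339 cm⁻¹) depend
on raw measurements no simulator default can stand in for. Those numbers
seed simulator settings; they are not reproduced results.

## Problem sizes

Default grids: 1551-channel Raman axis (350–1900 cm⁻¹ at 1 cm⁻¹),
351-channel DRS axis (450–800 nm at 1 nm), 1024-pixel calibrant spectra,
and 50-replicate recovery studies — sizes chosen to exercise every code
path at interactive speed while keeping statistical estimates (noise SD,
center errors) stable to the asserted tolerances.

## Known limitations

- The wavenumber calibration pairs detected and reference peaks 1:1 in
  ascending order; spectra where some reference bands are undetectable or
  extra bands outrank them in prominence need a user-supplied reference
  list matching what is visible.
- The exponential two-layer model cannot represent non-monotone depth
  effects (e.g. specular artifacts at thin layers).
- Skin MPE only; no eye exposure, no repetitive-pulse rules, no
  extended-source corrections.
- The despike scale floor assumes cosmic spikes are large relative to the
  spectral range; faint spikes comparable to genuine peaks are left alone
  by design.
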