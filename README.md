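# mmspec

Software data path for a multimodal tissue-optics instrument that combines
**diffuse reflectance spectroscopy (DRS)** with **spatially offset Raman
spectroscopy (SORS)** through a single fiber-optic probe. The probe carries a
zero-offset ball-lens fiber group for superficial sampling and spatially
offset collection fibers (1.5 mm for Raman, 2.5 mm for DRS) for subsurface
sampling. `mmspec` implements everything that happens to the photons after
the detector: calibration, spectral preprocessing, quantitative statistics,
laser-safety arithmetic — plus a forward simulator of the instrument and of
two-layer tissue phantoms, so the entire pipeline is testable without
hardware.

Intended users: biomedical-optics groups building or validating fiber-probe
DRS/Raman systems who need a reference implementation of the standard
processing chain and a synthetic test bench for it.

## What it computes

**Diffuse reflectance.** Raw counts are converted to reflectance against a
diffuse standard of known reflectivity (80% Spectralon by default):

    R(λ) = (I_sample(λ) − I_bg(λ)) / (I_standard(λ) − I_bg(λ))

reported over a configurable band (475–600 nm by default). A dye absorption
trough in `R` is located by smoothed minimum search with sub-channel
quadratic refinement, and tracked through overlying tissue via the ratio
`R(635)/R(730)` of the absorbing to a non-absorbing wavelength.

**Raman preprocessing.** The wavenumber axis is calibrated against
acetaminophen (pixel → cm⁻¹ polynomial fit through the standard calibrant
shifts); then: cosmic-spike removal (detect-and-replace against a running
median, iterated to a fixpoint), crop to the 600–1800 cm⁻¹ fingerprint
region, autofluorescence removal by an iterative peak-excluding fifth-order
polynomial fit, and vector normalization (`y / ‖y‖₂`) to cancel laser-power
variation.

**Statistics.** Peak detection with sub-channel refinement and assignment to
a shipped biomolecular vibrational-mode library; replicate signal-to-noise
ratio `SNR = mean(h) / sd(h)` of a peak height `h` across repeated
measurements; normalized depth-sensitivity curves for the lensed vs offset
fiber configurations.

**Laser safety.** ANSI Z136.1-style continuous-wave skin exposure limits in
the 400–1400 nm band: beam irradiance `P/(πr²)`, irradiance averaged over
the 3.5 mm skin limiting aperture, the skin MPE
`1.1·C_A·t^0.25 J/cm²` (t ≤ 10 s) / `0.2·C_A W/cm²` (t > 10 s) with
`C_A = 10^{0.002(λ−700)}`, and the longest permissible exposure duration
`t = (1.1·C_A/E)^{4/3}`.

**Forward simulator.** Raman spectra as narrow Gaussian/Lorentzian bands on
a smooth autofluorescence background with read noise, optional shot noise
and rare single-channel cosmic spikes; DRS triplets (sample / standard /
background) with a Gaussian dye band; CCD frames with fiber-row blocks; and
two-layer phantoms (dyed fat under muscle of thickness *d*) whose bottom
layer contributes `w(d) = exp(−d/δ)` with effective sensing depths
δ = 4.48 mm (offset) and 2.80 mm (lensed) — so the offset fibers retain
~64% and the lensed fibers ~49% of the bare-fat signal under 2 mm of
muscle. All generators are bit-reproducible from a seed.

## Worked example

```python
import numpy as np
from mmspec import (
    CalibrationBundle, NoiseSpec, PhantomSpec, MUSCLE_PEAKS,
    simulate_two_layer_drs, simulate_raman_measurement,
    compute_reflectance, find_absorption_trough, reflectance_ratio,
    preprocess_raman, detect_peaks, assign_peaks,
)

# DRS: simulate a dyed-fat phantom with no overlying muscle, calibrate,
# and locate the dye absorption trough
sample, standard, background = simulate_two_layer_drs(
    PhantomSpec(muscle_thickness_mm=0.0), NoiseSpec(additive_sd=2.0, seed=1)
)
bundle = CalibrationBundle(background_drs=background, standard=standard)
reflectance = compute_reflectance(sample, bundle, band_nm=(500.0, 780.0))
print(f"dye trough: {find_absorption_trough(reflectance):.1f} nm")
print(f"R635/R730 ratio: {reflectance_ratio(reflectance):.3f}")

# Raman: preprocess a noisy simulated muscle spectrum and assign its peaks
raw = simulate_raman_measurement(
    MUSCLE_PEAKS, baseline_coeffs=(200.0, 300.0, -150.0),
    noise=NoiseSpec(additive_sd=3.0, spike_rate=2.0, seed=1),
)[0]
result = preprocess_raman(raw)
for peak, row in assign_peaks(detect_peaks(result.spectrum,
                                           min_prominence=0.3,
                                           min_separation=20.0)):
    print(f"  {peak.center:7.1f} cm^-1  ->  "
          f"{row.biomolecule if row else 'unassigned'}")
```

prints

```
dye trough: 634.8 nm
R635/R730 ratio: 0.212
   1002.1 cm^-1  ->  Protein
   1338.8 cm^-1  ->  Protein/nucleic acid
   1645.2 cm^-1  ->  Protein
```

The trough sits at the dye band center (635 nm) to within half a
nanometre; the low `R635/R730` reflects strong dye absorption with the fat
layer fully exposed; and the three generator bands (phenylalanine ring
breathing at 1002, CH₂/CH₃ wag at 1339, amide I at 1645 cm⁻¹) come back at
their true positions to ~0.2 cm⁻¹ despite the spikes, autofluorescence
background, and noise.

The same workflows are scriptable from the shell, e.g.

```
mmspec safety --power-mw 40 --radius-cm 0.05 --wavelength-nm 785 --exposure-s 5
mmspec simulate drs --seed 3 --out drs/
mmspec reflectance --sample drs/sample.txt --standard drs/standard.txt \
       --background drs/background.txt --band 500 780 --output refl.txt
```

The `safety` command reports a beam irradiance of 5.093 W/cm², an
aperture-averaged irradiance of 0.4158 W/cm² (below the 0.4866 W/cm² MPE
for a 5 s exposure), and a maximum permissible exposure time of 6.17 s —
the arithmetic behind running 40 mW for 5 s on skin.

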