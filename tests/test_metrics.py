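"""Peak detection/assignment, SNR, trough ratio, depth sensitivity."""

import numpy as np
import pytest

from mmspec import (
    CalibrationBundle,
    NoiseSpec,
    Peak,
    PeakAssignmentTable,
    PhantomSpec,
    SpectralAxis,
    Spectrum,
    assign_peaks,
    compare_fiber_configurations,
    compute_reflectance,
    compute_snr,
    depth_sensitivity_curve,
    detect_peaks,
    find_absorption_trough,
    reflectance_ratio,
    simulate_two_layer_drs,
    simulate_two_layer_raman,
)
from mmspec.errors import (
    DegenerateInputError,
    InsufficientReplicatesError,
    NormalizationError,
    NoTroughError,
)

from conftest import gaussian

THICKNESS_SWEEP = np.arange(0.0, 6.1, 0.5)


def raman(x, y):
    return Spectrum(SpectralAxis(x, "raman_shift_cm-1"), y)


def drs(x, y):
    return Spectrum(SpectralAxis(x, "wavelength_nm"), y)


class TestDetectPeaks:
    def test_single_gaussian_center_recovered(self):
        x = np.arange(600.0, 1801.0)
        peaks = detect_peaks(raman(x, gaussian(x, 1339.0, 100.0, 14.0)))
        assert len(peaks) == 1
        assert abs(peaks[0].center - 1339.0) < 0.5

    def test_flat_spectrum_empty(self):
        x = np.arange(600.0, 1801.0)
        assert detect_peaks(raman(x, np.full(x.size, 5.0))) == []

    def test_close_doublet_merged_under_min_separation(self):
        # brute-force local-maximum oracle: with min_separation 30 the two
        # maxima 10 cm^-1 apart cannot both survive; the taller one wins
        x = np.arange(600.0, 1801.0)
        y = gaussian(x, 1000.0, 100.0, 8.0) + gaussian(x, 1010.0, 60.0, 8.0)
        peaks = detect_peaks(raman(x, y), min_separation=30.0)
        maxima = [
            i
            for i in range(1, x.size - 1)
            if y[i] > y[i - 1] and y[i] >= y[i + 1]
        ]
        tallest = x[max(maxima, key=lambda i: y[i])]
        assert len([p for p in peaks if 980 < p.center < 1030]) == 1
        detected = next(p for p in peaks if 980 < p.center < 1030)
        assert abs(detected.center - tallest) < 2.0


class TestAssignPeaks:
    def make_peak(self, center):
        return Peak(center=center, height=10.0, prominence=8.0, fwhm=10.0)

    def test_dna_phosphate_band_assignment(self):
        table = PeakAssignmentTable.default()
        result = assign_peaks([self.make_peak(1089.4)], table)
        assert result[0][1] is not None
        assert "PO2" in result[0][1].vibrational_mode
        assert result[0][1].center_cm1 == 1089.0

    def test_empty_peak_list(self):
        assert assign_peaks([]) == []

    def test_nearest_match_wins(self):
        table = PeakAssignmentTable.default()
        result = assign_peaks([self.make_peak(1000.0)], table, tolerance_cm1=8.0)
        assert result[0][1].center_cm1 == 1002.0

    def test_unmatched_is_unassigned(self):
        result = assign_peaks([self.make_peak(760.0)], tolerance_cm1=8.0)
        assert result[0][1] is None


class TestSNR:
    def make_replicates(self, heights):
        x = np.arange(1300.0, 1381.0)
        return [raman(x, gaussian(x, 1339.0, h, 14.0)) for h in heights]

    def test_hand_computed_snr_9_10_11(self):
        # mean 10, sample sd 1 -> SNR exactly 10
        snr = compute_snr(self.make_replicates([9.0, 10.0, 11.0]), 1339.0, window=20.0)
        assert snr == pytest.approx(10.0, abs=1e-12)

    def test_identical_replicates_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_snr(self.make_replicates([10.0, 10.0, 10.0]), 1339.0)

    def test_too_few_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            compute_snr(self.make_replicates([9.0, 11.0]), 1339.0)

    def test_positive_scale_invariance(self):
        reps = self.make_replicates([8.0, 10.0, 12.0, 9.5])
        snr = compute_snr(reps, 1339.0)
        scaled = [r.with_intensities(37.0 * r.y) for r in reps]
        assert compute_snr(scaled, 1339.0) == pytest.approx(snr, rel=1e-12)

    def test_monte_carlo_consistency(self):
        # heights mu + N(0, sigma): SNR -> mu/sigma = 10 within 20% at n=100
        rng = np.random.default_rng(101)
        x = np.arange(1330.0, 1349.0)
        mu, sigma = 50.0, 5.0
        reps = []
        for _ in range(100):
            y = np.zeros(x.size)
            y[9] = mu + rng.normal(0.0, sigma)
            reps.append(raman(x, y))
        snr = compute_snr(reps, 1339.0, window=1.0)
        assert abs(snr - mu / sigma) / (mu / sigma) < 0.2


class TestReflectanceRatio:
    def test_flat_spectrum_unity(self):
        x = np.arange(550.0, 801.0)
        assert reflectance_ratio(drs(x, np.full(x.size, 0.7))) == pytest.approx(1.0)

    def test_constructed_half_ratio(self):
        x = np.arange(550.0, 801.0)
        y = np.where(x < 680.0, 0.5, 1.0)
        assert reflectance_ratio(drs(x, y)) == pytest.approx(0.5)

    def test_band_average_option(self):
        x = np.arange(550.0, 801.0)
        y = np.ones(x.size)
        y[x == 635.0] = 0.0  # single-channel dip diluted by the +/-2 nm band
        point = reflectance_ratio(drs(x, y))
        banded = reflectance_ratio(drs(x, y), band_halfwidth_nm=2.0)
        assert point == pytest.approx(0.0)
        assert banded == pytest.approx(0.8)

    def test_monotone_in_muscle_thickness_noiseless(self):
        ratios = []
        for d in THICKNESS_SWEEP:
            sample, standard, background = simulate_two_layer_drs(
                PhantomSpec(muscle_thickness_mm=float(d)), NoiseSpec()
            )
            bundle = CalibrationBundle(background_drs=background, standard=standard)
            refl = compute_reflectance(sample, bundle, band_nm=(500.0, 780.0))
            ratios.append(reflectance_ratio(refl))
        assert np.all(np.diff(ratios) > 0)


class TestTrough:
    def test_v_shape_vertex(self):
        x = np.arange(550.0, 701.0)
        spec = drs(x, np.abs(x - 635.0))
        assert find_absorption_trough(spec, (560.0, 690.0)) == pytest.approx(635.0, abs=0.01)

    def test_monotone_spectrum_raises(self):
        x = np.arange(550.0, 701.0)
        with pytest.raises(NoTroughError):
            find_absorption_trough(drs(x, x / 700.0), (560.0, 690.0))

    def test_simulated_phantom_trough_recovery(self):
        sample, standard, background = simulate_two_layer_drs(
            PhantomSpec(muscle_thickness_mm=0.0), NoiseSpec()
        )
        bundle = CalibrationBundle(background_drs=background, standard=standard)
        refl = compute_reflectance(sample, bundle, band_nm=(500.0, 780.0))
        assert abs(find_absorption_trough(refl) - 635.0) < 2.0


class TestDepthCurve:
    def test_identical_spectra_all_unity(self):
        x = np.arange(600.0, 700.0)
        spec = raman(x, np.full(x.size, 3.0))
        curve = depth_sensitivity_curve(
            [(d, [spec]) for d in (0.0, 1.0, 2.0)], lambda s: float(np.max(s.y))
        )
        np.testing.assert_allclose(curve.values, 1.0, rtol=1e-15)

    def test_exponential_forward_model_closed_form(self):
        x = np.arange(600.0, 700.0)
        delta = 4.48
        measurements = [
            (float(d), [raman(x, np.full(x.size, np.exp(-d / delta)))])
            for d in THICKNESS_SWEEP
        ]
        curve = depth_sensitivity_curve(measurements, lambda s: float(np.mean(s.y)))
        np.testing.assert_allclose(
            curve.values, np.exp(-THICKNESS_SWEEP / delta), atol=1e-9
        )

    def test_missing_reference_thickness(self):
        x = np.arange(600.0, 700.0)
        spec = raman(x, np.ones(x.size))
        with pytest.raises(NormalizationError):
            depth_sensitivity_curve([(1.0, [spec]), (2.0, [spec])], lambda s: 1.0)

    def test_offset_curve_dominates_lensed_curve(self):
        # deeper sensing of the offset fibers keeps more bottom-layer signal
        def curve_for(config):
            measurements = []
            for d in THICKNESS_SWEEP:
                spec = simulate_two_layer_raman(
                    PhantomSpec(muscle_thickness_mm=float(d)), config, NoiseSpec()
                )
                measurements.append((float(d), [spec]))

            def probe(s):
                sel = np.abs(s.x - 1448.0) < 15.0
                return float(np.max(s.y[sel]))

            return depth_sensitivity_curve(measurements, probe)

        lensed = curve_for("lensed")
        offset = curve_for("offset")
        assert np.all(offset.values[1:] > lensed.values[1:])
        assert lensed.values[0] == 1.0 and offset.values[0] == 1.0


class TestCompareConfigurations:
    def test_table_flags_reproduce_unique_peaks(self):
        table = PeakAssignmentTable.default()
        mk = lambda c: Peak(center=c, height=5.0, prominence=4.0, fwhm=10.0)
        lensed = [mk(r.center_cm1) for r in table if r.present_lensed]
        offset = [mk(r.center_cm1) for r in table if r.present_offset_1p5]
        common, lensed_only, offset_only = compare_fiber_configurations(lensed, offset)
        lensed_centers = {p.center for p in lensed_only}
        offset_centers = {p.center for p in offset_only}
        assert {937.0, 1755.0} <= lensed_centers
        assert {718.0, 1089.0} <= offset_centers
        assert all(a.center == b.center for a, b in common)

    def test_identical_lists_all_common(self):
        peaks = [Peak(center=c, height=1.0, prominence=1.0, fwhm=5.0) for c in (700.0, 900.0)]
        common, lensed_only, offset_only = compare_fiber_configurations(peaks, peaks)
        assert len(common) == 2 and not lensed_only and not offset_only

    def test_disjoint_lists_no_common(self):
        a = [Peak(center=700.0, height=1.0, prominence=1.0, fwhm=5.0)]
        b = [Peak(center=1500.0, height=1.0, prominence=1.0, fwhm=5.0)]
        common, lensed_only, offset_only = compare_fiber_configurations(a, b)
        assert not common and len(lensed_only) == 1 and len(offset_only) == 1
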