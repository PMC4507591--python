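"""Optical-constant extraction: averaging, FFT conventions, deconvolution,
inversion formulas, matrix assembly."""

import numpy as np
import pytest
from scipy.constants import c as C

from thzchem.containers import (
    FrequencySpectrum,
    OpticalProperties,
    SampleGeometry,
    TimeDomainTrace,
    TransferFunction,
)
from thzchem.extraction import (
    absorption_coefficient,
    average_scans,
    build_matrix,
    extract_optical_properties,
    refractive_index,
    to_frequency,
    transfer_function,
)
from thzchem.simulate import (
    InstrumentModel,
    alpha_to_k,
    make_reference_pulse,
    propagate,
)


def _trace(amps, dt=0.02):
    amps = np.asarray(amps, float)
    return TimeDomainTrace(np.arange(amps.size) * dt, amps)


def _flat_props(f, n, alpha):
    n_arr = np.full_like(f, float(n))
    a_arr = np.full_like(f, float(alpha))
    return OpticalProperties(f, n_arr, alpha_to_k(a_arr, f), a_arr)


def _simulated_pair(n=1.5, alpha=10.0, d_mm=1.0, instrument=None):
    """Noiseless reference trace + sample trace through a flat slab."""
    inst = instrument or InstrumentModel(
        amplitude_noise_sd=0.0, additive_noise_sd=0.0
    )
    geom = SampleGeometry(thickness_d=d_mm)
    ref = make_reference_pulse(inst, 0)
    ref_spec = to_frequency(ref)
    props = _flat_props(ref_spec.frequencies, n, alpha)
    sam_spec = propagate(ref_spec, props, geom)
    sam = TimeDomainTrace(
        inst.delays, np.fft.irfft(sam_spec.complex_amplitudes, inst.n_points)
    )
    return sam, ref, geom


class TestAverageScans:
    def test_idempotent_on_identical_scans(self):
        tr = _trace(np.sin(np.arange(64)))
        out = average_scans([tr, tr, tr])
        np.testing.assert_allclose(out.amplitudes, tr.amplitudes, rtol=1e-15)

    def test_pointwise_mean(self):
        out = average_scans([_trace(np.full(64, v)) for v in (1.0, 2.0, 3.0)])
        np.testing.assert_allclose(out.amplitudes, 2.0)

    def test_mismatched_grid_names_offender(self):
        a = _trace(np.zeros(64), dt=0.02)
        b = _trace(np.zeros(64), dt=0.03)
        with pytest.raises(ValueError, match="scan 2"):
            average_scans([a, b])

    def test_noise_reduction_by_sqrt3(self):
        """Averaging 3 scans of iid noise shrinks the SD by ~1/sqrt(3)."""
        rng = np.random.default_rng(0)
        pooled = []
        for _ in range(400):
            scans = [_trace(rng.normal(0, 1.0, 64)) for _ in range(3)]
            pooled.append(average_scans(scans).amplitudes)
        sd = np.std(np.concatenate(pooled))
        assert abs(sd - 1.0 / np.sqrt(3)) < 0.02


class TestToFrequency:
    def test_pure_cosine_peaks_at_its_bin(self):
        t = np.arange(100) * 0.01  # 1 ps record -> 1 THz resolution
        tr = TimeDomainTrace(t, np.cos(2 * np.pi * 5.0 * t))
        spec = to_frequency(tr)
        assert spec.frequencies[np.argmax(spec.amplitude)] == pytest.approx(5.0)

    def test_parseval(self, quiet_instrument):
        tr = make_reference_pulse(quiet_instrument, 0)
        spec = to_frequency(tr)
        n = tr.n_points
        e_time = np.sum(tr.amplitudes**2)
        mags = np.abs(spec.complex_amplitudes) ** 2
        # one-sided weights: DC and Nyquist once, interior twice
        e_freq = (mags[0] + mags[-1] + 2 * np.sum(mags[1:-1])) / n
        assert abs(e_time - e_freq) / e_time < 1e-9

    def test_shift_theorem(self, quiet_instrument):
        """Delaying by m samples multiplies bins by exp(-i 2 pi f m dt)."""
        tr = make_reference_pulse(quiet_instrument, 0)
        m = 37
        shifted = TimeDomainTrace(tr.delays, np.roll(tr.amplitudes, m))
        a = to_frequency(tr)
        b = to_frequency(shifted)
        keep = a.amplitude > 1e-3 * a.amplitude.max()
        expected = np.exp(-2j * np.pi * a.frequencies * m * tr.time_step)
        np.testing.assert_allclose(
            (b.complex_amplitudes / a.complex_amplitudes)[keep],
            expected[keep],
            atol=1e-9,
        )

    def test_zero_pad_refines_grid_and_short_pad_rejected(self):
        tr = _trace(np.zeros(64))
        fine = to_frequency(tr, zero_pad_to=128)
        coarse = to_frequency(tr)
        assert fine.frequencies.size == 65 and coarse.frequencies.size == 33
        with pytest.raises(ValueError):
            to_frequency(tr, zero_pad_to=32)


class TestTransferFunction:
    def _spectra(self, scale=1.0):
        f = np.linspace(0.05, 2.0, 200)
        ref = FrequencySpectrum(f, np.ones(200, complex))
        sam = FrequencySpectrum(f, scale * np.ones(200, complex))
        return sam, ref

    def test_identity(self):
        sam, ref = self._spectra(1.0)
        tf = transfer_function(sam, ref, band=(0.2, 1.5))
        np.testing.assert_allclose(tf.rho, 1.0)
        np.testing.assert_allclose(tf.phi, 0.0, atol=1e-12)

    def test_pure_scaling(self):
        sam, ref = self._spectra(0.5)
        tf = transfer_function(sam, ref, band=(0.2, 1.5))
        np.testing.assert_allclose(tf.rho, 0.5)
        np.testing.assert_allclose(tf.phi, 0.0, atol=1e-12)

    def test_phase_matches_forward_model(self, geometry):
        sam, ref, geom = _simulated_pair(n=1.5, alpha=0.0)
        tf = transfer_function(
            to_frequency(sam), to_frequency(ref), band=(0.2, 1.5)
        )
        expected = 2 * np.pi * tf.frequencies * 1e12 * 0.5 * 1e-3 / C
        np.testing.assert_allclose(tf.phi, expected, atol=1e-6)

    def test_unwrap_robust_to_3mm_equivalent_delay(self):
        # (n-1)*d = 3 mm of excess optical path: many 2 pi wraps
        sam, ref, geom = _simulated_pair(n=2.5, alpha=0.0, d_mm=2.0)
        tf = transfer_function(
            to_frequency(sam), to_frequency(ref), band=(0.2, 1.5)
        )
        expected = 2 * np.pi * tf.frequencies * 1e12 * 1.5 * 2e-3 / C
        np.testing.assert_allclose(tf.phi, expected, atol=1e-6)

    def test_dead_reference_bins_reported(self):
        f = np.linspace(0.1, 2.0, 100)
        amps = np.ones(100, complex)
        amps[30] = 1e-9
        ref = FrequencySpectrum(f, amps)
        sam = FrequencySpectrum(f, np.ones(100, complex))
        with pytest.raises(ValueError, match="below floor"):
            transfer_function(sam, ref, band=(0.2, 1.5))


class TestInversionFormulas:
    def test_zero_phase_gives_vacuum_index(self, geometry):
        f = np.linspace(0.2, 1.5, 50)
        tf = TransferFunction(f, np.ones(50), np.zeros(50))
        np.testing.assert_allclose(refractive_index(tf, geometry), 1.0)

    def test_planted_phase_inverts_to_planted_index(self, geometry):
        f = np.linspace(0.2, 1.5, 50)
        phi = 2 * np.pi * f * 1e12 * 0.5 * 1e-3 / C
        tf = TransferFunction(f, np.ones(50), phi)
        np.testing.assert_allclose(refractive_index(tf, geometry), 1.5, rtol=1e-12)

    def test_lossless_fresnel_gives_zero_absorption(self, geometry):
        f = np.linspace(0.2, 1.5, 50)
        n = np.full(50, 1.5)
        rho = np.full(50, 4 * 1.5 / 2.5**2)
        tf = TransferFunction(f, rho, np.zeros(50))
        np.testing.assert_allclose(
            absorption_coefficient(tf, n, geometry), 0.0, atol=1e-12
        )

    def test_hand_evaluated_absorption(self, geometry):
        # rho = 0.96 * e^-1, n = 1.5, d = 1 mm -> alpha = 20 cm^-1
        f = np.linspace(0.2, 1.5, 8)
        tf = TransferFunction(f, np.full(8, 0.96 * np.exp(-1)), np.zeros(8))
        alpha = absorption_coefficient(tf, np.full(8, 1.5), geometry)
        np.testing.assert_allclose(alpha, 20.0, rtol=1e-12)

    def test_zero_rho_rejected(self, geometry):
        f = np.linspace(0.2, 1.5, 8)
        tf = TransferFunction(f, np.zeros(8), np.zeros(8))
        with pytest.raises(ValueError, match="rho"):
            absorption_coefficient(tf, np.full(8, 1.5), geometry)

    def test_negative_alpha_flagged_not_clipped(self, geometry):
        f = np.linspace(0.2, 1.5, 8)
        rho = np.full(8, 1.01 * 4 * 1.5 / 2.5**2)  # above lossless ratio
        tf = TransferFunction(f, rho, np.zeros(8))
        with pytest.warns(UserWarning, match="negative"):
            alpha = absorption_coefficient(tf, np.full(8, 1.5), geometry)
        assert np.all(alpha < 0)


class TestRoundTrip:
    @pytest.mark.parametrize("n,alpha", [(1.4, 5.0), (1.5, 40.0), (2.0, 25.0)])
    def test_flat_slab_round_trip(self, n, alpha):
        sam, ref, geom = _simulated_pair(n=n, alpha=alpha)
        props = extract_optical_properties(sam, ref, geom, band=(0.3, 1.4))
        np.testing.assert_allclose(props.n, n, atol=1e-6)
        np.testing.assert_allclose(props.alpha, alpha, atol=1e-6)

    def test_units_audit_thickness_declared_in_other_units(self):
        """The same physical thickness declared in mm, um or m yields the
        same absorption spectrum in cm^-1."""
        sam, ref, _ = _simulated_pair(n=1.5, alpha=30.0)
        results = []
        for d, unit in [(1.0, "mm"), (1000.0, "um"), (1e-3, "m")]:
            geom = SampleGeometry(thickness_d=d, thickness_unit=unit)
            props = extract_optical_properties(sam, ref, geom, band=(0.3, 1.4))
            results.append(props.alpha)
        np.testing.assert_allclose(results[0], results[1], rtol=1e-12)
        np.testing.assert_allclose(results[0], results[2], rtol=1e-12)


class TestBuildMatrix:
    def _props_list(self, values, f=None):
        f = np.linspace(0.1, 1.6, 151) if f is None else f
        out = []
        for v in values:
            a = np.full_like(f, float(v))
            out.append(OpticalProperties(f, np.full_like(f, 1.5), alpha_to_k(a, f), a))
        return out

    def test_matrix_width_128(self):
        props = self._props_list([40.0, 41.0])
        X = build_matrix(props, [1, 2], band=(0.2, 1.5), n_variables=128)
        assert X.X.shape == (2, 128)
        assert X.variable_frequencies[0] == 0.2
        assert X.variable_frequencies[-1] == 1.5

    def test_grid_identity_interpolation(self):
        grid = np.linspace(0.2, 1.5, 64)
        rng = np.random.default_rng(0)
        a = 40 + rng.normal(size=64)
        props = OpticalProperties(
            grid, np.full(64, 1.5), alpha_to_k(a, grid), a
        )
        X = build_matrix([props], [1], band=(0.2, 1.5), n_variables=64)
        np.testing.assert_allclose(X.X[0], a, rtol=1e-12)

    def test_constant_feature_gives_constant_row(self):
        X = build_matrix(self._props_list([40.0]), [1], n_variables=16)
        np.testing.assert_allclose(X.X[0], 40.0)

    def test_refractive_index_feature(self):
        X = build_matrix(
            self._props_list([40.0]), [1], n_variables=8, feature="refractive_index"
        )
        np.testing.assert_allclose(X.X[0], 1.5)

    def test_sample_not_covering_band_rejected(self):
        f = np.linspace(0.4, 1.2, 50)
        props = self._props_list([40.0], f=f)
        with pytest.raises(ValueError, match="covers"):
            build_matrix(props, [1], band=(0.2, 1.5), n_variables=16)
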