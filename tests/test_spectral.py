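"""Cross-spectral estimator and band filter: examples and invariants."""

import numpy as np
import pytest
from scipy import signal as sps

import xfcacoh as xc
from xfcacoh.exceptions import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
    ShapeError,
)
from xfcacoh.spectral import (
    blocks_from_coeffs,
    estimate_cross_spectra,
    segment_dft_at_bin,
)

from conftest import FS, tone


def white(n, seed, fs=FS):
    rng = np.random.default_rng(seed)
    return xc.TimeSeriesSet(rng.standard_normal(n)[None, :], fs)


def coherence_mag(cs):
    return np.abs(cs.cab[:, 0, 0]) / np.sqrt(
        np.real(cs.caa[:, 0, 0]) * np.real(cs.cbb[:, 0, 0])
    )


class TestEstimateCrossSpectra:
    def test_identical_signals_have_unit_coherence(self):
        a = white(30000, 0)
        cs = estimate_cross_spectra(a, a)
        assert np.allclose(coherence_mag(cs), 1.0, atol=1e-12)

    def test_independent_noise_coherence_near_null_level(self):
        # 300 s, 1 s segments: null coherence magnitude ~ 1/sqrt(K)
        a, b = white(150000, 1), white(150000, 2)
        cs = estimate_cross_spectra(a, b)
        thresh = 3.0 / np.sqrt(cs.n_segments)
        assert np.mean(coherence_mag(cs) < thresh) >= 0.95

    def test_sinusoid_pair_phase_convention(self):
        # b lags a by pi/4 at 3 Hz => arg(cab) = -pi/4
        a = tone(3.0, 20.0)
        b = tone(3.0, 20.0, phase=np.pi / 4)
        cs = estimate_cross_spectra(a, b, segment_len_s=1.0)
        k = xc.nearest_bin(cs.freqs, 3.0)
        assert np.angle(cs.cab[k, 0, 0]) == pytest.approx(-np.pi / 4, abs=0.01)

    def test_joint_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        a = xc.TimeSeriesSet(rng.standard_normal((3, 20000)), FS)
        b = xc.TimeSeriesSet(rng.standard_normal((2, 20000)), FS)
        cs = estimate_cross_spectra(a, b)
        joint = cs.joint()
        ev = np.linalg.eigvalsh(joint)
        tr = np.real(np.trace(joint, axis1=1, axis2=2))
        assert np.all(ev[:, 0] >= -1e-10 * tr)
        cs.validate()

    def test_swap_symmetry_conjugate_transpose(self):
        a = white(20000, 4)
        rng = np.random.default_rng(5)
        b = xc.TimeSeriesSet(rng.standard_normal((2, 20000)), FS)
        cs_ab = estimate_cross_spectra(a, b)
        cs_ba = estimate_cross_spectra(b, a)
        assert np.allclose(
            cs_ab.cab, np.conj(np.swapaxes(cs_ba.cab, 1, 2)), atol=1e-14
        )
        assert np.allclose(cs_ab.caa, cs_ba.cbb)

    def test_channel_scaling_linearity(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((2, 20000))
        b = white(20000, 7)
        a1 = xc.TimeSeriesSet(data, FS)
        scaled = data.copy()
        scaled[0] *= 3.5
        a2 = xc.TimeSeriesSet(scaled, FS)
        cs1 = estimate_cross_spectra(a1, b)
        cs2 = estimate_cross_spectra(a2, b)
        assert np.allclose(cs2.cab[:, 0, :], 3.5 * cs1.cab[:, 0, :])
        assert np.allclose(cs2.caa[:, 0, 0], 3.5**2 * cs1.caa[:, 0, 0])
        assert np.allclose(cs2.caa[:, 0, 1], 3.5 * cs1.caa[:, 0, 1])

    def test_single_channel_matches_scipy_welch_coherence(self):
        a = white(60000, 8)
        rng = np.random.default_rng(9)
        b = xc.TimeSeriesSet(
            (0.4 * a.data[0] + rng.standard_normal(60000))[None, :], FS
        )
        cs = estimate_cross_spectra(a, b, segment_len_s=1.0, overlap_frac=0.5)
        f, coh = sps.coherence(a.data[0], b.data[0], fs=FS, nperseg=500)
        assert np.allclose(coherence_mag(cs) ** 2, coh, atol=1e-10)
        assert np.allclose(cs.freqs, f)

    def test_bin_restricted_path_equals_full_estimator(self):
        a = white(20000, 10)
        b = white(20000, 11)
        cs = estimate_cross_spectra(a, b)
        k = xc.nearest_bin(cs.freqs, 6.0)
        za, f_actual = segment_dft_at_bin(a.data, FS, 6.0)
        zb, _ = segment_dft_at_bin(b.data, FS, 6.0)
        caa, cbb, cab = blocks_from_coeffs(za, zb)
        assert f_actual == cs.freqs[k]
        assert np.allclose(caa, cs.caa[k], rtol=1e-10)
        assert np.allclose(cab, cs.cab[k], rtol=1e-10)

    def test_alignment_and_data_errors(self):
        a = white(20000, 12)
        with pytest.raises(AlignmentError):
            estimate_cross_spectra(a, white(20000, 13, fs=250.0))
        with pytest.raises(AlignmentError):
            estimate_cross_spectra(a, white(10000, 13))
        with pytest.raises(InsufficientDataError):
            estimate_cross_spectra(
                white(600, 14), white(600, 15), segment_len_s=1.0, overlap_frac=0.0
            )


class TestBandFilter:
    def test_passband_center_preserves_amplitude(self):
        x = tone(3.0, 30.0)
        y = xc.band_filter(x, 3.0, 1.0)
        core = slice(1000, -1000)
        assert np.max(np.abs(y.data[0][core])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuation_exceeds_40db(self):
        x = white(150000, 20)
        y = xc.band_filter(x, 3.0, 1.0)
        f, p = sps.welch(y.data[0], fs=FS, nperseg=4096)
        p3 = p[np.argmin(np.abs(f - 3.0))]
        p9 = p[np.argmin(np.abs(f - 9.0))]
        assert 10 * np.log10(p3 / p9) >= 40.0

    def test_zero_phase_no_lag(self):
        x = xc.make_oscillator(5.0, 1.0, duration_s=60.0, fs=FS, seed=21)
        y = xc.band_filter(x, 5.0, 1.0)
        a, b = x.data[0][2000:-2000], y.data[0][2000:-2000]
        lags = sps.correlation_lags(len(a), len(b))
        xcorr = sps.correlate(a, b)
        assert lags[np.argmax(np.abs(xcorr))] == 0

    def test_band_outside_nyquist_rejected(self):
        x = white(2000, 22)
        with pytest.raises(ParameterError):
            xc.band_filter(x, 3.0, 3.5)  # lower edge <= 0
        with pytest.raises(ParameterError):
            xc.band_filter(x, 249.0, 2.0)  # upper edge >= fs/2


class TestNearestBin:
    @pytest.mark.parametrize(
        "freqs, target, expected",
        [
            (np.arange(1.0, 21.0), 3.0, 2),
            ((2.5, 3.5), 3.0, 0),  # tie broken toward the lower frequency
            (np.arange(0, 20.5, 0.5), 9.26, 19),  # 9.5 Hz bin
        ],
    )
    def test_lookup(self, freqs, target, expected):
        assert xc.nearest_bin(freqs, target) == expected

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            xc.nearest_bin([], 3.0)


class TestTimeSeriesSet:
    def test_validation(self):
        with pytest.raises(ShapeError):
            xc.TimeSeriesSet(np.zeros((2, 10)), FS, labels=["only-one"])
        with pytest.raises(ParameterError):
            xc.TimeSeriesSet(np.zeros((1, 10)), -1.0)
        with pytest.raises(ParameterError):
            xc.TimeSeriesSet(np.zeros((1, 10)), FS, epochs=[(0, 5), (3, 8)])
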