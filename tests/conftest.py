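"""Shared fixtures: small deterministic signals and simulation bundles."""

import numpy as np
import pytest

import xfcacoh as xc

FS = 500.0


def tone(freq_hz, duration_s=20.0, fs=FS, phase=0.0, amp=1.0):
    """A pure sinusoid as a single-channel TimeSeriesSet."""
    t = np.arange(int(round(duration_s * fs))) / fs
    return xc.TimeSeriesSet(
        (amp * np.cos(2 * np.pi * freq_hz * t + phase))[None, :], fs
    )


@pytest.fixture(scope="session")
def osc3():
    """Unit-variance 3 Hz narrow-band Gaussian oscillator, 120 s."""
    return xc.make_oscillator(3.0, 1.0, duration_s=120.0, fs=FS, seed=11)


@pytest.fixture(scope="session")
def s1_bundle():
    """Small S1 bundle at high brain SNR (shared, treated as read-only)."""
    scen = xc.SimulationScenario(
        set_id="S1", snr_brain=0.5, duration_s=60.0, fs=FS,
        n_channels=24, n_noise_dipoles=100, seed=5,
    )
    return xc.assemble_scenario(scen)


@pytest.fixture(scope="session")
def s2_bundle():
    """Small S2 bundle (non-sinusoidal peripheral, independent 6 Hz source)."""
    scen = xc.SimulationScenario(
        set_id="S2", snr_brain=0.5, duration_s=60.0, fs=FS,
        n_channels=24, n_noise_dipoles=100, seed=6,
    )
    return xc.assemble_scenario(scen)


def random_joint_csd(rng, pa, pb, rank=None):
    """A random Hermitian-PSD joint cross-spectral matrix, split in blocks."""
    p = pa + pb
    rank = rank or p + 2
    z = rng.standard_normal((p, rank)) + 1j * rng.standard_normal((p, rank))
    m = z @ z.conj().T / rank
    return m[:pa, :pa], m[pa:, pa:], m[:pa, pa:]
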