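"""Canonical coherence optimizer, patterns, and the coupling pipelines."""

import numpy as np
import pytest

import xfcacoh as xc
from xfcacoh.cacoh import (
    _maximize_univariate_b,
    filters_to_pattern,
    maximize_coherence_blocks,
)
from xfcacoh.exceptions import ShapeError
from xfcacoh.permutation import _coupling_pipeline, _prep_eeg_bin
from xfcacoh.spectral import CrossSpectra, band_filter, estimate_cross_spectra

from conftest import FS, random_joint_csd


def grid_oracle_coherence(caa, cbb, cab, step=0.002):
    """Exhaustive search over filter angles for 2x2 / 2x1 instances.

    Real unit filters in 2-D are parametrized by one angle in [0, pi);
    the optimal per-bin phase is absorbed by taking the modulus of the
    projected cross-spectrum, so no phase grid is needed.
    """
    angs = np.arange(0, np.pi, step)
    u = np.column_stack([np.cos(angs), np.sin(angs)])
    ra, rb = np.real(caa), np.real(cbb)
    qa = np.einsum("ip,pq,iq->i", u, ra, u)
    if cab.shape[1] == 1:
        num = np.abs(u @ cab[:, 0])
        return float(np.max(num / np.sqrt(qa * np.real(cbb[0, 0]))))
    qb = np.einsum("ip,pq,iq->i", u, rb, u)
    num = np.abs(u @ cab @ u.T)
    return float(np.max(num / np.sqrt(np.outer(qa, qb))))


def cs_single_bin(caa, cbb, cab, f=3.0):
    """Wrap per-bin blocks into a 2-bin CrossSpectra container."""
    shape = lambda m: np.stack([np.atleast_2d(m)] * 2)
    return CrossSpectra(
        freqs=np.array([f, f + 1.0]),
        caa=shape(caa).astype(complex),
        cbb=shape(cbb).astype(complex),
        cab=np.stack([np.atleast_2d(cab)] * 2).astype(complex),
        n_segments=10,
    )


class TestMaximizeCacoh:
    def test_scalar_case_closed_form(self):
        caa, cbb = np.array([[2.0]]), np.array([[3.0]])
        cab = np.array([[1.2 * np.exp(1j * 0.7)]])
        sol = xc.maximize_cacoh(cs_single_bin(caa, cbb, cab), 3.0, gamma=0)
        assert sol.coherence == pytest.approx(1.2 / np.sqrt(6.0), abs=1e-12)
        assert sol.phi == pytest.approx(0.7, abs=1e-9)

    def test_zero_cross_spectrum_gives_zero_coherence(self):
        rng = np.random.default_rng(0)
        caa, cbb, _ = random_joint_csd(rng, 3, 2)
        sol = xc.maximize_cacoh(
            cs_single_bin(caa, cbb, np.zeros((3, 2))), 3.0
        )
        assert sol.coherence == 0.0

    @pytest.mark.parametrize("pb", [1, 2])
    def test_matches_grid_oracle(self, pb):
        rng = np.random.default_rng(1)
        for trial in range(10):
            caa, cbb, cab = random_joint_csd(rng, 2, pb)
            _, _, _, coh, _ = maximize_coherence_blocks(
                caa, cbb, cab, gamma=0, rng=np.random.default_rng(trial)
            )
            oracle = grid_oracle_coherence(caa, cbb, cab)
            assert coh == pytest.approx(oracle, abs=1e-3)

    def test_closed_form_agrees_with_alternating_scheme(self):
        # the univariate-B shortcut must equal the converged general solver
        from scipy.linalg import cho_factor

        rng = np.random.default_rng(2)
        for trial in range(10):
            pa = int(rng.integers(2, 8))
            caa, cbb, cab = random_joint_csd(rng, pa, 2)
            cab1 = cab[:, :1]
            cbb1 = cbb[:1, :1]
            ra = np.real(caa)
            a1, b1, phi1, coh1, _ = _maximize_univariate_b(
                ra, np.real(cbb1), cab1, cho_factor(ra)
            )
            # alternating scheme on an artificially 2-channel B space whose
            # second channel is silent: same optimum
            cbb2 = np.diag([cbb1[0, 0], 1.0]).astype(complex)
            cab2 = np.hstack([cab1, np.zeros((pa, 1))])
            _, _, _, coh2, _ = maximize_coherence_blocks(
                caa, cbb2, cab2, n_restarts=10, gamma=0,
                rng=np.random.default_rng(trial),
            )
            assert coh1 == pytest.approx(coh2, abs=1e-9)

    def test_mixing_invariance_under_channel_transform(self):
        # invertible transform of space A leaves max coherence unchanged
        rng = np.random.default_rng(3)
        for trial in range(5):
            caa, cbb, cab = random_joint_csd(rng, 3, 2)
            t = rng.standard_normal((3, 3)) + 0.5 * np.eye(3)
            caa_t = t @ caa @ t.T
            cab_t = t @ cab
            _, _, _, coh, _ = maximize_coherence_blocks(
                caa, cbb, cab, n_restarts=8, gamma=0,
                rng=np.random.default_rng(trial),
            )
            _, _, _, coh_t, _ = maximize_coherence_blocks(
                caa_t, cbb, cab_t, n_restarts=8, gamma=0,
                rng=np.random.default_rng(trial + 100),
            )
            assert coh_t == pytest.approx(coh, abs=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        caa, cbb, cab = random_joint_csd(rng, 3, 2)
        cs = cs_single_bin(caa, cbb, cab)
        s1 = xc.maximize_cacoh(cs, 3.0, seed=7)
        s2 = xc.maximize_cacoh(cs, 3.0, seed=7)
        assert np.array_equal(s1.alpha, s2.alpha)
        assert s1.coherence == s2.coherence

    def test_unit_power_normalization_and_polarity(self):
        rng = np.random.default_rng(5)
        caa, cbb, cab = random_joint_csd(rng, 4, 1)
        sol = xc.maximize_cacoh(cs_single_bin(caa, cbb, cab), 3.0)
        assert sol.alpha @ np.real(caa) @ sol.alpha == pytest.approx(1.0, abs=1e-9)
        assert sol.beta @ np.real(cbb) @ sol.beta == pytest.approx(1.0, abs=1e-9)
        k = np.argmax(np.abs(sol.pattern_a))
        assert sol.pattern_a[k] > 0


class TestFiltersToPattern:
    def test_identity_and_diagonal(self):
        alpha = np.array([0.3, -0.8, 0.1])
        p = filters_to_pattern(np.eye(3), alpha)
        assert np.allclose(p, -alpha)  # polarity flip: largest |entry| positive
        d = np.diag([1.0, 2.0, 3.0])
        p2 = filters_to_pattern(d, np.array([1.0, 1.0, 1.0]))
        assert np.allclose(p2, [1, 2, 3])

    def test_rank_one_source_recovered(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal(8)
        caa = np.outer(m, m) + 1e-3 * np.eye(8)
        cab = (m * np.exp(0.3j))[:, None]
        sol = maximize_coherence_blocks(caa, np.array([[1.0]]), cab, gamma=0)
        pattern = filters_to_pattern(caa, sol[0])
        assert xc.recovery_error(m, pattern) < 0.01

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            filters_to_pattern(np.eye(3), np.ones(4))


class TestCouplingPipelines:
    def test_peripheral_copy_of_channel_found(self):
        rng = np.random.default_rng(7)
        eeg = xc.TimeSeriesSet(rng.standard_normal((5, 60000)), FS)
        periph = xc.TimeSeriesSet(
            (eeg.data[2] + 0.1 * rng.standard_normal(60000))[None, :], FS
        )
        res = xc.ckc(eeg, periph, 10.0)
        assert res.solution.coherence > 0.9
        p = np.abs(res.solution.pattern_a)
        assert np.argmax(p) == 2
        assert p[2] > 3 * np.sort(p)[-2]

    def test_warped_channel_construction(self, osc3):
        # one EEG channel IS the warped peripheral: near-perfect XF coupling
        rng = np.random.default_rng(8)
        w = xc.warp_frequency(osc3, 2, 3.0, 1.0)
        eeg_data = rng.standard_normal((4, osc3.n_samples))
        eeg_data[1] = w.data[0]
        eeg = xc.TimeSeriesSet(eeg_data, FS)
        res = xc.xf_ckc(eeg, osc3, xc.CouplingSpec(3, 6, 1, 2))
        assert res.solution.coherence > 0.98
        assert np.argmax(np.abs(res.solution.pattern_a)) == 1

    def test_r1_reduction_to_within_frequency(self, osc3):
        rng = np.random.default_rng(9)
        eeg_data = rng.standard_normal((3, osc3.n_samples))
        eeg_data[0] += 2 * band_filter(osc3, 3.0, 1.0).data[0]
        eeg = xc.TimeSeriesSet(eeg_data, FS)
        xf = xc.xf_ckc(eeg, osc3, xc.CouplingSpec(3.0, 3.0, 1, 1))
        within = xc.ckc(eeg, band_filter(osc3, 3.0, 1.0), 3.0)
        assert xf.solution.coherence == pytest.approx(
            within.solution.coherence, abs=1e-6
        )

    def test_projected_pair_coherence_self_consistent(self, s1_bundle):
        # recomputing coherence from the projected univariate series via the
        # single-channel path reproduces the multivariate optimum
        b = s1_bundle
        res = xc.ckc(b.eeg, b.peripheral, 3.0)
        proj = xc.TimeSeriesSet(
            (res.solution.alpha @ b.eeg.data)[None, :], FS
        )
        cs = estimate_cross_spectra(proj, b.peripheral)
        k = xc.nearest_bin(cs.freqs, 3.0)
        coh = np.abs(cs.cab[k, 0, 0]) / np.sqrt(
            np.real(cs.caa[k, 0, 0]) * np.real(cs.cbb[k, 0, 0])
        )
        assert coh == pytest.approx(res.solution.coherence, abs=0.02)

    def test_fast_bin_path_equals_public_pipeline(self, s1_bundle):
        b = s1_bundle
        prep = _prep_eeg_bin(b.eeg, 3.0, 1.0, 0.5, "hann")
        coh, pattern = _coupling_pipeline(
            prep, b.peripheral, xc.CouplingSpec(3, 3, 1, 1),
            1.0, 1.0, 0.5, "hann", 10, 1e-12, 200, 1e-4,
            np.random.default_rng(0),
        )
        pub = xc.ckc(b.eeg, b.peripheral, 3.0)
        assert coh == pytest.approx(pub.solution.coherence, abs=1e-12)
        assert xc.recovery_error(pattern, pub.solution.pattern_a) < 1e-12

    def test_project_linearity_and_basis_vector(self, s1_bundle):
        b = s1_bundle
        e1 = np.zeros(b.eeg.n_channels)
        e1[4] = 1.0
        proj = xc.project(b.eeg, e1, 6.0, 2.0)
        direct = band_filter(b.eeg.channel(4), 6.0, 2.0)
        assert np.allclose(proj.data, direct.data)
        scaled = xc.project(b.eeg, 2.5 * e1, 6.0, 2.0)
        assert np.allclose(scaled.data, 2.5 * proj.data)

    def test_s1_recovery_at_high_snr(self, s1_bundle):
        b = s1_bundle
        res = xc.ckc(b.eeg, b.peripheral, 3.0)
        assert xc.recovery_error(
            b.truth_patterns["3:3"].values, res.solution.pattern_a
        ) < 0.15
        res_xf = xc.xf_ckc(b.eeg, b.peripheral, xc.CouplingSpec(3, 6, 1, 2))
        assert xc.recovery_error(
            b.truth_patterns["3:6"].values, res_xf.solution.pattern_a
        ) < 0.25

    def test_projected_source_syncs_with_peripheral(self, s1_bundle):
        b = s1_bundle
        res = xc.ckc(b.eeg, b.peripheral, 3.0)
        proj = xc.project(b.eeg, res.solution.alpha, 3.0, 1.0)
        sync = xc.cross_freq_sync(proj, b.peripheral, xc.CouplingSpec(3, 3, 1, 1))
        assert sync.k_sync >= 0.8
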