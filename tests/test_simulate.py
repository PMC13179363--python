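"""Simulation generators: oscillators, peripheral composition, leadfield,
1/f background, scenario assembly and the SNR sweep."""

import numpy as np
import pytest
from scipy import signal as sps

import xfcacoh as xc
from xfcacoh.simulate import (
    aggregate_failures,
    electrode_layout,
    interactions_for_set,
    layout_neighbor_pairs,
)
from xfcacoh.spectral import band_filter, edge_samples
from xfcacoh.warping import analytic_signal

from conftest import FS


class TestMakeOscillator:
    def test_spectral_peak_within_band(self):
        osc = xc.make_oscillator(6.0, 2.0, duration_s=120.0, fs=FS, seed=0)
        f, p = sps.periodogram(osc.data[0], fs=FS)
        assert abs(f[np.argmax(p)] - 6.0) <= 2.0

    def test_unit_variance(self):
        osc = xc.make_oscillator(3.0, 1.0, duration_s=60.0, fs=FS, seed=1)
        assert osc.data[0].var() == pytest.approx(1.0, rel=0.02)

    def test_seeds_give_independent_realizations(self):
        a = xc.make_oscillator(3.0, 1.0, duration_s=300.0, fs=FS, seed=2)
        b = xc.make_oscillator(3.0, 1.0, duration_s=300.0, fs=FS, seed=3)
        assert abs(np.corrcoef(a.data[0], b.data[0])[0, 1]) < 0.05


class TestMakePeripheral:
    def test_s1_power_ratios(self):
        _, comps = xc.make_peripheral("S1", duration_s=300.0, seed=4)
        ratio = comps[2].data[0].var() / comps[0].data[0].var()
        assert ratio == pytest.approx(0.25, abs=0.02)
        assert comps[1].data[0].var() / comps[0].data[0].var() == \
            pytest.approx(0.5, abs=0.03)

    def test_realized_peripheral_snr(self):
        periph, comps = xc.make_peripheral("S1", duration_s=300.0, seed=5)
        total = sum(c.data[0] for c in comps)
        noise = periph.data[0] - total
        assert total.var() / noise.var() == pytest.approx(10.0, rel=0.05)

    def test_s2_components_cross_frequency_coupled_s1_not(self):
        def comp_sync(comps, r):
            # the warp operates on the band-filtered base, so the phase
            # reference is the filtered 3 Hz component
            phi_q = np.unwrap(
                analytic_signal(band_filter(comps[0], 3.0, 1.0)).phase
            )
            phi_r = np.unwrap(analytic_signal(comps[r - 1]).phase)
            keep = edge_samples(FS, phi_q.size)
            return xc.sync_index(phi_q[keep], phi_r[keep], 1, r).k_sync

        _, s2 = xc.make_peripheral("S2", duration_s=120.0, seed=6)
        assert comp_sync(s2, 2) >= 0.99
        _, s1 = xc.make_peripheral("S1", duration_s=120.0, seed=6)
        assert comp_sync(s1, 2) < 0.1


class TestSyntheticLeadfield:
    def test_columns_unit_norm_and_distinct(self):
        lf = xc.synthetic_leadfield(61, 5, seed=7)
        assert np.allclose(np.linalg.norm(lf, axis=0), 1.0)
        gram = np.abs(lf.T @ lf) - np.eye(5)
        assert np.max(gram) < 0.8

    def test_columns_spatially_smooth(self):
        pos = electrode_layout(61)
        lf = xc.synthetic_leadfield(61, 5, layout=pos, seed=8)
        pairs = layout_neighbor_pairs(pos)
        for k in range(5):
            col = lf[:, k]
            r = np.corrcoef(col[pairs[:, 0]], col[pairs[:, 1]])[0, 1]
            assert r > 0.5

    def test_s3_coupled_sources_colocated(self):
        scen = xc.SimulationScenario(
            set_id="S3", duration_s=30.0, n_channels=24,
            n_noise_dipoles=50, seed=9,
        )
        b = xc.assemble_scenario(scen)
        assert xc.recovery_error(
            b.truth_patterns["3:6"].values, b.truth_patterns["3:9"].values
        ) == 0.0


class TestPinkBackground:
    def test_one_over_f_spectral_slope(self):
        bg = xc.pink_background(8, 100, duration_s=120.0, fs=FS, seed=10)
        f, p = sps.welch(bg.data[0], fs=FS, nperseg=4096)
        sel = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_full_rank_channel_covariance(self):
        bg = xc.pink_background(16, 500, duration_s=30.0, fs=FS, seed=11)
        cov = np.cov(bg.data)
        assert np.linalg.matrix_rank(cov) == 16

    def test_seeds_uncorrelated(self):
        # correlation assessed in the 1-40 Hz analysis band: the raw 1/f
        # process carries few independent cycles at its slowest frequencies,
        # which inflates broadband sample correlations
        a = xc.pink_background(4, 50, duration_s=120.0, fs=FS, seed=12)
        b = xc.pink_background(4, 50, duration_s=120.0, fs=FS, seed=13)
        sos = sps.butter(4, [1.0, 40.0], btype="bandpass", fs=FS, output="sos")
        af = sps.sosfiltfilt(sos, a.data)
        bf = sps.sosfiltfilt(sos, b.data)
        rho = [abs(np.corrcoef(af[i], bf[i])[0, 1]) for i in range(4)]
        assert np.mean(rho) < 0.05


class TestAssembleScenario:
    def test_brain_lag_is_20_ms(self, s1_bundle):
        b = s1_bundle
        src = b.truth_sources["3:3"].data[0]
        base = band_filter(b.peripheral, 3.0, 1.0).data[0]
        xcorr = sps.correlate(src, base)
        lags = sps.correlation_lags(src.size, base.size)
        lag_s = lags[np.argmax(xcorr)] / FS
        assert abs(lag_s - 0.020) <= 1.5 / FS

    def test_realized_brain_snr(self, s1_bundle):
        b = s1_bundle
        # background = EEG minus all projected sources
        recon = np.zeros_like(b.eeg.data)
        for lab, pat in b.truth_patterns.items():
            recon += np.outer(pat.values, b.truth_sources[lab].data[0])
        bg = b.eeg.data - recon
        bg_var = bg.var(axis=1).mean()
        for lab in b.truth_patterns:
            comp = np.outer(
                b.truth_patterns[lab].values, b.truth_sources[lab].data[0]
            )
            snr = comp.var(axis=1).mean() / bg_var
            assert snr == pytest.approx(b.scenario.snr_brain, rel=0.05)

    def test_bundle_bit_identical_for_same_seed(self):
        scen = xc.SimulationScenario(
            set_id="S2", duration_s=30.0, n_channels=16,
            n_noise_dipoles=50, seed=14,
        )
        b1 = xc.assemble_scenario(scen)
        b2 = xc.assemble_scenario(scen)
        assert np.array_equal(b1.eeg.data, b2.eeg.data)
        assert np.array_equal(b1.peripheral.data, b2.peripheral.data)
        for k in b1.truth_patterns:
            assert np.array_equal(
                b1.truth_patterns[k].values, b2.truth_patterns[k].values
            )

    def test_truth_labels_per_set(self, s1_bundle, s2_bundle):
        assert set(s1_bundle.truth_patterns) == {"3:3", "6:6", "9:9", "3:6", "3:9"}
        assert set(s2_bundle.truth_patterns) == {"3:6", "3:9", "independent"}

    def test_warped_truth_source_locked_to_peripheral_base(self, s1_bundle):
        b = s1_bundle
        src = b.truth_sources["3:6"]
        base = band_filter(b.peripheral, 3.0, 1.0)
        # undo the brain lag before comparing phases
        lag = int(round(b.scenario.lag_ms * FS / 1000))
        phi_r = analytic_signal(src).phase[lag:]
        phi_q = np.unwrap(analytic_signal(base).phase)[:-lag]
        keep = edge_samples(FS, phi_q.size)
        res = xc.sync_index(phi_q[keep], phi_r[keep], 1, 2)
        assert res.k_sync >= 0.95


class TestSnrSweep:
    def test_sweep_table_and_failure_aggregation(self):
        table = xc.snr_sweep(
            "S1", (0.5,), n_repetitions=2, n_permutations=39, seed=15,
            duration_s=30.0, n_channels=16, n_noise_dipoles=50,
            interactions=["3:3", "3:6"],
        )
        assert len(table) == 4
        assert set(table.columns) >= {
            "snr", "repetition", "interaction", "coherence", "rerror",
            "null_p95", "p_value", "failed",
        }
        agg = aggregate_failures(table)
        assert set(agg["interaction"]) == {"3:3", "3:6"}
        # strong coupling at snr 0.5: recovery should beat its null
        assert not table[table.interaction == "3:3"]["failed"].any()

    def test_interaction_sets(self):
        assert interactions_for_set("S1") == ["3:3", "6:6", "9:9", "3:6", "3:9"]
        assert "independent" in interactions_for_set("S2")
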