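"""Test coupling significance with an epoch-permutation null.

Runs the coupling test twice: on a recording with a genuine 3:6 Hz
cross-frequency interaction, and on a null recording whose EEG is pure
1/f background. The observed XF-CKC strength is compared with the 95th
percentile of 199 full pipeline recomputations on epoch-shuffled
peripherals.
"""

import xfcacoh as xc

scen = xc.SimulationScenario(
    set_id="S1", snr_brain=0.25, duration_s=120.0, n_channels=32,
    n_noise_dipoles=200, seed=11,
)
bundle = xc.assemble_scenario(scen)
spec = xc.CouplingSpec(3, 6, 1, 2)

null = xc.coupling_significance(bundle.eeg, bundle.peripheral, spec,
                                n_perm=199, seed=1)
print(f"coupled recording:   observed XF-CKC = {null.observed:.3f}, "
      f"null 95th pct = {null.percentile_95:.3f}, p = {null.p_value:.4f}, "
      f"significant = {null.significant}")

null_eeg = xc.pink_background(32, 200, duration_s=120.0, fs=500.0, seed=99)
null2 = xc.coupling_significance(null_eeg, bundle.peripheral, spec,
                                 n_perm=199, seed=1)
print(f"background-only EEG: observed XF-CKC = {null2.observed:.3f}, "
      f"null 95th pct = {null2.percentile_95:.3f}, p = {null2.p_value:.4f}, "
      f"significant = {null2.significant}")
print("a genuine interaction clears its null decisively (p near 1/(n_perm+1));")
print("a background-only recording lands at the threshold and crosses it only")
print("at the test's controlled ~5% false-positive rate.")
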