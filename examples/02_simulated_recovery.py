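"""Recover simulated cortical sources with caCOH and XF-caCOH.

Generates an S1-style recording (61-channel EEG with five hidden sources
coupled to a composite peripheral signal, brain SNR 0.5), runs the
within-frequency and cross-frequency analyses, and scores the recovered
spatial patterns against the ground truth.
"""

import xfcacoh as xc

scen = xc.SimulationScenario(set_id="S1", snr_brain=0.5, duration_s=120.0, seed=7)
bundle = xc.assemble_scenario(scen)

within = xc.ckc(bundle.eeg, bundle.peripheral, 3.0)
print(f"3:3 Hz CKC strength = {within.solution.coherence:.3f}")
err = xc.recovery_error(bundle.truth_patterns["3:3"].values, within.solution.pattern_a)
print(f"3:3 Hz pattern recovery error = {err:.4f} (0 = perfect, 1 = orthogonal)")

for r in (2, 3):
    spec = xc.CouplingSpec(3.0, 3.0 * r, 1, r)
    cross = xc.xf_ckc(bundle.eeg, bundle.peripheral, spec)
    err = xc.recovery_error(
        bundle.truth_patterns[spec.label].values, cross.solution.pattern_a
    )
    print(
        f"{spec.label} Hz XF-CKC strength = {cross.solution.coherence:.3f}, "
        f"recovery error = {err:.4f}"
    )
print("low recovery errors show the spatial filters found the true source")
print("topographies although the optimization never sees spatial information.")
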