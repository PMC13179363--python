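"""Map the SNR range over which source recovery remains reliable.

Runs a reduced recovery sweep on S1-style simulations: at each brain SNR,
sources are recovered repeatedly and each recovery error is compared with
a trial-permutation null. The failure proportion per SNR shows where the
method stops beating chance. (Reduced sizes keep this example fast; widen
the grid, repetitions and permutations for a full study.)
"""

import xfcacoh as xc

table = xc.snr_sweep(
    "S1", snr_grid=(0.5, 0.01, 5e-4, 1e-4), n_repetitions=3, n_permutations=99,
    seed=0, duration_s=60.0, n_channels=32, n_noise_dipoles=100,
    interactions=["3:3", "3:6"],
)
print(table[["snr", "repetition", "interaction", "coherence", "rerror", "p_value"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(xc.aggregate_failures(table).to_string(index=False))
print()
print("coherence drops and recovery error grows as the SNR falls, and at the")
print("lowest SNRs the recovery stops beating its permutation null. Note the")
print("synthetic leadfield (smooth distinct topographies, no volume-conductor")
print("smearing) is kinder than a realistic head model: recovery here stays")
print("reliable far below the SNRs at which realistic forward models fail.")
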