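"""Frequency-warp a narrow-band oscillator and measure phase locking.

Builds a 3 Hz narrow-band Gaussian oscillator, shifts its dominant
frequency to 6 Hz while keeping the amplitude envelope, and quantifies
the 1:2 phase synchronization between original and warped copy.
"""

import numpy as np
from scipy.signal import periodogram

import xfcacoh as xc

osc = xc.make_oscillator(3.0, 1.0, duration_s=120.0, fs=500.0, seed=1)
warped = xc.warp_frequency(osc, r=2, center_hz=3.0, half_bw_hz=1.0)

f, p = periodogram(warped.data[0], fs=500.0)
print(f"dominant frequency after warping: {f[np.argmax(p)]:.2f} Hz (expected 6)")

res = xc.cross_freq_sync(osc, warped, xc.CouplingSpec(3, 6, 1, 2))
print(f"1:2 phase synchronization k_sync = {res.k_sync:.3f} over {res.n_used} samples")
print("k_sync near 1 means the warped copy is phase-locked to the original;")
print("independent signals of these lengths would give k_sync < 0.05.")
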