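# Methods

## Model and estimators

### Cross-spectral estimation

All coupling quantities are built on Welch segment-averaged cross-spectra
of the joint channel space. Defaults: Hann taper, 1 s segments, 50 %
overlap, per-segment mean removal, no prewhitening. The 1 s segment length
puts the analysis frequencies 3, 6 and 9 Hz on exact bins at 1 Hz
resolution and gives a standard bias/variance trade-off; all of segment
length, overlap and taper are exposed as parameters. Sign convention:
forward DFT with `e^{-j2πft}` and `cab[p,q] = E[A_p(f)·conj(B_q(f))]`, so
a signal lagging by phase θ at the bin appears as `arg(cab) = -θ` (fixed
by a sinusoid-pair test). The averaged outer products make the joint
matrix positive semidefinite by construction; the single-channel case
reproduces `scipy.signal.coherence` to ~1e-15.

A bin-restricted path (`segment_dft_at_bin`) computes the same per-segment
coefficients at one bin via a direct windowed DFT kernel. It is
numerically identical to the full estimator at that bin (tested) and is
what makes thousands of permutation recomputations affordable.

### Band filtering and analytic signals

Narrow-band filtering is a zero-phase (forward–backward) 4th-order
Butterworth band-pass with odd-reflection padding of ≈3 filter time
constants. Default half-bandwidth is 1 Hz at 3 Hz, scaled proportionally
(r·1 Hz at r·3 Hz) so warped and target bands match. Instantaneous
amplitude/phase come from the Hilbert-transform analytic signal;
zero-amplitude samples get phase 0 by convention. The first and last 2 s
after filtering + Hilbert are excluded from every phase-based index
(filter and analytic-signal edge effects).

### Frequency warping

Warping by integer r operates on the band-filtered signal (filtering is
built into the operation to prevent broadband-phase misuse), unwraps the
phase before multiplying by r, and returns `Re{a·e^{jrφ}}`. With r = 1
the output equals the band-filtered input exactly. The envelope is
preserved by construction; the output phase equals r times the input
phase with circular RMS deviation < 0.1 rad away from edges.

A property worth knowing: the warped copy is phase-locked to its source
at k_sync ≈ 0.999 when the fast phase is read directly from the warped
signal's analytic representation, but ≈ 0.96–0.97 when measured through
the full synchronization pipeline, whose mandated re-filtering of the
fast band introduces brief phase slips near envelope zeros of a Gaussian
oscillator (where instantaneous frequency diverges and phase is
ill-defined). Only ~1 % of power is out of band; this is a property of
unweighted phase-locking indices on Gaussian envelopes, not an estimator
defect. Warping twice does not compose with warping by the product of the
ratios (the second warp re-filters); this composition is deliberately
left untested and unsupported.

### Canonical coherence

At one bin, real filters α, β maximize
`L = |αᵀ C_AB β|² / ((αᵀ C_AA α)(βᵀ C_BB β))` (real filters encode the
instantaneous-mixing assumption; for real α the quadratic form only sees
`Re(C_AA)`). The residual complex degree of freedom is a per-bin phase
rotation φ with closed-form update `φ = arg(αᵀ C_AB β)` — the "optimal
delay" is modeled at-bin rather than as a broadband time lag. The general
solver alternates closed-form updates (α ∝ Re(C_AA)⁻¹Dβ,
β ∝ Re(C_BB)⁻¹Dᵀα with D = Re(C_AB e^{-jφ}), then the φ update); each
step cannot decrease the objective (asserted every iterate), iteration
stops at relative objective change < 1e-12 (max 200 iterations), and the
best of 10 seeded random restarts is kept.

When space B is univariate (every CKC/XF-CKC call), β is a scalar and the
problem reduces to a rank-2 generalized Rayleigh quotient
`αᵀ(uuᵀ+vvᵀ)α / (αᵀ Re(C_AA) α)` with u, v the real and imaginary parts
of the cross-spectral column. Its maximizer lies in
span{Re(C_AA)⁻¹u, Re(C_AA)⁻¹v} and is obtained exactly from a 2×2
eigenproblem — deterministic, no restarts, and ~100× faster, which is
what makes full re-optimization inside every permutation feasible. The
closed form agrees with the converged alternating scheme to ~1e-9 and
with an exhaustive filter-angle grid oracle to < 1e-3 (tested).

Numerical choices: `Re(C_AA)`/`Re(C_BB)` are shrunk as
`(1-γ)C + γ(trace/P)I` with γ = 1e-4 before inversion (needed for
61-channel stability; the shrinkage is identity for scalars). A condition
number above 1e12 after regularization raises an error. Reported coupling
strength is `√L`, clipped to [0, 1] (the clip absorbs at most ~γ/2 of
regularization-induced overshoot); the squared value is also stored.
Filters are rescaled to unit projected power against the raw real
auto-spectra; pattern polarity is fixed by making the largest-magnitude
entry of the EEG pattern positive (arbitrary but reproducible). Only the
first canonical pair is extracted; deflation for further pairs is out of
scope. Exact mixing invariance (coherence unchanged under invertible
channel transforms) holds for γ = 0 and is tested there; with γ > 0 the
shrinkage target breaks it at O(γ).

Patterns are `p = Re(C_AA)α` — the activation topography interpretable as
a source projection, unlike the filter itself.

## Simulation framework

The generator reproduces three scenario families at their stated study
conditions: 300 s at 500 Hz; oscillators at 3/6/9 Hz with variance ratios
1 : 1/2 : 1/4; peripheral white-noise floor at total SNR 10; brain
sources delayed by 20 ms (10 samples); 61 channels; 500-dipole 1/f
background; brain SNR grid {0.5, 0.25, 0.1, 0.05, 0.025, 0.01}. Brain SNR
is defined per projected source component as mean-over-channels variance
of the component divided by mean-over-channels variance of the projected
background, enforced by explicit scaling and re-measured in tests rather
than assumed. S1 peripherals are three independent oscillators; S2/S3
derive the 6 and 9 Hz components by warping the 3 Hz component (ratios
1:2 and 1:3), giving a non-sinusoidal, cross-frequency-coupled signal. S2
adds an independent 6 Hz cortical oscillator; S3 co-locates the two
coupled cortical sources on one topography.

**Forward model.** The realistic volume-conductor model is replaced by a
synthetic leadfield: each source topography is a difference of two
spatial Gaussians (widths 0.40/0.80 rad, surround gain 0.6) centered at a
random location on an equiangular 61-electrode spherical cap, unit
normalized, resampled until all pairwise |cos| < 0.8. This is the central
desk-scale adaptation: the columns are smooth, overlapping, full-support
topographies like real EEG patterns, but carry no tissue-conductivity
structure, no depth dependence, and no radial/tangential distinction.
`assemble_scenario` accepts a user-supplied leadfield matrix to restore
realism. Consequences for interpretation: recovery errors measured here
show that the estimator separates linearly mixed sources at realistic
SNR; they do not certify performance under realistic head geometry.
Quantitatively, the combination of smooth distinct topographies and a
*broadband* SNR definition (a narrow-band source concentrates all its
variance in ~2 Hz while the 1/f background spreads its variance over the
whole spectrum) makes this setup markedly easier than a realistic head
model: recovery remains reliable across the entire nominal SNR grid and
only breaks down near SNR 1e-4 (measured). SNR-threshold numbers from
this generator therefore do not transfer to realistically
forward-modeled or real data; the monotone degradation and the
permutation machinery do.

The 1/f background synthesizes each dipole time course in the frequency
domain (amplitude ∝ f^(-1/2)), projects through random unit topographies
and sums; the log–log spectral slope over 1–40 Hz is −1 ± 0.2 and the
channel covariance is full rank. Independent realizations decorrelate to
|ρ| ≈ 0.02 in the 1–40 Hz analysis band; broadband sample correlations
are larger (~0.06 at 300 s) simply because a 1/f process has few
independent slow cycles — tests therefore assess independence in the
analysis band.

Determinism: a scenario seed is expanded through `SeedSequence.spawn`;
identical scenarios give bit-identical bundles.

## Permutation statistics

The null hypothesis is temporal independence of brain and peripheral
signals. The peripheral recording is cut into epochs (the recording's own
epoch markers when present, else 1 s blocks), the epoch order shuffled
(derangement not enforced), and the complete pipeline — filtering,
warping, cross-spectral estimation, coherence re-optimization — is
recomputed per shuffle. EEG-side per-segment DFT coefficients cannot
change when only the peripheral is permuted, so they are cached; the
result is numerically identical to naive recomputation (tested).

P-values use the add-one estimator `p = (1 + #{null ≥ obs})/(1 + n_perm)`
(avoiding exactly-zero p-values); the plain proportion is available via
flag. The 95th percentile is nearest-rank (the ⌈0.95 n⌉-th order
statistic), bit-reproducible across platforms. For recovery-error tests
the p-value counts permuted errors *smaller than or equal to* the
observed error: detection means unusually low error; p > 0.05 flags a
recovery failure.

Two regimes of the recovery-error null are worth distinguishing. When the
EEG bin is background-dominated, null-recovered patterns are near-random
and the null error concentrates near `1 − √(2/(π·n_ch))` (high-dimensional
near-orthogonality; verified against that closed form). At high source
SNR the bin is dominated by the true source and even permuted peripherals
partially recover it, pulling the null errors down — the permutation test
remains valid (observed and null are exchangeable under the null) but the
null distribution is not "random patterns".

## Problem sizes used in validation

The validation suite runs the method at reduced problem sizes chosen to
preserve every property being tested: parameter recovery uses 120 s
signals over the SNR grid {0.5, 0.1, 0.01} with 10 seeds; the uncoupled-
source failure regime uses S2 at {0.5, 0.05, 0.01} with 5 repetitions and
199 permutations (failure proportion ≥ 3/5 required per SNR — the
proportion, not a single draw, because an uncoupled observation is itself
a draw from its null and lands below p = 0.05 five percent of the time);
false-positive calibration uses 200 independent 60 s background-only
recordings at 32 channels with 199 permutations, with the rejection count
required inside the binomial 95 % interval around 5 % (4–16 of 200).
Type-I calibration is invariant to these sizes.

## Known limitations

* The synthetic leadfield omits head-geometry realism (above).
* The per-bin phase rotation is an at-bin surrogate for a broadband
  delay; a genuine lag parameterization is noted as an alternative but
  not implemented.
* Only q = 1 ratios (fast = integer multiple of slow) are supported, and
  only the first canonical component is extracted.
* The real-data workflow assumes pre-cleaned EEG; artifact handling is an
  upstream responsibility.
* Group-level regression modeling of coupling strengths is out of scope;
  the package stops at per-recording statistics, pattern comparisons and
  the similarity-vs-synchronization correlation analysis.
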