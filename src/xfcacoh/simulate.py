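"""Simulation framework: coupled oscillators, synthetic head projection,
1/f background and SNR-controlled EEG/peripheral bundles.

Three scenario families are generated:

* **S1** — the peripheral signal is the sum of three *independent*
  narrow-band Gaussian oscillators at 3, 6 and 9 Hz (power ratios
  1 : 1/2 : 1/4) plus white noise at a total SNR of 10. Five brain sources
  exist: within-frequency copies of the three peripheral oscillators
  (interactions 3:3, 6:6, 9:9) and warped copies of the 3 Hz oscillator at
  6 and 9 Hz (cross-frequency interactions 3:6, 3:9), each at a distinct
  scalp location.
* **S2** — the peripheral 6 and 9 Hz components are *warped copies* of the
  3 Hz oscillator, making the peripheral signal non-sinusoidal (3:6 and
  3:9 couplings exist within it). The brain carries the two warped sources
  plus one *independent* 6 Hz oscillator (no coupling to the periphery),
  all at distinct locations.
* **S3** — as S2, but the two coupled brain sources share a single scalp
  location (co-located generators).

Brain sources are delayed by 20 ms relative to the peripheral oscillators,
projected onto 61 channels through a synthetic leadfield (smooth
pseudo-dipolar topographies on a spherical cap — a stand-in forward model;
a user-supplied leadfield matrix can replace it), scaled so that the mean
channel variance of each projected component relative to the mean channel
variance of the 1/f dipole background equals the requested brain SNR, and
summed with that background.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import NumericalError, ParameterError
from .patterns import SpatialPattern
from .spectral import TimeSeriesSet, band_filter
from .warping import warp_frequency

logger = logging.getLogger(__name__)

#: the six brain-SNR conditions of the sweep analyses
DEFAULT_SNR_GRID = (0.5, 0.25, 0.1, 0.05, 0.025, 0.01)

_SET_IDS = ("S1", "S2", "S3")


@dataclasses.dataclass
class SimulationScenario:
    """Parameters of one simulated recording."""

    set_id: str = "S1"
    snr_brain: float = 0.5
    snr_peripheral: float = 10.0
    duration_s: float = 300.0
    fs: float = 500.0
    n_channels: int = 61
    n_noise_dipoles: int = 500
    lag_ms: float = 20.0
    power_ratios: tuple[float, float, float] = (1.0, 0.5, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_id not in _SET_IDS:
            raise ParameterError(f"set_id must be one of {_SET_IDS}")
        if self.snr_brain <= 0 or self.snr_peripheral <= 0:
            raise ParameterError("SNR values must be positive")
        if self.duration_s * self.fs < 1e4:
            raise ParameterError("need at least 1e4 samples (duration_s * fs)")


@dataclasses.dataclass
class SimulationBundle:
    """Generated EEG + peripheral signals with ground truth."""

    eeg: TimeSeriesSet
    peripheral: TimeSeriesSet
    truth_patterns: dict[str, SpatialPattern]
    truth_sources: dict[str, TimeSeriesSet]
    scenario: SimulationScenario


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_oscillator(
    center_hz: float,
    half_bw_hz: float | None = None,
    duration_s: float = 300.0,
    fs: float = 500.0,
    seed=None,
) -> TimeSeriesSet:
    """Unit-variance narrow-band Gaussian oscillator.

    White Gaussian noise is band-pass filtered around ``center_hz`` with a
    zero-phase 4th-order Butterworth filter and normalized to unit
    variance. The default half-bandwidth is ``center_hz / 3`` (1 Hz at
    3 Hz, scaled proportionally so relative bandwidth is constant).
    """
    rng = _rng(seed)
    if half_bw_hz is None:
        half_bw_hz = center_hz / 3.0
    n = int(round(duration_s * fs))
    white = TimeSeriesSet(
        rng.standard_normal(n)[None, :], fs, [f"osc{center_hz:g}"]
    )
    ts = band_filter(white, center_hz, half_bw_hz)
    v = ts.data[0]
    ts.data[0] = v / v.std()
    return ts


def make_peripheral(
    set_id: str = "S1",
    fs: float = 500.0,
    duration_s: float = 300.0,
    power_ratios: tuple[float, float, float] = (1.0, 0.5, 0.25),
    snr_peripheral: float = 10.0,
    seed=None,
) -> tuple[TimeSeriesSet, list[TimeSeriesSet]]:
    """Composite peripheral signal and its three component oscillators.

    S1: three independent oscillators at 3/6/9 Hz. S2/S3: the 6 and 9 Hz
    components are frequency-warped copies of the 3 Hz component (ratios
    1:2 and 1:3), producing a non-sinusoidal, cross-frequency-coupled
    signal. Components are scaled to the variance ratios ``power_ratios``
    and summed with white Gaussian noise such that
    ``var(sum of oscillators) / var(noise) = snr_peripheral``.
    """
    if set_id not in _SET_IDS:
        raise ParameterError(f"set_id must be one of {_SET_IDS}")
    rng = _rng(seed)
    base = make_oscillator(3.0, 1.0, duration_s, fs, rng)
    if set_id == "S1":
        comp6 = make_oscillator(6.0, 2.0, duration_s, fs, rng)
        comp9 = make_oscillator(9.0, 3.0, duration_s, fs, rng)
    else:
        comp6 = warp_frequency(base, 2, 3.0, 1.0)
        comp9 = warp_frequency(base, 3, 3.0, 1.0)
        for c in (comp6, comp9):
            c.data[0] /= c.data[0].std()
    comps = []
    for ratio, ts, f in zip(power_ratios, (base, comp6, comp9), (3, 6, 9)):
        scaled = ts.data[0] * np.sqrt(ratio)
        comps.append(TimeSeriesSet(scaled[None, :], fs, [f"comp{f}"]))
    total = sum(c.data[0] for c in comps)
    noise = rng.standard_normal(total.size)
    noise *= np.sqrt(total.var() / (snr_peripheral * noise.var()))
    periph = TimeSeriesSet((total + noise)[None, :], fs, ["peripheral"])
    return periph, comps


# ---------------------------------------------------------------------------
# Synthetic head model
# ---------------------------------------------------------------------------

def electrode_layout(n_channels: int = 61) -> np.ndarray:
    """Equiangular electrode positions on a unit-sphere cap.

    Electrodes are arranged in concentric rings (1, 6, 12, 18, 24, ... per
    ring) from the vertex down to a polar angle of 72 degrees; the layout
    is truncated/extended to exactly ``n_channels`` positions. Returns unit
    vectors of shape (n_channels, 3).
    """
    if n_channels < 8:
        raise ParameterError("need at least 8 channels")
    ring_sizes = [1]
    k = 1
    while sum(ring_sizes) < n_channels:
        ring_sizes.append(6 * k)
        k += 1
    n_rings = len(ring_sizes)
    positions = []
    for i, size in enumerate(ring_sizes):
        theta = np.deg2rad(72.0) * i / max(n_rings - 1, 1)
        for m in range(size):
            phi = 2 * np.pi * m / size + (i % 2) * np.pi / max(size, 1)
            positions.append(
                [
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ]
            )
            if len(positions) == n_channels:
                return np.asarray(positions)
    return np.asarray(positions[:n_channels])


def layout_neighbor_pairs(positions: np.ndarray) -> np.ndarray:
    """Index pairs of adjacent electrodes on the layout graph.

    Two electrodes are neighbors when their angular distance is below 1.6
    times the median nearest-neighbor distance.
    """
    cosang = np.clip(positions @ positions.T, -1, 1)
    ang = np.arccos(cosang)
    np.fill_diagonal(ang, np.inf)
    nn = np.min(ang, axis=1)
    thresh = 1.6 * np.median(nn)
    i, j = np.where(np.triu(ang < thresh, k=1))
    return np.column_stack([i, j])


def synthetic_leadfield(
    n_channels: int,
    n_sources: int,
    layout: np.ndarray | None = None,
    seed=None,
    max_pairwise_cos: float = 0.8,
    max_tries: int = 100,
) -> np.ndarray:
    """Random smooth pseudo-dipolar source topographies.

    Each source column is a difference of two spatial Gaussians (widths
    0.40 and 0.80 rad) centered at a random location on the electrode cap,
    giving a positive core with a weak surround — a desk-scale stand-in for
    a volume-conductor forward model. Columns are unit-normalized and
    resampled until all pairwise ``|cos|`` similarities are below
    ``max_pairwise_cos`` (spatially distinct sources).
    """
    rng = _rng(seed)
    pos = electrode_layout(n_channels) if layout is None else np.asarray(layout)
    sigma_core, sigma_surround, surround_gain = 0.40, 0.80, 0.60

    def draw_column() -> np.ndarray:
        theta = np.deg2rad(rng.uniform(0.0, 70.0))
        phi = rng.uniform(0, 2 * np.pi)
        c = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        d = np.arccos(np.clip(pos @ c, -1, 1))
        g = np.exp(-(d**2) / (2 * sigma_core**2)) - surround_gain * np.exp(
            -(d**2) / (2 * sigma_surround**2)
        )
        return g / np.linalg.norm(g)

    cols: list[np.ndarray] = []
    for _ in range(n_sources):
        for attempt in range(max_tries):
            cand = draw_column()
            if all(abs(cand @ c) < max_pairwise_cos for c in cols):
                cols.append(cand)
                break
        else:
            raise NumericalError(
                f"could not draw a distinct source column in {max_tries} tries"
            )
    return np.column_stack(cols)


def pink_background(
    n_channels: int,
    n_noise_dipoles: int = 500,
    duration_s: float = 300.0,
    fs: float = 500.0,
    seed=None,
) -> TimeSeriesSet:
    """Superposition of many 1/f dipole time courses at the sensors.

    ``n_noise_dipoles`` independent time courses with power spectral
    density proportional to 1/f (synthesized in the frequency domain) are
    projected through random unit topographies and summed, yielding a
    full-rank spatially colored background.
    """
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 => power ~ 1/f
    out = np.zeros((n_channels, n))
    chunk = max(1, int(2e7 // n))
    for i in range(0, n_noise_dipoles, chunk):
        m = min(chunk, n_noise_dipoles - i)
        spec = (
            rng.standard_normal((m, freqs.size))
            + 1j * rng.standard_normal((m, freqs.size))
        ) * shape
        dipoles = np.fft.irfft(spec, n=n, axis=-1)
        topo = rng.standard_normal((n_channels, m))
        topo /= np.linalg.norm(topo, axis=0, keepdims=True)
        out += topo @ dipoles
    labels = [f"E{i:02d}" for i in range(n_channels)]
    return TimeSeriesSet(out, fs, labels)


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

def _delay(v: np.ndarray, lag_samples: int) -> np.ndarray:
    out = np.zeros_like(v)
    if lag_samples == 0:
        return v.copy()
    out[lag_samples:] = v[:-lag_samples]
    return out


def _unit_var(v: np.ndarray) -> np.ndarray:
    return v / v.std()


def assemble_scenario(
    scenario: SimulationScenario,
    leadfield: np.ndarray | None = None,
) -> SimulationBundle:
    """Build a full EEG + peripheral bundle with ground truth.

    Brain sources are constructed per ``scenario.set_id``, delayed by
    ``lag_ms`` relative to the peripheral oscillators, projected through
    the (synthetic or user-supplied) leadfield and scaled so that, for
    each source, mean-over-channels variance of the projected component
    divided by mean-over-channels variance of the 1/f background equals
    ``snr_brain``. Deterministic: identical scenario and seed give a
    bit-identical bundle.

    Parameters
    ----------
    leadfield : ndarray (n_channels, n_sources), optional
        Replaces the synthetic leadfield; column order must follow the
        source labels of the scenario set (S1: 3:3, 6:6, 9:9, 3:6, 3:9;
        S2/S3: 3:6, 3:9, independent).
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    rng_periph, rng_lead, rng_bg, rng_extra = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    periph, comps = make_peripheral(
        sc.set_id, sc.fs, sc.duration_s, sc.power_ratios, sc.snr_peripheral, rng_periph
    )
    base3 = TimeSeriesSet(_unit_var(comps[0].data[0])[None, :], sc.fs, ["base3"])
    sources: dict[str, np.ndarray] = {}
    if sc.set_id == "S1":
        sources["3:3"] = _unit_var(comps[0].data[0])
        sources["6:6"] = _unit_var(comps[1].data[0])
        sources["9:9"] = _unit_var(comps[2].data[0])
        sources["3:6"] = _unit_var(warp_frequency(base3, 2, 3.0, 1.0).data[0])
        sources["3:9"] = _unit_var(warp_frequency(base3, 3, 3.0, 1.0).data[0])
        labels = ["3:3", "6:6", "9:9", "3:6", "3:9"]
    else:
        # the warped peripheral components ARE the coupled brain sources
        sources["3:6"] = _unit_var(comps[1].data[0])
        sources["3:9"] = _unit_var(comps[2].data[0])
        sources["independent"] = make_oscillator(
            6.0, 2.0, sc.duration_s, sc.fs, rng_extra
        ).data[0]
        labels = ["3:6", "3:9", "independent"]

    if leadfield is None:
        if sc.set_id == "S3":
            # coupled sources co-located: two distinct columns only
            lf2 = synthetic_leadfield(sc.n_channels, 2, seed=rng_lead)
            col = {"3:6": lf2[:, 0], "3:9": lf2[:, 0], "independent": lf2[:, 1]}
        else:
            lf = synthetic_leadfield(sc.n_channels, len(labels), seed=rng_lead)
            col = {lab: lf[:, i] for i, lab in enumerate(labels)}
    else:
        leadfield = np.asarray(leadfield, dtype=float)
        if leadfield.shape != (sc.n_channels, len(labels)):
            raise ParameterError(
                f"leadfield must have shape ({sc.n_channels}, {len(labels)})"
            )
        col = {lab: leadfield[:, i] for i, lab in enumerate(labels)}

    background = pink_background(
        sc.n_channels, sc.n_noise_dipoles, sc.duration_s, sc.fs, rng_bg
    )
    bg_var = background.data.var(axis=1).mean()
    lag = int(round(sc.lag_ms * sc.fs / 1000.0))
    eeg_data = background.data.copy()
    truth_patterns: dict[str, SpatialPattern] = {}
    truth_sources: dict[str, TimeSeriesSet] = {}
    ch_labels = background.labels
    for lab in labels:
        src = _delay(sources[lab], lag)
        c = col[lab]
        # unit-norm column => mean channel variance of the projection is
        # var(src)/n_channels; scale to the requested brain SNR
        gain = np.sqrt(
            sc.snr_brain * bg_var / (src.var() * np.mean(c**2))
        )
        eeg_data += np.outer(c, gain * src)
        truth_patterns[lab] = SpatialPattern(c.copy(), list(ch_labels))
        truth_sources[lab] = TimeSeriesSet(
            (gain * src)[None, :], sc.fs, [f"src_{lab}"]
        )
    eeg = TimeSeriesSet(eeg_data, sc.fs, list(ch_labels))
    return SimulationBundle(
        eeg=eeg,
        peripheral=periph,
        truth_patterns=truth_patterns,
        truth_sources=truth_sources,
        scenario=sc,
    )


def interactions_for_set(set_id: str) -> list[str]:
    """Interaction labels evaluated in the sweep for a scenario family."""
    if set_id == "S1":
        return ["3:3", "6:6", "9:9", "3:6", "3:9"]
    return ["6:6", "9:9", "3:6", "3:9", "independent"]


def snr_sweep(
    set_id: str,
    snr_grid=DEFAULT_SNR_GRID,
    n_repetitions: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
    duration_s: float = 300.0,
    fs: float = 500.0,
    n_channels: int = 61,
    n_noise_dipoles: int = 500,
    interactions: list[str] | None = None,
    n_restarts: int = 10,
    progress: Callable[[str], None] | None = None,
    pattern_store: dict | None = None,
) -> pd.DataFrame:
    """Recovery-performance sweep over a brain-SNR grid.

    For each (SNR, repetition, interaction): a fresh bundle is generated,
    the pattern recovered with caCOH (within-frequency) or XF-caCOH
    (cross-frequency), the recovery error against the ground-truth pattern
    computed, and a trial-permutation null of the recovery error built by
    shuffling 1 s peripheral epochs and re-running the pipeline
    ``n_permutations`` times. The p-value is the proportion of permuted
    errors smaller than or equal to the observed one; the combination is
    flagged as failed when p > 0.05 (the recovery is indistinguishable
    from chance).

    When ``pattern_store`` is a dict, the recovered pattern of every
    combination is stored under ``(snr, repetition, interaction)`` as a
    :class:`SpatialPattern` (for downstream polarity-aligned averaging).

    Returns a long-format DataFrame with one row per combination; aggregate
    failure proportions with :func:`aggregate_failures`.
    """
    from .permutation import rerror_significance

    if len(tuple(snr_grid)) == 0:
        raise ParameterError("snr_grid must be non-empty")
    interactions = interactions or interactions_for_set(set_id)
    ss = np.random.SeedSequence(seed)
    rows = []
    for snr in snr_grid:
        for rep in range(n_repetitions):
            child = ss.spawn(1)[0]
            scen = SimulationScenario(
                set_id=set_id,
                snr_brain=snr,
                duration_s=duration_s,
                fs=fs,
                n_channels=n_channels,
                n_noise_dipoles=n_noise_dipoles,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            bundle = assemble_scenario(scen)
            cache: dict = {}
            for inter in interactions:
                if progress:
                    progress(f"snr={snr} rep={rep} interaction={inter}")
                null = rerror_significance(
                    bundle,
                    inter,
                    n_perm=n_permutations,
                    seed=int(child.generate_state(2)[1] % (2**31)),
                    n_restarts=n_restarts,
                    _prep_cache=cache,
                )
                if pattern_store is not None:
                    pattern_store[(snr, rep, inter)] = SpatialPattern(
                        null.observed_pattern.copy(), list(bundle.eeg.labels)
                    )
                rows.append(
                    {
                        "snr": snr,
                        "repetition": rep,
                        "interaction": inter,
                        "coherence": null.observed_coherence,
                        "rerror": null.observed,
                        "null_p95": null.percentile_95,
                        "p_value": null.p_value,
                        "failed": null.p_value > 0.05,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_failures(sweep: pd.DataFrame) -> pd.DataFrame:
    """Failure proportion per (snr, interaction) from a sweep table."""
    return (
        sweep.groupby(["snr", "interaction"])["failed"]
        .mean()
        .rename("failure_proportion")
        .reset_index()
    )
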