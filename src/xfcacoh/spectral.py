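"""Cross-spectral estimation and narrow-band filtering.

This module provides the numerical substrate of canonical coherence: a
Welch-style estimator of the joint cross-spectral matrix of two multichannel
signal spaces, zero-phase Butterworth band-pass filtering, and frequency-bin
lookup.

Conventions
-----------
* Forward DFT with kernel ``exp(-j 2 pi f t)`` (the numpy/scipy convention).
* ``cab[p, q] = E[A_p(f) * conj(B_q(f))]`` so that if channel ``b`` lags
  channel ``a`` by a phase ``theta`` at the bin, ``arg(cab) = -theta``.
* One-sided spectral-density scaling (as in :func:`scipy.signal.csd`); all
  coherence-type quantities are invariant to this scaling.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    NumericalError,
    ParameterError,
    ShapeError,
)

logger = logging.getLogger(__name__)

#: seconds discarded at each end of a signal after zero-phase filtering and
#: Hilbert transformation, before any phase-based index is computed
EDGE_SECONDS = 2.0


@dataclasses.dataclass
class TimeSeriesSet:
    """A multichannel signal block with sampling rate and channel labels.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Real-valued signals, one row per channel. A 1-D array is promoted to
        a single-channel block.
    fs : float
        Sampling rate in Hz, strictly positive.
    labels : list of str, optional
        Channel names; generated as ``ch00, ch01, ...`` when omitted.
    epochs : list of (int, int), optional
        Half-open sample intervals ``[start, end)`` marking trials/blocks;
        must be sorted, non-overlapping and within ``[0, n_samples)``.
    """

    data: np.ndarray
    fs: float
    labels: list[str] | None = None
    epochs: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ShapeError("data must be a (n_channels, n_samples) matrix")
        if self.data.shape[1] < 2:
            raise ShapeError("need at least 2 samples")
        if not self.fs > 0:
            raise ParameterError("fs must be positive")
        if self.labels is None:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ShapeError("labels length must equal n_channels")
        if self.epochs is not None:
            prev_end = 0
            for start, end in self.epochs:
                if not (0 <= start < end <= self.data.shape[1]):
                    raise ParameterError(f"epoch [{start}, {end}) out of range")
                if start < prev_end:
                    raise ParameterError("epochs must be sorted and non-overlapping")
                prev_end = end

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int) -> "TimeSeriesSet":
        """Return a single-channel view as a new TimeSeriesSet."""
        return TimeSeriesSet(
            self.data[index : index + 1].copy(),
            self.fs,
            [self.labels[index]],
            self.epochs,
        )


@dataclasses.dataclass
class CrossSpectra:
    """Per-frequency-bin cross-spectral blocks of two channel spaces.

    Attributes
    ----------
    freqs : ndarray, shape (n_bins,)
        Bin centers in Hz, strictly increasing, within ``[0, fs/2]``.
    caa, cbb : complex ndarray, shape (n_bins, P_A, P_A) / (n_bins, P_B, P_B)
        Hermitian auto-spectral matrices of spaces A and B.
    cab : complex ndarray, shape (n_bins, P_A, P_B)
        Cross-spectral block between spaces.
    n_segments : int
        Number of averaged Welch segments.
    """

    freqs: np.ndarray
    caa: np.ndarray
    cbb: np.ndarray
    cab: np.ndarray
    n_segments: int

    def validate(self, atol: float = 1e-10) -> None:
        """Check Hermitian symmetry and joint positive semidefiniteness."""
        if not np.all(np.diff(self.freqs) > 0):
            raise ParameterError("freqs must be strictly increasing")
        for name, block in (("caa", self.caa), ("cbb", self.cbb)):
            if not np.allclose(block, np.conj(np.swapaxes(block, 1, 2)), atol=atol):
                raise NumericalError(f"{name} is not Hermitian within tolerance")
            if np.any(np.min(np.real(np.diagonal(block, axis1=1, axis2=2)), axis=1) < -atol):
                raise ParameterError(f"{name} has negative diagonal entries")
        joint = self.joint()
        ev = np.linalg.eigvalsh(joint)
        tr = np.real(np.trace(joint, axis1=1, axis2=2))
        if np.any(ev[:, 0] < -1e-10 * np.maximum(tr, 1e-300)):
            raise ParameterError("joint cross-spectral matrix is not PSD")

    def joint(self) -> np.ndarray:
        """Assemble the joint matrix ``[[caa, cab], [cab^H, cbb]]`` per bin."""
        upper = np.concatenate([self.caa, self.cab], axis=2)
        lower = np.concatenate(
            [np.conj(np.swapaxes(self.cab, 1, 2)), self.cbb], axis=2
        )
        return np.concatenate([upper, lower], axis=1)

    def at(self, index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return the (caa, cbb, cab) blocks at one bin."""
        return self.caa[index], self.cbb[index], self.cab[index]


# ---------------------------------------------------------------------------
# Welch machinery
# ---------------------------------------------------------------------------

def _segment_starts(n_samples: int, seg_len: int, hop: int) -> np.ndarray:
    return np.arange(0, n_samples - seg_len + 1, hop)


def _windowed_segments(data: np.ndarray, starts: np.ndarray, seg_len: int) -> np.ndarray:
    """Mean-removed segments, shape (n_segments, P, seg_len). No window yet."""
    view = sliding_window_view(data, seg_len, axis=-1)  # (P, n_pos, seg_len)
    segs = view[:, starts, :].transpose(1, 0, 2).astype(float, copy=True)
    segs -= segs.mean(axis=-1, keepdims=True)
    return segs


def _welch_params(
    fs: float, n_samples: int, segment_len_s: float, overlap_frac: float, taper: str
) -> tuple[int, int, np.ndarray]:
    seg_len = int(round(segment_len_s * fs))
    if seg_len < 16:
        raise ParameterError("segment length must cover at least 16 samples")
    if not 0 <= overlap_frac < 1:
        raise ParameterError("overlap_frac must lie in [0, 1)")
    hop = max(1, int(round(seg_len * (1 - overlap_frac))))
    window = sps.get_window(taper, seg_len)
    return seg_len, hop, window


def estimate_cross_spectra(
    a: TimeSeriesSet,
    b: TimeSeriesSet,
    segment_len_s: float = 1.0,
    overlap_frac: float = 0.5,
    taper: str = "hann",
) -> CrossSpectra:
    """Welch segment-averaged cross-spectra over the joint channel space.

    Segments of ``segment_len_s`` seconds (per-segment mean removed, tapered)
    are Fourier transformed and the outer products of the joint coefficient
    vectors averaged, yielding Hermitian ``caa``/``cbb`` blocks and the
    cross block ``cab`` at every rFFT bin. The joint matrix is positive
    semidefinite by construction.

    Raises
    ------
    AlignmentError
        If ``a`` and ``b`` differ in sampling rate or length.
    InsufficientDataError
        If fewer than 2 complete segments fit.
    """
    if a.fs != b.fs:
        raise AlignmentError(f"sampling rates differ: {a.fs} vs {b.fs}")
    if a.n_samples != b.n_samples:
        raise AlignmentError("signal lengths differ; inputs must be time-aligned")
    seg_len, hop, window = _welch_params(
        a.fs, a.n_samples, segment_len_s, overlap_frac, taper
    )
    starts = _segment_starts(a.n_samples, seg_len, hop)
    if len(starts) < 2:
        raise InsufficientDataError(
            f"only {len(starts)} complete segment(s); need at least 2"
        )
    pa, pb = a.n_channels, b.n_channels
    data = np.vstack([a.data, b.data])
    freqs = np.fft.rfftfreq(seg_len, 1.0 / a.fs)
    n_bins = len(freqs)
    p = pa + pb
    acc = np.zeros((n_bins, p, p), dtype=complex)
    # chunk over segments to bound memory on long recordings
    chunk = max(1, int(2e7 // (p * n_bins)))
    for i in range(0, len(starts), chunk):
        segs = _windowed_segments(data, starts[i : i + chunk], seg_len)
        segs *= window
        z = np.fft.rfft(segs, axis=-1)  # (n_seg, P, n_bins)
        acc += np.einsum("spf,sqf->fpq", z, np.conj(z))
    acc /= len(starts)
    # one-sided density scaling, matching scipy.signal.csd
    scale = 1.0 / (a.fs * np.sum(window**2))
    acc *= scale
    one_sided = np.full(n_bins, 2.0)
    one_sided[0] = 1.0
    if seg_len % 2 == 0:
        one_sided[-1] = 1.0
    acc *= one_sided[:, None, None]
    # exact Hermitian symmetrization (removes float round-off asymmetry)
    acc = 0.5 * (acc + np.conj(np.swapaxes(acc, 1, 2)))
    return CrossSpectra(
        freqs=freqs,
        caa=acc[:, :pa, :pa],
        cbb=acc[:, pa:, pa:],
        cab=acc[:, :pa, pa:],
        n_segments=len(starts),
    )


# ---------------------------------------------------------------------------
# Single-bin fast path (shared with the permutation machinery)
# ---------------------------------------------------------------------------

def segment_dft_at_bin(
    data: np.ndarray,
    fs: float,
    bin_hz: float,
    segment_len_s: float = 1.0,
    overlap_frac: float = 0.5,
    taper: str = "hann",
) -> tuple[np.ndarray, float]:
    """Per-segment windowed DFT coefficients at the bin nearest ``bin_hz``.

    Returns ``(Z, f_actual)`` where ``Z`` has shape (n_segments, P). The
    coefficients follow the same segmentation, detrending, taper and scaling
    as :func:`estimate_cross_spectra`, so outer-product averages of ``Z``
    reproduce that estimator's blocks at the bin to round-off.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    seg_len, hop, window = _welch_params(
        fs, data.shape[1], segment_len_s, overlap_frac, taper
    )
    starts = _segment_starts(data.shape[1], seg_len, hop)
    if len(starts) < 2:
        raise InsufficientDataError("need at least 2 complete segments")
    freqs = np.fft.rfftfreq(seg_len, 1.0 / fs)
    k = nearest_bin(freqs, bin_hz)
    kernel = window * np.exp(-2j * np.pi * k * np.arange(seg_len) / seg_len)
    segs = _windowed_segments(data, starts, seg_len)
    z = segs @ kernel  # (n_seg, P)
    scale = 1.0 / (fs * np.sum(window**2))
    side = 2.0 if (k != 0 and not (seg_len % 2 == 0 and k == seg_len // 2)) else 1.0
    z *= np.sqrt(scale * side)
    return z, float(freqs[k])


def blocks_from_coeffs(
    za: np.ndarray, zb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average outer products of per-segment coefficients into CSD blocks."""
    n = za.shape[0]
    caa = (za.T @ np.conj(za)) / n
    cbb = (zb.T @ np.conj(zb)) / n
    cab = (za.T @ np.conj(zb)) / n
    caa = 0.5 * (caa + np.conj(caa.T))
    cbb = 0.5 * (cbb + np.conj(cbb.T))
    return caa, cbb, cab


# ---------------------------------------------------------------------------
# Filtering and bin lookup
# ---------------------------------------------------------------------------

def band_filter(
    x: TimeSeriesSet, center_hz: float, half_bw_hz: float
) -> TimeSeriesSet:
    """Zero-phase 4th-order Butterworth band-pass filter.

    The passband is ``[center - half_bw, center + half_bw]``; the filter is
    applied forward and backward (``sosfiltfilt``), doubling the effective
    attenuation and cancelling phase distortion. Edges are protected by
    odd-reflection padding of about three filter time constants; callers
    computing phase-based indices should additionally discard
    :data:`EDGE_SECONDS` at each end.
    """
    lo = center_hz - half_bw_hz
    hi = center_hz + half_bw_hz
    if not lo > 0:
        raise ParameterError(f"lower band edge {lo} Hz must be positive")
    if not hi < x.fs / 2:
        raise ParameterError(f"upper band edge {hi} Hz must be below Nyquist")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=x.fs, output="sos")
    padlen = int(min(x.n_samples - 1, round(3 * x.fs / half_bw_hz)))
    filtered = sps.sosfiltfilt(sos, x.data, axis=-1, padtype="odd", padlen=padlen)
    return TimeSeriesSet(filtered, x.fs, list(x.labels), x.epochs)


def nearest_bin(freqs: Sequence[float], target_hz: float) -> int:
    """Index of the bin center closest to ``target_hz``; ties go low.

    Logs a warning when the closest bin is farther than one bin spacing from
    the target (the target falls between frequency grids).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ParameterError("freqs must be non-empty")
    dist = np.abs(freqs - target_hz)
    idx = int(np.argmin(dist))  # argmin returns the first (lower-frequency) tie
    spacing = np.min(np.diff(freqs)) if freqs.size > 1 else np.inf
    if dist[idx] > spacing:
        logger.warning(
            "target %.3f Hz is %.3f Hz from the nearest bin (%.3f Hz), "
            "more than one bin spacing",
            target_hz,
            dist[idx],
            freqs[idx],
        )
    return idx


def edge_samples(fs: float, n_samples: int, edge_s: float = EDGE_SECONDS) -> slice:
    """Slice that drops ``edge_s`` seconds at each end (clamped to n/4)."""
    k = int(round(min(edge_s, n_samples / fs / 4) * fs))
    return slice(k, n_samples - k if k > 0 else n_samples)
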