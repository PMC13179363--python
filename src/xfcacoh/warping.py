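"""Non-linear frequency warping of narrow-band signals.

A narrow-band signal ``b(t)`` has an analytic representation
``s(t) = b(t) + j H{b(t)}`` (Hilbert transform ``H``), from which the
instantaneous amplitude ``a(t) = |s(t)|`` and phase ``phi(t) = arg s(t)``
are obtained. Frequency warping by an integer factor ``r`` keeps the
amplitude envelope and multiplies the (unwrapped) phase:

    b_r(t) = Re{ a(t) * exp(j * r * phi(t)) }

shifting the dominant frequency to ``r``-times the original while preserving
the envelope and the phase dynamics. This is the manipulation that makes a
slow peripheral signal comparable, in phase, to a cortical rhythm at an
integer multiple of its frequency.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

from .exceptions import ParameterError, ShapeError
from .spectral import TimeSeriesSet, band_filter

logger = logging.getLogger(__name__)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values to the interval ``(-pi, pi]``."""
    return -(np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) - np.pi)


@dataclasses.dataclass
class AnalyticSeries:
    """Instantaneous amplitude and phase of a univariate narrow-band signal.

    ``phase`` is stored wrapped to ``(-pi, pi]``; operations that multiply
    the phase unwrap it first.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ShapeError("amplitude and phase must have equal length")
        if np.any(self.amplitude < 0):
            raise ParameterError("amplitude must be nonnegative")

    def reconstruct(self) -> np.ndarray:
        """Return ``a(t) * cos(phi(t))``, the real part of the analytic signal."""
        return self.amplitude * np.cos(self.phase)

    def unwrapped_phase(self) -> np.ndarray:
        return np.unwrap(self.phase)


def analytic_signal(
    x: TimeSeriesSet, flatness_warn_threshold: float = 0.6
) -> AnalyticSeries:
    """Hilbert-transform analytic representation of a univariate signal.

    The caller is responsible for narrow-band filtering the input first;
    a warning is logged when the spectral flatness (geometric over
    arithmetic mean of the periodogram) exceeds ``flatness_warn_threshold``,
    indicating a broadband signal whose instantaneous phase is ill-defined.
    Zero-amplitude samples get phase 0 by convention.
    """
    if x.n_channels != 1:
        raise ShapeError("analytic_signal expects a single-channel input")
    v = x.data[0]
    _, pxx = sps.periodogram(v, fs=x.fs)
    pxx = pxx[pxx > 0]
    if pxx.size:
        flatness = np.exp(np.mean(np.log(pxx))) / np.mean(pxx)
        if flatness > flatness_warn_threshold:
            logger.warning(
                "input looks broadband (spectral flatness %.2f); "
                "instantaneous phase may be unreliable",
                flatness,
            )
    s = sps.hilbert(v)
    amp = np.abs(s)
    phase = np.angle(s)
    phase[amp == 0] = 0.0
    return AnalyticSeries(amplitude=amp, phase=phase, fs=x.fs)


def warp_frequency(
    x: TimeSeriesSet,
    r: int,
    center_hz: float,
    half_bw_hz: float,
) -> TimeSeriesSet:
    """Scale the dominant frequency of ``x`` by an integer factor ``r``.

    The input is first band-pass filtered around ``center_hz`` (zero-phase,
    4th-order Butterworth) so the instantaneous phase is well defined, then
    the amplitude envelope is retained while the unwrapped phase is
    multiplied by ``r``. With ``r = 1`` the output equals the band-filtered
    input. The first and last 2 s are affected by filter/Hilbert edge
    effects; downstream phase indices exclude them.

    Raises
    ------
    ParameterError
        If ``r < 1``, or the warped band ``r * (center + half_bw)`` would
        reach the Nyquist frequency (aliasing).
    """
    if x.n_channels != 1:
        raise ShapeError("warp_frequency expects a single-channel input")
    if not (isinstance(r, (int, np.integer)) and r >= 1):
        raise ParameterError("r must be a positive integer")
    if r * (center_hz + half_bw_hz) >= x.fs / 2:
        raise ParameterError(
            f"warped band reaches {r * (center_hz + half_bw_hz)} Hz, "
            f"at or above Nyquist ({x.fs / 2} Hz)"
        )
    filtered = band_filter(x, center_hz, half_bw_hz)
    s = sps.hilbert(filtered.data[0])
    amp = np.abs(s)
    phase = np.unwrap(np.angle(s))
    warped = amp * np.cos(r * phase)
    label = f"{x.labels[0]}_x{r}"
    return TimeSeriesSet(warped[None, :], x.fs, [label], x.epochs)
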