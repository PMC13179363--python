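"""n:m phase-synchronization between univariate signals.

Two narrow-band processes with central frequencies ``f_q`` and ``f_r``
related by ``q * f_r = r * f_q`` are phase synchronized when their
generalized phase difference

    psi(t) = q * phi_r(t) - r * phi_q(t)

is concentrated rather than uniform. The synchronization index is the
modulus of the circular mean of ``exp(j psi)`` over time, ranging from 0
(no synchronization) to 1 (perfect phase locking). Within-frequency
synchronization is the special case q = r = 1.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .exceptions import InsufficientDataError, ParameterError, ShapeError
from .spectral import EDGE_SECONDS, TimeSeriesSet, band_filter, edge_samples
from .warping import analytic_signal, wrap_phase

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CouplingSpec:
    """The (f_q, f_r, q, r) frequency-ratio contract of an interaction.

    The public surface of this package fixes ``q = 1`` (a fast process at an
    integer multiple ``r`` of a slow one); the phase-level core functions
    accept general (q, r).
    """

    f_q: float
    f_r: float
    q: int = 1
    r: int = 1

    def __post_init__(self) -> None:
        if self.q != 1:
            raise ParameterError("CouplingSpec fixes q = 1")
        if not (isinstance(self.r, (int, np.integer)) and self.r >= 1):
            raise ParameterError("r must be a positive integer")
        if self.f_q <= 0 or self.f_r <= 0:
            raise ParameterError("frequencies must be positive")
        if abs(self.q * self.f_r - self.r * self.f_q) > 1.0 + 1e-9:
            raise ParameterError(
                f"q*f_r = {self.q * self.f_r} and r*f_q = {self.r * self.f_q} "
                "differ by more than one bin spacing (1 Hz)"
            )

    @property
    def label(self) -> str:
        return f"{self.f_q:g}:{self.f_r:g}"


@dataclasses.dataclass
class SyncResult:
    """Synchronization index with bookkeeping."""

    k_sync: float
    n_used: int
    spec: CouplingSpec | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k_sync <= 1 + 1e-12:
            raise ParameterError("k_sync must lie in [0, 1]")
        if self.n_used <= 0:
            raise ParameterError("n_used must be positive")


def generalized_phase_difference(
    phi_q: np.ndarray, phi_r: np.ndarray, q: int, r: int
) -> np.ndarray:
    """``psi(t) = q * phi_r(t) - r * phi_q(t)``, wrapped to ``(-pi, pi]``."""
    phi_q = np.asarray(phi_q, dtype=float)
    phi_r = np.asarray(phi_r, dtype=float)
    if phi_q.shape != phi_r.shape:
        raise ShapeError("phase vectors must have equal length")
    return wrap_phase(q * phi_r - r * phi_q)


def sync_index(
    phi_q: np.ndarray,
    phi_r: np.ndarray,
    q: int,
    r: int,
    spec: CouplingSpec | None = None,
) -> SyncResult:
    """Modulus of the circular mean of ``exp(j psi)``.

    Deterministic for fixed input. Warns for fewer than 100 samples, where
    the null distribution of the index is wide (its null expectation is
    approximately ``sqrt(pi)/2 / sqrt(N)``).
    """
    psi = generalized_phase_difference(phi_q, phi_r, q, r)
    n = psi.size
    if n == 0:
        raise InsufficientDataError("empty phase vectors")
    if n < 100:
        logger.warning("sync_index called with only %d samples", n)
    k = float(np.abs(np.mean(np.exp(1j * psi))))
    return SyncResult(k_sync=min(k, 1.0), n_used=n, spec=spec)


def cross_freq_sync(
    x: TimeSeriesSet,
    y: TimeSeriesSet,
    spec: CouplingSpec,
    half_bw_hz: float = 1.0,
    edge_s: float = EDGE_SECONDS,
) -> SyncResult:
    """n:m synchronization between two signals at ``spec.f_q : spec.f_r``.

    ``x`` is band-filtered around ``f_q`` with half-bandwidth ``half_bw_hz``
    and ``y`` around ``f_r`` with the half-bandwidth scaled by ``f_r/f_q``
    (constant relative bandwidth, so a warped copy of ``x`` and ``y`` see
    matching bands); instantaneous phases come from the Hilbert transform,
    edge samples are dropped, and the synchronization index is returned.

    The peripheral self-coupling analysis (e.g. 3:6 on an accelerometer
    component) is exactly this function applied to ``(x, x)``.
    """
    if x.fs != y.fs:
        raise ParameterError("x and y must share the sampling rate")
    xf = band_filter(x, spec.f_q, half_bw_hz)
    yf = band_filter(y, spec.f_r, half_bw_hz * spec.f_r / spec.f_q)
    phi_q = analytic_signal(xf).phase
    phi_r = analytic_signal(yf).phase
    keep = edge_samples(x.fs, min(phi_q.size, phi_r.size), edge_s)
    return sync_index(phi_q[keep], phi_r[keep], spec.q, spec.r, spec=spec)
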