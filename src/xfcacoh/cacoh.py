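"""Canonical coherence (caCOH) and its cross-frequency extension (XF-caCOH).

At one frequency bin, caCOH finds real spatial filters ``alpha`` (space A,
e.g. multichannel EEG) and ``beta`` (space B, e.g. kinematics) maximizing

    L(alpha, beta) = |alpha^T C_AB beta|^2
                     / ((alpha^T C_AA alpha) (beta^T C_BB beta))

where C_AA, C_BB, C_AB are the cross-spectral blocks at the bin. The filters
are restricted to real coefficients (instantaneous linear mixing); the
residual complex degree of freedom is a per-bin phase rotation ``phi`` —
the delay at which the projected pair is maximally coherent. The reported
coupling strength is ``sqrt(max L)``, a coherence magnitude in [0, 1].

The optimum is found by alternating closed-form updates: with
``D = Re(C_AB e^{-j phi})``,

    alpha ∝ Re(C_AA)^-1 D beta,   beta ∝ Re(C_BB)^-1 D^T alpha,
    phi = arg(alpha^T C_AB beta),

each of which cannot decrease the objective; the best of several random
restarts is kept (the problem is not jointly convex).

Spatial *patterns* — the forward-model-like topographies interpretable as
source projections — are obtained from the filters as
``p = Re(C_AA) alpha``.

The cross-frequency variant warps the slow peripheral signal from ``f_q``
to ``f_r = r f_q`` (envelope kept, phase multiplied by ``r``) and applies
caCOH at the ``f_r`` bin.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import NumericalError, ShapeError
from .spectral import (
    CrossSpectra,
    TimeSeriesSet,
    band_filter,
    estimate_cross_spectra,
    nearest_bin,
)
from .sync import CouplingSpec
from .warping import warp_frequency

logger = logging.getLogger(__name__)

#: default shrinkage weight for the real auto-spectral matrices
DEFAULT_GAMMA = 1e-4


@dataclasses.dataclass
class CacohSolution:
    """Spatial filters, phase, coherence and patterns at one frequency bin.

    ``alpha``/``beta`` are unit-power filters (``a^T Re(C_AA) a = 1``);
    ``coherence`` is ``sqrt(max L)`` in [0, 1]; ``coherence_sq`` stores the
    squared objective. Pattern polarity: the largest-magnitude entry of
    ``pattern_a`` is positive.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: float
    coherence: float
    bin_hz: float
    pattern_a: np.ndarray
    pattern_b: np.ndarray
    n_restarts_used: int
    converged: bool
    coherence_sq: float = 0.0


@dataclasses.dataclass
class CouplingResult:
    """A caCOH/XF-caCOH solution together with its coupling contract."""

    solution: CacohSolution
    spec: CouplingSpec
    null_percentile_95: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.null_percentile_95 is not None:
            self.significant = bool(
                self.solution.coherence > self.null_percentile_95
            )


def _regularize(r: np.ndarray, gamma: float) -> np.ndarray:
    p = r.shape[0]
    if gamma <= 0 or p == 1:
        # for scalars the shrinkage target equals the matrix itself
        return r
    return (1 - gamma) * r + gamma * (np.trace(r) / p) * np.eye(p)


def maximize_coherence_blocks(
    caa: np.ndarray,
    cbb: np.ndarray,
    cab: np.ndarray,
    n_restarts: int = 10,
    tol: float = 1e-12,
    max_iter: int = 200,
    gamma: float = DEFAULT_GAMMA,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Alternating maximization on raw per-bin blocks.

    Returns ``(alpha, beta, phi, coherence, converged)`` with filters
    normalized to unit power against the regularized real auto-spectra.
    This is the computational core shared by :func:`maximize_cacoh` and the
    permutation fast path.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    cab = np.atleast_2d(np.asarray(cab))
    pa, pb = cab.shape
    ra = _regularize(np.real(np.atleast_2d(caa)), gamma)
    rb = _regularize(np.real(np.atleast_2d(cbb)), gamma)
    for name, r in (("Re(C_AA)", ra), ("Re(C_BB)", rb)):
        cond = np.linalg.cond(r, 1)  # 1-norm: exact enough, no SVD cost
        if not np.isfinite(cond) or cond > 1e12:
            raise NumericalError(
                f"{name} is ill-conditioned (cond={cond:.2e}) after regularization"
            )
    cho_a = cho_factor(ra)
    cho_b = cho_factor(rb)
    if not np.any(np.abs(cab) > 0):
        alpha = np.zeros(pa)
        alpha[0] = 1.0
        alpha /= np.sqrt(alpha @ ra @ alpha)
        beta = np.zeros(pb)
        beta[0] = 1.0
        beta /= np.sqrt(beta @ rb @ beta)
        return alpha, beta, 0.0, 0.0, True
    if pb == 1:
        return _maximize_univariate_b(ra, rb, cab, cho_a)

    best_obj = -np.inf
    best = None
    any_converged = False
    for _ in range(n_restarts):
        alpha = rng.standard_normal(pa)
        alpha /= np.sqrt(alpha @ ra @ alpha)
        beta = rng.standard_normal(pb)
        beta /= np.sqrt(beta @ rb @ beta)
        g = alpha @ cab @ beta
        obj_prev = np.abs(g) ** 2
        converged = False
        for _ in range(max_iter):
            phi = np.angle(g)
            d = np.real(cab * np.exp(-1j * phi))
            alpha = cho_solve(cho_a, d @ beta)
            na = np.sqrt(alpha @ ra @ alpha)
            if na < 1e-300:
                break
            alpha /= na
            beta = cho_solve(cho_b, d.T @ alpha)
            nb = np.sqrt(beta @ rb @ beta)
            if nb < 1e-300:
                break
            beta /= nb
            g = alpha @ cab @ beta
            obj = np.abs(g) ** 2
            if obj < obj_prev - 1e-8 * (abs(obj_prev) + 1e-15):
                raise NumericalError(
                    "alternating objective decreased; cross-spectral blocks "
                    "are inconsistent (not jointly PSD?)"
                )
            if obj - obj_prev <= tol * max(obj, 1e-300):
                converged = True
                break
            obj_prev = obj
        obj = np.abs(g) ** 2
        if obj > best_obj:
            best_obj = obj
            best = (alpha.copy(), beta.copy(), float(np.angle(g)))
            any_converged = converged
    alpha, beta, phi = best
    coherence = float(np.clip(np.sqrt(max(best_obj, 0.0)), 0.0, 1.0))
    return alpha, beta, phi, coherence, any_converged


def _maximize_univariate_b(
    ra: np.ndarray, rb: np.ndarray, cab: np.ndarray, cho_a
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Exact solution for a univariate space B (the CKC case).

    With a scalar beta the objective reduces to the generalized Rayleigh
    quotient ``alpha^T (u u^T + v v^T) alpha / (alpha^T Ra alpha * rb)``
    with ``u = Re(c)``, ``v = Im(c)`` and ``c`` the cross-spectral column.
    The maximizer lies in span{Ra^-1 u, Ra^-1 v}; writing
    ``G = B^T Ra^-1 B`` for ``B = [u, v]`` (2x2, PSD), the maximum equals
    the largest eigenvalue of G over rb, attained at the corresponding
    eigvector coordinates. Exact and deterministic — equivalent to the
    converged alternating scheme, without restarts.
    """
    c = cab[:, 0]
    u, v = np.real(c), np.imag(c)
    xu = cho_solve(cho_a, u)
    xv = cho_solve(cho_a, v)
    g = np.array([[u @ xu, u @ xv], [v @ xu, v @ xv]])
    g = 0.5 * (g + g.T)
    evals, evecs = np.linalg.eigh(g)
    lam = float(evals[-1])
    w = evecs[:, -1]
    alpha = xu * w[0] + xv * w[1]
    na = np.sqrt(alpha @ ra @ alpha)
    if na < 1e-300:  # cross-spectrum in the null space of Ra^-1
        alpha = np.zeros_like(alpha)
        alpha[0] = 1.0
        na = np.sqrt(alpha @ ra @ alpha)
    alpha /= na
    rb_val = float(rb[0, 0])
    beta = np.array([1.0 / np.sqrt(rb_val)])
    obj = max(lam, 0.0) / rb_val
    phi = float(np.angle(alpha @ c * beta[0]))
    coherence = float(np.clip(np.sqrt(obj), 0.0, 1.0))
    return alpha, beta, phi, coherence, True


def _fix_polarity(pattern: np.ndarray) -> int:
    """Sign making the largest-magnitude entry of ``pattern`` positive."""
    k = int(np.argmax(np.abs(pattern)))
    return -1 if pattern[k] < 0 else 1


def maximize_cacoh(
    cs: CrossSpectra,
    bin_hz: float,
    n_restarts: int = 10,
    tol: float = 1e-12,
    max_iter: int = 200,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> CacohSolution:
    """Maximize coherence between spaces A and B at the bin nearest ``bin_hz``.

    Deterministic given ``seed`` (restart initialization). The returned
    filters are rescaled to unit projected power against the *raw*
    ``Re(C_AA)``/``Re(C_BB)`` and the patterns' polarity is fixed so the
    largest-magnitude entry of ``pattern_a`` is positive.
    """
    k = nearest_bin(cs.freqs, bin_hz)
    caa, cbb, cab = cs.at(k)
    rng = np.random.default_rng(seed)
    alpha, beta, phi, coherence, converged = maximize_coherence_blocks(
        caa, cbb, cab, n_restarts, tol, max_iter, gamma, rng
    )
    if not converged:
        logger.warning(
            "caCOH did not converge within %d iterations at %.3g Hz; "
            "returning best iterate",
            max_iter,
            cs.freqs[k],
        )
    ra = np.real(np.atleast_2d(caa))
    rb = np.real(np.atleast_2d(cbb))
    alpha = alpha / np.sqrt(alpha @ ra @ alpha)
    beta = beta / np.sqrt(beta @ rb @ beta)
    pattern_a = ra @ alpha
    pattern_b = rb @ beta
    sa = _fix_polarity(pattern_a)
    alpha, pattern_a = sa * alpha, sa * pattern_a
    sb = _fix_polarity(pattern_b)
    beta, pattern_b = sb * beta, sb * pattern_b
    phi = float(np.angle(alpha @ np.atleast_2d(cab) @ beta))
    return CacohSolution(
        alpha=alpha,
        beta=beta,
        phi=phi,
        coherence=coherence,
        bin_hz=float(cs.freqs[k]),
        pattern_a=pattern_a,
        pattern_b=pattern_b,
        n_restarts_used=n_restarts,
        converged=converged,
        coherence_sq=coherence**2,
    )


def filters_to_pattern(caa_bin: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Spatial pattern ``p = Re(C_AA) alpha``, polarity-fixed.

    The pattern is the activation topography associated with a filter: the
    covariance-weighted back-projection that is interpretable as a source
    projection (unlike the filter itself). Not normalized.
    """
    caa_bin = np.atleast_2d(np.asarray(caa_bin))
    alpha = np.asarray(alpha, dtype=float)
    if caa_bin.shape[1] != alpha.shape[0]:
        raise ShapeError("caa_bin and alpha dimensions disagree")
    p = np.real(caa_bin) @ alpha
    return _fix_polarity(p) * p


def ckc(
    eeg: TimeSeriesSet,
    peripheral: TimeSeriesSet,
    f: float,
    segment_len_s: float = 1.0,
    overlap_frac: float = 0.5,
    taper: str = "hann",
    n_restarts: int = 10,
    tol: float = 1e-12,
    max_iter: int = 200,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> CouplingResult:
    """Within-frequency cortico-kinematic coupling at ``f`` Hz (spec f:f).

    Cross-spectra of (EEG, peripheral) are estimated and coherence maximized
    at the bin nearest ``f``. With a single peripheral channel the space-B
    filter is a scalar and only the EEG filters are free.
    """
    if peripheral.n_channels != 1:
        raise ShapeError("peripheral must be univariate")
    cs = estimate_cross_spectra(eeg, peripheral, segment_len_s, overlap_frac, taper)
    sol = maximize_cacoh(cs, f, n_restarts, tol, max_iter, gamma, seed)
    return CouplingResult(solution=sol, spec=CouplingSpec(f_q=f, f_r=f, q=1, r=1))


def xf_ckc(
    eeg: TimeSeriesSet,
    peripheral: TimeSeriesSet,
    spec: CouplingSpec,
    half_bw_hz: float = 1.0,
    segment_len_s: float = 1.0,
    overlap_frac: float = 0.5,
    taper: str = "hann",
    n_restarts: int = 10,
    tol: float = 1e-12,
    max_iter: int = 200,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> CouplingResult:
    """Cross-frequency CKC at ``spec.f_q : spec.f_r`` via frequency warping.

    The peripheral signal is band-filtered at ``f_q`` (half-bandwidth
    ``half_bw_hz``), its frequency scaled by ``r`` so its dominant frequency
    matches ``f_r = r * f_q``, and caCOH applied at the ``f_r`` bin. With
    ``r = 1`` the warp is the identity on the filtered signal, reducing to
    within-frequency coupling against the band-filtered peripheral.
    """
    if peripheral.n_channels != 1:
        raise ShapeError("peripheral must be univariate")
    warped = warp_frequency(peripheral, spec.r, spec.f_q, half_bw_hz)
    cs = estimate_cross_spectra(eeg, warped, segment_len_s, overlap_frac, taper)
    sol = maximize_cacoh(cs, spec.f_r, n_restarts, tol, max_iter, gamma, seed)
    return CouplingResult(solution=sol, spec=spec)


def project(
    eeg: TimeSeriesSet,
    alpha: np.ndarray,
    band_center: float,
    half_bw: float,
) -> TimeSeriesSet:
    """Project multichannel EEG onto a spatial filter and band-filter it.

    Returns the univariate source estimate ``alpha^T EEG`` filtered around
    ``band_center``; used for source-level synchronization analyses between
    different caCOH/XF-caCOH projections.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[0] != eeg.n_channels:
        raise ShapeError("alpha length must equal the number of EEG channels")
    mixed = TimeSeriesSet(
        (alpha @ eeg.data)[None, :], eeg.fs, ["projection"], eeg.epochs
    )
    return band_filter(mixed, band_center, half_bw)
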