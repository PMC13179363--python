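"""Spatial-pattern quality and comparison measures.

Patterns are channel-space topographies. All comparisons here are based on
the absolute cosine similarity, which is invariant to the scale and sign
ambiguity inherent to spatial-filter methods:

    k_sim  = |p1^T p2| / (||p1|| ||p2||)        (similarity, 1 = equal)
    RError = 1 - k_sim                           (recovery error, 0 = equal)

Polarity-aligned averaging and the similarity-vs-synchronization
correlation analysis (Pearson with Holm-Bonferroni adjustment across a
comparison family) are also provided.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ShapeError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SpatialPattern:
    """A channel-space topography with labels."""

    values: np.ndarray
    labels: list[str] | None = None
    norm_flag: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("pattern values must be finite")
        if np.linalg.norm(self.values) == 0:
            raise ParameterError("pattern must have non-zero norm")
        if self.labels is None:
            self.labels = [f"ch{i:02d}" for i in range(self.values.size)]
        if len(self.labels) != self.values.size:
            raise ShapeError("labels length must equal pattern length")

    def normalized(self) -> "SpatialPattern":
        return SpatialPattern(
            self.values / np.linalg.norm(self.values), list(self.labels), True
        )


def _as_values(p) -> np.ndarray:
    return p.values if isinstance(p, SpatialPattern) else np.asarray(p, float).ravel()


def _check_pair(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    v1, v2 = _as_values(p1), _as_values(p2)
    if v1.shape != v2.shape:
        raise ShapeError("patterns must have equal length")
    if isinstance(p1, SpatialPattern) and isinstance(p2, SpatialPattern):
        if p1.labels != p2.labels:
            raise ShapeError("pattern channel labels do not match")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ParameterError("zero-norm pattern")
    return v1, v2


def pattern_similarity(p1, p2) -> float:
    """Absolute cosine similarity ``k_sim`` in [0, 1]; 1 iff collinear."""
    v1, v2 = _check_pair(p1, p2)
    k = abs(float(v1 @ v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return min(k, 1.0)


def recovery_error(p_orig, p_rec) -> float:
    """``RError = 1 - k_sim``; scale- and sign-invariant, 0 iff collinear."""
    return 1.0 - pattern_similarity(p_orig, p_rec)


def average_patterns(
    patterns: Sequence[SpatialPattern], reference_index: int = 0
) -> SpatialPattern:
    """Polarity-aligned arithmetic mean of unit-normalized patterns.

    Each pattern is divided by its norm, then sign-flipped so its dot
    product with the reference pattern is positive (a zero dot product
    leaves the polarity unchanged, with a warning), and the mean is
    returned. Alignment prevents cancellation between topographies of
    opposite polarity.
    """
    if len(patterns) == 0:
        raise ParameterError("empty pattern list")
    if not 0 <= reference_index < len(patterns):
        raise ParameterError("reference_index out of range")
    ref = patterns[reference_index].normalized().values
    labels = list(patterns[reference_index].labels)
    acc = np.zeros_like(ref)
    for p in patterns:
        v = p.normalized().values
        if v.shape != ref.shape:
            raise ShapeError("patterns must have equal length")
        d = float(v @ ref)
        if d == 0:
            logger.warning(
                "pattern orthogonal to the reference; polarity left unchanged"
            )
        elif d < 0:
            v = -v
        acc += v
    return SpatialPattern(acc / len(patterns), labels)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def sim_sync_correlation(
    k_sim_values,
    k_sync_values,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate pattern similarity with source synchronization per family.

    Parameters
    ----------
    k_sim_values, k_sync_values : mapping or array-like
        Either mappings ``{comparison label: vector of observations}`` with
        identical keys, or a single pair of equal-length vectors (treated as
        a one-member family). Each vector needs at least 3 observations.
    method : {"pearson", "spearman"}
        Correlation type. The absolute-cosine/synchronization analysis uses
        Pearson by default; rank correlation is available as an alternative.

    Returns
    -------
    DataFrame with columns ``r``, ``p_raw``, ``p_adj`` (Holm-Bonferroni
    across the family), indexed by comparison label.
    """
    if not isinstance(k_sim_values, Mapping):
        k_sim_values = {"all": np.asarray(k_sim_values, float)}
        k_sync_values = {"all": np.asarray(k_sync_values, float)}
    if set(k_sim_values) != set(k_sync_values):
        raise ShapeError("comparison labels of the two mappings differ")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ParameterError("method must be 'pearson' or 'spearman'")
    rows = {}
    for key in k_sim_values:
        x = np.asarray(k_sim_values[key], float)
        y = np.asarray(k_sync_values[key], float)
        if x.shape != y.shape:
            raise ShapeError(f"length mismatch for comparison {key!r}")
        if x.size < 3:
            raise ParameterError("need at least 3 observations per comparison")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ParameterError(f"constant input for comparison {key!r}")
        res = corr(x, y)
        rows[key] = (float(res.statistic), float(res.pvalue))
    labels = list(rows)
    r = [rows[k][0] for k in labels]
    p_raw = [rows[k][1] for k in labels]
    p_adj = holm_adjust(p_raw)
    return pd.DataFrame({"r": r, "p_raw": p_raw, "p_adj": p_adj}, index=labels)
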