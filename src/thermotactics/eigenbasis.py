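"""Sinusoidal temporal eigenfunction basis (AEM/PCNM-style) on an hourly grid.

A regular time series of ``n`` hourly samples admits an orthogonal basis of
sine waves

    E_k(i) = sin(k * pi * i / (n + 1)),   i = 1..n,  k = 1..K,

whose periods ``2 n / k`` decrease from the study-window scale down to a few
hours.  Used as regression predictors, these eigenfunctions decompose a body
temperature series into contributions at distinct temporal scales even when
many observations are missing, which is why they are preferred over Fourier
analysis for telemetry data.

Only eigenfunctions carrying positive, significant temporal autocorrelation
(Moran's I against lag-1 contiguity) are kept as candidate predictors; the
collinearity that missing data induce among them is controlled afterwards by
iterative variance-inflation-factor (VIF) pruning on the observed rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    EmptyResultError,
    InvalidRequestError,
    UnderdeterminedDesignError,
)

__all__ = [
    "TimeGrid",
    "MoranResult",
    "EigenBasis",
    "VifReport",
    "harmonic_period",
    "build_basis",
    "moran_statistic",
    "filter_by_moran",
    "vif_prune",
]


@dataclass(frozen=True)
class TimeGrid:
    """Regular hourly sampling grid shared by every series in a study."""

    n_hours: int
    start: pd.Timestamp = pd.Timestamp("2010-07-05 00:00")

    def __post_init__(self) -> None:
        if self.n_hours < 4:
            raise InvalidRequestError("a time grid needs at least 4 hourly samples")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_hours, freq="h")

    @property
    def hour_index(self) -> np.ndarray:
        """1-based hour positions ``1..n_hours``."""
        return np.arange(1, self.n_hours + 1)


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its randomization-based normal approximation."""

    I: float
    expected: float
    z: float
    p_one_sided: float


@dataclass(frozen=True)
class VifReport:
    kept: tuple[int, ...]
    removed: tuple[tuple[int, float], ...]
    final_vifs: np.ndarray


@dataclass
class EigenBasis:
    """Matrix of temporal eigenfunctions with per-column period and Moran data.

    ``values`` always spans the complete grid; missing observations in a
    response series never alter the basis, only which regression rows are
    used downstream.
    """

    values: np.ndarray            # (n_hours, K)
    periods: np.ndarray           # (K,) hours, strictly decreasing
    retained: tuple[int, ...]     # 1-based harmonic indices kept after filtering
    moran: tuple[MoranResult, ...] = field(default=())

    @property
    def n_hours(self) -> int:
        return self.values.shape[0]

    @property
    def n_harmonics(self) -> int:
        return self.values.shape[1]

    def retained_values(self) -> np.ndarray:
        """Columns of the retained harmonics, in original order."""
        idx = np.asarray(self.retained, dtype=int) - 1
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"E_{k}": self.values[:, k - 1] for k in range(1, self.n_harmonics + 1)}
        return pd.DataFrame({"hour_index": np.arange(1, self.n_hours + 1), **cols})


def harmonic_period(k: int, n_hours: int) -> float:
    """Period in hours of harmonic ``k`` on a grid of ``n_hours`` samples.

    ``period(k) = 2 * n_hours / k``: the half-wave of the first harmonic
    spans the whole study window, and periods decrease strictly with ``k``.
    """
    if k < 1:
        raise InvalidRequestError("harmonic index k must be >= 1")
    if k > n_hours:
        raise InvalidRequestError("harmonic index k cannot exceed n_hours")
    return 2.0 * n_hours / k


def build_basis(n_hours: int, n_harmonics: int) -> EigenBasis:
    """Build the sinusoidal eigenfunction matrix on the complete hourly grid.

    Column ``k`` is ``sin(k * pi * i / (n_hours + 1))`` at ``i = 1..n_hours``;
    distinct columns are exactly orthogonal on the complete grid.  Moran's I
    (lag-1 contiguity) is computed for every column at build time.
    """
    if n_hours < 4:
        raise InvalidRequestError("n_hours must be >= 4")
    if n_harmonics < 1 or n_harmonics > n_hours:
        raise InvalidRequestError("need 1 <= n_harmonics <= n_hours")
    i = np.arange(1, n_hours + 1)
    k = np.arange(1, n_harmonics + 1)
    values = np.sin(np.outer(i, k) * np.pi / (n_hours + 1))
    periods = 2.0 * n_hours / k
    moran = tuple(_moran_lag1(values[:, j]) for j in range(n_harmonics))
    return EigenBasis(values=values, periods=periods,
                      retained=tuple(range(1, n_harmonics + 1)), moran=moran)


def _chain_weights(n: int) -> np.ndarray:
    w = np.zeros((n, n))
    idx = np.arange(n - 1)
    w[idx, idx + 1] = 1.0
    w[idx + 1, idx] = 1.0
    return w


def _moran_lag1(x: np.ndarray) -> MoranResult:
    """Moran's I against lag-1 temporal contiguity, closed-form sums.

    For the binary chain, S0 = 2(n-1), S1 = 4(n-1) and S2 = 16n - 24; the
    cross-product term reduces to twice the lag-1 autocovariance sum.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    z = x - x.mean()
    m2 = z @ z
    if m2 <= 0 or not np.isfinite(m2):
        raise DegenerateInputError("Moran's I is undefined for a constant series")
    s0 = 2.0 * (n - 1)
    s1 = 4.0 * (n - 1)
    s2 = 16.0 * n - 24.0
    cross = 2.0 * (z[:-1] @ z[1:])
    I = (n / s0) * cross / m2
    return _finish_moran(I, n, s0, s1, s2, z, m2)


def _finish_moran(I: float, n: int, s0: float, s1: float, s2: float,
                  z: np.ndarray, m2: float) -> MoranResult:
    expected = -1.0 / (n - 1)
    b2 = n * np.sum(z**4) / m2**2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var = num / den - expected**2
    var = max(var, 0.0)
    zscore = (I - expected) / np.sqrt(var) if var > 0 else np.inf * np.sign(I - expected)
    p = float(stats.norm.sf(zscore))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return MoranResult(I=float(I), expected=float(expected), z=float(zscore), p_one_sided=p)


def moran_statistic(values: np.ndarray, weights: np.ndarray | None = None) -> MoranResult:
    """Moran's I of a series; one-sided p-value for positive autocorrelation.

    Parameters
    ----------
    values : 1-D array, non-constant.
    weights : optional symmetric spatial-weight matrix; defaults to binary
        lag-1 temporal contiguity (``w_ij = 1`` iff ``|i - j| = 1``).

    The p-value uses the analytic normal approximation under randomization,
    one-sided for ``H1: I > E[I] = -1/(n-1)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidRequestError("values must be a 1-D series")
    if weights is None:
        return _moran_lag1(x)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if w.shape != (n, n):
        raise InvalidRequestError("weights must be n x n")
    z = x - x.mean()
    m2 = z @ z
    if m2 <= 0:
        raise DegenerateInputError("Moran's I is undefined for a constant series")
    s0 = w.sum()
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    rows = w.sum(axis=1)
    cols = w.sum(axis=0)
    s2 = np.sum((rows + cols) ** 2)
    I = (n / s0) * (z @ w @ z) / m2
    return _finish_moran(I, n, s0, s1, s2, z, m2)


def filter_by_moran(basis: EigenBasis, alpha: float = 0.05) -> EigenBasis:
    """Keep only harmonics with positive, significant temporal autocorrelation.

    A column survives when ``I > E[I]`` and its one-sided p-value is below
    ``alpha``; order is preserved.  Raises :class:`EmptyResultError` if no
    column passes.
    """
    if not 0 < alpha < 1:
        raise InvalidRequestError("alpha must lie in (0, 1)")
    moran = basis.moran
    if len(moran) != basis.n_harmonics:
        moran = tuple(_moran_lag1(basis.values[:, j]) for j in range(basis.n_harmonics))
    kept = tuple(
        k for k in basis.retained
        if moran[k - 1].I > moran[k - 1].expected and moran[k - 1].p_one_sided < alpha
    )
    if not kept:
        raise EmptyResultError("no eigenfunction passed the Moran filter")
    return EigenBasis(values=basis.values, periods=basis.periods,
                      retained=kept, moran=moran)


def _vifs(design: np.ndarray) -> np.ndarray:
    """VIF of every column: diagonal of the inverse cosine (cross-product)
    matrix of the norm-scaled raw columns.

    The auxiliary regressions are uncentered: the eigenfunction design is
    exactly orthogonal on the complete grid, so every VIF is then exactly 1
    and any collinearity flagged here is a pure missing-data artifact (an
    intercept-free convention; centering would instead flag the low odd
    harmonics, whose means are far from zero, as collinear with a constant
    even on complete data).  Columns lying in a null-space direction
    (perfect collinearity) get an infinite VIF.
    """
    x = np.asarray(design, dtype=float)
    norms = np.linalg.norm(x, axis=0)
    zero = norms == 0
    norms[zero] = 1.0
    x = x / norms
    r = x.T @ x
    w, v = np.linalg.eigh(r)
    tiny = w < 1e-10 * max(w.max(), 1.0)
    in_null = (np.abs(v[:, tiny]) > 1e-8).any(axis=1) if tiny.any() else np.zeros(r.shape[0], bool)
    finite = (v[:, ~tiny] ** 2 / w[~tiny]).sum(axis=1)
    vifs = np.where(in_null | zero, np.inf, finite)
    return vifs


def vif_prune(design: np.ndarray, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the worst-collinear column until all VIFs <= threshold.

    At each pass the VIF of every remaining column is recomputed and the
    single column with the largest VIF is removed while any exceeds the
    threshold; ties are resolved by removing the higher column index, which
    preserves the coarser temporal scales.
    """
    if threshold <= 0:
        raise InvalidRequestError("VIF threshold must be positive")
    x = np.asarray(design, dtype=float)
    if x.ndim != 2:
        raise InvalidRequestError("design must be a 2-D matrix")
    n, p = x.shape
    if n <= p:
        raise UnderdeterminedDesignError(
            f"design has {n} rows for {p} columns; more rows than columns required")
    if p == 1:
        return VifReport(kept=(0,), removed=(), final_vifs=np.ones(1))
    keep = list(range(p))
    removed: list[tuple[int, float]] = []
    while len(keep) > 1:
        vifs = _vifs(x[:, keep])
        vmax = vifs.max()
        if vmax <= threshold:
            break
        # ties resolved toward the higher original column index
        worst_local = np.where(vifs == vmax)[0][-1]
        removed.append((keep[worst_local], float(vmax)))
        del keep[worst_local]
    final = _vifs(x[:, keep]) if len(keep) > 1 else np.ones(1)
    return VifReport(kept=tuple(keep), removed=tuple(removed), final_vifs=final)
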