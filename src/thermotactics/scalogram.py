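"""Per-individual eigenfunction regression and the partial-R2adj scalogram.

Each fish's hourly body-temperature series is modelled by ordinary least
squares on the retained temporal eigenfunctions (observed rows only; missing
hours are dropped listwise, never imputed).  The importance of eigenfunction
``k`` is its partial R2adj: the model's adjusted R2 (floored at zero)
allocated across predictors in proportion to each one's leave-one-out SSE
increment — the rise in residual sum of squares when that predictor is
removed and the model refit on the same rows.  The partials therefore sum
exactly to the (floored) adjusted R2, and on a complete grid, where the
basis is orthogonal, each reduces to the per-harmonic variance share
rescaled to the adjusted scale.

Per-harmonic contributions are grouped into four temporal scales — broad
(>35 h), diel (35-14 h), crepuscular (14-10 h) and fine (<10 h) — and
averaged across individuals into a population scalogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .eigenbasis import EigenBasis, vif_prune
from .exceptions import (
    EmptyResultError,
    InvalidBandsError,
    InvalidRequestError,
    UnderdeterminedDesignError,
)

__all__ = [
    "BodyTempSeries",
    "ScalogramResult",
    "default_bands",
    "DEFAULT_BANDS",
    "fit_individual",
    "loo_contribution",
    "aggregate_bands",
    "population_scalogram",
    "ScalogramRegressor",
]

#: (name, first harmonic, last harmonic) — the four temporal scales.
DEFAULT_BANDS: tuple[tuple[str, int, int], ...] = (
    ("broad", 1, 25),
    ("diel", 26, 62),
    ("crepuscular", 63, 87),
    ("fine", 88, 205),
)

BAND_NAMES = tuple(name for name, _, _ in DEFAULT_BANDS)


def default_bands(n_harmonics: int = 205) -> tuple[tuple[str, int, int], ...]:
    """The four-scale partition, with the fine band stretched to ``n_harmonics``."""
    if n_harmonics < 88:
        raise InvalidRequestError("default bands need at least 88 harmonics")
    return DEFAULT_BANDS[:3] + (("fine", 88, n_harmonics),)


@dataclass
class BodyTempSeries:
    """One fish's hourly body temperatures aligned to the shared grid.

    ``temps`` has one entry per grid hour; missing hours are NaN.
    """

    fish_id: str
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        obs = self.temps[np.isfinite(self.temps)]
        if obs.size == 0:
            raise InvalidRequestError(f"fish {self.fish_id}: series is entirely missing")
        if obs.min() < 0 or obs.max() > 35:
            raise InvalidRequestError(
                f"fish {self.fish_id}: temperatures outside the plausible 0-35 degC range")

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.temps)))


@dataclass
class ScalogramResult:
    """Fit summary for one fish: full adjusted R2 and per-harmonic shares."""

    fish_id: str
    r2adj_full: float
    partial: np.ndarray                  # length K; zero at non-kept harmonics
    band_totals: dict[str, float]
    kept: tuple[int, ...]                # harmonics surviving Moran + VIF filters
    n_obs: int


class _OlsContext:
    """Fitted OLS with the pieces needed for closed-form leave-one-out R2."""

    def __init__(self, design: np.ndarray, y: np.ndarray, kept: tuple[int, ...]):
        n, p = design.shape
        X = np.column_stack([np.ones(n), design])
        xtx = X.T @ X
        self.xtx_inv = np.linalg.pinv(xtx)
        self.beta = self.xtx_inv @ (X.T @ y)
        resid = y - X @ self.beta
        self.sse = float(resid @ resid)
        yc = y - y.mean()
        self.sst = float(yc @ yc)
        self.n = n
        self.p = p
        self.kept = kept                  # harmonic index per design column

    def r2adj(self) -> float:
        return _adjusted_r2(self.sse, self.sst, self.n, self.p)

    def sse_without(self, col: int) -> float:
        """SSE after deleting design column ``col`` (0-based), same rows.

        Classical deletion identity: dropping predictor j raises the SSE by
        ``beta_j^2 / [(X'X)^{-1}]_{jj}``; the result equals an explicit
        refit without that column on the same rows.
        """
        j = col + 1                       # account for the intercept column
        d = self.xtx_inv[j, j]
        if d <= 0:
            return self.sse
        return self.sse + float(self.beta[j] ** 2) / d

    def loo_increments(self) -> np.ndarray:
        """Leave-one-out SSE increment of every design column."""
        return np.array([self.sse_without(c) - self.sse for c in range(self.p)])


def _adjusted_r2(sse: float, sst: float, n: int, p: int) -> float:
    if sst <= 0:
        return 0.0
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def loo_contribution(fit: _OlsContext, k: int) -> float:
    """Partial R2adj of harmonic ``k`` in a fitted model.

    The model's adjusted R2 (floored at 0) is allocated across the kept
    predictors in proportion to their leave-one-out SSE increments — the
    rise in residual sum of squares when a predictor is removed and the
    model refit on the same rows.  Contributions are nonnegative and sum
    exactly to the floored adjusted R2; on an orthogonal (complete-grid)
    design the increment of harmonic ``k`` is its explained sum of squares,
    so the contribution is that harmonic's variance share rescaled to the
    adjusted scale.
    """
    if k not in fit.kept:
        raise InvalidRequestError(f"harmonic {k} is not part of the fitted model")
    total = max(0.0, fit.r2adj())
    if total == 0.0:
        return 0.0
    incr = fit.loo_increments()
    denom = float(incr.sum())
    if denom <= 0:
        return 0.0
    col = fit.kept.index(k)
    return float(total * max(incr[col], 0.0) / denom)


def fit_individual(series: BodyTempSeries, basis: EigenBasis,
                   vif_threshold: float = 10.0,
                   bands: tuple[tuple[str, int, int], ...] | None = None) -> ScalogramResult:
    """OLS of one fish's series on the retained eigenfunctions.

    Observed rows only (listwise deletion); predictors are then pruned by
    iterative VIF (missing data break the exact orthogonality of the basis).
    Requires at least 10 more observations than surviving predictors.
    """
    y_full = series.temps
    if y_full.size != basis.n_hours:
        raise InvalidRequestError("series length does not match the basis grid")
    obs = np.isfinite(y_full)
    y = y_full[obs]
    design_all = basis.retained_values()[obs, :]
    report = vif_prune(design_all, threshold=vif_threshold)
    kept = tuple(basis.retained[i] for i in report.kept)
    design = design_all[:, list(report.kept)]
    n, p = design.shape
    if n - p < 10:
        raise UnderdeterminedDesignError(
            f"fish {series.fish_id}: {n} observations for {p} predictors "
            "(need at least 10 more rows than predictors)")
    fit = _OlsContext(design, y, kept)
    partial = np.zeros(basis.n_harmonics)
    for k in kept:
        partial[k - 1] = loo_contribution(fit, k)
    result = ScalogramResult(
        fish_id=series.fish_id,
        r2adj_full=fit.r2adj(),
        partial=partial,
        band_totals={},
        kept=kept,
        n_obs=n,
    )
    if bands is None:
        bands = (default_bands(basis.n_harmonics) if basis.n_harmonics >= 88
                 else (("all", 1, basis.n_harmonics),))
    result.band_totals = aggregate_bands(result, bands)
    return result


def aggregate_bands(result: ScalogramResult,
                    bands: tuple[tuple[str, int, int], ...]) -> dict[str, float]:
    """Sum per-harmonic contributions over a contiguous partition of ``1..K``."""
    K = result.partial.size
    cursor = 1
    for _, lo, hi in bands:
        if lo != cursor or hi < lo:
            raise InvalidBandsError("bands must be contiguous, disjoint and ordered")
        cursor = hi + 1
    if cursor != K + 1:
        raise InvalidBandsError(f"bands cover 1..{cursor - 1} but the basis has {K} harmonics")
    return {name: float(result.partial[lo - 1:hi].sum()) for name, lo, hi in bands}


def population_scalogram(results: list[ScalogramResult],
                         periods: np.ndarray | None = None) -> pd.DataFrame:
    """Mean and SD of partial R2adj across individuals, per harmonic.

    Rows are ordered by decreasing period (increasing harmonic index).  With
    a single individual the SD column is zero and a warning is emitted.
    """
    if not results:
        raise EmptyResultError("no individual scalogram results to average")
    K = results[0].partial.size
    if any(r.partial.size != K for r in results):
        raise InvalidRequestError("all results must share the same basis")
    mat = np.vstack([r.partial for r in results])
    mean = mat.mean(axis=0)
    if len(results) > 1:
        sd = mat.std(axis=0, ddof=1)
    else:
        warnings.warn("population scalogram from a single individual: SD reported as 0",
                      stacklevel=2)
        sd = np.zeros(K)
    out = pd.DataFrame({
        "harmonic": np.arange(1, K + 1),
        "period_h": periods if periods is not None else np.full(K, np.nan),
        "mean_partial": mean,
        "sd_partial": sd,
        "n_individuals": len(results),
    })
    return out


class ScalogramRegressor(BaseEstimator, RegressorMixin):
    """Eigenfunction regression of one temperature series, sklearn-style.

    Parameters
    ----------
    vif_threshold : float, default 10.0
        Collinearity cap for iterative predictor removal on the observed rows.
    bands : optional partition ``(name, lo, hi)`` of the harmonics; defaults
        to the four-scale broad/diel/crepuscular/fine partition.

    ``fit(X, y)`` takes the full basis matrix (``n_hours x K``) and the
    response with NaN marking missing hours.  Fitted attributes carry a
    trailing underscore: ``r2adj_``, ``partial_``, ``band_totals_``,
    ``kept_``, ``coef_``, ``intercept_``.
    """

    def __init__(self, vif_threshold: float = 10.0,
                 bands: tuple[tuple[str, int, int], ...] | None = None):
        self.vif_threshold = vif_threshold
        self.bands = bands

    def fit(self, X, y, fish_id: str = "fish"):
        basis = X if isinstance(X, EigenBasis) else _basis_from_matrix(np.asarray(X, float))
        series = BodyTempSeries(fish_id=fish_id, temps=np.asarray(y, dtype=float))
        res = fit_individual(series, basis, vif_threshold=self.vif_threshold,
                             bands=self.bands)
        design = basis.retained_values()
        obs = np.isfinite(series.temps)
        keep_cols = [basis.retained.index(k) for k in res.kept]
        ctx = _OlsContext(design[obs][:, keep_cols], series.temps[obs], res.kept)
        self.result_ = res
        self.r2adj_ = res.r2adj_full
        self.partial_ = res.partial
        self.band_totals_ = res.band_totals
        self.kept_ = res.kept
        self.intercept_ = float(ctx.beta[0])
        self.coef_ = ctx.beta[1:]
        self.n_features_in_ = basis.n_harmonics
        self._basis_retained = basis.retained
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        basis = X if isinstance(X, EigenBasis) else _basis_from_matrix(np.asarray(X, float))
        idx = [k - 1 for k in self.kept_]
        return self.intercept_ + basis.values[:, idx] @ self.coef_


def _basis_from_matrix(values: np.ndarray) -> EigenBasis:
    K = values.shape[1]
    periods = 2.0 * values.shape[0] / np.arange(1, K + 1)
    return EigenBasis(values=values, periods=periods, retained=tuple(range(1, K + 1)))
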