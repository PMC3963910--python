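"""Classification of thermoregulatory tactics from scale-band profiles.

Each fish is summarized by its cumulative partial R2adj over the four
temporal scales (broad, diel, crepuscular, fine).  Rows are Hellinger
transformed (square root of row proportions), ordinated by covariance PCA,
and the two leading axes oriented so that

* axis 1 is positive toward broad-scale periodicity (negative scores mean
  clear diel cycling),
* axis 2 is positive toward the presence of crepuscular and fine
  periodicities.

The four quadrants of the oriented score plot define tactics I-IV; the sign
of axis 1 alone defines the pooled I/IV (diel-side) versus II/III
(broad-side) dichotomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateInputError, InvalidRequestError
from .scalogram import BAND_NAMES

__all__ = [
    "TacticAssignment",
    "hellinger_transform",
    "pca_scores",
    "orient_axes",
    "assign_tactics",
    "TacticPCA",
]


@dataclass
class TacticAssignment:
    """Oriented PCA scores and quadrant tactic labels for a set of fish."""

    scores: np.ndarray               # (n, 2) oriented
    loadings: np.ndarray             # (n_bands, 2) oriented
    var_fraction: np.ndarray         # all components; sums to 1
    tactic: list[str]                # quadrant labels I..IV
    pooled: list[str]                # "I/IV" or "II/III"
    boundary_flag: np.ndarray        # True where a score was exactly 0


def hellinger_transform(matrix: np.ndarray, ids=None) -> np.ndarray:
    """Row-wise square root of proportions: ``sqrt(x_ij / sum_j x_ij)``.

    Every output row has unit sum of squares.  A nonpositive or zero row is
    degenerate and raises, naming the offending individual.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InvalidRequestError("band matrix must be 2-D")
    if (x < 0).any():
        raise InvalidRequestError("band totals must be nonnegative")
    sums = x.sum(axis=1)
    bad = np.where(sums <= 0)[0]
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise DegenerateInputError(f"individual {name} has an all-zero band profile")
    return np.sqrt(x / sums[:, None])


def pca_scores(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance PCA of the (Hellinger-transformed) band matrix.

    Returns ``(scores, loadings, var_fraction)``: scores of every row on the
    two leading components, the 2-column loading matrix, and the variance
    fractions of *all* components (they sum to 1).
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise InvalidRequestError("PCA needs at least 3 individuals")
    pca = PCA()
    all_scores = pca.fit_transform(x)
    var_fraction = pca.explained_variance_ratio_
    n_comp = all_scores.shape[1]
    if n_comp < 2:
        raise DegenerateInputError("fewer than two principal components available")
    scores = all_scores[:, :2]
    loadings = pca.components_[:2].T
    return scores, loadings, var_fraction


def orient_axes(scores: np.ndarray, loadings: np.ndarray,
                band_names: tuple[str, ...] = BAND_NAMES
                ) -> tuple[np.ndarray, np.ndarray]:
    """Fix the sign convention of the two leading axes.

    Axis 1 is flipped so the broad-band loading is positive; axis 2 so that
    the summed crepuscular + fine loading is positive.  An exactly-zero
    orienting loading leaves the axis as computed, with a warning.
    """
    scores = np.array(scores, dtype=float, copy=True)
    loadings = np.array(loadings, dtype=float, copy=True)
    names = list(band_names)
    broad = loadings[names.index("broad"), 0]
    if broad == 0:
        warnings.warn("axis 1 orientation ambiguous: broad loading is exactly zero",
                      stacklevel=2)
    elif broad < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1
    finer = loadings[names.index("crepuscular"), 1] + loadings[names.index("fine"), 1]
    if finer == 0:
        warnings.warn("axis 2 orientation ambiguous: crepuscular+fine loading is zero",
                      stacklevel=2)
    elif finer < 0:
        scores[:, 1] *= -1
        loadings[:, 1] *= -1
    return scores, loadings


_QUADRANT = {(False, True): "I", (True, True): "II", (True, False): "III",
             (False, False): "IV"}


def assign_tactics(scores: np.ndarray, loadings: np.ndarray | None = None,
                   var_fraction: np.ndarray | None = None) -> TacticAssignment:
    """Quadrant tactics from oriented scores.

    Negative axis-1 scores (diel side) give tactics I (axis 2 positive:
    finer periodicities present) or IV; positive axis-1 scores (broad side)
    give II or III.  A score of exactly zero is resolved toward the positive
    side and flagged.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] < 2:
        raise InvalidRequestError("scores must have two columns")
    tactic, pooled = [], []
    boundary = np.zeros(s.shape[0], dtype=bool)
    for i, (s1, s2) in enumerate(s[:, :2]):
        if s1 == 0 or s2 == 0:
            boundary[i] = True
        q = _QUADRANT[(s1 >= 0 if s1 == 0 else s1 > 0,
                       s2 >= 0 if s2 == 0 else s2 > 0)]
        tactic.append(q)
        pooled.append("II/III" if (s1 > 0 or s1 == 0) else "I/IV")
    return TacticAssignment(
        scores=s[:, :2],
        loadings=loadings if loadings is not None else np.array([]),
        var_fraction=var_fraction if var_fraction is not None else np.array([]),
        tactic=tactic,
        pooled=pooled,
        boundary_flag=boundary,
    )


class TacticPCA(BaseEstimator, TransformerMixin):
    """Hellinger-PCA tactic classifier, sklearn-style.

    ``fit(X)`` takes the nonnegative band matrix (individuals x 4 scales).
    Fitted attributes: ``scores_``, ``loadings_``, ``var_fraction_``,
    ``tactic_``, ``pooled_``, ``boundary_flag_``.  ``transform`` projects
    new band profiles onto the fitted, oriented axes.
    """

    def __init__(self, band_names: tuple[str, ...] = BAND_NAMES):
        self.band_names = band_names

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        h = hellinger_transform(x)
        scores, loadings, var_fraction = pca_scores(h)
        self._flip = np.ones(2)
        oriented_scores, oriented_loadings = orient_axes(scores, loadings,
                                                         self.band_names)
        # remember the flip applied to each axis, for transform()
        for j in range(2):
            col = loadings[:, j]
            if np.allclose(oriented_loadings[:, j], -col) and not np.allclose(col, 0):
                self._flip[j] = -1.0
        assign = assign_tactics(oriented_scores, oriented_loadings, var_fraction)
        self.mean_ = h.mean(axis=0)
        self.components_ = oriented_loadings.T          # (2, n_bands)
        self.scores_ = assign.scores
        self.loadings_ = assign.loadings
        self.var_fraction_ = assign.var_fraction
        self.tactic_ = assign.tactic
        self.pooled_ = assign.pooled
        self.boundary_flag_ = assign.boundary_flag
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        h = hellinger_transform(np.asarray(X, dtype=float))
        return (h - self.mean_) @ self.components_.T

    def to_frame(self, ids=None) -> pd.DataFrame:
        check_is_fitted(self, "scores_")
        n = self.scores_.shape[0]
        return pd.DataFrame({
            "fish_id": ids if ids is not None else [f"fish{i}" for i in range(n)],
            "score1": self.scores_[:, 0],
            "score2": self.scores_[:, 1],
            "tactic": self.tactic_,
            "pooled": self.pooled_,
            "boundary_flag": self.boundary_flag_,
        })
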