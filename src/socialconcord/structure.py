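"""Representational structure of feature ratings and its comparison
between two annotation sources.

The feature x feature Pearson correlation matrix of mean ratings
captures how features covary across stimuli.  Two such matrices are
compared by (i) the Pearson correlation of their strict upper triangles,
with significance from a Mantel permutation test, and (ii) principal
coordinate analysis (classical MDS) on the correlation distance
``d = 1 - r``, whose component loadings are correlated between sources
to reveal shared latent perceptual dimensions.  Component signs are
arbitrary, so loading concordance reports absolute correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .rating_model import MIN_COMPLETE_PAIRS, MeanRatingMatrix

__all__ = [
    "FeatureCorrelationMatrix",
    "PCoAResult",
    "ConcordanceMatrix",
    "feature_correlation_matrix",
    "matrix_similarity",
    "mantel_test",
    "pcoa",
    "loading_concordance",
]


@dataclass
class FeatureCorrelationMatrix:
    """Symmetric unit-diagonal matrix of pairwise feature correlations."""

    features: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        f = len(self.features)
        if self.values.shape != (f, f):
            raise ValueError("matrix shape does not match feature count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be 1")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("entries outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features,
                            columns=self.features)


@dataclass
class PCoAResult:
    """Loadings and eigenvalues of the correlation-distance ordination."""

    features: list
    loadings: np.ndarray      # F x K, columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray   # K retained positive eigenvalues, descending
    variance_fraction: np.ndarray
    n_negative_eigenvalues: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be descending")
        if np.any(self.eigenvalues <= 0):
            raise ValueError("retained eigenvalues must be positive")


@dataclass
class ConcordanceMatrix:
    """Absolute loading correlations between two sets of components."""

    abs_r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float


def feature_correlation_matrix(mean_ratings: MeanRatingMatrix) -> FeatureCorrelationMatrix:
    """Pairwise Pearson correlations between feature columns across items.

    Pairwise-complete: each entry uses the items where both features are
    observed (minimum 3).  Zero-variance features must be excluded
    upstream; one reaching this stage is an integrity error.
    """
    vals = mean_ratings.values
    if vals.shape[0] < MIN_COMPLETE_PAIRS:
        raise ValueError("need at least 3 items")
    for j, feat in enumerate(mean_ratings.features):
        col = vals[:, j]
        obs = col[np.isfinite(col)]
        if obs.size and np.ptp(obs) == 0:
            raise ValueError(f"zero-variance feature reached correlation stage: {feat!r}")
    df = pd.DataFrame(vals)
    corr = df.corr(method="pearson", min_periods=MIN_COMPLETE_PAIRS).to_numpy()
    np.fill_diagonal(corr, 1.0)
    return FeatureCorrelationMatrix(list(mean_ratings.features), corr)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def matrix_similarity(a: FeatureCorrelationMatrix,
                      b: FeatureCorrelationMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two matrices."""
    if list(a.features) != list(b.features):
        raise ValueError("feature sets or order differ")
    x, y = _upper(a.values), _upper(b.values)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def mantel_test(a: FeatureCorrelationMatrix, b: FeatureCorrelationMatrix,
                n_permutations: int = 1_000_000, seed: int | None = None,
                exhaustive: bool = False):
    """Permutation test of association between two feature matrices.

    The observed statistic is :func:`matrix_similarity`; the null is
    built by applying one random permutation jointly to the rows and
    columns of ``b``.  The Monte-Carlo p-value is
    ``(#{null r >= observed} + 1) / (n_permutations + 1)``.  With
    ``exhaustive=True`` all F! permutations are enumerated instead
    (feasible only for tiny F) and p is the exact permutation fraction.
    """
    if list(a.features) != list(b.features):
        raise ValueError("feature sets or order differ")
    f = len(a.features)
    if f < 3:
        raise ValueError("need at least 3 features")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")

    iu = np.triu_indices(f, k=1)
    x = a.values[iu]
    xc = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
    bv = b.values

    def stat(mat):
        y = mat[iu]
        yc = y - y.mean()
        return float(xc @ yc / np.sqrt(yc @ yc))

    r_obs = stat(bv)

    if exhaustive:
        null = np.array([
            stat(bv[np.ix_(p, p)]) for p in iter_permutations(range(f))
        ])
        p_val = float((null >= r_obs - 1e-12).mean())
        return r_obs, p_val

    rng = np.random.default_rng(seed)
    count = 0
    # permute in vectorised blocks to bound memory at ~block * F^2 floats
    block = max(1, min(n_permutations, int(2e7) // (f * f)))
    done = 0
    while done < n_permutations:
        nb = min(block, n_permutations - done)
        perms = np.argsort(rng.random((nb, f)), axis=1)
        permuted = bv[perms[:, :, None], perms[:, None, :]]  # nb x F x F
        y = permuted[:, iu[0], iu[1]]
        yc = y - y.mean(axis=1, keepdims=True)
        null = (yc @ xc) / np.sqrt((yc * yc).sum(axis=1))
        count += int((null >= r_obs - 1e-12).sum())
        done += nb
    p_val = (count + 1) / (n_permutations + 1)
    return r_obs, float(p_val)


def pcoa(c: FeatureCorrelationMatrix, k: int | None = None,
         distance: str = "one_minus_r") -> PCoAResult:
    """Classical multidimensional scaling of the correlation distance.

    The correlation matrix is turned into a distance ``d = 1 - r``
    (features correlating perfectly sit at distance zero), the squared
    distances are double-centred with the Gower projector
    ``B = -1/2 J D^2 J``, and the coordinates are the eigenvectors of B
    scaled by the square root of their (positive) eigenvalues.  Negative
    eigenvalues — the correlation distance is not guaranteed Euclidean —
    are dropped and counted.
    """
    f = len(c.features)
    if k is None:
        k = f - 1
    if k > f - 1:
        raise ValueError("k must be at most F - 1")
    if distance == "one_minus_r":
        d = 1.0 - c.values
    elif distance == "sqrt_two_one_minus_r":
        d = np.sqrt(np.maximum(2.0 * (1.0 - c.values), 0.0))
    else:
        raise ValueError(f"unknown distance transform {distance!r}")
    d2 = d * d
    j = np.eye(f) - np.full((f, f), 1.0 / f)
    bmat = -0.5 * j @ d2 @ j
    bmat = (bmat + bmat.T) / 2
    evals, evecs = linalg.eigh(bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-10, 1e-10 * abs(evals[0]) if evals.size else 0.0)
    positive = evals > tol
    n_pos = int(positive.sum())
    n_neg = int((evals < -tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        import warnings
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating to {k_eff} components"
        )
    lam = evals[:k_eff]
    coords = evecs[:, :k_eff] * np.sqrt(lam)
    total_pos = evals[positive].sum()
    return PCoAResult(
        features=list(c.features),
        loadings=coords,
        eigenvalues=lam,
        variance_fraction=lam / total_pos,
        n_negative_eigenvalues=n_neg,
    )


def loading_concordance(l_a: PCoAResult, l_b: PCoAResult,
                        alpha: float = 0.001,
                        k_max: int | None = None) -> ConcordanceMatrix:
    """Correlate component loadings between two ordinations.

    For every component pair the loadings are correlated across the
    shared features; because the sign of each component is arbitrary the
    result reports |r|, with a two-sided p from the exact t-transform of
    r on F - 2 degrees of freedom.
    """
    if list(l_a.features) != list(l_b.features):
        raise ValueError("feature sets differ between ordinations")
    ka = l_a.loadings.shape[1]
    kb = l_b.loadings.shape[1]
    if k_max is not None:
        if k_max > min(ka, kb):
            raise ValueError("k_max exceeds available components")
        ka = kb = k_max
    f = len(l_a.features)
    abs_r = np.zeros((ka, kb))
    pv = np.ones((ka, kb))
    for i in range(ka):
        for j in range(kb):
            r, p = stats.pearsonr(l_a.loadings[:, i], l_b.loadings[:, j])
            abs_r[i, j] = abs(r)
            pv[i, j] = p
    assert f > 2
    return ConcordanceMatrix(abs_r=abs_r, p=pv,
                             significant=pv < alpha, alpha=alpha)
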