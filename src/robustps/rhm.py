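"""Resampling-by-half-means (RHM) multivariate outlier detection.

RHM repeatedly standardises the full data matrix by the column means and
standard deviations of a random half-sample, and records each subject's
Euclidean length in the standardised coordinates.  A subject that is
consistently long — across half-samples that mostly exclude other
outliers — sits far from the bulk of the data.  The per-subject mean
length over replicates is compared against ``median + 3 * MAD`` of the
mean lengths; exceedances are flagged.  Because only column-wise means
and standard deviations are estimated, the method is usable when the
number of variables far exceeds the number of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin

from .robust_pca import mad

__all__ = ["RHMResult", "rhm_detect", "RHMDetector"]


@dataclass
class RHMResult:
    """Mean scaled lengths, the optional per-replicate matrix, cutoff and flags."""

    mean_lengths: np.ndarray
    cutoff: float
    flags: np.ndarray
    lengths_matrix: np.ndarray | None = None


def rhm_detect(
    X,
    nrep: int = 100,
    rng: np.random.Generator | None = None,
    keep_lengths: bool = False,
) -> RHMResult:
    """Flag subject outliers by resampling by half means.

    Per replicate, ``floor(n/2)`` rows are sampled without replacement;
    all ``n`` rows are standardised by the half-sample column means and
    standard deviations (ddof=1) and their Euclidean lengths recorded.
    Columns whose half-sample standard deviation is zero contribute
    nothing to the lengths for that replicate — this avoids infinities
    on locally constant SNP columns.  The flag cutoff is
    ``median + 3 * MAD`` of the per-subject mean lengths.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("RHM needs at least 4 subjects")
    if nrep < 1:
        raise ValueError("nrep must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    half = n // 2
    L = np.empty((n, nrep))
    # ||(x - m) / s||^2 expanded as x'Wx - 2 x'(Wm) + m'Wm with W = diag(1/s^2)
    # (zero weight on excluded columns): two matrix-vector products per
    # replicate instead of materialising the scaled n x p matrix
    X2 = X * X
    for i in range(nrep):
        rows = rng.choice(n, size=half, replace=False)
        sub = X[rows]
        m = sub.mean(axis=0)
        s = sub.std(axis=0, ddof=1)
        w = np.zeros_like(s)
        ok = s > 0
        w[ok] = 1.0 / (s[ok] * s[ok])
        sq = X2 @ w - 2.0 * (X @ (w * m)) + float(w @ (m * m))
        L[:, i] = np.sqrt(np.maximum(sq, 0.0))
    mean_lengths = L.mean(axis=1)
    cutoff = float(np.median(mean_lengths) + 3.0 * mad(mean_lengths))
    flags = mean_lengths > cutoff
    return RHMResult(
        mean_lengths=mean_lengths,
        cutoff=cutoff,
        flags=flags,
        lengths_matrix=L if keep_lengths else None,
    )


class RHMDetector(BaseEstimator, OutlierMixin):
    """Scikit-learn style wrapper around :func:`rhm_detect`.

    ``fit_predict`` follows the sklearn outlier convention: +1 for
    inliers, -1 for flagged subjects.

    Attributes
    ----------
    mean_lengths_ : ndarray (n_samples,)
    cutoff_ : float
    flags_ : ndarray of bool
    """

    def __init__(self, nrep: int = 100, random_state: int | None = None):
        self.nrep = nrep
        self.random_state = random_state

    def fit(self, X, y=None):
        rng = np.random.default_rng(self.random_state)
        res = rhm_detect(X, nrep=self.nrep, rng=rng)
        self.result_ = res
        self.mean_lengths_ = res.mean_lengths
        self.cutoff_ = res.cutoff
        self.flags_ = res.flags
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return np.where(self.flags_, -1, 1)
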