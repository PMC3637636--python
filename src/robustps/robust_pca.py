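"""Projection-pursuit robust PCA and score/orthogonal-distance outlier diagnostics.

Classical PCA finds directions of maximal variance; because the variance
is driven quadratically by extreme observations, a handful of aberrant
subjects can rotate the leading eigenvectors toward themselves.  The
projection-pursuit (PP) approach replaces the variance with a robust
scale estimator ``S_n`` (here the 1.4826-scaled median absolute
deviation) and maximises ``S_n`` of the projected data over unit
directions.  No covariance matrix is formed, so the method applies when
there are far more variables than subjects (``n < p``), the typical
shape of a GWA genotype panel.

Two direction-search algorithms are provided:

* ``cr`` — maximisation over the finite candidate set of centred,
  normalised observations, component by component with deflation.
* ``grid`` — a grid search over angles in two-dimensional coordinate
  planes, cycled over planes with successive interval halvings; the
  recommended algorithm for genotype panels, where the candidate-set
  search is prone to swamping (flagging good observations) at small n.

Both searches run in the row space of the centred data (an orthonormal
SVD basis of dimension ``min(n, p)``): the robust scale of a projection
depends only on the component of the direction inside the row space, so
the maximiser is unchanged while the search dimension drops from ``p``
to ``min(n, p)``.

Outlier diagnostics follow the score-distance / orthogonal-distance
construction: within the fitted K-dimensional robust subspace, the score
distance ``SD_i = sqrt(sum_j t_ij^2 / l_j)`` is compared with the square
root of the chi-square 0.975 quantile at K degrees of freedom; the
orthogonal distance ``OD_i = ||x_i - x_hat_i||`` is compared with a
cutoff obtained by a Wilson-Hilferty normal approximation of ``OD^2`` as
a scaled chi-square.  Subjects are labelled type A (large SD only),
type B (large OD only) or type C (both); all three types are removed
before stratification inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "mad",
    "RobustPCAResult",
    "OutlierDiagnostics",
    "PPRobustPCA",
    "pp_pca_cr",
    "pp_pca_grid",
    "score_distances",
    "orth_distances",
    "classify_outliers",
    "outlier_diagnostics",
]

def mad(sample) -> float:
    """Median absolute deviation, scaled by 1.4826 for Gaussian consistency.

    ``MAD(z) = 1.4826 * median_j |z_j - median_i(z_i)|``; returns 0 for
    constant samples and raises on empty input.
    """
    z = np.asarray(sample, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("mad of an empty sample is undefined")
    return 1.4826 * float(np.median(np.abs(z - np.median(z))))


def _mad_cols(Y: np.ndarray) -> np.ndarray:
    med = np.median(Y, axis=0)
    return 1.4826 * np.median(np.abs(Y - med), axis=0)


def _sd_cols(Y: np.ndarray) -> np.ndarray:
    return Y.std(axis=0, ddof=1)


_PP_INDICES = {"mad": _mad_cols, "sd": _sd_cols}


@dataclass
class RobustPCAResult:
    """Fitted robust principal components.

    ``eigenvectors`` is the p-by-K matrix with orthonormal columns,
    ``eigenvalues`` the nonincreasing vector of squared robust scales,
    ``scores`` the n-by-K matrix ``(X - 1 mu') eigenvectors`` and
    ``location`` the coordinatewise-median centre used.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    location: np.ndarray
    pp_index: str
    algorithm: str
    grid_points: int | None = None
    candidate_set_size: int | None = None
    truncated: bool = False

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class OutlierDiagnostics:
    """Per-subject score/orthogonal distances, cutoffs and outlier labels."""

    score_distance: np.ndarray
    orth_distance: np.ndarray
    sd_cutoff: float
    od_cutoff: float
    od_g1: float
    od_g2: float
    labels: np.ndarray

    @property
    def outlier_mask(self) -> np.ndarray:
        """Union of the A, B and C types — the subjects to remove."""
        return self.labels != "regular"


# ---------------------------------------------------------------------------
# direction searches (in the reduced SVD basis)
# ---------------------------------------------------------------------------


def _reduce_basis(X: np.ndarray, location: np.ndarray):
    """Rotate centred data into its row-space basis.

    Returns ``(Z, W)`` with ``Z = Xc @ W`` of shape (n, r) and ``W`` the
    p-by-r orthonormal basis, r the numerical rank bound.
    """
    Xc = X - location
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0:
        raise ValueError("empty data matrix")
    keep = s > max(s[0], 1.0) * 1e-12 * max(Xc.shape)
    keep_n = max(int(keep.sum()), 1)
    # canonicalise signs on the left singular vectors: U is invariant
    # under right-multiplication of X by an orthogonal matrix, so this
    # makes the search path (and hence the result) equivariant under
    # variable rotations instead of depending on LAPACK sign choices
    for i in range(keep_n):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i, :] = -Vt[i, :]
    W = Vt[:keep_n].T
    Z = U[:, :keep_n] * s[:keep_n]
    return Z, W


def _cr_direction(Z: np.ndarray, scale_cols) -> tuple[np.ndarray, float]:
    """Best direction among the normalised observations (candidate set)."""
    norms = np.linalg.norm(Z, axis=1)
    ok = norms > 0
    if not ok.any():
        return np.zeros(Z.shape[1]), 0.0
    cand = Z[ok] / norms[ok, None]
    vals = scale_cols(Z @ cand.T)
    best = int(np.argmax(vals))
    return cand[best].copy(), float(vals[best])


def _grid_direction(
    Z: np.ndarray,
    scale_cols,
    J: int,
    n_refinements: int,
    max_cycles: int,
    tol: float,
) -> tuple[np.ndarray, float]:
    """Maximise the projection scale by cycling grid searches over planes.

    The incumbent direction ``a`` is rotated inside the plane spanned by
    ``a`` and each coordinate axis ``e_j`` in turn: the scale of the
    projection of the data onto ``(cos t * a + sin t * e_j) / norm`` is
    evaluated on J angles tiling (-pi/2, pi/2] and the bracket around the
    best angle is halved ``n_refinements`` times.  The first pass runs
    the refinement unconditionally in every plane — the optimum can hide
    inside the coarse cell around the incumbent without any coarse point
    beating it — while later passes skip refinement in planes whose
    coarse scan shows no gain (improving planes still refine fully).
    Cycling stops when the direction moves by less than ``tol`` or after
    ``max_cycles`` passes.
    """
    n, r = Z.shape
    col_scales = scale_cols(Z)
    j0 = int(np.argmax(col_scales))
    state = {
        "a": np.zeros(r),
        "y": Z[:, j0].copy(),
        "best": float(col_scales[j0]),
    }
    state["a"][j0] = 1.0
    base_angles = (np.arange(1, J + 1) / J - 0.5) * np.pi
    refine_offsets = np.arange(J + 1) / J - 0.5

    def sweep(always_refine: bool) -> bool:
        """One pass over all coordinate planes; returns True on improvement."""
        any_improved = False
        a = state["a"]
        y = state["y"]
        for j in range(r):
            zj = Z[:, j]
            aj = a[j]
            theta = base_angles
            width = np.pi / J
            best_theta = 0.0
            improved = False
            for _h in range(n_refinements + 1):
                c = np.cos(theta)
                s = np.sin(theta)
                sq = c * c + s * s + 2.0 * c * s * aj
                good = sq > 1e-16
                if good.any():
                    norms = np.sqrt(sq[good])
                    Y = (y[:, None] * c[good] + zj[:, None] * s[good]) / norms
                    vals = scale_cols(Y)
                    i = int(np.argmax(vals))
                    if vals[i] > state["best"] + 1e-14:
                        state["best"] = float(vals[i])
                        best_theta = float(theta[good][i])
                        improved = True
                if not improved and not always_refine:
                    break  # fast phase: skip refinements in a flat plane
                theta = best_theta + width * refine_offsets
                width /= 2.0
            if improved and best_theta != 0.0:
                c, s = np.cos(best_theta), np.sin(best_theta)
                a = c * a
                a[j] += s
                nrm = np.linalg.norm(a)
                a /= nrm
                y = (c * y + s * zj) / nrm
                state["a"] = a
                state["y"] = y
                any_improved = True
        return any_improved

    for cycle in range(max_cycles):
        a_prev = state["a"].copy()
        sweep(always_refine=cycle == 0)
        if np.linalg.norm(state["a"] - a_prev) < tol:
            break
    return state["a"], state["best"]


def _pp_fit(X, K, pp_index, algorithm, grid_points, n_refinements, max_cycles, tol,
            location=None):
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("projection-pursuit PCA requires complete data; impute first")
    n, p = X.shape
    if K > min(n - 1, p):
        raise ValueError("K must not exceed min(n - 1, p)")
    scale_cols = _PP_INDICES[pp_index]
    if location is None:
        location = np.median(X, axis=0)
    else:
        location = np.asarray(location, dtype=float)
    Z, W = _reduce_basis(X, location)
    r = Z.shape[1]
    Zd = Z.copy()
    dirs = []
    truncated = False
    for _k in range(K):
        if algorithm == "cr":
            a, val = _cr_direction(Zd, scale_cols)
        else:
            a, val = _grid_direction(Zd, scale_cols, grid_points, n_refinements, max_cycles, tol)
        if val <= 1e-12 or not np.isfinite(val):
            truncated = True
            warnings.warn(
                "deflated data carries no remaining scale; returning a truncated "
                f"result with {_k} component(s)",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        # deflation never reintroduces previous directions, but the grid search
        # may leave a numerically tiny component along them; strip it
        for prev in dirs:
            a -= (a @ prev) * prev
        nrm = np.linalg.norm(a)
        if nrm <= 1e-12:
            truncated = True
            break
        a /= nrm
        dirs.append(a)
        yk = Zd @ a
        Zd -= np.outer(yk, a)
    if not dirs:
        raise ValueError("no component with positive robust scale could be found")
    B = np.column_stack(dirs)
    scores = Z @ B
    # The coordinatewise median need not project onto the centre of the
    # data bulk along every pursuit direction (the median is not
    # projection-equivariant), which would bias every score distance.
    # Refine the location inside the fitted subspace so each robust
    # score column has zero median; scores stay exactly (X - 1 mu') P.
    offsets = np.median(scores, axis=0)
    scores = scores - offsets
    location = location + (W @ B) @ offsets
    eigvals = scale_cols(scores) ** 2
    order = np.argsort(-eigvals, kind="stable")
    B = B[:, order]
    eigvals = eigvals[order]
    scores = scores[:, order]
    return RobustPCAResult(
        eigenvectors=W @ B,
        eigenvalues=eigvals,
        scores=scores,
        location=location,
        pp_index=pp_index,
        algorithm=algorithm,
        grid_points=grid_points if algorithm == "grid" else None,
        candidate_set_size=n if algorithm == "cr" else None,
        truncated=truncated,
    )


def pp_pca_cr(X, K: int, pp_index: str = "mad", location=None) -> RobustPCAResult:
    """Projection-pursuit robust PCA with the candidate-set (CR) search.

    Component k maximises the robust scale of projections over the finite
    set of normalised, deflated observations; the k-th eigenvalue is the
    squared winning scale.  Eigenvalues are reported in nonincreasing
    order (a robust index need not decrease along the search order).
    """
    return _pp_fit(X, K, pp_index, "cr", None, 0, 0, 0.0, location=location)


def pp_pca_grid(
    X,
    K: int,
    pp_index: str = "mad",
    J: int = 10,
    n_refinements: int = 10,
    max_cycles: int = 25,
    tol: float = 1e-6,
    location=None,
) -> RobustPCAResult:
    """Projection-pursuit robust PCA with the plane-wise grid search.

    ``location`` overrides the default coordinatewise-median centre.
    Note that the coordinatewise median is not equivariant under
    rotations of the variables; conditional on a given centre the rest
    of the procedure is.
    """
    if J < 3:
        raise ValueError("J must be at least 3")
    return _pp_fit(X, K, pp_index, "grid", J, n_refinements, max_cycles, tol,
                   location=location)


# ---------------------------------------------------------------------------
# outlier diagnostics
# ---------------------------------------------------------------------------


def score_distances(result: RobustPCAResult, alpha: float = 0.975) -> tuple[np.ndarray, float]:
    """Mahalanobis-type distances within the robust PC subspace, with cutoff.

    ``SD_i = sqrt(sum_j t_ij^2 / l_j)``; the cutoff is the square root of
    the chi-square ``alpha`` quantile at k degrees of freedom.  Requires
    strictly positive eigenvalues — truncate zero-scale components first.
    """
    l = np.asarray(result.eigenvalues, dtype=float)
    if (l <= 0).any():
        raise ValueError(
            "score distances need positive eigenvalues; drop zero-eigenvalue "
            "components before calling"
        )
    sd = np.sqrt(((result.scores**2) / l).sum(axis=1))
    cutoff = float(np.sqrt(stats.chi2.ppf(alpha, df=l.size)))
    return sd, cutoff


def orth_distances(
    X, result: RobustPCAResult, alpha: float = 0.975, moments: str = "classical"
) -> tuple[np.ndarray, float, float, float]:
    """Distances to the robust PC subspace with a Wilson-Hilferty cutoff.

    ``OD_i = ||x_i - (mu + P t_i)||``.  Squared orthogonal distances are
    approximately a scaled chi-square ``g2 * chi2_{g1}``; by the
    Wilson-Hilferty transformation ``OD^(2/3)`` is then approximately
    normal, so the cutoff is ``(m + s * z_0.975)^(3/2)`` with ``m`` and
    ``s`` location and scale estimates of ``OD^(2/3)``.  By default these
    are the classical mean and standard deviation (the convention of the
    ROBPCA literature, which tracks the mild right skew of the bulk);
    ``moments='robust'`` uses the median and scaled MAD instead, which
    resists gross OD outliers but under-covers a skewed bulk.  The
    implied ``(g1, g2)`` of the chi-square approximation are returned
    alongside.

    When the fitted subspace exhausts the data (all OD numerically zero)
    the cutoff degenerates to zero and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    fitted = result.location + result.scores @ result.eigenvectors.T
    od = np.linalg.norm(X - fitted, axis=1)
    z = np.cbrt(od**2)
    if moments == "classical":
        m = float(z.mean())
        s = float(z.std(ddof=1)) if z.size > 1 else 0.0
    elif moments == "robust":
        m = float(np.median(z))
        s = mad(z)
    else:
        raise ValueError("moments must be 'classical' or 'robust'")
    if od.max() <= 1e-8 or s == 0.0:
        if od.max() <= 1e-8:
            warnings.warn(
                "all orthogonal distances are numerically zero (complete subspace); "
                "the OD cutoff is degenerate",
                RuntimeWarning,
                stacklevel=2,
            )
        cutoff = float(max(m, 0.0) ** 1.5)
    else:
        cutoff = float((m + s * stats.norm.ppf(alpha)) ** 1.5)
    # invert the Wilson-Hilferty moments: for OD^2 ~ g2 chi2_{g1},
    # OD^(2/3) ~ N(g2^(1/3)(1 - u), g2^(2/3) u / 2 * ... ) with u = 2/(9 g1):
    # mean = g2^(1/3)(1 - u), sd = g2^(1/3) sqrt(u); solve s/m for u.
    if s > 0 and m > 0:
        rho = s / m
        sqrt_u = (-1.0 + np.sqrt(1.0 + 4.0 * rho * rho)) / (2.0 * rho)
        u = sqrt_u**2
        g1 = 2.0 / (9.0 * u)
        g2 = (m / (1.0 - u)) ** 3 if u < 1 else float("nan")
    else:
        g1, g2 = float("nan"), float("nan")
    return od, cutoff, float(g1), float(g2)


def classify_outliers(sd, od, sd_cutoff: float, od_cutoff: float) -> np.ndarray:
    """Label subjects as ``regular`` or outlier types ``A``/``B``/``C``.

    A: large score distance only; B: large orthogonal distance only;
    C: both large.  All three types are removed before stratification.
    """
    sd = np.asarray(sd, dtype=float)
    od = np.asarray(od, dtype=float)
    if sd.shape != od.shape:
        raise ValueError("sd and od must have equal length")
    big_sd = sd > sd_cutoff
    big_od = od > od_cutoff
    labels = np.full(sd.shape, "regular", dtype=object)
    labels[big_sd & ~big_od] = "A"
    labels[~big_sd & big_od] = "B"
    labels[big_sd & big_od] = "C"
    return labels


def outlier_diagnostics(
    X, result: RobustPCAResult, alpha: float = 0.975, od_moments: str = "classical"
) -> OutlierDiagnostics:
    """Full diagnostics for a fitted robust PCA: distances, cutoffs, labels.

    Components with non-positive eigenvalues are dropped from the score
    distance (they carry no robust scale) but retained in the orthogonal
    distance through the fitted subspace.
    """
    keep = result.eigenvalues > 0
    if not keep.all():
        trimmed = RobustPCAResult(
            eigenvectors=result.eigenvectors[:, keep],
            eigenvalues=result.eigenvalues[keep],
            scores=result.scores[:, keep],
            location=result.location,
            pp_index=result.pp_index,
            algorithm=result.algorithm,
        )
    else:
        trimmed = result
    sd, sd_cut = score_distances(trimmed, alpha=alpha)
    od, od_cut, g1, g2 = orth_distances(X, trimmed, alpha=alpha, moments=od_moments)
    labels = classify_outliers(sd, od, sd_cut, od_cut)
    return OutlierDiagnostics(
        score_distance=sd,
        orth_distance=od,
        sd_cutoff=sd_cut,
        od_cutoff=od_cut,
        od_g1=g1,
        od_g2=g2,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------


class PPRobustPCA(BaseEstimator):
    """Projection-pursuit robust PCA as a scikit-learn style transformer.

    Parameters
    ----------
    n_components : int, default 5
        Number of robust components to extract.
    algorithm : {'grid', 'cr'}, default 'grid'
        Direction search; the grid search is recommended for wide
        genotype matrices, the candidate-set search is kept as an option.
    pp_index : {'mad', 'sd'}, default 'mad'
        Robust scale maximised along candidate directions.  ``'sd'``
        (classical standard deviation) is non-robust and exists for
        validation against classical PCA.
    grid_points, n_refinements, max_cycles, tol :
        Grid-search controls (J angles per plane, interval halvings,
        plane-cycling limit and direction-change stopping tolerance).
    impute_missing : bool, default True
        Mean-impute missing genotypes per SNP before fitting.

    Attributes
    ----------
    components_ : ndarray (n_features, n_components)
    eigenvalues_ : ndarray (n_components,)
    location_ : ndarray (n_features,)
    scores_ : ndarray (n_samples, n_components)
    result_ : RobustPCAResult
    """

    def __init__(
        self,
        n_components: int = 5,
        algorithm: str = "grid",
        pp_index: str = "mad",
        grid_points: int = 10,
        n_refinements: int = 10,
        max_cycles: int = 25,
        tol: float = 1e-6,
        impute_missing: bool = True,
    ):
        self.n_components = n_components
        self.algorithm = algorithm
        self.pp_index = pp_index
        self.grid_points = grid_points
        self.n_refinements = n_refinements
        self.max_cycles = max_cycles
        self.tol = tol
        self.impute_missing = impute_missing

    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.algorithm not in ("grid", "cr"):
            raise ValueError("algorithm must be 'grid' or 'cr'")
        if self.pp_index not in _PP_INDICES:
            raise ValueError(f"pp_index must be one of {sorted(_PP_INDICES)}")
        if np.isnan(X).any():
            if not self.impute_missing:
                raise ValueError("X contains missing values and impute_missing=False")
            X = X.copy()
            means = np.nanmean(X, axis=0)
            means = np.where(np.isfinite(means), means, 0.0)
            holes = np.isnan(X)
            X[holes] = np.broadcast_to(means, X.shape)[holes]
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        if self.algorithm == "cr":
            result = pp_pca_cr(X, self.n_components, self.pp_index)
        else:
            result = pp_pca_grid(
                X,
                self.n_components,
                self.pp_index,
                J=self.grid_points,
                n_refinements=self.n_refinements,
                max_cycles=self.max_cycles,
                tol=self.tol,
            )
        self.result_ = result
        self.components_ = result.eigenvectors
        self.eigenvalues_ = result.eigenvalues
        self.location_ = result.location
        self.scores_ = result.scores
        self._fit_X_ = X
        return self

    def transform(self, X):
        X = self._validate(X)
        return (X - self.location_) @ self.components_

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_

    def outlier_diagnostics(
        self, X=None, alpha: float = 0.975, od_moments: str = "classical"
    ) -> OutlierDiagnostics:
        """Score/orthogonal-distance diagnostics for the fitted data (or ``X``)."""
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted")
        if X is None:
            X = self._fit_X_
            result = self.result_
        else:
            X = self._validate(X)
            scores = (X - self.location_) @ self.components_
            result = RobustPCAResult(
                eigenvectors=self.components_,
                eigenvalues=self.eigenvalues_,
                scores=scores,
                location=self.location_,
                pp_index=self.pp_index,
                algorithm=self.algorithm,
            )
        return outlier_diagnostics(X, result, alpha=alpha, od_moments=od_moments)
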