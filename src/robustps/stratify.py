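"""Population-structure inference: PCA, eigenvalue testing and clustering.

After subject outliers are removed, ordinary PCA of the (optionally
allele-frequency standardised) genotype matrix recovers axes of
ancestry variation.  The number of informative axes is chosen by
sequential Tracy-Widom tests of the leading eigenvalues against the
null spectral-edge distribution.  Discrete structure is then captured
by partitioning the retained PC scores with k-medoids (PAM), with the
number of clusters selected by the Gap statistic against uniform
reference data.  Continuous structure (admixture gradients) stays in
the PC scores themselves; both the scores and the cluster indicator
variables feed the downstream logistic association model.

Missing genotypes are handled by an alternating-least-squares PCA that
fits each rank-one term by regressing rows and columns on each other
using only observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from ._pam import pam

__all__ = [
    "classical_pca",
    "als_pca",
    "tracy_widom_count",
    "KMedoids",
    "kmedoids",
    "gap_select",
    "StratificationModel",
    "build_stratification",
    "PopulationStratifier",
]

# Tracy-Widom (beta = 1) upper-tail critical values
_TW1_CRITICAL = {0.10: 0.4501, 0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def classical_pca(X, K: int | None = None, normalize: bool = True):
    """SVD-based PCA of a genotype matrix.

    Columns are mean-centred; with ``normalize=True`` each column is
    additionally scaled by ``sqrt(q (1 - q))`` where ``q`` is the
    column allele-frequency estimate (mean dosage / 2) — the standard
    genotype standardisation that equalises drift variance across SNPs.
    Columns that are constant (or fixed, ``q`` in {0, 1}) carry no
    information and are dropped with a warning under normalisation.

    Returns
    -------
    scores : ndarray (n, K)
        Principal-component scores (left singular vectors times
        singular values), ordered by decreasing eigenvalue.
    eigenvalues : ndarray (min(n-1, p_kept),)
        Eigenvalues of the sample covariance of the processed matrix.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("classical_pca requires complete data; use als_pca")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    if normalize:
        q = X.mean(axis=0) / 2.0
        denom = np.sqrt(q * (1.0 - q))
        ok = denom > 0
        if not ok.all():
            warnings.warn(
                f"dropping {int((~ok).sum())} constant/fixed column(s) before "
                "allele-frequency normalisation",
                RuntimeWarning,
                stacklevel=2,
            )
        Xc = Xc[:, ok] / denom[ok]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / max(n - 1, 1)
    m = min(n - 1, Xc.shape[1])
    eigenvalues = eigenvalues[:m]
    if K is None:
        K = m
    if K > m:
        raise ValueError("K must not exceed min(n - 1, p)")
    scores = U[:, :K] * s[:K]
    return scores, eigenvalues


def als_pca(X, K: int, tol: float = 1e-8, max_iter: int = 500):
    """Rank-K PCA of a matrix with missing entries by alternating least squares.

    For each component the left vector is fit by no-intercept
    least-squares regressions of the rows on the current right vector
    (observed entries only), then the right vector by regressing the
    columns on the left vector, until the relative change of the fitted
    rank-one term drops below ``tol``; the term is subtracted and the
    next component extracted from the residual.  Columns are centred on
    their observed means first.

    Returns ``(scores, right_vectors, converged)`` where right vectors
    have unit norm and scores carry the scale.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = np.isfinite(X)
    if not obs.any(axis=0).all() or not obs.any(axis=1).all():
        raise ValueError("every row and column needs at least one observed entry")
    col_means = np.nanmean(X, axis=0)
    R = np.where(obs, X - col_means, 0.0)
    scores = np.zeros((n, K))
    right = np.zeros((p, K))
    converged = True
    W = obs.astype(float)
    for k in range(K):
        v = R.std(axis=0)
        nrm = np.linalg.norm(v)
        if nrm <= 1e-15:
            v = np.ones(p)
            nrm = np.sqrt(p)
        v = v / nrm
        u = np.zeros(n)
        ok = False
        for _ in range(max_iter):
            # rows on v (no intercept): u_i = sum_j obs R_ij v_j / sum_j obs v_j^2
            denom_u = W @ (v * v)
            u_new = (R @ v) / np.where(denom_u > 0, denom_u, 1.0)
            denom_v = W.T @ (u_new * u_new)
            v_new = (R.T @ u_new) / np.where(denom_v > 0, denom_v, 1.0)
            vn = np.linalg.norm(v_new)
            if vn <= 1e-15:
                u, v = u_new, v_new
                ok = True  # zero residual: converged to the null component
                break
            v_new = v_new / vn
            u_scaled = u_new * vn
            # relative change of the fitted rank-one term
            prev = np.outer(u, v)
            cur = np.outer(u_scaled, v_new)
            delta = np.linalg.norm(cur - prev)
            scale = max(np.linalg.norm(cur), 1e-15)
            u, v = u_scaled, v_new
            if delta / scale < tol:
                ok = True
                break
        if not ok:
            converged = False
        scores[:, k] = u
        right[:, k] = v
        R = np.where(obs, R - np.outer(u, v), 0.0)
    return scores, right, converged


def tracy_widom_count(eigenvalues, n: int, p: int, alpha: float = 0.05) -> int:
    """Number of significant eigenvalues by sequential Tracy-Widom tests.

    At each stage the remaining spectrum is rescaled to the null Wishart
    edge using the effective-marker-count standardisation: with ``m``
    remaining eigenvalues, ``S1 = sum(l)``, ``S2 = sum(l^2)``,

    ``n_eff = (m + 1) S1^2 / ((m - 1) S2 - S1^2)``,
    ``l* = m l_1 / S1``,
    ``mu = (sqrt(n_eff - 1) + sqrt(m))^2 / n_eff``,
    ``sigma = (sqrt(n_eff - 1) + sqrt(m)) / n_eff *
    (1/sqrt(n_eff - 1) + 1/sqrt(m))^(1/3)``,

    and ``(l* - mu) / sigma`` is referred to the Tracy-Widom (beta=1)
    distribution.  Testing proceeds from the top eigenvalue down and
    stops at the first acceptance; the count of consecutive rejections
    is returned.
    """
    if n < 2 or p < 2:
        raise ValueError("need at least 2 subjects and 2 SNPs")
    if alpha not in _TW1_CRITICAL:
        raise ValueError(f"alpha must be one of {sorted(_TW1_CRITICAL)}")
    crit = _TW1_CRITICAL[alpha]
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    ev = ev[ev > 1e-12]
    count = 0
    for i in range(ev.size - 2):
        rem = ev[i:]
        m = rem.size
        s1 = rem.sum()
        s2 = (rem**2).sum()
        denom = (m - 1) * s2 - s1**2
        if denom <= 0:
            break
        n_eff = (m + 1) * s1**2 / denom
        if n_eff <= 1:
            break
        lstar = m * rem[0] / s1
        a = np.sqrt(n_eff - 1.0)
        b = np.sqrt(m)
        mu = (a + b) ** 2 / n_eff
        sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
        tw = (lstar - mu) / sigma
        if tw > crit:
            count += 1
        else:
            break
    return count


# ---------------------------------------------------------------------------
# k-medoids and the Gap statistic
# ---------------------------------------------------------------------------


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM k-medoids clustering on Euclidean dissimilarities.

    Medoids are data points; the BUILD+SWAP search is deterministic for
    a given input, so ``random_state`` exists only for interface
    compatibility.

    Attributes
    ----------
    labels_ : ndarray (n_samples,)
    medoid_indices_ : ndarray (n_clusters,)
    inertia_ : float
        Summed point-to-medoid dissimilarity.
    """

    def __init__(self, n_clusters: int = 2, max_swaps: int = 200, random_state=None):
        self.n_clusters = n_clusters
        self.max_swaps = max_swaps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")
        if self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters cannot exceed the number of points")
        D = squareform(pdist(X))
        medoids, labels, total = pam(D, self.n_clusters, self.max_swaps)
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = total
        return self


def kmedoids(points, k: int, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Cluster ``points`` into ``k`` groups with PAM; returns (labels, medoids)."""
    if k == 0:
        raise ValueError("k must be at least 1")
    est = KMedoids(n_clusters=k).fit(points)
    return est.labels_, est.medoid_indices_


def _within_dispersion(D2: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster dispersion W = sum_r (1/(2 n_r)) sum_{i,i' in r} d^2."""
    w = 0.0
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if members.size > 1:
            w += D2[np.ix_(members, members)].sum() / (2.0 * members.size)
    return w


def gap_select(
    points,
    K_max: int = 6,
    B: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[int, dict]:
    """Choose the number of clusters with the Gap statistic.

    For each ``k`` the observed log within-cluster dispersion of the PAM
    partition is compared with its average over ``B`` reference datasets
    drawn uniformly over the per-dimension bounding box of the points:
    ``Gap(k) = mean_b log(W*_kb) - log(W_k)``.  The selected count is the
    smallest ``k`` with ``Gap(k) >= Gap(k+1) - s_{k+1}`` where
    ``s_k = sd_b(log W*_kb) * sqrt(1 + 1/B)``; if no ``k`` qualifies the
    maximum is returned.  Degenerate all-identical inputs yield 1.

    Returns ``(k_star, curve)`` with the curve holding per-k Gap values,
    simulation standard deviations and the observed log dispersions.
    """
    if K_max < 1:
        raise ValueError("K_max must be at least 1")
    if B < 10:
        raise ValueError("B must be at least 10")
    if rng is None:
        rng = np.random.default_rng()
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if np.allclose(lo, hi):
        return 1, {"gap": np.zeros(K_max), "sk": np.zeros(K_max), "log_w": np.zeros(K_max)}
    K_max = min(K_max, n)

    def log_w_curve(X):
        """log W_k for k = 1..K_max from one distance decomposition."""
        D = squareform(pdist(X))
        D2 = D * D
        out = np.empty(K_max)
        for k in range(1, K_max + 1):
            if k == 1:
                labels = np.zeros(X.shape[0], dtype=int)
            else:
                _, labels, _ = pam(D, k)
            out[k - 1] = np.log(max(_within_dispersion(D2, labels), 1e-300))
        return out

    log_w_obs = log_w_curve(pts)
    log_w_ref = np.empty((B, K_max))
    for b in range(B):
        log_w_ref[b] = log_w_curve(rng.uniform(lo, hi, size=(n, d)))
    gap = log_w_ref.mean(axis=0) - log_w_obs
    sk = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    k_star = K_max
    for k in range(K_max - 1):
        if gap[k] >= gap[k + 1] - sk[k + 1]:
            k_star = k + 1
            break
    return k_star, {"gap": gap, "sk": sk, "log_w": log_w_obs}


# ---------------------------------------------------------------------------
# assembled stratification model
# ---------------------------------------------------------------------------


@dataclass
class StratificationModel:
    """Classical PCs and cluster structure of the outlier-free subjects.

    ``pcs``/``memberships`` are indexed by the retained subjects (rows of
    the input minus ``removed_subjects``).
    """

    pcs: np.ndarray
    eigenvalues: np.ndarray
    n_components: int
    cluster_count: int
    memberships: np.ndarray
    medoid_indices: np.ndarray
    gap_curve: dict
    removed_subjects: np.ndarray

    def cluster_indicators(self) -> np.ndarray:
        """Dummy-coded cluster membership with the first level dropped.

        Returns an (n_kept, cluster_count - 1) matrix; empty when there
        is a single cluster (the intercept absorbs it).
        """
        k = self.cluster_count
        if k <= 1:
            return np.empty((self.memberships.shape[0], 0))
        out = np.zeros((self.memberships.shape[0], k - 1))
        for j in range(1, k):
            out[:, j - 1] = self.memberships == j
        return out


def build_stratification(
    X,
    outlier_flags=None,
    K: int | str = "auto",
    K_max_clusters: int = 6,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    normalize: bool = True,
    tw_alpha: float = 0.05,
    max_components: int = 10,
) -> StratificationModel:
    """Remove flagged subjects, run PCA, select PCs and cluster them.

    ``K='auto'`` selects the component count by sequential Tracy-Widom
    tests (capped at ``max_components``).  When the test finds no
    significant eigenvalue the model carries zero PC covariates and a
    single cluster.  Clustering runs PAM on the retained PC scores with
    the Gap statistic choosing the cluster count.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if outlier_flags is None:
        keep = np.ones(n, dtype=bool)
    else:
        keep = ~np.asarray(outlier_flags, dtype=bool).ravel()
        if keep.shape[0] != n:
            raise ValueError("outlier_flags length must match the number of subjects")
    if not keep.any():
        raise ValueError("all subjects are flagged as outliers")
    removed = np.where(~keep)[0]
    Xk = X[keep]
    if rng is None:
        rng = np.random.default_rng()

    scores_all, eigenvalues = classical_pca(Xk, K=None, normalize=normalize)
    if K == "auto":
        n_comp = tracy_widom_count(eigenvalues, Xk.shape[0], X.shape[1], alpha=tw_alpha)
        n_comp = min(n_comp, max_components)
    else:
        n_comp = int(K)
    n_comp = min(n_comp, scores_all.shape[1])
    pcs = scores_all[:, :n_comp]

    if n_comp == 0:
        cluster_count = 1
        memberships = np.zeros(Xk.shape[0], dtype=int)
        medoids = np.empty(0, dtype=int)
        curve = {"gap": np.zeros(0), "sk": np.zeros(0), "log_w": np.zeros(0)}
    else:
        cluster_count, curve = gap_select(pcs, K_max=K_max_clusters, B=B, rng=rng)
        if cluster_count == 1:
            memberships = np.zeros(Xk.shape[0], dtype=int)
            medoids = np.empty(0, dtype=int)
        else:
            memberships, medoids = kmedoids(pcs, cluster_count)
    return StratificationModel(
        pcs=pcs,
        eigenvalues=eigenvalues,
        n_components=n_comp,
        cluster_count=cluster_count,
        memberships=memberships,
        medoid_indices=medoids,
        gap_curve=curve,
        removed_subjects=removed,
    )


class PopulationStratifier(BaseEstimator):
    """Estimator facade over :func:`build_stratification`.

    Parameters mirror the functional interface; ``fit(X)`` accepts the
    genotype matrix (optionally with an ``outlier_flags`` keyword) and
    exposes ``pcs_``, ``eigenvalues_``, ``cluster_count_``, ``labels_``
    and the assembled ``model_``.
    """

    def __init__(
        self,
        n_components: int | str = "auto",
        max_clusters: int = 6,
        gap_B: int = 1000,
        normalize: bool = True,
        tw_alpha: float = 0.05,
        max_components: int = 10,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_clusters = max_clusters
        self.gap_B = gap_B
        self.normalize = normalize
        self.tw_alpha = tw_alpha
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y=None, outlier_flags=None):
        rng = np.random.default_rng(self.random_state)
        model = build_stratification(
            X,
            outlier_flags=outlier_flags,
            K=self.n_components,
            K_max_clusters=self.max_clusters,
            B=self.gap_B,
            rng=rng,
            normalize=self.normalize,
            tw_alpha=self.tw_alpha,
            max_components=self.max_components,
        )
        self.model_ = model
        self.pcs_ = model.pcs
        self.eigenvalues_ = model.eigenvalues
        self.cluster_count_ = model.cluster_count
        self.labels_ = model.memberships
        return self
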