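"""Per-SNP logistic association tests under six stratification strategies.

The association model is the logistic regression

    logit P(Y = 1) = beta * g + gamma' X + eta' Z

with ``g`` the SNP dosage, ``X`` the retained principal-component
scores and ``Z`` the cluster-membership indicator variables.  The
methods compared are:

``trend``
    the 1-df logistic likelihood-ratio test of ``g`` with no adjustment;
``gc``
    the trend test with genomic control — all statistics divided by
    ``lambda = max(1, median(stat) / median(chi2_1))`` estimated from a
    null SNP panel;
``pca``
    the trend test with the significant top PCs as covariates
    (continuous adjustment only);
``mds``
    PCs plus cluster indicators, no outlier removal (the PCA/MDS
    equivalence for Euclidean similarity makes classical PCs the MDS
    coordinates, so this implements MDS-plus-clustering without an
    explicit distance decomposition);
``rpca_rhm`` / ``rpca_pp``
    resampling-by-half-means or projection-pursuit robust PCA subject
    outlier removal first, then PCs plus cluster indicators on the
    retained subjects.

Likelihood-ratio statistics are referred to chi-square with 1 df; a
score test is substituted (and flagged) whenever the maximum-likelihood
fit fails to converge, e.g. under perfect separation, so that rate
computations never lose SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import GenotypeDataset
from .rhm import rhm_detect
from .robust_pca import PPRobustPCA
from .stratify import StratificationModel, build_stratification

__all__ = [
    "AssociationResult",
    "METHODS",
    "trend_test",
    "adjusted_test",
    "genomic_control",
    "run_method",
    "adjust_multiplicity",
    "inflation_factor",
    "CHI2_1_MEDIAN",
]

METHODS = ("trend", "gc", "pca", "mds", "rpca_rhm", "rpca_pp")

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class AssociationResult:
    """Outcome of one SNP's association test."""

    snp_id: str
    method: str
    statistic: float
    df: int
    p_value: float
    beta_hat: float
    n_used: int
    status: str = "ok"
    adjusted_p: float | None = None


def _null_loglik(y) -> float:
    n = y.size
    n1 = y.sum()
    n0 = n - n1
    ll = 0.0
    if n1 > 0:
        ll += n1 * np.log(n1 / n)
    if n0 > 0:
        ll += n0 * np.log(n0 / n)
    return float(ll)


class _LogitFit:
    """Lightweight IRLS logistic fit (iteratively reweighted least squares).

    Mirrors the behaviour of R's ``glm`` binomial fit: fitted
    probabilities are clamped away from 0/1, the working least-squares
    system is solved with a pseudo-inverse when (near-)singular, and
    convergence is declared on the relative deviance change.  Under
    complete or quasi-complete separation the deviance still converges
    to a finite value, so likelihood-ratio statistics remain usable; the
    ``separated`` flag records that the MLE itself diverged.
    """

    __slots__ = ("params", "llf", "cov_params", "fitted", "separated", "converged")

    def __init__(self, params, llf, cov_params, fitted, separated, converged):
        self.params = params
        self.llf = llf
        self.cov_params = cov_params
        self.fitted = fitted
        self.separated = separated
        self.converged = converged

    @property
    def bse(self):
        return np.sqrt(np.diag(self.cov_params))

    def predict(self):
        return self.fitted


_PROB_EPS = 1e-10


def _fit_logit(y, exog, maxiter: int = 60, tol: float = 1e-10):
    y = np.asarray(y, dtype=float)
    X = np.asarray(exog, dtype=float)
    n, q = X.shape
    beta = np.zeros(q)
    dev = np.inf
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))
        mu = np.clip(mu, _PROB_EPS, 1.0 - _PROB_EPS)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        try:
            beta_new = np.linalg.solve(H, Xw.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.pinv(H) @ (Xw.T @ z)
        if not np.isfinite(beta_new).all():
            raise RuntimeError("IRLS produced non-finite coefficients")
        beta = beta_new
        dev_new = -2.0 * float(y @ np.log(mu) + (1.0 - y) @ np.log(1.0 - mu))
        if abs(dev_new - dev) / (abs(dev_new) + 0.1) < tol:
            converged = True
            dev = dev_new
            break
        dev = dev_new
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0))), _PROB_EPS, 1.0 - _PROB_EPS)
    llf = float(y @ np.log(mu) + (1.0 - y) @ np.log(1.0 - mu))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    separated = bool(np.abs(eta).max() > 20.0)
    if not converged and not separated:
        raise RuntimeError("logistic fit did not converge")
    return _LogitFit(beta, llf, cov, mu, separated, converged)

def _score_test(y, g, covars, null_probs):
    """Rao score test for adding ``g`` to a fitted null logistic model."""
    w = null_probs * (1.0 - null_probs)
    U = float(g @ (y - null_probs))
    C = np.column_stack([np.ones_like(g)] + ([covars] if covars is not None and covars.size else []))
    gw = g * w
    CwC = C.T @ (C * w[:, None])
    Cwg = C.T @ gw
    v = float(g @ gw - Cwg @ np.linalg.solve(CwC, Cwg))
    if v <= 0:
        return 0.0, 1.0
    stat = U * U / v
    return stat, float(stats.chi2.sf(stat, df=1))


def _drop_collinear(covars: np.ndarray) -> np.ndarray:
    """Drop trailing columns until [1, covars] has full column rank."""
    if covars.size == 0:
        return covars
    while covars.shape[1] > 0:
        design = np.column_stack([np.ones(covars.shape[0]), covars])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            return covars
        warnings.warn("dropping a collinear covariate column", RuntimeWarning, stacklevel=3)
        covars = covars[:, :-1]
    return covars


def _lrt_one(y, g, covars, null_res, test="lrt"):
    """One SNP's adjusted test given a fitted covariate-only null model.

    ``null_res`` is either a statsmodels result for the covariate model
    or a float log-likelihood for the intercept-only model.
    """
    g = np.asarray(g, dtype=float)
    if np.ptp(g) == 0.0:
        return 0.0, 1.0, 0.0, "degenerate"
    has_covars = covars is not None and covars.size
    exog_cols = [np.ones_like(g), g]
    if has_covars:
        exog_cols.append(covars)
    exog = np.column_stack(exog_cols)
    llf0 = null_res if isinstance(null_res, float) else null_res.llf
    try:
        res = _fit_logit(y, exog)
        beta = float(res.params[1])
        if test == "wald":
            se = float(res.bse[1])
            stat = (beta / se) ** 2 if se > 0 else 0.0
        else:
            stat = 2.0 * (res.llf - llf0)
        stat = max(float(stat), 0.0)
        status = "separated" if res.separated else "ok"
        return stat, float(stats.chi2.sf(stat, df=1)), beta, status
    except (RuntimeError, np.linalg.LinAlgError, ValueError):
        if isinstance(null_res, float):
            probs = np.full(y.shape, y.mean())
        else:
            probs = null_res.predict()
        stat, p = _score_test(y, g, covars if has_covars else None, probs)
        return stat, p, float("nan"), "score_fallback"


def trend_test(genotype, phenotype, snp_id: str = "snp", test: str = "lrt") -> AssociationResult:
    """Unadjusted 1-df logistic likelihood-ratio test of genotype on phenotype."""
    y = np.asarray(phenotype, dtype=float).ravel()
    g = np.asarray(genotype, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("phenotype must contain both cases and controls")
    stat, p, beta, status = _lrt_one(y, g, None, _null_loglik(y), test=test)
    return AssociationResult(
        snp_id=snp_id,
        method="trend",
        statistic=stat,
        df=1,
        p_value=p,
        beta_hat=beta,
        n_used=y.size,
        status=status,
    )


def adjusted_test(
    genotype,
    phenotype,
    pcs=None,
    clusters=None,
    test: str = "lrt",
    snp_id: str = "snp",
    method: str = "adjusted",
) -> AssociationResult:
    """Covariate-adjusted logistic test of one SNP.

    ``pcs`` is an (n, q) matrix of continuous covariates; ``clusters``
    an integer membership vector which is dummy-coded with the first
    level dropped.  With neither supplied this reduces exactly to
    :func:`trend_test`.  Collinear cluster indicator columns are
    dropped with a warning.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    g = np.asarray(genotype, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("phenotype must contain both cases and controls")
    blocks = []
    if pcs is not None and np.size(pcs):
        blocks.append(np.atleast_2d(np.asarray(pcs, dtype=float)).reshape(y.size, -1))
    if clusters is not None and np.size(clusters):
        labels = np.asarray(clusters).ravel()
        levels = np.unique(labels)
        for lev in levels[1:]:
            blocks.append((labels == lev).astype(float)[:, None])
    covars = np.hstack(blocks) if blocks else np.empty((y.size, 0))
    covars = _drop_collinear(covars)
    if covars.shape[1]:
        null_res = _fit_logit(y, np.column_stack([np.ones(y.size), covars]))
    else:
        null_res = _null_loglik(y)
    stat, p, beta, status = _lrt_one(y, g, covars, null_res, test=test)
    return AssociationResult(
        snp_id=snp_id,
        method=method,
        statistic=stat,
        df=1,
        p_value=p,
        beta_hat=beta,
        n_used=y.size,
        status=status,
    )


def genomic_control(results, panel_statistics) -> tuple[list[AssociationResult], float]:
    """Apply genomic control to trend results using a null SNP panel.

    ``lambda = max(1, median(panel statistics) / median(chi2_1))``; every
    statistic is divided by lambda and its p-value recomputed from
    chi-square with 1 df.
    """
    panel = np.asarray(panel_statistics, dtype=float)
    if panel.size == 0:
        raise ValueError("genomic control needs a non-empty null panel")
    lam = max(1.0, float(np.median(panel)) / CHI2_1_MEDIAN)
    corrected = []
    for r in results:
        stat = r.statistic / lam
        corrected.append(
            AssociationResult(
                snp_id=r.snp_id,
                method="gc",
                statistic=stat,
                df=r.df,
                p_value=float(stats.chi2.sf(stat, df=r.df)),
                beta_hat=r.beta_hat,
                n_used=r.n_used,
                status=r.status,
            )
        )
    return corrected, lam


def inflation_factor(statistics) -> float:
    """Genomic inflation factor: median statistic over the chi2_1 median."""
    s = np.asarray(statistics, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one statistic")
    return float(np.median(s)) / CHI2_1_MEDIAN


def adjust_multiplicity(p_values, procedure: str = "bh") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    mapping = {"holm": "holm", "bh": "fdr_bh"}
    if procedure not in mapping:
        raise ValueError("procedure must be 'holm' or 'bh'")
    return multipletests(p, method=mapping[procedure])[1]


# ---------------------------------------------------------------------------
# whole-dataset method dispatch
# ---------------------------------------------------------------------------


@dataclass
class MethodRunDetails:
    """Side information from a :func:`run_method` call."""

    method: str
    n_removed: int = 0
    removed_subjects: np.ndarray | None = None
    gc_lambda: float | None = None
    stratification: StratificationModel | None = None
    n_pcs: int = 0


def _testing_columns(dataset: GenotypeDataset):
    mask = np.isin(dataset.snp_role, ("random", "differentiated", "causal"))
    return np.where(mask)[0]


def run_method(
    dataset: GenotypeDataset,
    method: str,
    rng: np.random.Generator | None = None,
    gap_B: int = 1000,
    max_clusters: int = 6,
    n_robust_components: int = 5,
    rhm_nrep: int = 100,
    tw_alpha: float = 0.05,
    max_pc_covariates: int = 10,
    test: str = "lrt",
    return_details: bool = False,
):
    """Test every testing SNP of a dataset under one stratification method.

    Returns the list of :class:`AssociationResult` (one per testing SNP,
    in column order); with ``return_details=True`` a
    :class:`MethodRunDetails` is returned alongside.  Subjects removed
    by the robust methods are excluded from both stratification and
    testing.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if rng is None:
        rng = np.random.default_rng()
    y_all = dataset.phenotype
    X_inf = dataset.inference
    test_cols = _testing_columns(dataset)
    if X_inf.shape[1] == 0 and method not in ("trend",):
        raise ValueError("dataset has no inference SNPs for stratification")
    if test_cols.size == 0:
        raise ValueError("dataset has no testing SNPs")

    details = MethodRunDetails(method=method)
    keep = np.ones(dataset.n_subjects, dtype=bool)
    if method == "rpca_rhm":
        flags = rhm_detect(X_inf, nrep=rhm_nrep, rng=rng).flags
        keep = ~flags
    elif method == "rpca_pp":
        est = PPRobustPCA(n_components=n_robust_components, algorithm="grid").fit(X_inf)
        flags = est.outlier_diagnostics().outlier_mask
        keep = ~flags
    details.n_removed = int((~keep).sum())
    details.removed_subjects = np.where(~keep)[0]

    y = y_all[keep].astype(float)
    if y.min() == y.max():
        raise ValueError("outlier removal left a single phenotype class")

    pcs = None
    clusters = None
    if method in ("pca", "mds", "rpca_rhm", "rpca_pp"):
        use_clusters = method != "pca"
        model = build_stratification(
            X_inf,
            outlier_flags=~keep,
            K="auto",
            K_max_clusters=max_clusters,
            B=gap_B,
            rng=rng,
            tw_alpha=tw_alpha,
            max_components=max_pc_covariates,
        )
        details.stratification = model
        details.n_pcs = model.n_components
        pcs = model.pcs if model.n_components else None
        if use_clusters and model.cluster_count > 1:
            clusters = model.memberships

    blocks = []
    if pcs is not None and np.size(pcs):
        blocks.append(np.asarray(pcs, dtype=float))
    if clusters is not None:
        labels = np.asarray(clusters).ravel()
        for lev in np.unique(labels)[1:]:
            blocks.append((labels == lev).astype(float)[:, None])
    covars = np.hstack(blocks) if blocks else np.empty((y.size, 0))
    covars = _drop_collinear(covars)
    if covars.shape[1]:
        null_res = _fit_logit(y, np.column_stack([np.ones(y.size), covars]))
    else:
        null_res = _null_loglik(y)

    out_method = "trend" if method in ("trend", "gc") else method
    results = []
    for col in test_cols:
        g = dataset.genotypes[keep, col]
        if np.isnan(g).any():
            fill = np.nanmean(g)
            g = np.where(np.isnan(g), fill if np.isfinite(fill) else 0.0, g)
        stat, p, beta, status = _lrt_one(y, g, covars if covars.shape[1] else None, null_res, test=test)
        results.append(
            AssociationResult(
                snp_id=str(dataset.snp_ids[col]),
                method=out_method,
                statistic=stat,
                df=1,
                p_value=p,
                beta_hat=beta,
                n_used=y.size,
                status=status,
            )
        )

    if method == "gc":
        inf_cols = np.where(dataset.snp_role == "inference")[0]
        panel = np.empty(inf_cols.size)
        for i, col in enumerate(inf_cols):
            g = dataset.genotypes[keep, col]
            stat, _, _, _ = _lrt_one(y, g, None, null_res, test=test)
            panel[i] = stat
        results, lam = genomic_control(results, panel)
        details.gc_lambda = lam

    if return_details:
        return results, details
    return results
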