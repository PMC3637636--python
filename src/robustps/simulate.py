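"""Synthetic case-control genotype data with known population structure.

Two families of generators are provided:

* :func:`simulate_discrete` — subjects drawn from a small number of
  discrete subpopulations whose per-SNP allele frequencies follow the
  Balding-Nichols Beta model parameterised by Wright's fixation index
  ``F_ST``.  Cases and controls are sampled from the subpopulations with
  different proportion vectors, which induces population stratification.
* :func:`simulate_admixed` — a two-way admixed population where each
  subject carries an ancestry proportion ``a ~ U(0, 1)`` and disease risk
  grows as ``r**a``, so ancestry confounds the case-control contrast.

Each dataset contains a block of null *inference* SNPs used to estimate
structure, plus up to three categories of *testing* SNPs: ``random``
(null, exchangeable with the inference block), ``differentiated`` (null
but with a large between-population frequency gap, the stress test for
stratification correction), and ``causal`` (multiplicative relative risk
``R`` per copy of the risk allele).

Subject outliers can be injected into any dataset by replacing part of a
left singular vector of the genotype matrix with extreme values,
reconstructing and clipping to the genotype range (:func:`inject_outliers`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .datasets import GenotypeDataset

__all__ = [
    "DiscreteScenario",
    "AdmixedScenario",
    "OutlierInjectionConfig",
    "draw_subpop_freqs",
    "sample_control_genotypes",
    "sample_case_genotypes_causal",
    "simulate_discrete",
    "simulate_admixed",
    "simulate_scenario",
    "inject_outliers",
    "scenario",
    "SCENARIO_NAMES",
]


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteScenario:
    """Configuration of a discrete-subpopulation case-control study.

    Defaults correspond to the standard study conditions: 500 cases and
    500 controls, ``F_ST = 0.01`` (typical of divergent European
    populations), ancestral allele frequencies uniform on ``[0.1, 0.9]``,
    2000 inference SNPs, 1000 testing SNPs per category, relative risk
    ``R = 1.3`` at causal SNPs and differentiated-SNP frequencies of 0.8
    in population 1 versus 0.2 elsewhere.
    """

    n_pops: int
    case_props: tuple[float, ...]
    control_props: tuple[float, ...]
    fst: float = 0.01
    freq_low: float = 0.1
    freq_high: float = 0.9
    n_cases: int = 500
    n_controls: int = 500
    n_inference_snps: int = 2000
    n_testing_snps: int = 1000
    relative_risk: float = 1.3
    diff_freqs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be at least 1")
        for name in ("case_props", "control_props"):
            props = np.asarray(getattr(self, name), dtype=float)
            if props.shape != (self.n_pops,):
                raise ValueError(f"{name} must have length n_pops={self.n_pops}")
            if (props < 0).any() or abs(props.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if not 0.0 < self.freq_low < self.freq_high < 1.0:
            raise ValueError("require 0 < freq_low < freq_high < 1")
        if self.relative_risk < 1.0:
            raise ValueError("relative_risk must be >= 1")
        if self.diff_freqs is None:
            # 0.8 in population 1 versus 0.2 in the others
            object.__setattr__(
                self, "diff_freqs", (0.8,) + (0.2,) * (self.n_pops - 1)
            )
        dfreqs = np.asarray(self.diff_freqs, dtype=float)
        if dfreqs.shape != (self.n_pops,):
            raise ValueError("diff_freqs must have length n_pops")
        if ((dfreqs <= 0) | (dfreqs >= 1)).any():
            raise ValueError("diff_freqs must lie in (0, 1)")


@dataclass(frozen=True)
class AdmixedScenario:
    """Configuration of a two-way admixed case-control study.

    Disease probability for a subject with ancestry proportion ``a`` from
    population 1 is ``0.5 * log(r) * r**a / (r - 1)``, which integrates
    to 0.5 over ``a ~ U(0, 1)``; ``r`` is the ancestry risk (default 3).
    The default inference panel is 20,000 SNPs — denser than in the
    discrete scenarios because a continuous ancestry gradient is harder
    to estimate.
    """

    ancestry_risk: float = 3.0
    fst: float = 0.01
    freq_low: float = 0.1
    freq_high: float = 0.9
    n_cases: int = 500
    n_controls: int = 500
    n_inference_snps: int = 20000
    n_testing_snps: int = 1000
    relative_risk: float = 1.3
    diff_freqs: tuple[float, float] = (0.8, 0.2)
    max_attempts: int = 10_000_000

    def __post_init__(self) -> None:
        if self.ancestry_risk <= 1.0:
            raise ValueError("ancestry_risk must be > 1 (the risk model is degenerate at r <= 1)")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if not 0.0 < self.freq_low < self.freq_high < 1.0:
            raise ValueError("require 0 < freq_low < freq_high < 1")
        if self.relative_risk < 1.0:
            raise ValueError("relative_risk must be >= 1")


@dataclass(frozen=True)
class OutlierInjectionConfig:
    """How subject outliers are injected through the SVD of the genotype matrix.

    ``fraction`` of the subjects (rounded up) have their entry of the
    ``eigen_index``-th left singular vector replaced by extreme values;
    the matrix is then reconstructed and clipped to
    ``[clip_low, clip_high]``.  When ``magnitude`` is ``None`` it defaults
    to 20 times the largest absolute entry of the original singular
    vector: large enough that every perturbed subject is unambiguously
    aberrant to both detectors even after clipping bounds the damage.  ``sign_pattern='constant'`` (default) gives
    every perturbed subject ``+magnitude`` so the outliers form one
    coherent aberrant group, the way a shared technical artefact would;
    ``'alternating'`` spreads them over ``±magnitude``.
    """

    fraction: float = 0.05
    eigen_index: int = 2
    magnitude: float | None = None
    clip_low: float = 0.0
    clip_high: float = 2.0
    sign_pattern: str = "constant"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("fraction must lie in [0, 1)")
        if self.eigen_index < 1:
            raise ValueError("eigen_index is 1-based and must be >= 1")
        if self.clip_low >= self.clip_high:
            raise ValueError("clip_low must be smaller than clip_high")
        if self.sign_pattern not in ("constant", "alternating"):
            raise ValueError("sign_pattern must be 'constant' or 'alternating'")


def scenario(name: str, **overrides) -> DiscreteScenario | AdmixedScenario:
    """Return a named scenario preset (``S1``–``S4`` discrete, ``admixed``).

    S1/S2 have two subpopulations with moderate / extreme case-control
    proportion differences; S3/S4 are their three-population analogues.
    Keyword overrides replace any configuration field.
    """
    key = name.strip().lower()
    presets = {
        "s1": dict(n_pops=2, case_props=(0.6, 0.4), control_props=(0.4, 0.6)),
        "s2": dict(n_pops=2, case_props=(0.5, 0.5), control_props=(0.0, 1.0)),
        "s3": dict(
            n_pops=3,
            case_props=(0.45, 0.35, 0.20),
            control_props=(0.35, 0.20, 0.45),
        ),
        "s4": dict(
            n_pops=3,
            case_props=(0.33, 0.67, 0.0),
            control_props=(0.0, 0.33, 0.67),
        ),
    }
    if key in presets:
        cfg = dict(presets[key])
        cfg.update(overrides)
        return DiscreteScenario(**cfg)
    if key == "admixed":
        return AdmixedScenario(**overrides)
    raise ValueError(f"unknown scenario {name!r}; expected S1-S4 or 'admixed'")


SCENARIO_NAMES = ("S1", "S2", "S3", "S4", "admixed")


# ---------------------------------------------------------------------------
# elementary sampling operations
# ---------------------------------------------------------------------------


def draw_subpop_freqs(p_anc, fst: float, n_pops: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-population allele frequencies from the Balding-Nichols model.

    Each subpopulation frequency is an independent
    ``Beta(p(1-F_ST)/F_ST, (1-p)(1-F_ST)/F_ST)`` draw around the
    ancestral frequency ``p``, so that ``E = p`` and
    ``Var = F_ST * p * (1-p)``.

    Parameters
    ----------
    p_anc : float or ndarray
        Ancestral allele frequency (or one per SNP), strictly in (0, 1).
    fst : float
        Fixation index in (0, 1).
    n_pops : int
        Number of subpopulations.
    rng : numpy.random.Generator

    Returns
    -------
    ndarray of shape (n_pops,) or (n_pops, len(p_anc))
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if ((p_anc <= 0) | (p_anc >= 1)).any():
        raise ValueError("ancestral frequency must lie strictly in (0, 1)")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    ratio = (1.0 - fst) / fst
    shape = (n_pops,) if p_anc.ndim == 0 else (n_pops, p_anc.shape[0])
    return rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=shape)


def sample_control_genotypes(freq, n: int | None = None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample Hardy-Weinberg genotypes 0/1/2 at allele frequency ``freq``.

    ``P(0) = (1-p)^2``, ``P(1) = 2p(1-p)``, ``P(2) = p^2``.  ``freq`` may
    be an array, in which case one genotype is drawn per entry and ``n``
    must be ``None``.
    """
    freq = np.asarray(freq, dtype=float)
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("allele frequency must lie in [0, 1]")
    if rng is None:
        raise ValueError("an explicit random generator is required")
    size = n if freq.ndim == 0 else None
    return rng.binomial(2, freq, size=size).astype(float)


def case_genotype_probs(freq, rr: float) -> np.ndarray:
    """Genotype probabilities for a case at a causal SNP with relative risk ``rr``.

    The unnormalised probabilities are ``((1-p)^2, 2Rp(1-p), R^2 p^2)``;
    the normaliser is their sum.  ``rr = 1`` recovers Hardy-Weinberg.
    """
    p = np.asarray(freq, dtype=float)
    p0 = (1.0 - p) ** 2
    p1 = 2.0 * rr * p * (1.0 - p)
    p2 = (rr * p) ** 2
    z = p0 + p1 + p2
    return np.stack([p0 / z, p1 / z, p2 / z], axis=-1)


def sample_case_genotypes_causal(freq, rr: float, n: int | None = None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample case genotypes at a causal SNP under the multiplicative risk model."""
    if rr < 1.0:
        raise ValueError("relative risk must be >= 1")
    if rng is None:
        raise ValueError("an explicit random generator is required")
    freq = np.asarray(freq, dtype=float)
    probs = case_genotype_probs(freq, rr)
    if freq.ndim == 0:
        if n is None:
            n = 1
        u = rng.random(n)
        return (
            (u > probs[0]).astype(float) + (u > probs[0] + probs[1]).astype(float)
        )
    u = rng.random(freq.shape)
    c0 = probs[..., 0]
    c1 = c0 + probs[..., 1]
    return (u > c0).astype(float) + (u > c1).astype(float)


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------


def _quota_assignment(props: np.ndarray, n: int) -> np.ndarray:
    """Deterministic subpopulation counts matching the proportion vector.

    The configured proportions are treated as exact design quotas
    (largest-remainder rounding), not as multinomial probabilities:
    every replicate dataset then carries the same case-control ancestry
    contrast instead of a randomly perturbed one.
    """
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return np.repeat(np.arange(props.size), counts)


def _null_snp_block(pop_idx, scen, n_snps, rng):
    """HWE genotypes for null SNPs under the Beta frequency model."""
    p_anc = rng.uniform(scen.freq_low, scen.freq_high, size=n_snps)
    pop_freqs = draw_subpop_freqs(p_anc, scen.fst, scen.n_pops, rng)
    per_subject = pop_freqs[pop_idx, :]
    geno = rng.binomial(2, per_subject).astype(float)
    return geno, pop_freqs


def simulate_discrete(scen: DiscreteScenario, rng: np.random.Generator) -> GenotypeDataset:
    """Simulate a discrete-subpopulation case-control dataset.

    Cases precede controls in row order.  Columns are ordered as
    inference, random, differentiated, causal, with role labels recorded
    in the returned dataset.  Differentiated SNPs all share the fixed
    per-population frequencies of the scenario; causal SNPs tilt the case
    genotype distribution using the subject's own population frequency.
    """
    pop_case = _quota_assignment(np.asarray(scen.case_props), scen.n_cases)
    pop_ctrl = _quota_assignment(np.asarray(scen.control_props), scen.n_controls)
    pop_idx = np.concatenate([pop_case, pop_ctrl])
    phenotype = np.concatenate(
        [np.ones(scen.n_cases, dtype=int), np.zeros(scen.n_controls, dtype=int)]
    )
    n = pop_idx.shape[0]
    is_case = phenotype == 1

    blocks, roles, freq_blocks = [], [], []

    geno, freqs = _null_snp_block(pop_idx, scen, scen.n_inference_snps, rng)
    blocks.append(geno)
    roles += ["inference"] * scen.n_inference_snps
    freq_blocks.append(freqs)

    m = scen.n_testing_snps
    if m > 0:
        geno, freqs = _null_snp_block(pop_idx, scen, m, rng)
        blocks.append(geno)
        roles += ["random"] * m
        freq_blocks.append(freqs)

        dfreqs = np.asarray(scen.diff_freqs, dtype=float)
        per_subject = np.repeat(dfreqs[pop_idx][:, None], m, axis=1)
        blocks.append(rng.binomial(2, per_subject).astype(float))
        roles += ["differentiated"] * m
        freq_blocks.append(np.repeat(dfreqs[:, None], m, axis=1))

        # causal: controls are HWE at their population frequency, cases tilted by R
        p_anc = rng.uniform(scen.freq_low, scen.freq_high, size=m)
        pop_freqs = draw_subpop_freqs(p_anc, scen.fst, scen.n_pops, rng)
        per_subject = pop_freqs[pop_idx, :]
        geno = rng.binomial(2, per_subject).astype(float)
        geno[is_case] = sample_case_genotypes_causal(
            per_subject[is_case], scen.relative_risk, rng=rng
        )
        blocks.append(geno)
        roles += ["causal"] * m
        freq_blocks.append(pop_freqs)

    return GenotypeDataset(
        genotypes=np.concatenate(blocks, axis=1),
        phenotype=phenotype,
        snp_role=np.asarray(roles, dtype=object),
        subject_pop=pop_idx,
        snp_freqs=np.concatenate(freq_blocks, axis=1),
    )


def admixture_disease_prob(a, ancestry_risk: float) -> np.ndarray:
    """``P(disease | a) = 0.5 * log(r) * r**a / (r - 1)``; averages 0.5 over a~U(0,1)."""
    r = float(ancestry_risk)
    if r <= 1.0:
        raise ValueError("ancestry_risk must be > 1")
    a = np.asarray(a, dtype=float)
    return 0.5 * math.log(r) * np.power(r, a) / (r - 1.0)


def simulate_admixed(scen: AdmixedScenario, rng: np.random.Generator) -> GenotypeDataset:
    """Simulate a two-way admixed case-control dataset.

    Subjects are drawn by rejection sampling: ancestry ``a ~ U(0, 1)``,
    disease via :func:`admixture_disease_prob`, until the case and
    control quotas are filled (capped at ``scen.max_attempts`` draws).
    Genotypes use the subject-specific frequency ``a*p1 + (1-a)*p2``
    where ``p1, p2`` follow the two-population Beta model.
    """
    cases_a: list[float] = []
    ctrls_a: list[float] = []
    attempts = 0
    batch = max(1024, 2 * (scen.n_cases + scen.n_controls))
    while len(cases_a) < scen.n_cases or len(ctrls_a) < scen.n_controls:
        if attempts >= scen.max_attempts:
            raise RuntimeError(
                "could not fill case/control quotas within the attempt budget"
            )
        a = rng.uniform(0.0, 1.0, size=batch)
        diseased = rng.random(batch) < admixture_disease_prob(a, scen.ancestry_risk)
        attempts += batch
        need_cases = scen.n_cases - len(cases_a)
        need_ctrls = scen.n_controls - len(ctrls_a)
        cases_a.extend(a[diseased][:need_cases])
        ctrls_a.extend(a[~diseased][:need_ctrls])

    a = np.concatenate([np.asarray(cases_a), np.asarray(ctrls_a)])
    phenotype = np.concatenate(
        [np.ones(scen.n_cases, dtype=int), np.zeros(scen.n_controls, dtype=int)]
    )
    is_case = phenotype == 1

    def beta_pair(n_snps):
        p_anc = rng.uniform(scen.freq_low, scen.freq_high, size=n_snps)
        return draw_subpop_freqs(p_anc, scen.fst, 2, rng)

    def subject_freqs(pair):
        return a[:, None] * pair[0][None, :] + (1.0 - a[:, None]) * pair[1][None, :]

    blocks, roles, freq_blocks = [], [], []

    pair = beta_pair(scen.n_inference_snps)
    blocks.append(rng.binomial(2, subject_freqs(pair)).astype(float))
    roles += ["inference"] * scen.n_inference_snps
    freq_blocks.append(pair)

    m = scen.n_testing_snps
    if m > 0:
        pair = beta_pair(m)
        blocks.append(rng.binomial(2, subject_freqs(pair)).astype(float))
        roles += ["random"] * m
        freq_blocks.append(pair)

        d1, d2 = scen.diff_freqs
        per_subject = a[:, None] * d1 + (1.0 - a[:, None]) * d2
        blocks.append(rng.binomial(2, np.repeat(per_subject, m, axis=1)).astype(float))
        roles += ["differentiated"] * m
        freq_blocks.append(np.repeat(np.asarray([[d1], [d2]]), m, axis=1))

        pair = beta_pair(m)
        per_subject = subject_freqs(pair)
        geno = rng.binomial(2, per_subject).astype(float)
        geno[is_case] = sample_case_genotypes_causal(
            per_subject[is_case], scen.relative_risk, rng=rng
        )
        blocks.append(geno)
        roles += ["causal"] * m
        freq_blocks.append(pair)

    return GenotypeDataset(
        genotypes=np.concatenate(blocks, axis=1),
        phenotype=phenotype,
        snp_role=np.asarray(roles, dtype=object),
        subject_ancestry=a,
        snp_freqs=np.concatenate(freq_blocks, axis=1),
    )


def simulate_scenario(scen, rng: np.random.Generator) -> GenotypeDataset:
    """Dispatch on the scenario type (discrete versus admixed)."""
    if isinstance(scen, DiscreteScenario):
        return simulate_discrete(scen, rng)
    if isinstance(scen, AdmixedScenario):
        return simulate_admixed(scen, rng)
    raise TypeError(f"unsupported scenario type {type(scen).__name__}")


# ---------------------------------------------------------------------------
# outlier injection
# ---------------------------------------------------------------------------


def inject_outliers(
    X: np.ndarray,
    cfg: OutlierInjectionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Inject subject outliers by perturbing one left singular vector.

    Computes the thin SVD ``X = U diag(d) V^T``, replaces
    ``ceil(fraction * n)`` uniformly chosen entries of the
    ``cfg.eigen_index``-th column of ``U`` with ``±magnitude`` (signs
    alternating across the selected subjects in index order),
    reconstructs ``X_mod = U_mod diag(d) V^T`` and clips to
    ``[clip_low, clip_high]``.  Rows that were not selected are
    reproduced exactly up to clipping.

    Returns
    -------
    (X_mod, indices) :
        The modified matrix and the sorted array of perturbed row indices.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if cfg.fraction == 0.0:
        return X.copy(), np.empty(0, dtype=int)
    k = int(math.ceil(cfg.fraction * n))
    if k < 1:
        return X.copy(), np.empty(0, dtype=int)
    if cfg.eigen_index > min(n, p):
        raise ValueError("eigen_index exceeds the rank bound min(n, p)")
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    col = cfg.eigen_index - 1
    idx = np.sort(rng.choice(n, size=k, replace=False))
    magnitude = cfg.magnitude
    if magnitude is None:
        magnitude = 20.0 * float(np.abs(U[:, col]).max())
    if cfg.sign_pattern == "alternating":
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    else:
        signs = np.ones(k)
    U_mod = U.copy()
    U_mod[idx, col] = signs * magnitude
    X_mod = (U_mod * d) @ Vt
    np.clip(X_mod, cfg.clip_low, cfg.clip_high, out=X_mod)
    return X_mod, idx


def inject_dataset_outliers(
    dataset: GenotypeDataset,
    cfg: OutlierInjectionConfig,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Apply :func:`inject_outliers` to a dataset's full genotype matrix.

    The perturbation acts on all columns (inference and testing SNPs
    alike) since an outlying subject is aberrant across its entire
    genotype vector.  Returns a new dataset with ``outlier_flags`` set.
    """
    X_mod, idx = inject_outliers(dataset.genotypes, cfg, rng)
    flags = np.zeros(dataset.n_subjects, dtype=bool)
    flags[idx] = True
    return GenotypeDataset(
        genotypes=X_mod,
        phenotype=dataset.phenotype.copy(),
        snp_role=dataset.snp_role.copy(),
        snp_ids=dataset.snp_ids.copy(),
        subject_ids=dataset.subject_ids.copy(),
        subject_pop=None if dataset.subject_pop is None else dataset.subject_pop.copy(),
        subject_ancestry=(
            None if dataset.subject_ancestry is None else dataset.subject_ancestry.copy()
        ),
        outlier_flags=flags,
        snp_freqs=None if dataset.snp_freqs is None else dataset.snp_freqs.copy(),
    )
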