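"""In-memory container for subject-by-SNP case-control genotype data.

Genotypes are stored as a dense ``float64`` matrix with additive coding
(0, 1, 2 copies of the reference allele).  Missing calls are ``NaN``.
Real-valued dosages are permitted because the outlier-injection scheme
reconstructs genotypes from a truncated SVD and only clips them to
``[0, 2]`` without re-rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: the four column roles a SNP can play in a simulated study
SNP_ROLES = ("inference", "random", "differentiated", "causal")

#: prefixes used to encode the role into SNP identifiers on disk
ROLE_PREFIX = {
    "inference": "inf",
    "random": "rnd",
    "differentiated": "dif",
    "causal": "cau",
}
PREFIX_ROLE = {v: k for k, v in ROLE_PREFIX.items()}


def role_from_snp_id(snp_id: str) -> str:
    """Infer a SNP's role from its identifier prefix (``inf``/``rnd``/``dif``/``cau``).

    Unrecognised identifiers default to ``inference`` so that externally
    produced panels are usable for structure inference.
    """
    prefix = str(snp_id).split("_", 1)[0]
    return PREFIX_ROLE.get(prefix, "inference")


@dataclass
class GenotypeDataset:
    """A subject-by-SNP genotype matrix with phenotype and provenance.

    Parameters
    ----------
    genotypes : ndarray of shape (n_subjects, n_snps)
        Additively coded genotypes; ``NaN`` marks missing calls.  Entries
        may be real-valued dosages in ``[0, 2]``.
    phenotype : ndarray of shape (n_subjects,)
        Binary outcome, 1 for cases and 0 for controls.
    snp_role : ndarray of shape (n_snps,)
        One of :data:`SNP_ROLES` per column.
    snp_ids, subject_ids : ndarray, optional
        Identifiers; generated automatically when omitted.
    subject_pop : ndarray, optional
        True subpopulation index for discrete simulations.
    subject_ancestry : ndarray, optional
        True ancestry proportion ``a`` for admixed simulations.
    outlier_flags : ndarray of bool, optional
        Marks subjects perturbed by outlier injection.
    snp_freqs : ndarray, optional
        True per-population allele frequencies, shape (n_pops, n_snps).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_role: np.ndarray
    snp_ids: np.ndarray | None = None
    subject_ids: np.ndarray | None = None
    subject_pop: np.ndarray | None = None
    subject_ancestry: np.ndarray | None = None
    outlier_flags: np.ndarray | None = None
    snp_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D subject-by-SNP matrix")
        n, p = self.genotypes.shape
        self.phenotype = np.asarray(self.phenotype, dtype=int).ravel()
        if self.phenotype.shape[0] != n:
            raise ValueError("phenotype length does not match the number of subjects")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary with 1 = case, 0 = control")
        self.snp_role = np.asarray(self.snp_role, dtype=object).ravel()
        if self.snp_role.shape[0] != p:
            raise ValueError("snp_role length does not match the number of SNPs")
        bad = set(self.snp_role) - set(SNP_ROLES)
        if bad:
            raise ValueError(f"unknown SNP roles: {sorted(bad)}")
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("non-missing genotypes must lie in [0, 2]")
        if self.snp_ids is None:
            counters: dict[str, int] = {}
            ids = []
            for role in self.snp_role:
                counters[role] = counters.get(role, 0) + 1
                ids.append(f"{ROLE_PREFIX[role]}_{counters[role]:06d}")
            self.snp_ids = np.asarray(ids, dtype=object)
        else:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object).ravel()
            if self.snp_ids.shape[0] != p:
                raise ValueError("snp_ids length does not match the number of SNPs")
        if self.subject_ids is None:
            self.subject_ids = np.asarray(
                [f"subj_{i + 1:05d}" for i in range(n)], dtype=object
            )
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object).ravel()
            if self.subject_ids.shape[0] != n:
                raise ValueError("subject_ids length does not match the number of subjects")
        if self.outlier_flags is not None:
            self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool).ravel()

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    # -- role-based column access ---------------------------------------
    def role_mask(self, role: str) -> np.ndarray:
        if role not in SNP_ROLES:
            raise ValueError(f"unknown SNP role {role!r}")
        return self.snp_role == role

    def matrix(self, role: str) -> np.ndarray:
        """Return the genotype columns whose role equals ``role``."""
        return self.genotypes[:, self.role_mask(role)]

    @property
    def inference(self) -> np.ndarray:
        """The structure-inference SNP block used for stratification."""
        return self.matrix("inference")

    def testing_roles(self) -> list[str]:
        """Roles of testing SNPs present in the dataset, in canonical order."""
        present = set(self.snp_role)
        return [r for r in ("random", "differentiated", "causal") if r in present]
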