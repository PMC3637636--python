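"""Readers and writers for genotype matrices (matrix TSV and PLINK ``.raw``).

The canonical interchange format is a tab-separated matrix with one row
per subject: the first two columns are the subject identifier and the
binary phenotype (1 = case), followed by one column per SNP with the
SNP identifier in the header.  Missing genotypes are written as ``NA``.
SNP roles are carried in the identifier prefix (``inf``/``rnd``/``dif``/
``cau``); identifiers without a recognised prefix are treated as
inference SNPs.

The PLINK ``.raw`` additive dialect (``FID IID PAT MAT SEX PHENOTYPE``
then one dosage column per SNP, phenotype coded 1 = control / 2 = case)
is supported for interoperability with upstream quality-control
pipelines.  Binary ``.bed`` input is intentionally out of scope.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset, role_from_snp_id

__all__ = ["read_genotypes", "write_genotypes", "write_table"]

FORMATS = ("tsv", "plink_raw")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be decoded."""


def _strip_comments(path: Path) -> _io.StringIO:
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    if not lines:
        raise GenotypeParseError(f"{path}: file is empty")
    return _io.StringIO("\n".join(lines) + "\n")


def _check_entries(values: np.ndarray, snp_ids, subject_ids, path, integral_only: bool) -> None:
    bad = np.isfinite(values) & ((values < 0) | (values > 2))
    if integral_only:
        bad |= np.isfinite(values) & (values != np.round(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: invalid genotype {values[i, j]!r} for subject "
            f"{subject_ids[i]!r} at SNP {snp_ids[j]!r}"
        )


def read_genotypes(path, format: str = "tsv", integral_only: bool = False) -> GenotypeDataset:
    """Read a genotype dataset from ``tsv`` or ``plink_raw``.

    ``integral_only=True`` additionally rejects non-integer dosages,
    which is appropriate for called (non-reconstructed) genotypes.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    buf = _strip_comments(path)
    try:
        df = pd.read_csv(buf, sep="\t" if format == "tsv" else r"\s+", engine="python")
    except Exception as exc:
        raise GenotypeParseError(f"{path}: cannot parse ({exc})") from exc
    if df.shape[0] == 0:
        raise GenotypeParseError(f"{path}: no data rows")

    if format == "tsv":
        if df.shape[1] < 3:
            raise GenotypeParseError(f"{path}: expected subject, phenotype and SNP columns")
        subject_ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        pheno_raw = df.iloc[:, 1]
        snp_frame = df.iloc[:, 2:]
        if pheno_raw.isna().any():
            raise GenotypeParseError(f"{path}: phenotype column contains missing values")
        phenotype = pheno_raw.astype(int).to_numpy()
        if not np.isin(phenotype, (0, 1)).all():
            raise GenotypeParseError(f"{path}: phenotype must be coded 0/1")
    else:
        required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != required:
            raise GenotypeParseError(
                f"{path}: PLINK .raw header must start with {' '.join(required)}"
            )
        subject_ids = df["IID"].astype(str).to_numpy(dtype=object)
        pheno_raw = df["PHENOTYPE"]
        if pheno_raw.isna().any():
            raise GenotypeParseError(f"{path}: phenotype column contains missing values")
        phen = pheno_raw.astype(int).to_numpy()
        if not np.isin(phen, (1, 2)).all():
            raise GenotypeParseError(f"{path}: PLINK phenotype must be coded 1/2")
        phenotype = (phen == 2).astype(int)
        snp_frame = df.iloc[:, 6:]
        # strip the _A allele suffix PLINK appends to counted-allele columns
        snp_frame = snp_frame.rename(columns=lambda c: c.rsplit("_", 1)[0] if c.endswith("_A") else c)

    snp_ids = np.asarray(snp_frame.columns, dtype=object)
    try:
        values = snp_frame.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except Exception as exc:
        raise GenotypeParseError(f"{path}: non-numeric genotype token ({exc})") from exc
    _check_entries(values, snp_ids, subject_ids, path, integral_only)
    roles = np.asarray([role_from_snp_id(s) for s in snp_ids], dtype=object)
    return GenotypeDataset(
        genotypes=values,
        phenotype=phenotype,
        snp_role=roles,
        snp_ids=snp_ids,
        subject_ids=subject_ids,
    )


def _provenance_header(meta: dict | None) -> str:
    import robustps

    fields = {"robustps_version": robustps.__version__}
    if meta:
        fields.update(meta)
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def write_genotypes(dataset: GenotypeDataset, path, format: str = "tsv", meta: dict | None = None) -> Path:
    """Write a dataset to disk; inverse of :func:`read_genotypes`.

    Output column order is deterministic (the dataset's column order).
    A ``#``-prefixed provenance header records the package version and
    any supplied metadata.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}")
    G = dataset.genotypes

    def fmt(x):
        if not np.isfinite(x):
            return "NA"
        if x == int(x):
            return str(int(x))
        return format_float(x)

    def format_float(x):
        return np.format_float_positional(x, precision=6, trim="0")

    with path.open("w") as fh:
        fh.write(_provenance_header(meta))
        if format == "tsv":
            fh.write("subject_id\tphenotype\t" + "\t".join(map(str, dataset.snp_ids)) + "\n")
            for i in range(dataset.n_subjects):
                row = [str(dataset.subject_ids[i]), str(int(dataset.phenotype[i]))]
                row += [fmt(x) for x in G[i]]
                fh.write("\t".join(row) + "\n")
        else:
            cols = [f"{s}_A" for s in dataset.snp_ids]
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(cols) + "\n")
            for i in range(dataset.n_subjects):
                sid = str(dataset.subject_ids[i])
                row = [sid, sid, "0", "0", "0", str(int(dataset.phenotype[i]) + 1)]
                row += [fmt(x) for x in G[i]]
                fh.write(" ".join(row) + "\n")
    return path


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a DataFrame as TSV with a provenance comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_header(meta))
        df.to_csv(fh, sep="\t", index=False)
    return path
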