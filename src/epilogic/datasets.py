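"""Case-control genotype data model and text-format I/O.

Genotypes are stored as minor-allele dosages (0, 1, 2) in an int8 matrix of
shape (subjects, SNPs); missing calls use the sentinel :data:`MISSING` (-1)
so they can never silently enter arithmetic.  The minor allele of each SNP is
defined by its frequency among *controls* (controls approximate the source
population, which keeps odds-ratio directions stable across case mixes);
frequency ties break to the lexicographically smaller allele.

Two plain-text formats are supported: whitespace-delimited PLINK PED/MAP and
a tab-separated table with one row per subject
(``subject_id<TAB>phenotype<TAB>BMI<TAB>rs...``, dosage cells 0/1/2/NA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT")


class GenotypeFormatError(ValueError):
    """Malformed genotype file; message names the offending line/cell."""


@dataclass
class SNPMeta:
    """Metadata for one biallelic SNP.

    ``alleles`` is the ordered pair (major, minor); dosage counts copies of
    the minor allele.  ``position`` is carried from MAP files but unused.
    """

    snp_id: str
    chrom: str = "0"
    alleles: tuple[str, str] = ("A", "B")
    gene_label: str | None = None
    position: int = 0

    def __post_init__(self) -> None:
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.snp_id}: major and minor allele must differ")

    @property
    def label(self) -> str:
        return f"{self.gene_label}-{self.snp_id}" if self.gene_label else self.snp_id


@dataclass
class QCThresholds:
    """QC gates: call rate > ``min_call_rate`` and control HWE p > ``min_hwe_p``."""

    min_call_rate: float = 0.99
    min_hwe_p: float = 1e-6
    hwe_controls_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        if not 0 <= self.min_hwe_p < 1:
            raise ValueError("min_hwe_p must be in [0, 1)")


@dataclass
class CohortDataset:
    """Subjects x SNPs dosage matrix with phenotype and optional covariates.

    phenotype: 1 = case, 0 = control.  genotypes: int8, values in
    {0, 1, 2, MISSING}.  covariates: DataFrame indexed like ``subjects``
    (may be empty).
    """

    subjects: list[str]
    phenotype: np.ndarray
    genotypes: np.ndarray
    snps: list[SNPMeta]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, p = self.genotypes.shape
        if len(self.subjects) != n:
            raise ValueError("subject list does not match genotype rows")
        if len(self.snps) != p:
            raise ValueError("SNP list does not match genotype columns")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match subjects")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.genotypes[i, j]} at subject "
                f"{self.subjects[i]!r}, SNP {self.snps[j].snp_id!r}"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in dataset")
        if len(self.covariates) and len(self.covariates) != n:
            raise ValueError("covariate rows do not match subjects")

    # -- accessors ---------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def is_case(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def subset_subjects(self, mask: np.ndarray) -> "CohortDataset":
        mask = np.asarray(mask, dtype=bool)
        cov = self.covariates.iloc[mask].reset_index(drop=True) if len(self.covariates) else pd.DataFrame()
        return CohortDataset(
            subjects=[s for s, m in zip(self.subjects, mask) if m],
            phenotype=self.phenotype[mask],
            genotypes=self.genotypes[mask],
            snps=list(self.snps),
            covariates=cov,
        )

    def subset_snps(self, snp_ids: list[str]) -> "CohortDataset":
        idx = [self.snp_index(s) for s in snp_ids]
        return replace(self, genotypes=self.genotypes[:, idx], snps=[self.snps[i] for i in idx])


def complete_case_filter(
    data: CohortDataset, snp_subset: list[str] | None = None
) -> tuple[CohortDataset, int]:
    """Drop subjects with any missing genotype among ``snp_subset``.

    Returns the filtered dataset (subject order preserved) and the number of
    subjects excluded.  Raises if nobody survives.
    """
    if snp_subset is None:
        cols = np.arange(data.n_snps)
    else:
        cols = np.array([data.snp_index(s) for s in snp_subset], dtype=int)
    keep = ~(data.genotypes[:, cols] == MISSING).any(axis=1)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("complete-case filter removed every subject")
    if n_excluded == 0:
        return data, 0
    return data.subset_subjects(keep), n_excluded


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def _control_minor_allele(pairs: np.ndarray, is_control: np.ndarray) -> tuple[str, str]:
    """(major, minor) from control allele frequencies; tie -> lexicographically
    smaller allele is minor.  ``pairs`` is an (n, 2) array of allele chars
    ('0' = missing)."""
    seen = sorted(set(pairs.ravel()) - {"0"})
    if len(seen) > 2:
        raise GenotypeFormatError(f"more than two alleles observed: {seen}")
    if len(seen) == 0:
        return ("N", "X")  # fully missing column; arbitrary placeholder
    if len(seen) == 1:
        a = seen[0]
        other = "N" if a != "N" else "X"
        return (a, other)  # monomorphic: observed allele is major
    a, b = seen  # a < b lexicographically
    ctrl = pairs[is_control].ravel()
    ctrl = ctrl[ctrl != "0"]
    if ctrl.size == 0:
        ctrl = pairs.ravel()
        ctrl = ctrl[ctrl != "0"]
    freq_a = float((ctrl == a).sum()) / ctrl.size
    if freq_a < 0.5 or freq_a == 0.5:  # tie -> smaller allele (a) is minor
        return (b, a)
    return (a, b)


def read_plink_text(ped_path, map_path) -> CohortDataset:
    """Read whitespace-delimited PLINK text PED/MAP into a CohortDataset.

    Phenotype uses the PLINK convention (1 = control, 2 = case; 0 or -9 =
    missing, and such subjects are dropped with a warning).  '0 0' allele
    pairs become missing dosages.
    """
    snps: list[SNPMeta] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeFormatError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts
            try:
                position = int(pos)
            except ValueError:
                raise GenotypeFormatError(
                    f"{map_path}: line {lineno}: bad position {pos!r}"
                ) from None
            snps.append(SNPMeta(snp_id=snp_id, chrom=chrom, position=position))
    n_snps = len(snps)

    subjects: list[str] = []
    phenos: list[int] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} columns "
                    f"for {n_snps} MAP SNPs, got {len(parts)}"
                )
            fid, iid, _pat, _mat, _sex, pheno = parts[:6]
            alleles = parts[6:]
            for a in alleles:
                if a not in _VALID_ALLELES and a != "0":
                    raise GenotypeFormatError(
                        f"{ped_path}: line {lineno}: invalid allele code {a!r}"
                    )
            if pheno in ("0", "-9"):
                warnings.warn(
                    f"{ped_path}: line {lineno}: subject {iid} has missing "
                    "phenotype; dropped",
                    stacklevel=2,
                )
                continue
            if pheno not in ("1", "2"):
                raise GenotypeFormatError(
                    f"{ped_path}: line {lineno}: invalid phenotype {pheno!r}"
                )
            subjects.append(iid)
            phenos.append(1 if pheno == "2" else 0)
            allele_rows.append(alleles)

    n = len(subjects)
    phenotype = np.array(phenos, dtype=np.int8)
    genotypes = np.full((n, n_snps), MISSING, dtype=np.int8)
    alle = np.array(allele_rows, dtype="U1").reshape(n, n_snps, 2) if n else np.empty((0, n_snps, 2), dtype="U1")
    is_control = phenotype == 0
    for j, snp in enumerate(snps):
        pairs = alle[:, j, :]
        major, minor = _control_minor_allele(pairs, is_control)
        snp.alleles = (major, minor)
        called = (pairs != "0").all(axis=1)
        genotypes[called, j] = (pairs[called] == minor).sum(axis=1)
    return CohortDataset(subjects=subjects, phenotype=phenotype, genotypes=genotypes, snps=snps)


def write_plink_text(data: CohortDataset, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for s in data.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, subj in enumerate(data.subjects):
            pheno = "2" if data.phenotype[i] == 1 else "1"
            fields = [subj, subj, "0", "0", "0", pheno]
            for j, snp in enumerate(data.snps):
                major, minor = snp.alleles
                d = int(data.genotypes[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [major, major]
                elif d == 1:
                    fields += [major, minor]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_genotype_table(tsv_path, snp_columns: list[str] | None = None) -> CohortDataset:
    """Read the TSV dialect: subject_id, phenotype, covariates, then dosage
    columns (0/1/2/NA).

    When ``snp_columns`` is None, columns whose name starts with ``rs`` are
    taken as SNPs and every other column after ``phenotype`` as a covariate.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, comment="#")
    if "subject_id" not in df.columns or "phenotype" not in df.columns:
        raise GenotypeFormatError(f"{tsv_path}: header must contain subject_id and phenotype")
    rest = [c for c in df.columns if c not in ("subject_id", "phenotype")]
    if snp_columns is None:
        snp_columns = [c for c in rest if c.startswith("rs")]
    cov_columns = [c for c in rest if c not in snp_columns]

    subjects = df["subject_id"].tolist()
    try:
        phenotype = df["phenotype"].astype(int).to_numpy(dtype=np.int8)
    except ValueError:
        raise GenotypeFormatError(f"{tsv_path}: non-integer phenotype value") from None
    if not np.isin(phenotype, (0, 1)).all():
        raise GenotypeFormatError(f"{tsv_path}: phenotype values must be 0 or 1")

    n = len(df)
    genotypes = np.full((n, len(snp_columns)), MISSING, dtype=np.int8)
    for j, col in enumerate(snp_columns):
        vals = df[col].fillna("NA")
        for i, v in enumerate(vals):
            if v == "NA":
                continue
            if v not in ("0", "1", "2"):
                raise GenotypeFormatError(
                    f"{tsv_path}: row {i + 2}, column {col!r}: invalid dosage {v!r}"
                )
            genotypes[i, j] = int(v)
    covariates = pd.DataFrame()
    if cov_columns:
        covariates = df[cov_columns].apply(pd.to_numeric, errors="coerce").reset_index(drop=True)
    snps = [SNPMeta(snp_id=c) for c in snp_columns]
    return CohortDataset(subjects=subjects, phenotype=phenotype, genotypes=genotypes,
                         snps=snps, covariates=covariates)


def write_genotype_table(data: CohortDataset, tsv_path, comments: list[str] | None = None) -> None:
    """Write the TSV dialect (UTF-8, tab-separated, NA for missing)."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        cov_cols = list(data.covariates.columns)
        header = ["subject_id", "phenotype"] + cov_cols + data.snp_ids
        fh.write("\t".join(header) + "\n")
        for i, subj in enumerate(data.subjects):
            row = [subj, str(int(data.phenotype[i]))]
            for c in cov_cols:
                v = data.covariates[c].iloc[i]
                row.append("NA" if pd.isna(v) else f"{v:g}")
            for j in range(data.n_snps):
                d = int(data.genotypes[i, j])
                row.append("NA" if d == MISSING else str(d))
            fh.write("\t".join(row) + "\n")
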