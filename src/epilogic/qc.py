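"""Per-SNP quality control and single-locus association tests.

QC gates follow common genotyping practice for candidate-SNP panels: a SNP
passes when its call rate exceeds the threshold and its genotype counts in
controls are consistent with Hardy-Weinberg equilibrium (1-df chi-square
goodness of fit, loose p > 1e-6 screen).  Association tests are the allelic
2x2 chi-square, the Cochran-Armitage trend test with scores (0, 1, 2), and a
covariate-adjusted logistic model (per-allele OR with Wald inference).  All
tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MISSING, CohortDataset, QCThresholds


@dataclass
class SNPQCRecord:
    snp_id: str
    call_rate: float
    maf_controls: float
    hwe_chi2_controls: float
    hwe_p_controls: float
    passed: bool


@dataclass
class SingleLocusResult:
    """Per-allele odds ratio with CI and p-values for one SNP."""

    snp_id: str
    per_allele_or: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    p_allelic: float = np.nan
    p_trend: float = np.nan
    p_genotypic: float = np.nan
    adjusted: bool = False
    converged: bool = True
    zero_cell_corrected: bool = False
    n_used: int = 0


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Expected counts come from the sample allele frequency.  A monomorphic
    sample carries no information against HWE, so it returns (0.0, 1.0) by
    convention.  Symmetric in (n_AA, n_BB).
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("no genotype calls")
    q = (2 * n_BB + n_AB) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    observed = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def call_rate(snp_column: np.ndarray) -> float:
    """Fraction of non-missing calls in one SNP column."""
    col = np.asarray(snp_column)
    if col.size == 0:
        raise ValueError("empty genotype column")
    return float((col != MISSING).sum() / col.size)


def duplicate_concordance(pairs: list[tuple[str, str]], data: CohortDataset) -> float:
    """Genotype concordance across duplicate subject pairs, averaged over SNPs.

    For each SNP, the fraction of pairs with identical calls among pairs where
    both calls are non-missing; SNPs with no comparable pair are skipped.
    """
    subj_idx = {s: i for i, s in enumerate(data.subjects)}
    try:
        ia = np.array([subj_idx[a] for a, _ in pairs], dtype=int)
        ib = np.array([subj_idx[b] for _, b in pairs], dtype=int)
    except KeyError as e:
        raise KeyError(f"unknown subject in duplicate pair: {e}") from None
    ga, gb = data.genotypes[ia], data.genotypes[ib]
    both = (ga != MISSING) & (gb != MISSING)
    per_snp = []
    for j in range(data.n_snps):
        m = both[:, j]
        if m.any():
            per_snp.append(float((ga[m, j] == gb[m, j]).mean()))
    if not per_snp:
        raise ValueError("no comparable genotype calls among duplicate pairs")
    return float(np.mean(per_snp))


def qc_report(data: CohortDataset, thresholds: QCThresholds | None = None) -> list[SNPQCRecord]:
    """Apply call-rate and control-HWE gates to every SNP."""
    thr = thresholds or QCThresholds()
    hwe_rows = (data.phenotype == 0) if thr.hwe_controls_only else np.ones(data.n_subjects, bool)
    records = []
    for j, snp in enumerate(data.snps):
        col = data.genotypes[:, j]
        cr = call_rate(col)
        ctrl = col[hwe_rows & (col != MISSING)]
        counts = [int((ctrl == d).sum()) for d in (0, 1, 2)]
        if ctrl.size:
            maf = float((2 * counts[2] + counts[1]) / (2 * ctrl.size))
            chi2, p = hwe_test(*counts)
        else:
            maf, chi2, p = np.nan, np.nan, np.nan
        passed = bool(cr > thr.min_call_rate and (np.isnan(p) or p > thr.min_hwe_p))
        records.append(SNPQCRecord(snp.snp_id, cr, maf, chi2, p, passed))
    return records


def _allele_counts(data: CohortDataset, snp_id: str) -> tuple[np.ndarray, int]:
    """2x2 allele-count table [[case_minor, case_major], [ctrl_minor, ctrl_major]]."""
    col = data.dosage(snp_id)
    ok = col != MISSING
    y = data.phenotype[ok]
    d = col[ok].astype(int)
    table = np.empty((2, 2), dtype=float)
    for row, cls in ((0, 1), (1, 0)):
        dd = d[y == cls]
        table[row, 0] = dd.sum()
        table[row, 1] = 2 * dd.size - dd.sum()
    return table, int(ok.sum())


def allelic_test(data: CohortDataset, snp_id: str) -> SingleLocusResult:
    """Allelic 2x2 test: cross-product OR, Woolf 95% CI, Pearson chi-square p.

    Zero cells get the Haldane-Anscombe 0.5 correction (flagged in the
    result).  Two alleles are counted per subject.
    """
    table, n_used = _allele_counts(data, snp_id)
    if table.sum(axis=0).min() == 0:
        raise ValueError(f"{snp_id}: monomorphic in pooled sample")
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return SingleLocusResult(
        snp_id=snp_id, per_allele_or=float(or_), ci95=(float(lo), float(hi)),
        p_allelic=float(p), zero_cell_corrected=corrected, n_used=n_used,
    )


def trend_chi2(case_counts, control_counts, scores=(0.0, 1.0, 2.0)) -> float:
    """Cochran-Armitage trend statistic on a 2xK genotype table."""
    r = np.asarray(case_counts, dtype=float)
    n = r + np.asarray(control_counts, dtype=float)
    s = np.asarray(scores, dtype=float)
    N, R = n.sum(), r.sum()
    if R == 0 or R == N:
        raise ValueError("need both cases and controls")
    num = N * (s * r).sum() - R * (s * n).sum()
    den = R * (N - R) * (N * (s**2 * n).sum() - ((s * n).sum()) ** 2)
    if den == 0:
        raise ValueError("degenerate table: no score variation")
    return float(N * num**2 / den)


def trend_test(data: CohortDataset, snp_id: str) -> float:
    """Two-sided p of the Cochran-Armitage trend test with scores (0, 1, 2)."""
    col = data.dosage(snp_id)
    ok = col != MISSING
    y, d = data.phenotype[ok], col[ok].astype(int)
    cases = [int(((d == g) & (y == 1)).sum()) for g in (0, 1, 2)]
    ctrls = [int(((d == g) & (y == 0)).sum()) for g in (0, 1, 2)]
    totals = [c + t for c, t in zip(cases, ctrls)]
    if sum(1 for t in totals if t > 0) < 2:
        raise ValueError(f"{snp_id}: monomorphic")
    chi2 = trend_chi2(cases, ctrls)
    return float(stats.chi2.sf(chi2, df=1))


def genotypic_test(data: CohortDataset, snp_id: str) -> float:
    """2-df genotypic chi-square on the 2x3 genotype table."""
    col = data.dosage(snp_id)
    ok = col != MISSING
    y, d = data.phenotype[ok], col[ok].astype(int)
    table = np.array([[int(((d == g) & (y == cls)).sum()) for g in (0, 1, 2)] for cls in (1, 0)])
    keep = table.sum(axis=0) > 0
    _, p, _, _ = stats.chi2_contingency(table[:, keep], correction=False)
    return float(p)


def adjusted_single_locus(
    data: CohortDataset, snp_id: str, covariate_names: list[str] | None = None
) -> SingleLocusResult:
    """Per-allele OR from logistic regression, optionally covariate-adjusted.

    Fits logit P(case) = b0 + b.dosage + sum(c_j cov_j) on complete cases;
    per-allele OR = exp(b) with Wald CI and p.  With an empty covariate list
    this is the plain additive (trend-model) logistic fit.
    """
    import statsmodels.api as sm

    covariate_names = covariate_names or []
    col = data.dosage(snp_id)
    ok = col != MISSING
    X = pd.DataFrame({"dosage": col[ok].astype(float)})
    for c in covariate_names:
        if c not in data.covariates.columns:
            raise KeyError(f"covariate {c!r} not in dataset")
        X[c] = data.covariates[c].to_numpy()[ok]
    keep = ~X.isna().any(axis=1).to_numpy()
    X, y = X.iloc[keep], data.phenotype[ok][keep]
    design = sm.add_constant(X, has_constant="add")
    converged = True
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        return SingleLocusResult(snp_id=snp_id, adjusted=bool(covariate_names),
                                 converged=False, n_used=int(keep.sum()))
    b = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    p = float(fit.pvalues["dosage"])
    return SingleLocusResult(
        snp_id=snp_id,
        per_allele_or=float(np.exp(b)),
        ci95=(float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
        p_trend=p,
        adjusted=bool(covariate_names),
        converged=converged,
        n_used=int(keep.sum()),
    )


def single_locus_table(
    data: CohortDataset, covariate_names: list[str] | None = None
) -> pd.DataFrame:
    """Allelic, trend, genotypic and (optionally adjusted) logistic results per SNP."""
    rows = []
    for snp in data.snps:
        sid = snp.snp_id
        try:
            al = allelic_test(data, sid)
            p_tr = trend_test(data, sid)
            p_gen = genotypic_test(data, sid)
            adj = adjusted_single_locus(data, sid, covariate_names)
            rows.append({
                "snp_id": sid, "allelic_or": al.per_allele_or,
                "ci_lo": al.ci95[0], "ci_hi": al.ci95[1],
                "p_allelic": al.p_allelic, "p_trend": p_tr, "p_genotypic": p_gen,
                "adjusted_or": adj.per_allele_or, "adjusted_p": adj.p_trend,
                "n_used": al.n_used,
            })
        except ValueError:
            rows.append({"snp_id": sid, "allelic_or": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "p_allelic": np.nan, "p_trend": np.nan,
                         "p_genotypic": np.nan, "adjusted_or": np.nan,
                         "adjusted_p": np.nan, "n_used": 0})
    return pd.DataFrame(rows)


def extreme_subject_filter(
    data: CohortDataset,
    age_bounds: tuple[float, float] = (35.0, 80.0),
    bmi_bounds: tuple[float, float] = (18.5, 40.0),
) -> CohortDataset:
    """Sensitivity filter dropping subjects with extreme age or BMI.

    Bounds are inclusive survival limits: subjects outside [lo, hi] on any
    available column are removed; missing covariate values are kept.
    """
    keep = np.ones(data.n_subjects, dtype=bool)
    for col, (lo, hi) in (("age", age_bounds), ("BMI", bmi_bounds)):
        if col in data.covariates.columns:
            v = data.covariates[col].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                keep &= ~((v < lo) | (v > hi))
    return data.subset_subjects(keep)
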