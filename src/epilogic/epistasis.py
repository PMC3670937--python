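"""Exhaustive pairwise SNP x SNP interaction scan.

For each unordered SNP pair the model

    logit P(case) = b0 + b1.dosageA + b2.dosageB + b3.(dosageA * dosageB)

is fitted by maximum likelihood on pairwise-complete subjects, using
additive (0/1/2) minor-allele dosage coding for both loci.  The interaction
odds ratio is exp(b3) with a Wald 95% CI and a two-sided Wald p; the
Benjamini-Hochberg step-up procedure converts the p-values of all C(k, 2)
pairs into FDR q-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MISSING, CohortDataset

_BETA_CAP = 30.0  # |coefficient| bound; beyond this the fit is separated


@dataclass
class LogisticFit:
    """IRLS maximum-likelihood logistic fit."""

    coef: np.ndarray
    se: np.ndarray
    deviance: float
    converged: bool
    n_used: int
    n_iter: int = 0
    message: str = ""


def _bernoulli_deviance(eta: np.ndarray, y: np.ndarray) -> float:
    # -2 log L, computed stably via logaddexp: log(1+e^eta) - y*eta
    return float(2.0 * (np.logaddexp(0.0, eta) - y * eta).sum())


def fit_logistic_irls(
    design: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_dev: float = 1e-10,
) -> LogisticFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    ``design`` must already include the intercept column.  Convergence is
    declared when the maximum absolute score drops below ``tol_score`` or the
    relative deviance change falls below ``tol_dev``.  Standard errors come
    from the inverse observed information at the solution.  Separated or
    singular fits return ``converged=False`` with a diagnostic message (the
    deviance is still the best value reached, with coefficients capped at
    +/-30 to keep it finite).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n == 0 or y.min() == y.max():
        raise ValueError("need at least one case and one control")
    beta = np.zeros(k)
    # start from the intercept-only MLE when an intercept column is present
    const_cols = np.ptp(X, axis=0) == 0
    if const_cols.any():
        beta[np.argmax(const_cols)] = np.log(y.mean() / (1 - y.mean())) / X[0, np.argmax(const_cols)]
    dev = _bernoulli_deviance(X @ beta, y)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving to guarantee deviance decrease
        new_dev = np.inf
        for half in range(11):
            cand = beta + step * (0.5**half)
            new_dev = _bernoulli_deviance(X @ cand, y)
            if new_dev <= dev + 1e-12:
                break
        beta = np.clip(cand, -_BETA_CAP, _BETA_CAP)
        if np.any(np.abs(cand) >= _BETA_CAP):
            message = "coefficients diverging (separation?)"
            dev = _bernoulli_deviance(X @ beta, y)
            break
        rel = abs(dev - new_dev) / (abs(dev) + 1e-300)
        dev = new_dev
        if rel < tol_dev:
            converged = True
            break
    dev = _bernoulli_deviance(X @ beta, y)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        converged = False
        message = message or "singular information matrix at solution"
    return LogisticFit(coef=beta, se=se, deviance=dev, converged=converged,
                       n_used=n, n_iter=it, message=message)


@dataclass
class PairResult:
    """One SNP pair's interaction estimate (a Table-1-style row)."""

    snp_a: str
    snp_b: str
    or_interaction: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    p: float = np.nan
    fdr_q: float = np.nan
    n_used: int = 0
    converged: bool = True
    message: str = ""


def interaction_test(
    data: CohortDataset,
    snp_a: str,
    snp_b: str,
    covariate_names: list[str] | None = None,
) -> PairResult:
    """Wald test of the dosage-product interaction between two SNPs.

    Subjects missing either genotype are dropped (pairwise complete-case).
    Covariates default to none, matching the unadjusted pair scan.
    """
    da, db = data.dosage(snp_a), data.dosage(snp_b)
    ok = (da != MISSING) & (db != MISSING)
    cov_arrays = []
    for c in covariate_names or []:
        v = data.covariates[c].to_numpy(dtype=float)
        ok &= ~np.isnan(v)
        cov_arrays.append(v)
    a = da[ok].astype(float)
    b = db[ok].astype(float)
    y = data.phenotype[ok].astype(float)
    if a.min() == a.max() or b.min() == b.max():
        return PairResult(snp_a, snp_b, n_used=int(ok.sum()), converged=False,
                          message="constant dosage among complete cases")
    cols = [np.ones_like(a), a, b, a * b] + [v[ok] for v in cov_arrays]
    X = np.column_stack(cols)
    fit = fit_logistic_irls(X, y)
    if not fit.converged:
        return PairResult(snp_a, snp_b, n_used=fit.n_used, converged=False,
                          message=fit.message or "did not converge")
    b3, se3 = fit.coef[3], fit.se[3]
    z = b3 / se3
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PairResult(
        snp_a=snp_a, snp_b=snp_b,
        or_interaction=float(np.exp(b3)),
        ci95=(float(np.exp(b3 - 1.96 * se3)), float(np.exp(b3 + 1.96 * se3))),
        p=p, n_used=fit.n_used,
    )


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    ``m`` overrides the number of tests (useful when only the smallest
    p-values of a larger family are supplied); it defaults to len(p_values).
    q_(i) = min_{j >= i} m p_(j) / j along the sorted order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def scan_all_pairs(
    data: CohortDataset,
    snp_ids: list[str] | None = None,
    stratum: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    globally_complete: bool = False,
) -> list[PairResult]:
    """Interaction test for every unordered SNP pair, with BH FDR over all.

    ``stratum`` restricts the scan to a boolean subject mask (e.g. one tumor
    subtype); ``globally_complete`` first removes subjects missing any of the
    scanned SNPs instead of the default pairwise complete-case handling.
    Non-converging pairs are flagged and excluded from the FDR family.
    """
    snp_ids = snp_ids or data.snp_ids
    if len(snp_ids) < 2:
        raise ValueError("need at least 2 SNPs to scan pairs")
    d = data.subset_subjects(np.asarray(stratum, bool)) if stratum is not None else data
    if globally_complete:
        from .datasets import complete_case_filter

        d, _ = complete_case_filter(d, snp_ids)
    results = [interaction_test(d, a, b, covariate_names)
               for a, b in itertools.combinations(snp_ids, 2)]
    valid = [i for i, r in enumerate(results) if np.isfinite(r.p)]
    if valid:
        q = bh_fdr([results[i].p for i in valid])
        for i, qi in zip(valid, q):
            results[i].fdr_q = float(qi)
    return results


def pairs_to_dataframe(results: list[PairResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"snp_a": r.snp_a, "snp_b": r.snp_b, "OR": r.or_interaction,
         "CI_lo": r.ci95[0], "CI_hi": r.ci95[1], "P": r.p, "FDR_q": r.fdr_q,
         "n": r.n_used, "converged": r.converged}
        for r in results
    ])
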