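"""Firth bias-reduced logistic regression and variant-level association.

Firth's penalty (the Jeffreys prior, half the log determinant of the Fisher
information) keeps coefficient estimates finite under complete or quasi-
complete separation, the regime rare-variant case-control tests live in.
Newton iterations use the modified score

    U*_j = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ij

where h_i are the diagonal entries of the weighted hat matrix, with
step-halving whenever a step would decrease the penalized log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .qc import ld_r2, mac_filter
from .types import CohortBundle


@dataclass
class FirthFit:
    beta: np.ndarray
    se: np.ndarray
    fitted: np.ndarray  # per-sample probabilities
    hat: np.ndarray  # per-sample leverages
    penalized_loglik: float
    converged: bool
    n_iter: int


def penalized_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    """l(beta) + 0.5 * log det X' W X with W = diag(pi (1 - pi))."""
    eta = X @ beta
    pi = expit(eta)
    eps = 1e-12
    ll = float(y @ np.log(pi + eps) + (1 - y) @ np.log(1 - pi + eps))
    W = pi * (1 - pi)
    sign, logdet = np.linalg.slogdet(X.T * W @ X)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
    max_halvings: int = 25,
) -> FirthFit:
    """Maximize the Firth-penalized binomial log-likelihood by Newton steps.

    X must contain an intercept column and be full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    pll = penalized_loglik(y, X, beta)
    converged = False
    it = 0
    pi = np.full(n, 0.5)
    h = np.zeros(n)
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        W = pi * (1 - pi)
        XtWX = X.T * W @ X
        XtWX_inv = np.linalg.inv(XtWX)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * W
        score = X.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        delta = XtWX_inv @ score
        step = 1.0
        for _ in range(max_halvings):
            new_pll = penalized_loglik(y, X, beta + step * delta)
            if new_pll >= pll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        pll = penalized_loglik(y, X, beta)
        if np.max(np.abs(step * delta)) < step_tol:
            converged = True
            break

    pi = expit(X @ beta)
    W = pi * (1 - pi)
    XtWX_inv = np.linalg.inv(X.T * W @ X)
    h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * W
    se = np.sqrt(np.diag(XtWX_inv))
    return FirthFit(
        beta=beta,
        se=se,
        fitted=pi,
        hat=h,
        penalized_loglik=penalized_loglik(y, X, beta),
        converged=converged,
        n_iter=it,
    )


def firth_wald_p(fit: FirthFit, term: int) -> float:
    """Two-sided Wald p-value for one coefficient."""
    from scipy.stats import norm

    z = fit.beta[term] / fit.se[term]
    return float(2.0 * norm.sf(abs(z)))


def firth_plrt_p(y: np.ndarray, X: np.ndarray, term: int) -> float:
    """Penalized likelihood-ratio p-value for one coefficient.

    The reduced model drops the tested column (its own Jeffreys penalty);
    preferable to the Wald test under heavy separation, where Wald standard
    errors are unstable.
    """
    from scipy.stats import chi2

    full = fit_firth(y, X)
    X_red = np.delete(np.asarray(X, dtype=float), term, axis=1)
    reduced = fit_firth(y, X_red)
    lr = 2.0 * (full.penalized_loglik - reduced.penalized_loglik)
    return float(chi2.sf(max(lr, 0.0), 1))


@dataclass
class AssociationResult:
    variant_key: tuple
    gene: str
    beta: float
    se: float
    odds_ratio: float
    p: float
    p_bonferroni: float
    mac_total: int
    mac_case: int
    converged: bool


def variant_association(
    bundle: CohortBundle,
    covariates: pd.DataFrame,
    variant_idx: list,
    min_mac: int = 3,
    min_case_mac: int = 1,
) -> list:
    """Firth association of each variant with case status, adjusting for the
    given covariate columns (everything except sample_id is used).

    Variants failing the MAC filter are skipped.  Samples with missing
    covariates are dropped.  Missing dosages enter the design as 0 (the
    sample is flagged only through the cohort-level missingness logs).
    Bonferroni correction uses the number of variants actually tested.
    """
    cov = covariates.set_index("sample_id").loc[bundle.sample_ids]
    keep = ~cov.isna().any(axis=1).to_numpy()
    cov_mat = cov.to_numpy(dtype=float)[keep]
    y = bundle.phenotype[keep]
    case_mask = bundle.case_mask

    results = []
    for j in variant_idx:
        col = bundle.genotypes[:, j]
        if not mac_filter(col, case_mask, min_mac=min_mac, min_case_mac=min_case_mac):
            continue
        g = np.nan_to_num(col[keep], nan=0.0)
        X = np.column_stack([np.ones(y.size), g, cov_mat])
        fit = fit_firth(y, X)
        p = firth_wald_p(fit, term=1)
        v = bundle.variants[j]
        obs = ~np.isnan(col)
        alt = np.nansum(col)
        mac_total = int(min(alt, 2 * obs.sum() - alt))
        minor_is_alt = 2 * alt <= 2 * obs.sum()
        cc = col[case_mask & obs]
        mac_case = int(cc.sum() if minor_is_alt else 2 * cc.size - cc.sum())
        results.append(
            AssociationResult(
                variant_key=v.key,
                gene=v.gene or "",
                beta=float(fit.beta[1]),
                se=float(fit.se[1]),
                odds_ratio=float(np.exp(fit.beta[1])),
                p=p,
                p_bonferroni=p,  # filled below once m is known
                mac_total=mac_total,
                mac_case=mac_case,
                converged=fit.converged,
            )
        )
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, m * r.p)
    return results


def pairwise_ld(bundle: CohortBundle, variant_idx: list) -> pd.DataFrame:
    """Symmetric r^2 matrix over the given variants (nan for monomorphic)."""
    keys = [
        f"{bundle.variants[j].chrom}:{bundle.variants[j].pos}:"
        f"{bundle.variants[j].ref}>{bundle.variants[j].alt}"
        for j in variant_idx
    ]
    k = len(variant_idx)
    out = np.full((k, k), np.nan)
    for a in range(k):
        out[a, a] = 1.0
        for b in range(a + 1, k):
            r2 = ld_r2(
                bundle.genotypes[:, variant_idx[a]], bundle.genotypes[:, variant_idx[b]]
            )
            out[a, b] = out[b, a] = r2
    return pd.DataFrame(out, index=keys, columns=keys)


def association_table(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        chrom, pos, ref, alt = r.variant_key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": r.gene,
                "mac_total": r.mac_total,
                "mac_case": r.mac_case,
                "beta": r.beta,
                "se": r.se,
                "or": r.odds_ratio,
                "p": r.p,
                "p_bonferroni": r.p_bonferroni,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
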