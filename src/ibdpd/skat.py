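"""Gene-level rare-variant association: SKAT, burden and SKAT-O.

The test statistic for one gene with dosage matrix G (n x m), weights
W = diag(w_j) and null-model residuals r is

    Q_rho = r' G W R_rho W G' r,   R_rho = (1 - rho) I + rho 11',

so rho = 0 is the SKAT variance-component statistic and rho = 1 the squared
weighted burden score.  Under the null Q_rho is a mixture of 1-df
chi-squares whose weights are the eigenvalues of Z_rho' P0 Z_rho, with
P0 = V - V X (X' V X)^{-1} X' V the projection from the logistic null model.
Mixture tails are computed by numerical inversion of the characteristic
function (Imhof's formula) with a moment-matched (Liu-type) fallback, and
SKAT-O combines the rho grid through the analytic minimum-p procedure
(one-dimensional integration over the shared burden component).

Genes with small total minor-allele counts are calibrated by a carriers-
only parametric bootstrap of the binary residuals (the Gaussian mixture
null drifts on such discrete data), and a residual-permutation mode is
provided as an independent validation oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, ncx2, norm

from .types import CohortBundle

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


# ---------------------------------------------------------------------------
# Null model

@dataclass
class NullModel:
    """Logistic phenotype ~ covariates fit used by every gene test."""

    X: np.ndarray  # n x p design (with intercept)
    mu: np.ndarray  # fitted probabilities
    resid: np.ndarray  # y - mu
    v: np.ndarray  # mu (1 - mu)
    xtvx_inv: np.ndarray  # (X' V X)^{-1}
    firth_fallback: bool = False

    def sigma(self, Z: np.ndarray) -> np.ndarray:
        """Z' P0 Z without forming the n x n projection matrix."""
        VZ = Z * self.v[:, None]
        XtVZ = self.X.T @ VZ
        return Z.T @ VZ - XtVZ.T @ self.xtvx_inv @ XtVZ


def fit_null(y: np.ndarray, X: np.ndarray) -> NullModel:
    """Ordinary ML logistic fit; falls back to Firth under separation."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    firth_fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        mu = np.asarray(res.fittedvalues)
        if np.min(mu) < 1e-10 or np.max(mu) > 1 - 1e-10 or not np.all(np.isfinite(mu)):
            raise FloatingPointError("separation")
    except Exception:
        from .firth import fit_firth

        warnings.warn("null model separation; using Firth-penalized covariate fit")
        mu = fit_firth(y, X).fitted
        firth_fallback = True
    v = mu * (1.0 - mu)
    xtvx = X.T * v @ X
    return NullModel(
        X=X,
        mu=mu,
        resid=y - mu,
        v=v,
        xtvx_inv=np.linalg.inv(xtvx),
        firth_fallback=firth_fallback,
    )


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Standard Beta(1,25)-density weights on folded MAF; upweights rarer sites."""
    maf = np.clip(np.asarray(maf, dtype=float), 1e-10, 1 - 1e-10)
    return beta_dist.pdf(maf, a, b)


# ---------------------------------------------------------------------------
# Quadratic-form statistics and mixture-chi-square tails

def q_statistic(G: np.ndarray, weights: np.ndarray, null: NullModel, rho: float) -> float:
    """Q_rho = r' (GW) R_rho (GW)' r for one gene."""
    if G.shape[1] == 0:
        raise ValueError("gene has no variants")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0,1]")
    s = (G * np.asarray(weights)[None, :]).T @ null.resid
    return float((1.0 - rho) * (s @ s) + rho * s.sum() ** 2)


def _liu_params(lambdas: np.ndarray):
    """Moment-matched noncentral chi-square surrogate (modified Liu method)."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    return mu_q, sigma_q, mu_x, sigma_x, df, delta


def _liu_sf(q: float, lambdas: np.ndarray) -> float:
    mu_q, sigma_q, mu_x, sigma_x, df, delta = _liu_params(lambdas)
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(ncx2.sf(x, df, delta))


def _liu_quantile(p_upper: float, lambdas: np.ndarray) -> float:
    """Value q with mixture upper-tail probability p_upper (Liu surrogate)."""
    mu_q, sigma_q, mu_x, sigma_x, df, delta = _liu_params(lambdas)
    x = ncx2.isf(p_upper, df, delta)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


def _imhof_sf(q: float, lambdas: np.ndarray, tol: float = 1e-9) -> float:
    """Upper-tail P(sum lambda_i chi2_1 > q) by CF inversion (Imhof's formula).

    The oscillatory integrand sin(theta(u)) / (u rho(u)) is integrated by
    composite Simpson on [0, U], with U chosen so the integration-by-parts
    bound on the truncated tail, (2/q) / (U rho(U)), falls below ``tol``.
    Node density tracks the oscillation frequency q/2.
    """
    lmax = float(lambdas.max())
    lam = lambdas / lmax
    qn = q / lmax

    def log_rho(u):
        return 0.25 * np.log1p(np.square(lam[:, None] * u)).sum(axis=0)

    q_eff = max(qn, 1e-3)
    cand = np.exp2(np.arange(0, 28, dtype=float))
    bound = (2.0 / q_eff) / (cand * np.exp(log_rho(cand)))
    ok = np.flatnonzero(bound <= tol)
    u_max = float(cand[ok[0]]) if ok.size else float(cand[-1])
    n_periods = q_eff * u_max / (4.0 * np.pi) + lam.size + 2.0
    n = int(min(max(4001, 32 * n_periods), 4_000_001))
    if n % 2 == 0:
        n += 1
    u = np.linspace(1e-10, u_max, n)
    h = u[1] - u[0]
    w_simp = np.ones(n)
    w_simp[1:-1:2], w_simp[2:-1:2] = 4.0, 2.0
    val = 0.0
    block = 1 << 17
    for lo in range(0, n, block):
        ub = u[lo : lo + block]
        theta = 0.5 * np.arctan(lam[:, None] * ub).sum(axis=0) - 0.5 * qn * ub
        val += (np.sin(theta) / (ub * np.exp(log_rho(ub)))) @ w_simp[lo : lo + block]
    return 0.5 + val * h / (3.0 * np.pi)


def pvalue_mixture_chisq(q: float, lambdas) -> float:
    """P(sum_i lambda_i chi2_1,i > q), clipped to (0, 1].

    Numerical CF inversion first; the moment-matched surrogate if inversion
    fails or returns a value outside [0, 1].
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    lambdas = np.asarray(lambdas, dtype=float)
    lambdas = lambdas[lambdas > 1e-12 * max(lambdas.max(initial=0.0), 1.0)]
    if lambdas.size == 0:
        raise ValueError("mixture spectrum is empty or all zero")
    if lambdas.size == 1:  # exact: scaled 1-df chi-square
        return float(max(chi2.sf(q / lambdas[0], 1), 1e-300))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = _imhof_sf(q, lambdas)
        if not (-1e-6 <= p <= 1.0 + 1e-6) or not np.isfinite(p):
            raise FloatingPointError
    except Exception:
        p = _liu_sf(q, lambdas)
    return float(min(1.0, max(p, 1e-300)))


def _spectrum(sigma: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^{1/2} Sigma R_rho^{1/2}, Sigma = Z' P0 Z."""
    m = sigma.shape[0]
    if rho >= 1.0:
        return np.array([max(sigma.sum(), 0.0)])
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + m * rho) - a) / m
    # R^{1/2} = a I + b 11'
    s1 = sigma.sum(axis=1)
    total = sigma.sum()
    M = (
        a * a * sigma
        + a * b * (s1[:, None] + s1[None, :])
        + b * b * total
    )
    lam = np.linalg.eigvalsh(M)
    lam = lam[lam > max(lam.max(initial=0.0), 1.0) * 1e-10]
    return np.sort(lam)[::-1]


# ---------------------------------------------------------------------------
# SKAT-O

@dataclass
class GeneTestResult:
    gene: str
    n_variants: int
    p_skat: float
    p_burden: float
    p_skato: float
    rho_grid: tuple
    p_rho: tuple = ()
    mac: int = 0
    adjusted: bool = False
    p_bonferroni: float = 1.0


def _bootstrap_skato(Z, null, rho_grid, q_obs, n_boot, rng):
    """Small-sample SKAT-O calibration by a carriers-only parametric bootstrap.

    With few minor alleles the exact null of Q is discrete and skewed, and
    the Gaussian chi-square mixture drifts in both bulk and tail.  Here the
    Bernoulli residuals of the carrier samples are redrawn from their fitted
    probabilities (non-carriers contribute nothing to the score), giving the
    joint empirical null of every Q_rho at once.  The null carries large
    atoms at this scale, so ties are broken by the randomized-p convention
    (a seeded uniform jitter on the statistic scale); the exact, super-
    uniform convention would systematically deflate genomic-control
    estimates.  Per-rho p-values and the minimum-p combination are both
    taken against the same jittered null.

    Returns (p_rho, p_skato_emp, tail_p_rho) where p_skato_emp is None when
    the observed statistic falls beyond the bootstrap resolution; tail_p_rho
    are smooth mean/variance/skewness-matched shifted-chi-square tail
    p-values used by the analytic combination in that regime.
    """
    carriers = np.flatnonzero(np.abs(Z).sum(axis=1) > 0)
    Zc = Z[carriers]
    mu_c = null.mu[carriers]
    r_obs_c = null.resid[carriers]
    draws = (rng.random((n_boot, carriers.size)) < mu_c[None, :]) - mu_c[None, :]
    # honour the null-model fit conditionally on the non-carrier phenotypes:
    # the observed residuals satisfy X'r = 0 exactly, and with non-carriers
    # fixed the covariate score of a redraw is X'r_b = Xc'(y_b - y_obs),
    # so the one-step-refit projected score is
    #   s_b = Zc' r_b - A Xc'(y_b - y_obs),  A = Z'VX (X'VX)^{-1},
    # which equals the observed score exactly when y_b reproduces the
    # observed carrier phenotypes (exchangeability preserved, atoms intact).
    X = null.X
    A = ((Z * null.v[:, None]).T @ X) @ null.xtvx_inv  # m x p
    Xc = X[carriers]
    U = (draws - r_obs_c[None, :]) @ Xc
    S = draws @ Zc - U @ A.T  # n_boot x m projected score draws
    s2 = (S**2).sum(axis=1)
    s1 = S.sum(axis=1) ** 2

    n_rho = len(rho_grid)
    qb = np.empty((n_rho, n_boot))
    q_jit = np.empty(n_rho)
    p_rho, p_emp_rho, tail_p_rho = [], [], []
    # randomized tie-breaking: values equal within numerical tolerance get a
    # tiny seeded jitter, making observed and draws exchangeable and
    # continuous, so add-one counts give an exactly uniform null p.  One
    # jitter realization per draw, shared across the rho grid -- the grid
    # statistics are functions of the same configuration, and independent
    # per-rho randomizations would bias the minimum over the grid.
    eps_draws = rng.random(n_boot)
    eps_obs = rng.random()
    for k, (rho, q) in enumerate(zip(rho_grid, q_obs)):
        qb[k] = (1.0 - rho) * s2 + rho * s1
        m1 = qb[k].mean()
        m2c = qb[k].var()
        m3c = ((qb[k] - m1) ** 3).mean()
        amp = 1e-9 * max(abs(q), np.abs(qb[k]).max(), 1.0)
        qb[k] += eps_draws * amp
        q_jit[k] = q + eps_obs * amp
        n_above = int((qb[k] > q_jit[k]).sum())
        p_emp = (1 + n_above) / (n_boot + 1)
        if m3c > 0 and m2c > 0:
            df = 8.0 * m2c**3 / m3c**2
            a = np.sqrt(m2c / (2.0 * df))
            tail = float(max(chi2.sf((q - (m1 - a * df)) / a, df), 1e-300))
        else:
            tail = p_emp
        p_emp_rho.append(p_emp)
        tail_p_rho.append(tail)
        p_rho.append(p_emp if p_emp > 0.01 else tail)

    # joint minimum-p combination against the same jittered bootstrap null;
    # lattice ties of the min-p statistic get the randomized weight
    order = np.argsort(qb, axis=1)
    ranks = np.empty_like(order)
    ranks[np.arange(n_rho)[:, None], order] = np.arange(n_boot)[None, :]
    p_boot = (n_boot - ranks) / (n_boot + 1)  # strict: larger Q -> smaller p
    minp_boot = p_boot.min(axis=0)
    minp_obs = min(p_emp_rho)
    eps = 0.1 / (n_boot + 1)
    n_below = int((minp_boot < minp_obs - eps).sum())
    n_tie = int((np.abs(minp_boot - minp_obs) <= eps).sum())
    p_skato_emp = (n_below + rng.random() * (1 + n_tie)) / (n_boot + 1)
    if p_skato_emp <= 0.01:
        p_skato_emp = None  # beyond bootstrap resolution; analytic tail
    return p_rho, p_skato_emp, tail_p_rho


def skato_test(
    G: np.ndarray,
    weights: np.ndarray,
    null: NullModel,
    rho_grid=DEFAULT_RHO_GRID,
    small_sample_mac: int = 40,
    n_boot: int = 8000,
    seed: int = 0,
    gene: str = "",
) -> GeneTestResult:
    """SKAT-O for one gene: per-rho mixture p-values combined by the
    analytic minimum-p procedure.

    Missing dosages are imputed to the variant mean.  When the gene's total
    minor-allele count is below ``small_sample_mac`` the per-rho p-values
    are calibrated by the carriers-only parametric bootstrap (``n_boot``
    draws, seeded); the rho grid is still combined analytically.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if m == 0:
        raise ValueError("gene has no variants")
    if np.isnan(G).any():
        G = G.copy()
        for j in range(m):
            col = G[:, j]
            col[np.isnan(col)] = np.nanmean(col) if not np.all(np.isnan(col)) else 0.0
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    mac = int(round(min(G.sum(), 2 * n * m - G.sum())))
    adjust = mac < small_sample_mac

    Z = G * weights[None, :]
    sigma = null.sigma(Z)
    if sigma.max(initial=0.0) <= 1e-300:  # no genotype variance left
        return GeneTestResult(
            gene=gene, n_variants=m, p_skat=1.0, p_burden=1.0, p_skato=1.0,
            rho_grid=tuple(rho_grid), p_rho=(1.0,) * len(tuple(rho_grid)),
            mac=mac, adjusted=adjust,
        )
    rho_grid = tuple(rho_grid)
    q_rho = [q_statistic(G, weights, null, rho) for rho in rho_grid]
    spectra = [_spectrum(sigma, rho) for rho in rho_grid]
    p_skato_emp = None
    if adjust:
        rng = np.random.default_rng(seed)
        p_rho, p_skato_emp, _tails = _bootstrap_skato(
            Z, null, rho_grid, q_rho, n_boot, rng
        )
    else:
        p_rho = [
            1.0 if lam.size == 0 else pvalue_mixture_chisq(max(q, 0.0), lam)
            for q, lam in zip(q_rho, spectra)
        ]

    p_skat = p_rho[rho_grid.index(0.0)] if 0.0 in rho_grid else np.nan
    p_burden = p_rho[rho_grid.index(1.0)] if 1.0 in rho_grid else np.nan
    t_min = float(min(p_rho))

    if m == 1 or len(rho_grid) == 1:
        p_skato = t_min
    elif p_skato_emp is not None:
        # jointly bootstrap-calibrated combination (bulk of the distribution)
        p_skato = float(np.clip(p_skato_emp, t_min, min(1.0, t_min * len(rho_grid))))
    else:
        p_skato = _optimal_p(t_min, sigma, rho_grid, spectra)
        # theoretical bounds of the minimum-p combination
        p_skato = float(np.clip(p_skato, t_min, min(1.0, t_min * len(rho_grid))))

    return GeneTestResult(
        gene=gene,
        n_variants=m,
        p_skat=float(p_skat),
        p_burden=float(p_burden),
        p_skato=float(p_skato),
        rho_grid=rho_grid,
        p_rho=tuple(p_rho),
        mac=mac,
        adjusted=adjust,
    )


def _mixture_quantile(p_upper: float, lam: np.ndarray) -> float:
    """Upper-tail quantile of a central chi-square mixture: one batched CF
    inversion on a geometric q-grid around the moment-matched estimate,
    inverted by monotone interpolation."""
    if lam.size == 1:
        return float(lam[0] * chi2.isf(p_upper, 1))
    guess = max(_liu_quantile(p_upper, lam), 1e-8)
    sf_tol = min(1e-4, max(1e-8, 0.01 * p_upper))
    for span in (3.0, 30.0):
        qs = guess * np.geomspace(1.0 / span, span, 20)
        sf = _noncentral_imhof_sf_batch(
            qs, np.zeros_like(qs), lam, np.zeros_like(lam), tol=sf_tol
        )
        sf = np.clip(sf, 1e-300, 1.0)
        dec = np.minimum.accumulate(sf)  # enforce monotone decrease
        if dec[-1] < p_upper < dec[0]:
            return float(
                np.exp(np.interp(-np.log(p_upper), -np.log(dec), np.log(qs)))
            )
    return guess  # moment-matched fallback for extreme tails


def _noncentral_imhof_sf_batch(
    t: np.ndarray, x: np.ndarray, lam: np.ndarray, d: np.ndarray, tol: float = 1e-5
) -> np.ndarray:
    """P(sum_k lam_k chi2_1(d_k x_j) > t_j) for a batch of thresholds.

    CF inversion with the noncentrality terms entering the phase and modulus
    separably in x, so the u-grid quantities are shared across the batch.
    """
    lmax = float(lam.max())
    lamn = lam / lmax
    tn = t / lmax
    pos = tn > 0
    out = np.ones_like(tn)
    if not pos.any():
        return out
    q_lo = max(float(tn[pos].min()), 1e-3)
    q_hi = float(tn[pos].max())

    def log_rho0(u):
        return 0.25 * np.log1p(np.square(lamn[:, None] * u)).sum(axis=0)

    u_max = 1.0
    while (2.0 / q_lo) / (u_max * np.exp(log_rho0(np.array([u_max]))[0])) > tol:
        u_max *= 2.0
        if u_max > 1e7:
            break
    n = int(min(max(3001, 12 * (q_hi * u_max / (4.0 * np.pi) + lamn.size + 2)), 2_000_001))
    if n % 2 == 0:
        n += 1
    u = np.linspace(1e-10, u_max, n)
    h = u[1] - u[0]
    w_simp = np.ones(n)
    w_simp[1:-1:2], w_simp[2:-1:2] = 4.0, 2.0
    w_simp *= h / 3.0

    acc = np.zeros(int(pos.sum()))
    tn_p = tn[pos]
    x_p = x[pos]
    block = 1 << 14
    for lo_i in range(0, n, block):
        ub = u[lo_i : lo_i + block]
        lu = lamn[:, None] * ub
        lu2 = np.square(lu)
        frac = lu / (1.0 + lu2)
        a_u = np.arctan(lu).sum(axis=0)
        l_u = np.log1p(lu2).sum(axis=0)
        g1 = (d[:, None] * frac).sum(axis=0)
        g2 = (d[:, None] * lu * frac).sum(axis=0)
        theta = (
            0.5 * (a_u[None, :] + x_p[:, None] * g1[None, :])
            - 0.5 * tn_p[:, None] * ub[None, :]
        )
        log_mod = 0.25 * l_u[None, :] + 0.5 * x_p[:, None] * g2[None, :]
        vals = np.sin(theta) / (ub[None, :] * np.exp(log_mod))
        acc += vals @ w_simp[lo_i : lo_i + block]
    out[pos] = np.clip(0.5 + acc / np.pi, 0.0, 1.0)
    return out


def _optimal_p(t_min: float, sigma: np.ndarray, rho_grid, spectra) -> float:
    """Analytic SKAT-O combination.

    Writing the weighted score s ~ N(0, Sigma) as its burden projection
    eta = 1's/m plus an orthogonal remainder, every Q_rho decomposes as
    Q_rho = (1-rho) W + [(1-rho)|cof|^2-ish + rho m^2] eta^2 where
    W | eta is a noncentral chi-square mixture on the remainder spectrum.
    The probability that all Q_rho stay below their level-t_min quantiles
    is integrated over the 1-df chi-square of the burden component, with
    the conditional tail evaluated exactly by noncentral CF inversion.
    """
    m = sigma.shape[0]
    u1 = sigma.sum(axis=1)
    zz = float(sigma.sum())
    if zz <= 1e-12:
        return t_min
    zbar2 = zz / m**2
    cof = m * u1 / zz  # conditional mean direction of s given eta
    sigma2 = sigma - np.outer(u1, u1) / zz
    lam_bar, vecs = np.linalg.eigh(sigma2)
    keep = lam_bar > max(lam_bar.max(initial=0.0), 1.0) * 1e-10
    lamb = lam_bar[keep]
    if lamb.size == 0:
        return t_min
    proj = (vecs[:, keep].T @ cof) ** 2
    # noncentrality slope per eigenmode and the deterministic offset from
    # conditional-mean mass outside the remainder spectrum
    d = proj * zbar2 / lamb
    c0 = zbar2 * max(float(cof @ cof) - float(proj.sum()), 0.0)

    # exact level-t_min quantiles per rho (the argmin rho's quantile is its
    # own observed statistic)
    q_quant = np.empty(len(rho_grid))
    for i, lam in enumerate(spectra):
        q_quant[i] = _mixture_quantile(t_min, lam)

    rho_arr = np.asarray(rho_grid, dtype=float)
    sub1 = rho_arr < 1.0
    if (~sub1).any():
        x_cap = chi2.isf(t_min, 1)  # burden constraint: zz * x <= q_{rho=1}
    else:
        x_cap = np.inf

    z_hi = min(8.5, np.sqrt(x_cap)) if np.isfinite(x_cap) else 8.5
    nodes, wts = np.polynomial.legendre.leggauss(64)
    z = 0.5 * z_hi * (nodes + 1.0)
    wz = 0.5 * z_hi * wts
    x = z**2
    thr = np.min(
        (q_quant[sub1][:, None] - rho_arr[sub1][:, None] * zz * x[None, :])
        / (1.0 - rho_arr[sub1][:, None]),
        axis=0,
    ) - c0 * x
    sf = _noncentral_imhof_sf_batch(thr, x, lamb, d)
    below = 1.0 - sf
    below[thr <= 0] = 0.0
    prob_all_below = float((below * 2.0 * norm.pdf(z) * wz).sum())
    return 1.0 - prob_all_below


def skato_permutation_p(
    G: np.ndarray,
    weights: np.ndarray,
    null: NullModel,
    rho_grid=DEFAULT_RHO_GRID,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Permutation-calibrated SKAT-O p-value.

    Null-model residuals are permuted (which preserves the covariate fit),
    the minimum per-rho empirical p over the grid is the statistic, and the
    observed minimum-p is ranked against its own permutation distribution.
    """
    rng = np.random.default_rng(seed)
    G = np.nan_to_num(np.asarray(G, dtype=float))
    Z = G * np.asarray(weights)[None, :]
    r = null.resid
    s_obs = Z.T @ r
    perms = np.stack([rng.permutation(r) for _ in range(n_perm)])
    S = perms @ Z  # n_perm x m
    rho = np.asarray(rho_grid)[:, None]
    q_perm = (1.0 - rho) * (S**2).sum(axis=1)[None, :] + rho * S.sum(axis=1)[None, :] ** 2
    q_obs = (1.0 - rho[:, 0]) * (s_obs @ s_obs) + rho[:, 0] * s_obs.sum() ** 2

    # per-rho empirical upper-tail p for observed and each permutation
    p_obs = (1 + (q_perm >= q_obs[:, None] - 1e-12).sum(axis=1)) / (n_perm + 1)
    order = np.argsort(q_perm, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(len(rho_grid))[:, None]
    ranks[rows, order] = np.arange(n_perm)[None, :]
    p_perm = (n_perm - ranks) / (n_perm + 1)  # larger Q -> smaller p

    minp_obs = p_obs.min()
    minp_perm = p_perm.min(axis=0)
    return float((1 + (minp_perm <= minp_obs + 1e-12).sum()) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Cohort-level drivers and diagnostics

def gene_skat_o(
    bundle: CohortBundle,
    qualifying,
    covariates: pd.DataFrame,
    rho_grid=DEFAULT_RHO_GRID,
    weights: str = "beta",
    small_sample_mac: int = 40,
    n_boot: int = 8000,
    seed: int = 0,
) -> pd.DataFrame:
    """SKAT-O across all genes of a qualifying-variant set.

    Returns a frame with one row per gene (p_skat, p_burden, p_skato,
    Bonferroni-adjusted p over the genes tested).
    """
    cov = covariates.set_index("sample_id").loc[bundle.sample_ids]
    X = np.column_stack([np.ones(bundle.n_samples), cov.to_numpy(dtype=float)])
    null = fit_null(bundle.phenotype, X)

    rows = []
    for gene in sorted(qualifying.per_gene):
        idx = [
            j for j in qualifying.per_gene[gene] if bundle.variants[j].cohort_mac > 0
        ]
        if not idx:
            continue
        G = bundle.genotypes[:, idx]
        maf = np.array([bundle.variants[j].cohort_maf for j in idx])
        if weights == "beta":
            w = beta_maf_weights(maf)
        else:
            w = np.ones(len(idx))
        res = skato_test(
            G,
            w,
            null,
            rho_grid=rho_grid,
            small_sample_mac=small_sample_mac,
            n_boot=n_boot,
            seed=seed + len(rows),
            gene=gene,
        )
        rows.append(res)
    n_genes = len(rows)
    out = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "n_variants": [r.n_variants for r in rows],
            "mac": [r.mac for r in rows],
            "p_skat": [r.p_skat for r in rows],
            "p_burden": [r.p_burden for r in rows],
            "p_skato": [r.p_skato for r in rows],
            "adjusted": [r.adjusted for r in rows],
        }
    )
    out["p_bonferroni"] = np.minimum(1.0, out["p_skato"] * n_genes)
    return out.sort_values("p_skato").reset_index(drop=True)


def genomic_inflation(pvalues) -> float:
    """lambda_GC: median 1-df chi-square quantile of the p-values over the
    null median 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 50:
        raise ValueError("need at least 50 p-values for a stable lambda_GC")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / chi2.ppf(0.5, 1))


def neutral_model_check(
    bundle: CohortBundle,
    qualifying_synonymous,
    covariates: pd.DataFrame,
    bonferroni_alpha: float = 0.05,
) -> dict:
    """Run SKAT-O on the synonymous (neutral-model) sets and summarize
    inflation: lambda_GC, QQ data, genes beyond the Bonferroni threshold."""
    if qualifying_synonymous.n_genes == 0:
        return {"results": pd.DataFrame(), "lambda_gc": np.nan, "significant": []}
    res = gene_skat_o(bundle, qualifying_synonymous, covariates)
    lam = genomic_inflation(res["p_skato"]) if len(res) >= 50 else np.nan
    thr = bonferroni_alpha / len(res)
    sig = res.loc[res["p_skato"] < thr, "gene"].tolist()
    qq = pd.DataFrame(
        {
            "expected": -np.log10(
                (np.arange(1, len(res) + 1) - 0.5) / len(res)
            ),
            "observed": -np.log10(np.sort(res["p_skato"].to_numpy())),
        }
    )
    return {
        "results": res,
        "lambda_gc": lam,
        "significant": sig,
        "threshold": thr,
        "qq": qq,
    }
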