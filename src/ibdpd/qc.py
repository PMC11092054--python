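"""Cohort quality control: Hardy-Weinberg exact test, common-variant
selection, LD pruning, PCA covariates, MAC filtering and the
excess-heterozygosity sample screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CohortBundle


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (full enumeration over heterozygote counts)

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test p-value by enumeration of all heterozygote counts
    compatible with the observed allele counts; the p-value is the summed
    probability of configurations no more likely than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no genotyped samples")
    n_a = n_Aa + 2 * n_aa  # minor-allele count (fold below)
    n_A = n_Aa + 2 * n_AA
    rare = min(n_a, n_A)

    # attainable het counts share parity with the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each het configuration under the
    # conditional (hypergeometric-type) HWE distribution
    from scipy.special import gammaln

    def logprob(h):
        homr = (rare - h) // 2  # rare-allele homozygotes
        homc = n - h - homr  # common-allele homozygotes
        return (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(homr + 1)
            - gammaln(homc + 1)
            + h * np.log(2.0)
        )

    lp = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_Aa)] if n_Aa in hets else 0.0
    if n_Aa not in hets:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_enumeration_probs(n_AA: int, n_Aa: int, n_aa: int):
    """All attainable het counts and their exact conditional probabilities."""
    n = n_AA + n_Aa + n_aa
    rare = min(n_Aa + 2 * n_aa, n_Aa + 2 * n_AA)
    from scipy.special import gammaln

    hets = np.arange(rare % 2, rare + 1, 2)
    lp = []
    for h in hets:
        homr = (rare - h) // 2
        homc = n - h - homr
        lp.append(
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(homr + 1)
            - gammaln(homc + 1)
            + h * np.log(2.0)
        )
    lp = np.array(lp)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    return hets, probs


# ---------------------------------------------------------------------------
# Variant selection and LD

def genotype_counts(col: np.ndarray):
    """(n_AA, n_Aa, n_aa) hom-ref / het / hom-alt counts, ignoring missing."""
    obs = col[~np.isnan(col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def select_common(
    bundle: CohortBundle,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    miss_max: float = 0.2,
) -> list:
    """Indices of common variants for PCA: cohort MAF > maf_min, HWE exact
    p >= hwe_alpha, missingness <= miss_max."""
    keep = []
    n = bundle.n_samples
    for j, v in enumerate(bundle.variants):
        col = bundle.genotypes[:, j]
        missing = np.isnan(col).mean() if n else 1.0
        if missing > miss_max:
            continue
        if not v.cohort_maf > maf_min:
            continue
        n_AA, n_Aa, n_aa = genotype_counts(col)
        if n_AA + n_Aa + n_aa == 0:
            continue
        if hwe_exact_p(n_AA, n_Aa, n_aa) < hwe_alpha:
            continue
        keep.append(j)
    return keep


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    entries; nan when either vector has zero variance."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[ok], y[ok]
    if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    bundle: CohortBundle,
    variant_idx: list,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> list:
    """Greedy sliding-window LD pruning: within each window the later variant
    of any pair with r^2 > r2_max is dropped.  window=None prunes all pairs."""
    idx = list(variant_idx)
    if window is None or window >= len(idx):
        window, step = len(idx), max(1, len(idx))
    removed = set()
    start = 0
    while start < len(idx):
        win = [j for j in idx[start : start + window] if j not in removed]
        for a_pos in range(len(win)):
            if win[a_pos] in removed:
                continue
            for b_pos in range(a_pos + 1, len(win)):
                if win[b_pos] in removed:
                    continue
                r2 = ld_r2(
                    bundle.genotypes[:, win[a_pos]], bundle.genotypes[:, win[b_pos]]
                )
                if np.isnan(r2):
                    continue
                if r2 > r2_max:
                    removed.add(win[b_pos])
        start += step
    return [j for j in idx if j not in removed]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # k, descending
    scree: pd.DataFrame


def pca(bundle: CohortBundle, variant_idx: list, k: int = 2) -> PcaResult:
    """PCA on common variants with the usual genotype standardization.

    Each dosage column is mean-imputed, centered by 2*p_hat and scaled by
    sqrt(2*p_hat*(1-p_hat)).  Scores are the top-k left singular vectors
    scaled by their singular values; the sign convention makes the largest
    absolute loading of each component positive.
    """
    if not variant_idx:
        raise ValueError("no variants supplied to pca")
    G = bundle.genotypes[:, variant_idx].astype(float).copy()
    n = G.shape[0]
    if k > min(n - 1, G.shape[1]):
        raise ValueError(f"k={k} exceeds the attainable rank")
    for j in range(G.shape[1]):
        col = G[:, j]
        m = np.nanmean(col)
        col[np.isnan(col)] = m
        p = m / 2.0
        denom = np.sqrt(2.0 * p * (1.0 - p)) if 0 < p < 1 else 1.0
        G[:, j] = (col - 2.0 * p) / denom
    # monomorphic columns are all-zero after centering and contribute nothing
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    eigenvalues = (s**2) / max(n - 1, 1)
    for comp in range(min(k, Vt.shape[0])):
        peak = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, peak] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U[:, :k] * s[:k]
    scree = pd.DataFrame(
        {
            "component": np.arange(1, len(eigenvalues) + 1),
            "eigenvalue": eigenvalues,
            "prop_var": eigenvalues / eigenvalues.sum() if eigenvalues.sum() else 0.0,
        }
    )
    return PcaResult(scores=scores, eigenvalues=eigenvalues[:k], scree=scree)


def covariate_table(
    bundle: CohortBundle, pca_result: PcaResult = None, n_pcs: int = 0
) -> pd.DataFrame:
    """Per-sample covariates: sex (0=female, 1=male), age if present, PCs."""
    tab = pd.DataFrame(
        {
            "sample_id": bundle.sample_ids,
            "sex": [1.0 if s.sex == "male" else 0.0 for s in bundle.samples],
        }
    )
    ages = [s.age for s in bundle.samples]
    if all(a is not None for a in ages):
        tab["age"] = [float(a) for a in ages]
    if pca_result is not None and n_pcs > 0:
        for i in range(n_pcs):
            tab[f"PC{i + 1}"] = pca_result.scores[:, i]
    return tab


# ---------------------------------------------------------------------------
# MAC filter and heterozygosity outliers

def mac_filter(
    col: np.ndarray, case_mask: np.ndarray, min_mac: int = 3, min_case_mac: int = 1
) -> bool:
    """Keep a variant iff total minor allele count >= min_mac and the count
    among cases >= min_case_mac."""
    obs = ~np.isnan(col)
    alt = np.nansum(col)
    n_alleles = 2 * obs.sum()
    mac = min(alt, n_alleles - alt)
    minor_is_alt = alt * 2 <= n_alleles
    case_col = col[case_mask & obs]
    if minor_is_alt:
        case_mac = case_col.sum()
    else:
        case_mac = (2 * case_col.size) - case_col.sum()
    return bool(mac >= min_mac and case_mac >= min_case_mac)


def flag_high_missingness_samples(bundle: CohortBundle, max_frac: float = 0.05):
    """Samples whose genotype missingness exceeds max_frac (biobank-style QC)."""
    miss = np.isnan(bundle.genotypes).mean(axis=1)
    return [bundle.sample_ids[i] for i in np.flatnonzero(miss > max_frac)]


def flag_het_outliers(
    bundle: CohortBundle, variant_idx: list, z_max: float = 4.0
) -> list:
    """Samples whose heterozygote count over the given variants exceeds
    mean + z_max * SD (computed over all samples)."""
    if bundle.n_samples < 3:
        raise ValueError("need at least 3 samples to screen for outliers")
    G = bundle.genotypes[:, variant_idx] if variant_idx else bundle.genotypes
    counts = np.nansum(G == 1, axis=1).astype(float)
    mu, sd = counts.mean(), counts.std()
    if sd == 0:
        return []
    flagged = np.flatnonzero(counts > mu + z_max * sd)
    return [bundle.sample_ids[i] for i in flagged]
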