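"""Gene-level PheWAS over phecodes derived from ICD-9/10 diagnoses.

ICD codes are mapped to phecodes (Phecode-Map-style CSV); a sample is a case
for a phecode if it has at least one mapped diagnosis, excluded if it
instead has a diagnosis inside the phecode's exclusion range, and a control
otherwise.  Phecodes with fewer than 20 cases are skipped, controls are
randomly capped at 99 per case, and each (gene, phecode) pair is tested
with SKAT-O using age, sex and PCs as covariates.  Significance is assessed
against the phenome-wide Bonferroni threshold 0.05 / number of phecodes
tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import bonferroni_threshold
from .skat import beta_maf_weights, fit_null, skato_test
from .types import CohortBundle

CASE, CONTROL, EXCLUDED = 1, 0, -1


@dataclass
class PhecodeMap:
    """(icd_version, icd_code) -> phecode, plus per-phecode description and
    exclusion interval [low, high] on the phecode axis."""

    icd_to_phecode: dict
    description: dict
    exclusion: dict  # phecode -> (low, high)

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        tab = pd.read_csv(path, dtype={"icd_code": str, "phecode": str})
        key = list(zip(tab["icd_version"].astype(int), tab["icd_code"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (icd_version, icd_code) keys in phecode map")
        icd_to_phecode = dict(zip(key, tab["phecode"]))
        description = dict(zip(tab["phecode"], tab["description"]))
        exclusion = {
            row.phecode: (float(row.exclusion_low), float(row.exclusion_high))
            for row in tab.itertuples(index=False)
        }
        for code, (lo, hi) in exclusion.items():
            if lo > hi:
                raise ValueError(f"malformed exclusion range for phecode {code}")
        return cls(icd_to_phecode, description, exclusion)

    @property
    def phecodes(self) -> list:
        return sorted(self.description, key=float)


def toy_phecode_map() -> PhecodeMap:
    """The small phecode map bundled for tests and the synthetic cohort."""
    with resources.as_file(
        resources.files("ibdpd") / "data" / "phecode_map_toy.csv"
    ) as p:
        return PhecodeMap.from_csv(p)


def map_icd(
    icd_table: pd.DataFrame,
    pmap: PhecodeMap,
    sample_ids=None,
    apply_exclusions: bool = True,
) -> pd.DataFrame:
    """Sample x phecode assignment frame with entries 1=case, 0=control,
    -1=excluded.

    ``icd_table`` columns: sample_id, icd_version, icd_code.  Samples with
    no diagnoses are controls everywhere.  A non-case holding a diagnosis
    mapping inside a phecode's exclusion range is excluded for that phecode.
    """
    if sample_ids is None:
        sample_ids = sorted(icd_table["sample_id"].unique())
    phecodes = pmap.phecodes
    assign = pd.DataFrame(
        CONTROL, index=list(sample_ids), columns=phecodes, dtype=int
    )
    per_sample_codes: dict = {s: set() for s in sample_ids}
    n_unmapped = 0
    for row in icd_table.itertuples(index=False):
        try:
            version = int(row.icd_version)
            code = str(row.icd_code)
        except (TypeError, ValueError):
            n_unmapped += 1
            continue
        phe = pmap.icd_to_phecode.get((version, code))
        if phe is None:
            n_unmapped += 1
            continue
        if row.sample_id in per_sample_codes:
            per_sample_codes[row.sample_id].add(phe)

    for s, codes in per_sample_codes.items():
        if not codes:
            continue
        vals = {float(c) for c in codes}
        for phe in phecodes:
            if phe in codes:
                assign.loc[s, phe] = CASE
            elif apply_exclusions:
                lo, hi = pmap.exclusion[phe]
                if any(lo <= v <= hi for v in vals):
                    assign.loc[s, phe] = EXCLUDED
    assign.attrs["n_unmapped"] = n_unmapped
    return assign


def assemble_case_control(
    table: pd.DataFrame,
    phecode: str,
    min_cases: int = 20,
    max_ratio: int = 99,
    seed: int = 0,
):
    """(case_ids, control_ids) for one phecode, or None if below min_cases.

    Controls are randomly downsampled (seeded) to at most max_ratio per
    case; excluded samples are never controls.
    """
    col = table[phecode]
    cases = list(table.index[col == CASE])
    if len(cases) < min_cases:
        return None
    controls = list(table.index[col == CONTROL])
    cap = max_ratio * len(cases)
    if len(controls) > cap:
        rng = np.random.default_rng(seed)
        controls = sorted(rng.choice(controls, size=cap, replace=False))
    return cases, controls


def gene_phewas(
    bundle: CohortBundle,
    qualifying,
    phecode_table: pd.DataFrame,
    covariates: pd.DataFrame,
    genes=None,
    min_cases: int = 20,
    max_ratio: int = 99,
    seed: int = 0,
    alpha: float = 0.05,
    variant_whitelist=None,
) -> pd.DataFrame:
    """SKAT-O of each gene's qualifying variants against every phecode that
    passes the case-count filter.

    ``variant_whitelist`` optionally restricts the tested variants to a set
    of (chrom, pos, ref, alt) keys, mirroring a discovery-cohort restriction.
    Returns one row per (gene, phecode) with the phenome-wide threshold in
    ``attrs['threshold']``.
    """
    genes = sorted(qualifying.per_gene) if genes is None else list(genes)
    cov = covariates.set_index("sample_id")
    id_to_row = {s: i for i, s in enumerate(bundle.sample_ids)}

    tested_phecodes = [
        phe
        for phe in phecode_table.columns
        if (phecode_table[phe] == CASE).sum() >= min_cases
    ]
    threshold = (
        bonferroni_threshold(alpha, len(tested_phecodes)) if tested_phecodes else np.nan
    )

    rows = []
    for phe in tested_phecodes:
        sets = assemble_case_control(
            phecode_table, phe, min_cases=min_cases, max_ratio=max_ratio, seed=seed
        )
        case_ids, control_ids = sets
        ids = [s for s in case_ids + control_ids if s in id_to_row and s in cov.index]
        idx = np.array([id_to_row[s] for s in ids])
        y = np.array([1.0 if s in set(case_ids) else 0.0 for s in ids])
        X = np.column_stack(
            [np.ones(len(ids)), cov.loc[ids].to_numpy(dtype=float)]
        )
        null = fit_null(y, X)
        for gene in genes:
            var_idx = qualifying.per_gene.get(gene, [])
            if variant_whitelist is not None:
                var_idx = [
                    j for j in var_idx if bundle.variants[j].key in variant_whitelist
                ]
            if not var_idx:
                continue
            G = bundle.genotypes[np.ix_(idx, var_idx)]
            if np.nansum(G) == 0:
                continue  # no qualifying alleles among retained samples
            maf = np.array([bundle.variants[j].cohort_maf for j in var_idx])
            res = skato_test(
                G, beta_maf_weights(maf), null, seed=seed + len(rows), gene=gene
            )
            rows.append(
                {
                    "gene": gene,
                    "phecode": phe,
                    "n_cases": len(case_ids),
                    "n_controls": len(control_ids),
                    "p": res.p_skato,
                    "significant": res.p_skato < threshold,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_phecodes_tested"] = len(tested_phecodes)
    return out
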