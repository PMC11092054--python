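"""Cohort QC: common-variant selection, LD pruning, PCA covariates and the
excess-heterozygosity screen.

Writes covariates.tsv (sex, PC1) and scree.tsv under results/qc/ and
reports how well PC1 separates the two simulated subpopulations.
"""

from pathlib import Path

import numpy as np

from ibdpd.filtering import build_qualifying_sets
from ibdpd.qc import (
    covariate_table,
    flag_het_outliers,
    ld_prune,
    pca,
    select_common,
)

import importlib.util

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("step02", ROOT / "analysis" / "02_filter.py")
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)

OUT = ROOT / "results" / "qc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = step02.load_bundle()
    common = select_common(bundle, maf_min=0.05, hwe_alpha=1e-6)
    kept = ld_prune(bundle, common, r2_max=0.2)
    print(f"common variants: {len(common)}, after LD pruning: {len(kept)}")
    res = pca(bundle, kept, k=2)
    res.scree.head(20).to_csv(OUT / "scree.tsv", sep="\t", index=False)

    pop = np.array([s.ancestry_label == "POP2" for s in bundle.samples], float)
    r = np.corrcoef(res.scores[:, 0], pop)[0, 1]
    print(f"|corr(PC1, subpopulation)| = {abs(r):.3f}")

    cov = covariate_table(bundle, res, n_pcs=1)[["sample_id", "sex", "PC1"]]
    cov.to_csv(OUT / "covariates.tsv", sep="\t", index=False)

    qset = build_qualifying_sets(bundle, model="synonymous")
    syn_idx = [j for idx in qset.per_gene.values() for j in idx]
    flagged = flag_het_outliers(bundle, syn_idx, z_max=4.0)
    print(f"heterozygosity outliers flagged: {flagged or 'none'}")


if __name__ == "__main__":
    main()
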