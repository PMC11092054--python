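"""Gene-level PheWAS on the synthetic EHR.

Maps the simulated ICD diagnoses to phecodes with the bundled toy map,
applies the >= 20 case and 1:99 case-control constraints, and runs SKAT-O
for the final candidate genes against every eligible phecode with sex and
PC1 as covariates.  Writes phewas_results.tsv under results/phewas/.
"""

from pathlib import Path
import importlib.util

import pandas as pd

from ibdpd import io
from ibdpd.filtering import build_qualifying_sets
from ibdpd.phewas import gene_phewas, map_icd, toy_phecode_map

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("step02", ROOT / "analysis" / "02_filter.py")
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)

SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "phewas"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = step02.load_bundle()
    cov = pd.read_csv(ROOT / "results" / "qc" / "covariates.tsv", sep="\t")
    icd = pd.read_csv(SYN / "icd_diagnoses.csv", dtype={"icd_code": str})
    pmap = toy_phecode_map()
    table = map_icd(icd, pmap, sample_ids=bundle.sample_ids)
    n_case_cols = (table == 1).sum()
    print(f"phecodes with >= 20 cases: {(n_case_cols >= 20).sum()} "
          f"of {table.shape[1]}")

    qset = build_qualifying_sets(bundle)
    truth = pd.read_csv(SYN / "truth.tsv", sep="\t")
    genes = sorted(truth.loc[truth["causal"], "gene"].unique())
    res = gene_phewas(bundle, qset, table, cov, genes=genes, seed=seed)
    res.to_csv(OUT / "phewas_results.tsv", sep="\t", index=False)
    print(f"tested {len(res)} (gene, phecode) pairs; "
          f"phenome-wide threshold {res.attrs['threshold']:.2e}")
    if not res.empty:
        top = res.sort_values("p").head(5)
        print(top.to_string(index=False))


if __name__ == "__main__":
    main()
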