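"""Network-based heterogeneity clustering of case qualifying genes.

Scans the PPI edge-weight threshold from 0.99 down to 0.70, emits
connected clusters carried by >= 2 cases with >= 3 genes, tests each
cluster's carrier burden with Firth regression, and flags clusters whose
enrichment matches the control-embedded pathway list.  Writes clusters.tsv
and cluster_enrichment.tsv under results/nhc/.
"""

from pathlib import Path
import importlib.util

import pandas as pd

from ibdpd import io
from ibdpd.filtering import build_qualifying_sets
from ibdpd.nhc import (
    case_gene_sets,
    cluster_burden_p,
    cluster_genes,
    clusters_table,
    flag_control_embedded,
)
from ibdpd.prioritize import ora_enrichment

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("step02", ROOT / "analysis" / "02_filter.py")
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)

SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "nhc"

#: gene-set terms treated as control-embedded (deprioritized, not dropped)
CONTROL_EMBEDDED_TERMS = ["RANDOM_0", "RANDOM_1"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = step02.load_bundle()
    cov = pd.read_csv(ROOT / "results" / "qc" / "covariates.tsv", sep="\t")
    network = io.read_edge_list(SYN / "ppi_edges.tsv")
    collection = io.read_gmt(SYN / "gene_sets.gmt")

    qset = build_qualifying_sets(bundle)
    case_sets = case_gene_sets(qset, bundle)
    clusters = cluster_genes(case_sets, network)
    print(f"{len(clusters)} clusters emitted from "
          f"{sum(bool(s) for s in case_sets.values())} carrier cases")

    universe = sorted(bundle.gene_annotations)
    enr_frames = []
    for c in clusters:
        cluster_burden_p(c, qset, bundle, cov)
        enr = ora_enrichment(c.genes, collection, universe)
        enr.insert(0, "cluster_id", c.cluster_id)
        enr_frames.append(enr)
        flag_control_embedded(c, CONTROL_EMBEDDED_TERMS, enr)

    tab = clusters_table(clusters)
    tab.to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    pd.concat(enr_frames).to_csv(OUT / "cluster_enrichment.tsv", sep="\t", index=False)
    sig = tab[(tab["p"] < 0.05) & ~tab["control_embedded"]]
    print(f"significant non-control-embedded clusters (p < 0.05): {len(sig)}")
    if not sig.empty:
        print(sig[["cluster_id", "genes", "n_case_carriers",
                   "n_control_carriers", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
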