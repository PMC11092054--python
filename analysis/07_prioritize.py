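"""Candidate pooling, enrichment, biological-distance statistics and
importance scores.

Pools SKAT-O genes (p < 0.01) with significant cluster genes, measures the
pool's mean biological distance to the known IBD and PD panels against a
10,000-draw resampling null, intersects the package's two in-house ranking
methods (enrichment, distance) as a stand-in for the multi-method step, and
scores candidates by known-gene co-occurrence.  Writes tables under
results/prioritize/.
"""

from pathlib import Path
import importlib.util

import pandas as pd

from ibdpd import io
from ibdpd.filtering import build_qualifying_sets
from ibdpd.nhc import GeneCluster
from ibdpd.prioritize import (
    avg_set_distance,
    distance_to_set,
    importance_scores,
    intersect_methods,
    ora_enrichment,
    overlap_percent,
    pool_candidates,
    resampling_p,
)

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("step02", ROOT / "analysis" / "02_filter.py")
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)

SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "prioritize"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = step02.load_bundle()
    gene_res = pd.read_csv(ROOT / "results" / "assoc_gene" / "assoc_gene.tsv", sep="\t")
    clus = pd.read_csv(ROOT / "results" / "nhc" / "clusters.tsv", sep="\t")
    clusters = [
        GeneCluster(
            cluster_id=row.cluster_id,
            genes=frozenset(row.genes.split(",")),
            emission_threshold=row.emission_threshold,
            p=row.p,
            control_embedded=row.control_embedded,
            degenerate=row.degenerate,
        )
        for row in clus.itertuples(index=False)
    ]
    pool = pool_candidates(gene_res, clusters)
    io.write_gene_list(OUT / "candidate_pool.txt", sorted(pool))
    print(f"candidate pool: {len(pool)} genes")

    known_ibd = io.read_gene_list(SYN / "known_ibd.txt")
    known_pd = io.read_gene_list(SYN / "known_pd.txt")
    print(f"overlap with known IBD panel: {overlap_percent(pool, known_ibd):.2f}% "
          f"of candidates; PD panel: {overlap_percent(pool, known_pd):.2f}%")

    distances = io.read_distance_matrix(SYN / "distances.tsv")
    rows = []
    for name, known in (("IBD", known_ibd), ("PD", known_pd)):
        summ = resampling_p(pool, known, distances, n_iter=10000, seed=seed)
        rows.append(
            {
                "panel": name,
                "d_candidate": summ.d_candidate,
                "d_within": summ.d_within,
                "d_random_mean": float(summ.d_random.mean()),
                "p_empirical": summ.p_empirical,
            }
        )
        print(f"{name}: D_candidate={summ.d_candidate:.2f} "
              f"D_within={summ.d_within:.2f} empirical p={summ.p_empirical:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "distance_summary.tsv", sep="\t", index=False)

    collection = io.read_gmt(SYN / "gene_sets.gmt")
    universe = sorted(bundle.gene_annotations)
    enr = ora_enrichment(pool, collection, universe)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    # two in-house ranking methods stand in for the external multi-method step
    sig_terms = set(enr.loc[enr["p_adj"] < 0.05, "term_id"])
    method_enrichment = sorted(
        g for g in pool
        if any(g in collection.genes(t) for t in sig_terms)
    ) or sorted(pool)
    known_all = sorted(set(known_ibd) | set(known_pd))
    ranked = sorted(
        (g for g in pool if g in distances),
        key=lambda g: distance_to_set(g, known_all, distances),
    )
    method_distance = ranked[: max(5, len(ranked) // 2)]
    final = intersect_methods(
        {"enrichment": method_enrichment, "distance": method_distance}
    )
    io.write_gene_list(OUT / "final_candidates.txt", final)
    print(f"final candidates (both methods): {len(final)}")

    term_genes = {t: set(collection.genes(t)) for t in collection.terms()}
    term_p = dict(zip(enr["term_id"], enr["p"]))
    network = io.read_edge_list(SYN / "ppi_edges.tsv")
    scores = importance_scores(
        final,
        {"ora": ("terms", term_genes, term_p), "ppi": ("network", network, 0.7)},
        known_ibd,
        known_pd,
    )
    scores.to_csv(OUT / "importance_scores.tsv", sep="\t", index=False)
    cols = ["gene", "score_ibd", "score_pd", "score_combined"]
    print(scores[cols].head(5).to_string(index=False))


if __name__ == "__main__":
    main()
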