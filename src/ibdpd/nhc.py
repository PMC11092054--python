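"""Network-based heterogeneity clustering (NHC).

Genes carrying qualifying variants in cases are grouped into clusters that
are connected in a weighted background PPI network, scanning an edge-weight
threshold from high to low; each cluster is then tested for carrier burden
(cases vs controls) with Firth logistic regression.  Clusters whose
enrichment matches previously identified control-embedded pathways are
deprioritized rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .firth import firth_wald_p, fit_firth
from .types import CohortBundle


def case_gene_sets(qualifying, bundle: CohortBundle) -> dict:
    """Per-case mapping sample_id -> set of genes in which the case carries
    at least one qualifying allele."""
    out = {}
    case_idx = np.flatnonzero(bundle.case_mask)
    for gene, var_idx in qualifying.per_gene.items():
        sub = bundle.genotypes[np.ix_(case_idx, var_idx)]
        carriers = np.nansum(sub, axis=1) > 0
        for i in case_idx[carriers]:
            out.setdefault(bundle.sample_ids[i], set()).add(gene)
    for i in case_idx:
        out.setdefault(bundle.sample_ids[i], set())
    return out


@dataclass
class GeneCluster:
    cluster_id: int
    genes: frozenset
    emission_threshold: float
    case_carriers: set = field(default_factory=set)
    control_carriers: set = field(default_factory=set)
    p: float = np.nan
    degenerate: bool = False
    control_embedded: bool = False


def cluster_genes(
    case_sets: dict,
    network: nx.Graph,
    w_start: float = 0.99,
    w_stop: float = 0.70,
    w_step: float = 0.01,
    min_cases: int = 2,
    min_genes: int = 3,
) -> list:
    """Descending-threshold connected-component clustering.

    At each threshold w (w_start down to w_stop) the subgraph induced on the
    union of case genes keeps edges with weight >= w; connected components
    with >= min_genes genes carried by >= min_cases distinct cases are
    emitted at the first (highest) threshold where both conditions hold.  A
    component that merely grows at a lower threshold is re-emitted only if
    it gains a new carrier case.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty background network")
    union_genes = set().union(*case_sets.values()) if case_sets else set()
    pool = sorted(union_genes & set(network.nodes))
    clusters: list = []
    emitted: list = []  # (frozenset genes, frozenset cases)

    thresholds = np.arange(w_start, w_stop - 1e-9, -w_step)
    cid = 0
    for w in thresholds:
        g_w = nx.Graph()
        g_w.add_nodes_from(pool)
        for a, b, data in network.edges(data=True):
            if data["weight"] >= w - 1e-12 and a in union_genes and b in union_genes:
                g_w.add_edge(a, b)
        for comp in sorted(nx.connected_components(g_w), key=lambda c: sorted(c)[0]):
            if len(comp) < min_genes:
                continue
            cases = frozenset(
                cid_ for cid_, genes in case_sets.items() if genes & comp
            )
            if len(cases) < min_cases:
                continue
            already = any(
                genes_e <= comp and cases_e == cases for genes_e, cases_e in emitted
            )
            if already:
                continue
            cid += 1
            clusters.append(
                GeneCluster(
                    cluster_id=cid,
                    genes=frozenset(comp),
                    emission_threshold=float(round(w, 10)),
                    case_carriers=set(cases),
                )
            )
            emitted.append((frozenset(comp), cases))
    return clusters


def _carrier_indicator(cluster: GeneCluster, qualifying, bundle: CohortBundle):
    idx = sorted(
        {j for g in cluster.genes for j in qualifying.per_gene.get(g, [])}
    )
    if not idx:
        return np.zeros(bundle.n_samples, dtype=bool)
    return np.nansum(bundle.genotypes[:, idx], axis=1) > 0


def cluster_burden_p(
    cluster: GeneCluster,
    qualifying,
    bundle: CohortBundle,
    covariates: pd.DataFrame = None,
) -> GeneCluster:
    """Firth logistic regression of case status on the cluster carrier
    indicator (plus covariates); fills carrier sets and the Wald p in place."""
    carrier = _carrier_indicator(cluster, qualifying, bundle)
    ids = np.array(bundle.sample_ids)
    case = bundle.case_mask
    cluster.case_carriers = set(ids[carrier & case])
    cluster.control_carriers = set(ids[carrier & ~case])

    if carrier.all() or not carrier.any():
        cluster.p = 1.0
        cluster.degenerate = True
        return cluster
    y = bundle.phenotype
    cols = [np.ones(bundle.n_samples), carrier.astype(float)]
    if covariates is not None:
        cov = covariates.set_index("sample_id").loc[bundle.sample_ids]
        cols.append(cov.to_numpy(dtype=float))
    X = np.column_stack(cols)
    fit = fit_firth(y, X)
    cluster.p = firth_wald_p(fit, term=1)
    return cluster


def cluster_burden_fisher(
    cluster: GeneCluster, qualifying, bundle: CohortBundle
) -> float:
    """Covariate-free alternative: Fisher exact test on the carrier 2x2."""
    from scipy.stats import fisher_exact

    carrier = _carrier_indicator(cluster, qualifying, bundle)
    case = bundle.case_mask
    table = [
        [int((carrier & case).sum()), int((~carrier & case).sum())],
        [int((carrier & ~case).sum()), int((~carrier & ~case).sum())],
    ]
    return float(fisher_exact(table)[1])


def flag_control_embedded(
    cluster: GeneCluster, control_terms, enrichment: pd.DataFrame, p_adj_cut: float = 0.05
) -> bool:
    """True iff any significantly enriched term of the cluster (p_adj <
    p_adj_cut) is on the control-embedded pathway list."""
    if enrichment is None or enrichment.empty or not control_terms:
        cluster.control_embedded = False
        return False
    control = set(control_terms)
    sig = enrichment.loc[enrichment["p_adj"] < p_adj_cut, "term_id"]
    cluster.control_embedded = bool(any(t in control for t in sig))
    return cluster.control_embedded


def clusters_table(clusters: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "n_genes": [len(c.genes) for c in clusters],
            "genes": [",".join(sorted(c.genes)) for c in clusters],
            "n_case_carriers": [len(c.case_carriers) for c in clusters],
            "n_control_carriers": [len(c.control_carriers) for c in clusters],
            "emission_threshold": [c.emission_threshold for c in clusters],
            "p": [c.p for c in clusters],
            "degenerate": [c.degenerate for c in clusters],
            "control_embedded": [c.control_embedded for c in clusters],
        }
    )
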