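"""Candidate-gene prioritization.

Pools nominally significant SKAT-O genes with genes from significant,
non-control-embedded network clusters; runs hypergeometric over-
representation analysis; computes biological-distance statistics of the
candidate pool against known-disease gene panels with a resampling null;
intersects multiple prioritization methods; and assigns biological
importance scores by counting known-panel genes that co-occur with each
candidate in significant terms or network neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import DistanceMatrix, GeneSetCollection


def pool_candidates(gene_results: pd.DataFrame, clusters: list, p_cut: float = 0.01,
                    cluster_p_cut: float = 0.05) -> set:
    """Union of SKAT-O genes with p_skato < p_cut and genes of significant,
    non-control-embedded clusters."""
    pool = set(gene_results.loc[gene_results["p_skato"] < p_cut, "gene"])
    for c in clusters:
        if c.p < cluster_p_cut and not c.control_embedded and not c.degenerate:
            pool |= set(c.genes)
    return pool


# ---------------------------------------------------------------------------
# Over-representation analysis

def ora_enrichment(gene_set, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of every term in the collection,
    Benjamini-Hochberg adjusted, sorted by p."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_set) & universe
    rows = []
    for term in collection.terms():
        desc, term_genes = collection.sets[term]
        tg = set(term_genes) & universe
        if not tg:
            continue
        overlap = len(genes & tg)
        # P(X >= overlap), X ~ Hypergeom(|U|, |term|, |set|)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(tg), len(genes)))
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "overlap": overlap,
                "set_size": len(genes),
                "term_size": len(tg),
                "universe_size": len(universe),
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adj"] = []
        return out
    from statsmodels.stats.multitest import multipletests

    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p").reset_index(drop=True)


def compare_enrichment(results: dict, sig_cut: float = 0.05) -> dict:
    """Partition significant terms across several gene sets (Venn semantics).

    ``results`` maps gene-set name -> enrichment frame.  Returns
    {'shared_all': terms significant in every set, 'unique': {name: terms
    significant only there}, 'significant': {name: all significant terms}}.
    """
    sig = {
        name: set(df.loc[df["p_adj"] < sig_cut, "term_id"])
        for name, df in results.items()
    }
    names = list(sig)
    shared = set.intersection(*sig.values()) if sig else set()
    unique = {
        name: sig[name] - set().union(*(sig[o] for o in names if o != name))
        for name in names
    }
    return {"shared_all": shared, "unique": unique, "significant": sig}


# ---------------------------------------------------------------------------
# Biological-distance statistics

def distance_to_set(gene: str, known, D: DistanceMatrix, how: str = "min") -> float:
    """Distance from one gene to a gene set: minimum (default) or mean over
    members, the gene itself excluded."""
    members = [g for g in known if g != gene and g in D]
    if not members:
        raise ValueError(f"no known-set members in the matrix for {gene}")
    d = [D.distance(gene, m) for m in members]
    return float(min(d) if how == "min" else np.mean(d))


def avg_set_distance(candidates, known, D: DistanceMatrix, how: str = "min") -> float:
    """Mean over candidate genes of each gene's distance-to-known-set."""
    cand = [g for g in candidates if g in D]
    if not cand:
        raise ValueError("no candidate genes present in the distance matrix")
    return float(np.mean([distance_to_set(g, known, D, how=how) for g in cand]))


def within_set_distance(known, D: DistanceMatrix, how: str = "min") -> float:
    """Mean over members of the distance to the rest of the set."""
    members = [g for g in known if g in D]
    if len(members) < 2:
        raise ValueError("within-set distance needs at least 2 genes in the matrix")
    return float(
        np.mean([distance_to_set(g, members, D, how=how) for g in members])
    )


@dataclass
class DistanceSummary:
    d_candidate: float
    d_within: float
    d_random: np.ndarray
    p_empirical: float
    n_candidates: int
    n_iter: int


def resampling_p(
    candidates,
    known,
    D: DistanceMatrix,
    universe=None,
    n_iter: int = 10000,
    seed: int = 0,
    how: str = "min",
) -> DistanceSummary:
    """Empirical p for the candidate-to-known distance against random gene
    sets of the same size drawn from the universe (matrix genes minus the
    known set by default).  Add-one estimator: p = (1 + #{D_random <=
    D_candidate}) / (n_iter + 1)."""
    rng = np.random.default_rng(seed)
    known = [g for g in known if g in D]
    cand = [g for g in candidates if g in D]
    if universe is None:
        universe = [g for g in D.genes if g not in set(known)]
    universe = [g for g in universe if g in D]
    k = len(cand)
    if len(universe) <= k:
        raise ValueError("universe smaller than the candidate set")

    d_candidate = avg_set_distance(cand, known, D, how=how)
    d_within = within_set_distance(known, D, how=how) if len(known) >= 2 else np.nan

    # precompute each universe gene's distance-to-known once
    dist_lut = np.array([distance_to_set(g, known, D, how=how) for g in universe])
    draws = np.stack(
        [rng.choice(len(universe), size=k, replace=False) for _ in range(n_iter)]
    )
    d_random = dist_lut[draws].mean(axis=1)
    p = (1 + int((d_random <= d_candidate + 1e-12).sum())) / (n_iter + 1)
    return DistanceSummary(
        d_candidate=d_candidate,
        d_within=d_within,
        d_random=d_random,
        p_empirical=float(p),
        n_candidates=k,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Multi-method intersection and importance scores

def intersect_methods(method_lists: dict, k_required: int = None) -> list:
    """Genes present in all (default) or at least ``k_required`` of the
    supplied per-method gene lists, sorted."""
    if len(method_lists) < 2:
        raise ValueError("need at least two method lists")
    for name, genes in method_lists.items():
        if not genes:
            raise ValueError(f"method {name!r} supplied an empty gene list")
    k = len(method_lists) if k_required is None else k_required
    counts = {}
    for genes in method_lists.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= k)


@dataclass
class ImportanceScore:
    gene: str
    raw: dict = field(default_factory=dict)  # (source, panel) -> count
    scaled: dict = field(default_factory=dict)
    score_ibd: float = 0.0
    score_pd: float = 0.0
    score_combined: float = 0.0


def importance_scores(candidates, sources: dict, known_ibd, known_pd) -> pd.DataFrame:
    """Biological importance scores.

    ``sources`` maps source name to either

    * ``("terms", {term: genes}, {term: p})`` -- significant terms are those
      with p < 0.01; a candidate's raw count per panel is the number of
      distinct panel genes sharing at least one significant term with it; or
    * ``("network", graph, weight_cut)`` -- the raw count is the number of
      panel genes adjacent to the candidate with edge weight >= weight_cut.

    Raw counts are max-scaled within each (source, panel) over the candidate
    list; panel scores are the sums of scaled scores over sources.
    """
    panels = {
        "ibd": set(known_ibd),
        "pd": set(known_pd),
        "combined": set(known_ibd) | set(known_pd),
    }
    candidates = list(candidates)
    raw = {g: {} for g in candidates}
    for source, spec in sources.items():
        kind = spec[0]
        for g in candidates:
            if kind == "terms":
                _, term_genes, term_p = spec
                co = set()
                for term, genes in term_genes.items():
                    if term_p.get(term, 1.0) < 0.01 and g in genes:
                        co |= set(genes)
                co.discard(g)
            elif kind == "network":
                _, graph, w_cut = spec
                co = {
                    nb
                    for nb in (graph.neighbors(g) if g in graph else [])
                    if graph[g][nb]["weight"] >= w_cut
                }
            else:
                raise ValueError(f"unknown source kind {kind!r}")
            for panel, panel_genes in panels.items():
                raw[g][(source, panel)] = len(co & panel_genes)

    rows = []
    for g in candidates:
        rec = {"gene": g}
        for panel in panels:
            total = 0.0
            for source in sources:
                col = [raw[x][(source, panel)] for x in candidates]
                mx = max(col)
                scaled = raw[g][(source, panel)] / mx if mx > 0 else 0.0
                rec[f"raw_{source}_{panel}"] = raw[g][(source, panel)]
                rec[f"scaled_{source}_{panel}"] = scaled
                total += scaled
            rec[f"score_{panel}"] = total
        rows.append(rec)
    return (
        pd.DataFrame(rows)
        .sort_values("score_combined", ascending=False)
        .reset_index(drop=True)
    )


def overlap_percent(candidates, known) -> float:
    """Overlap of a candidate set with a known panel, as % of candidates."""
    cand = set(candidates)
    if not cand:
        raise ValueError("empty candidate set")
    return 100.0 * len(cand & set(known)) / len(cand)
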