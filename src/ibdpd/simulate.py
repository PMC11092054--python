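"""Synthetic cohort generator.

Produces every input the pipeline consumes -- genotypes with two-population
structure, a variant annotation table matching the qualifying cascade, gene
MSC/GDI records, a modular weighted PPI network with a planted
case-enriched module, a biological-distance matrix derived from that
network, gene-set collections with planted terms, known-disease gene
panels, and ICD diagnosis tables inducing phecodes -- together with a truth
table recording each variant's causal status and, for decoys, the single
cascade rule it was built to fail.

Population structure follows the Balding-Nichols drift model: subpopulation
allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws around an
ancestral frequency p.  Disease status is logistic on carrier indicators of
the causal genes (optionally on dosages), with the intercept tuned by
bisection to the configured case fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import (
    CohortBundle,
    DistanceMatrix,
    GeneRecord,
    GeneSetCollection,
    SampleRecord,
    VariantSite,
    recompute_cohort_freqs,
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the discovery design: a small case group (67) against
    1KGP-scale controls (426), ~200 genes with a handful of rare coding
    variants each, mild two-population structure (Fst 0.05), and causal
    genes whose carriers have elevated disease odds.
    """

    n_cases: int = 67
    n_controls: int = 426
    n_genes: int = 200
    mean_variants_per_gene: float = 12.0
    mean_synonymous_per_gene: float = 6.0
    rare_maf_range: tuple = (1e-3, 1e-2)
    common_maf_range: tuple = (0.05, 0.5)
    n_common_variants: int = 300
    fst: float = 0.05
    pop_fractions: tuple = (0.5, 0.5)
    causal_genes: dict = field(default_factory=dict)  # gene -> carrier odds ratio
    causal_carrier_freq: float = 0.05  # target control-pop carrier frequency
    dosage_model: bool = False  # logistic on dosage sums instead of carriers
    covariate_effects: dict = field(default_factory=lambda: {"sex": 0.0, "age": 0.0})
    decoy_fraction: float = 0.4  # non-causal variants failing one rule
    n_gdi_decoy_genes: int = 10
    # PPI: module 0 is the planted case-enriched module holding causal genes
    ppi_modules: int = 8
    ppi_module_size: int = 6
    ppi_p_in: float = 0.95
    ppi_p_out: float = 0.02
    ppi_w_in: tuple = (0.9, 1.0)
    ppi_w_out: tuple = (0.3, 0.7)
    distance_sentinel: float = 50.0
    n_gene_set_terms: int = 20
    phecode_spec: dict = field(default_factory=dict)
    # phecode -> (baseline_prevalence, carrier_odds_ratio, [carrier genes])
    seed: int = 0

    def __post_init__(self) -> None:
        for g, odds in self.causal_genes.items():
            if odds <= 0:
                raise ValueError(f"carrier odds ratio for {g} must be > 0")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total

    def gene_names(self) -> list:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


def _balding_nichols(rng, p_anc: float, fst: float, n_pops: int) -> np.ndarray:
    if fst == 0.0:
        return np.full(n_pops, p_anc)
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b, size=n_pops)


def simulate_cohort(config: SimulationConfig):
    """Generate (CohortBundle, truth table).

    The truth table has one row per variant: gene, model, causal flag and
    ``planted_fail`` -- the single cascade rule a decoy was built to fail
    ('' for qualifying variants).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    unknown = set(config.causal_genes) - set(genes)
    if unknown:
        raise ValueError(f"causal genes not in the gene panel: {sorted(unknown)}")

    n = config.n_total
    pop = rng.choice(len(config.pop_fractions), size=n, p=config.pop_fractions)
    sex = rng.choice([0, 1], size=n)  # 1 = male
    age = rng.normal(60.0, 10.0, size=n).clip(18, 95)

    # gene-level annotation records; a subset of genes is planted with high
    # GDI so every one of their variants fails the GDI rule
    gdi_decoys = set(
        rng.choice(
            [g for g in genes if g not in config.causal_genes],
            size=min(config.n_gdi_decoy_genes, config.n_genes),
            replace=False,
        )
    )
    gene_records = {}
    for g in genes:
        msc_lower = rng.uniform(2.0, 6.0)
        gdi = rng.uniform(14.5, 30.0) if g in gdi_decoys else rng.uniform(0.5, 12.0)
        gene_records[g] = GeneRecord(
            symbol=g, msc=msc_lower + rng.uniform(0.5, 2.0), msc_ci95_lower=msc_lower,
            gdi=gdi,
        )

    variants, columns, truth_rows = [], [], []
    pos = 1000
    decoy_rules = ["impact", "msc", "maf"]
    decoy_cycle = 0

    for g in genes:
        causal = g in config.causal_genes
        n_del = max(1, rng.poisson(config.mean_variants_per_gene))
        n_syn = rng.poisson(config.mean_synonymous_per_gene)

        # rare deleterious-candidate variants
        p_anc = np.exp(
            rng.uniform(
                np.log(config.rare_maf_range[0]), np.log(config.rare_maf_range[1]), n_del
            )
        )
        if causal:
            # rescale so the expected carrier frequency hits the target
            carrier = 1.0 - np.prod((1.0 - p_anc) ** 2)
            target = config.causal_carrier_freq
            if carrier > 0:
                scale = np.log1p(-target) / np.log1p(-carrier)
                p_anc = 1.0 - (1.0 - p_anc) ** scale
        for p0 in p_anc:
            pos += rng.integers(50, 500)
            if causal:
                # causal variants are kept panmictic so the configured
                # carrier frequency is realized reliably
                p_pops = np.full(len(config.pop_fractions), p0)
            else:
                p_pops = _balding_nichols(
                    rng, p0, config.fst, len(config.pop_fractions)
                )
            dosage = rng.binomial(2, p_pops[pop]).astype(float)
            gr = gene_records[g]
            if causal or rng.random() > config.decoy_fraction or g in gdi_decoys:
                # qualifying annotation (or GDI decoy: fails only via the gene)
                high = rng.random() < 0.3
                consequence = (
                    "stop_gained" if high else "missense_variant"
                )
                cadd = None if high else gr.msc_ci95_lower + rng.uniform(1.0, 20.0)
                if high:
                    cadd = rng.uniform(25.0, 45.0)
                pop_af = min(rng.uniform(0.2, 0.9) * 0.01, max(p0, 1e-5))
                planted = "gdi" if g in gdi_decoys else ""
            else:
                rule = decoy_rules[decoy_cycle % 3]
                decoy_cycle += 1
                if rule == "impact":
                    consequence = "intron_variant"
                    cadd = rng.uniform(0.0, 10.0)
                    pop_af = min(0.009 * rng.random(), max(p0, 1e-5))
                elif rule == "msc":
                    consequence = "missense_variant"
                    cadd = gr.msc_ci95_lower - rng.uniform(0.5, 2.0)
                    pop_af = min(0.009 * rng.random(), max(p0, 1e-5))
                else:  # maf
                    consequence = "missense_variant"
                    cadd = gr.msc_ci95_lower + rng.uniform(1.0, 20.0)
                    pop_af = rng.uniform(0.011, 0.2)
                planted = rule
            v = VariantSite(
                chrom="1",
                pos=pos,
                ref="A",
                alt="T",
                gene=g,
                consequence=consequence,
                cadd=cadd,
                pop_af={
                    ("gnomAD", "NFE"): float(pop_af),
                    ("1KGP", "EUR"): float(pop_af * rng.uniform(0.5, 1.0)),
                },
                annotated=True,
            )
            variants.append(v)
            columns.append(dosage)
            truth_rows.append(
                {
                    "gene": g,
                    "model": "deleterious",
                    "causal": bool(causal),
                    "planted_fail": planted,
                }
            )

        # synonymous variants for the neutral model
        for _ in range(n_syn):
            pos += rng.integers(50, 500)
            p0 = np.exp(
                rng.uniform(
                    np.log(config.rare_maf_range[0]), np.log(config.rare_maf_range[1])
                )
            )
            p_pops = _balding_nichols(rng, p0, config.fst, len(config.pop_fractions))
            dosage = rng.binomial(2, p_pops[pop]).astype(float)
            v = VariantSite(
                chrom="1",
                pos=pos,
                ref="G",
                alt="C",
                gene=g,
                consequence="synonymous_variant",
                cadd=rng.uniform(0.0, 10.0),
                pop_af={("gnomAD", "NFE"): float(min(0.009 * rng.random(), max(p0, 1e-5)))},
                annotated=True,
            )
            variants.append(v)
            columns.append(dosage)
            truth_rows.append(
                {"gene": g, "model": "synonymous", "causal": False, "planted_fail": ""}
            )

    # common structure variants (unannotated; used for PCA / LD pruning)
    for _ in range(config.n_common_variants):
        pos += rng.integers(50, 500)
        p0 = rng.uniform(*config.common_maf_range)
        p_pops = _balding_nichols(rng, p0, config.fst, len(config.pop_fractions))
        dosage = rng.binomial(2, p_pops[pop]).astype(float)
        variants.append(
            VariantSite(chrom="2", pos=pos, ref="C", alt="G", annotated=False)
        )
        columns.append(dosage)
        truth_rows.append(
            {"gene": "", "model": "common", "causal": False, "planted_fail": ""}
        )

    G = np.column_stack(columns)
    # mimic joint calling: only sites observed in the cohort enter the VCF
    observed = np.nansum(G, axis=0) > 0
    G = G[:, observed]
    variants = [v for v, keep in zip(variants, observed) if keep]
    truth_rows = [r for r, keep in zip(truth_rows, observed) if keep]

    # disease model on carriers (or dosage burden) of causal genes
    truth = pd.DataFrame(truth_rows)
    eta = np.zeros(n)
    for g, odds in config.causal_genes.items():
        idx = truth.index[(truth["gene"] == g) & (truth["model"] == "deleterious")]
        burden = G[:, idx].sum(axis=1)
        x = burden if config.dosage_model else (burden > 0).astype(float)
        eta += np.log(odds) * x
    eta += config.covariate_effects.get("sex", 0.0) * sex
    eta += config.covariate_effects.get("age", 0.0) * (age - 60.0) / 10.0

    target = config.case_fraction
    b0 = brentq(lambda b: expit(b + eta).mean() - target, -30.0, 30.0)
    y = rng.random(n) < expit(b0 + eta)
    if y.all() or not y.any():
        raise ValueError("degenerate phenotype draw; check the configuration")

    samples = [
        SampleRecord(
            sample_id=f"S{i:04d}",
            sex="male" if sex[i] else "female",
            phenotype="case" if y[i] else "control",
            age=float(age[i]),
            ancestry_label=f"POP{pop[i] + 1}",
        )
        for i in range(n)
    ]
    bundle = CohortBundle(
        samples=samples, variants=variants, genotypes=G, gene_annotations=gene_records
    )
    recompute_cohort_freqs(bundle)
    truth["chrom"] = [v.chrom for v in variants]
    truth["pos"] = [v.pos for v in variants]
    truth["ref"] = [v.ref for v in variants]
    truth["alt"] = [v.alt for v in variants]
    return bundle, truth


# ---------------------------------------------------------------------------
# PPI network, distances, gene sets

def simulate_ppi(config: SimulationConfig, genes=None) -> nx.Graph:
    """Stochastic-block-model PPI: dense high-weight modules, sparse weak
    background edges.  Module 0 contains the causal genes (the planted
    case-enriched cluster)."""
    rng = np.random.default_rng(config.seed + 1)
    genes = list(genes) if genes is not None else config.gene_names()
    causal = [g for g in config.causal_genes if g in genes]
    others = [g for g in genes if g not in config.causal_genes]
    rng.shuffle(others)

    modules = []
    first = causal + others[: max(0, config.ppi_module_size - len(causal))]
    modules.append(first[: max(config.ppi_module_size, len(causal))])
    used = len(first)
    for _ in range(config.ppi_modules - 1):
        modules.append(others[used : used + config.ppi_module_size])
        used += config.ppi_module_size
    membership = {g: k for k, mod in enumerate(modules) for g in mod}

    g_net = nx.Graph()
    g_net.add_nodes_from(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            same = membership.get(a, -1) == membership.get(b, -2)
            if same and rng.random() < config.ppi_p_in:
                w = rng.uniform(*config.ppi_w_in)
            elif rng.random() < config.ppi_p_out:
                w = rng.uniform(*config.ppi_w_out)
            else:
                continue
            g_net.add_edge(a, b, weight=float(w))
    g_net.graph["modules"] = [list(m) for m in modules]
    return g_net


def simulate_distances(
    network: nx.Graph, sentinel: float = 50.0
) -> DistanceMatrix:
    """All-pairs biological distances: shortest paths under edge length
    -log(weight), disconnected pairs set to the sentinel."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for a, b, data in network.edges(data=True):
        g.add_edge(a, b, length=-np.log(max(data["weight"], 1e-12)))
    nodes = sorted(g.nodes)
    mat = np.full((len(nodes), len(nodes)), sentinel, dtype=float)
    np.fill_diagonal(mat, 0.0)
    index = {n: i for i, n in enumerate(nodes)}
    n_disconnected = 0
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for dst, d in lengths.items():
            mat[index[src], index[dst]] = d
    n_disconnected = int((mat >= sentinel).sum() - 0)
    dm = DistanceMatrix(pd.DataFrame(mat, index=nodes, columns=nodes))
    dm.df.attrs["n_disconnected_pairs"] = n_disconnected // 2
    return dm


def simulate_gene_sets(
    config: SimulationConfig, network: nx.Graph, known_ibd, known_pd
) -> GeneSetCollection:
    """GMT-style collection: one planted term per PPI module (module 0 thus
    contains the causal genes), plus random filler terms."""
    rng = np.random.default_rng(config.seed + 2)
    genes = config.gene_names()
    sets = {}
    for k, mod in enumerate(network.graph.get("modules", [])):
        extra = [g for g in (known_ibd if k % 2 == 0 else known_pd) if g not in mod]
        members = list(mod) + list(rng.choice(extra, size=min(3, len(extra)), replace=False))
        if members:
            sets[f"PLANTED_{k}"] = (f"planted module {k}", members)
    for t in range(config.n_gene_set_terms):
        size = int(rng.integers(5, min(25, max(6, len(genes)))))
        members = list(rng.choice(genes, size=size, replace=False))
        sets[f"RANDOM_{t}"] = (f"random term {t}", members)
    return GeneSetCollection(name="synthetic", sets=sets)


def simulate_known_panels(config: SimulationConfig, n_ibd: int = 25, n_pd: int = 15):
    """Known-disease gene panels; each panel includes part of the planted
    module so candidate pools sit closer to the panels than random sets."""
    rng = np.random.default_rng(config.seed + 3)
    genes = config.gene_names()
    causal = list(config.causal_genes)
    rest = [g for g in genes if g not in causal]
    ibd = causal[: max(1, len(causal) // 2)] + list(
        rng.choice(rest, size=min(n_ibd, len(rest)), replace=False)
    )
    remaining = [g for g in rest if g not in ibd]
    pd_panel = causal[: max(1, len(causal) // 3)] + list(
        rng.choice(remaining, size=min(n_pd, len(remaining)), replace=False)
    )
    return sorted(set(ibd)), sorted(set(pd_panel))


# ---------------------------------------------------------------------------
# Electronic health records

def simulate_ehr(
    config: SimulationConfig, bundle: CohortBundle, truth: pd.DataFrame, pmap=None
) -> pd.DataFrame:
    """ICD diagnosis table (sample_id, icd_version, icd_code) under the
    configured per-phecode prevalences and carrier odds ratios."""
    from .phewas import toy_phecode_map

    pmap = pmap or toy_phecode_map()
    rng = np.random.default_rng(config.seed + 4)
    code_choices = {}
    for (version, code), phe in pmap.icd_to_phecode.items():
        code_choices.setdefault(phe, []).append((version, code))

    rows = []
    for phe, (prev, odds, carrier_genes) in config.phecode_spec.items():
        if phe not in code_choices:
            raise ValueError(f"phecode {phe} absent from the phecode map")
        carrier = np.zeros(bundle.n_samples, dtype=bool)
        for g in carrier_genes:
            idx = truth.index[(truth["gene"] == g) & (truth["model"] == "deleterious")]
            carrier |= np.nansum(bundle.genotypes[:, idx], axis=1) > 0
        if prev <= 0.0:
            continue
        if prev >= 1.0:
            prob = np.ones(bundle.n_samples)
        else:
            prob = expit(logit(prev) + np.log(odds) * carrier)
        hit = rng.random(bundle.n_samples) < prob
        for i in np.flatnonzero(hit):
            version, code = code_choices[phe][
                rng.integers(len(code_choices[phe]))
            ]
            rows.append(
                {
                    "sample_id": bundle.sample_ids[i],
                    "icd_version": version,
                    "icd_code": code,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "icd_version", "icd_code"])


# ---------------------------------------------------------------------------
# Writing a full synthetic input directory

def write_synthetic_inputs(outdir, config: SimulationConfig) -> dict:
    """Materialize every pipeline input as files under ``outdir`` and return
    the in-memory objects as well."""
    from pathlib import Path

    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle, truth = simulate_cohort(config)
    network = simulate_ppi(config)
    distances = simulate_distances(network, sentinel=config.distance_sentinel)
    known_ibd, known_pd = simulate_known_panels(config)
    collection = simulate_gene_sets(config, network, known_ibd, known_pd)
    icd = simulate_ehr(config, bundle, truth) if config.phecode_spec else pd.DataFrame(
        columns=["sample_id", "icd_version", "icd_code"]
    )

    io_mod.write_vcf(outdir / "cohort.vcf", bundle)
    pd.DataFrame(
        {
            "sample_id": bundle.sample_ids,
            "sex": [s.sex for s in bundle.samples],
            "age": [s.age for s in bundle.samples],
            "phenotype": [s.phenotype for s in bundle.samples],
            "ancestry": [s.ancestry_label for s in bundle.samples],
        }
    ).to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)

    var_rows = []
    for v in bundle.variants:
        if not v.annotated:
            continue
        var_rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence,
                "cadd": v.cadd,
                "af_gnomAD_NFE": v.pop_af.get(("gnomAD", "NFE")),
                "af_1KGP_EUR": v.pop_af.get(("1KGP", "EUR")),
            }
        )
    pd.DataFrame(var_rows).to_csv(outdir / "variant_annotations.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "symbol": [g.symbol for g in bundle.gene_annotations.values()],
            "msc": [g.msc for g in bundle.gene_annotations.values()],
            "msc_ci95_lower": [
                g.msc_ci95_lower for g in bundle.gene_annotations.values()
            ],
            "gdi": [g.gdi for g in bundle.gene_annotations.values()],
        }
    ).to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False)

    io_mod.write_edge_list(outdir / "ppi_edges.tsv", network)
    io_mod.write_distance_matrix(outdir / "distances.tsv", distances)
    io_mod.write_gmt(outdir / "gene_sets.gmt", collection)
    io_mod.write_gene_list(outdir / "known_ibd.txt", known_ibd)
    io_mod.write_gene_list(outdir / "known_pd.txt", known_pd)
    icd.to_csv(outdir / "icd_diagnoses.csv", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    return {
        "bundle": bundle,
        "truth": truth,
        "network": network,
        "distances": distances,
        "collection": collection,
        "known_ibd": known_ibd,
        "known_pd": known_pd,
        "icd": icd,
    }
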