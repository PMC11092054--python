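"""Qualifying-variant filtering cascade.

Two variant models are supported:

* ``deleterious`` -- high-impact consequences pass outright; moderate-impact
  consequences must additionally have CADD strictly above the lower bound of
  the gene's 95% MSC confidence interval.  Both classes must sit in a gene
  with GDI below the general-disease cutoff (default 13.84) and have a
  maximum reference-population allele frequency below 1%.
* ``synonymous`` -- the neutral model: synonymous consequence plus the same
  GDI and population-MAF rules (no CADD/MSC rule).

For each rejected variant the first failed rule is recorded in the fixed
order impact, msc, gdi, maf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import CohortBundle, GeneRecord, VariantSite

HIGH_IMPACT = frozenset(
    {
        "start_lost",
        "stop_lost",
        "stop_gained",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "protein_altering_variant",
        "start_retained_variant",
        "stop_retained_variant",
        "frameshift_variant",
    }
)

MODERATE_IMPACT = frozenset(
    {"missense_variant", "inframe_insertion", "inframe_deletion"}
)

#: severity order used when a variant carries several consequence terms
_SEVERITY = {"high": 0, "moderate": 1, "synonymous": 2, "other": 3}

GDI_CUTOFF_GENERAL = 13.84  # general disease model cutoff
MAX_POP_AF = 0.01


def classify_impact(consequence: str) -> str:
    """Map a sequence-ontology consequence term to an impact class.

    Multiple ampersand- or comma-separated terms are resolved to the most
    severe one (high > moderate > synonymous > other).
    """
    if not consequence:
        raise ValueError("empty consequence term")
    terms = consequence.replace(",", "&").split("&")
    classes = []
    for t in terms:
        t = t.strip()
        if t in HIGH_IMPACT:
            classes.append("high")
        elif t in MODERATE_IMPACT:
            classes.append("moderate")
        elif t == "synonymous_variant":
            classes.append("synonymous")
        else:
            classes.append("other")
    return min(classes, key=_SEVERITY.__getitem__)


def passes_deleterious(
    v: VariantSite,
    g: GeneRecord,
    gdi_cutoff: float = GDI_CUTOFF_GENERAL,
    max_pop_af: float = MAX_POP_AF,
):
    """Apply the deleterious cascade; returns (passed, failed_rule_or_None).

    Rule order for the reported failure: impact, msc, gdi, maf.  Population
    frequencies absent from the annotation are treated as 0 (unseen).
    """
    impact = classify_impact(v.consequence)
    if impact not in ("high", "moderate"):
        return False, "impact"
    if impact == "moderate":
        if v.cadd is None:
            raise ValueError(f"moderate-impact variant {v.key} lacks a CADD score")
        if g.msc_ci95_lower is None:
            raise ValueError(f"gene {g.symbol} lacks an MSC CI lower bound")
        if not v.cadd > g.msc_ci95_lower:  # strict: must exceed the lower bound
            return False, "msc"
    if g.gdi is None or not g.gdi < gdi_cutoff:
        return False, "gdi"
    if not v.max_pop_af < max_pop_af:
        return False, "maf"
    return True, None


def passes_synonymous(
    v: VariantSite,
    g: GeneRecord,
    gdi_cutoff: float = GDI_CUTOFF_GENERAL,
    max_pop_af: float = MAX_POP_AF,
):
    """Neutral-model filter: synonymous consequence + GDI + population MAF rules."""
    if classify_impact(v.consequence) != "synonymous":
        return False, "impact"
    if g.gdi is None or not g.gdi < gdi_cutoff:
        return False, "gdi"
    if not v.max_pop_af < max_pop_af:
        return False, "maf"
    return True, None


@dataclass
class QualifyingVariantSet:
    """Per-gene qualifying variant indices plus per-variant provenance."""

    model: str  # 'deleterious' | 'synonymous'
    per_gene: dict = field(default_factory=dict)  # gene -> list of variant indices
    provenance: dict = field(default_factory=dict)  # variant index -> failed rule/None

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    @property
    def n_variants(self) -> int:
        return sum(len(v) for v in self.per_gene.values())

    def gene_variants(self, gene: str) -> list:
        return self.per_gene.get(gene, [])


def build_qualifying_sets(
    bundle: CohortBundle,
    model: str = "deleterious",
    gdi_cutoff: float = GDI_CUTOFF_GENERAL,
    max_pop_af: float = MAX_POP_AF,
) -> QualifyingVariantSet:
    """Run the cascade over every annotated variant of the bundle.

    Unannotated variants and variants in genes without MSC/GDI records are
    skipped (recorded as 'unannotated').  Genes with zero qualifying variants
    are omitted from ``per_gene``.
    """
    if model not in ("deleterious", "synonymous"):
        raise ValueError(f"unknown model {model!r}")
    rule = passes_deleterious if model == "deleterious" else passes_synonymous
    out = QualifyingVariantSet(model=model)
    for j, v in enumerate(bundle.variants):
        if not v.annotated or v.gene is None:
            out.provenance[j] = "unannotated"
            continue
        g = bundle.gene_annotations.get(v.gene)
        if g is None:
            out.provenance[j] = "unannotated"
            continue
        ok, failed = rule(v, g, gdi_cutoff=gdi_cutoff, max_pop_af=max_pop_af)
        out.provenance[j] = failed
        if ok:
            out.per_gene.setdefault(v.gene, []).append(j)
    return out


def qualifying_table(bundle: CohortBundle, qset: QualifyingVariantSet):
    """Long-format provenance table (variant key, gene, model, pass, failed rule)."""
    import pandas as pd

    rows = []
    for j, v in enumerate(bundle.variants):
        failed = qset.provenance.get(j)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "model": qset.model,
                "pass": failed is None,
                "failed_rule": failed or "",
            }
        )
    return pd.DataFrame(rows)
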