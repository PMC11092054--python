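"""Readers and writers for the pipeline's external formats.

VCF is read through cyvcf2; annotation tables, gene-set GMT files, weighted
edge lists, distance matrices, gene lists and ICD/phecode tables are plain
TSV/CSV handled with pandas.  Multiallelic VCF records are split into
biallelic sites at read time (dosage refers to the named alternate allele).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from .types import (
    CohortBundle,
    DistanceMatrix,
    GeneRecord,
    GeneSetCollection,
    SampleRecord,
    VariantSite,
    recompute_cohort_freqs,
)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, sample_phenotypes) -> CohortBundle:
    """Read a multi-sample VCF into a CohortBundle (no functional annotations yet).

    Parameters
    ----------
    path : str or Path
        VCF file (plain or bgzipped).
    sample_phenotypes : pandas.DataFrame
        Must contain ``sample_id`` and ``phenotype`` ('case'/'control');
        optional ``sex`` and ``age`` columns.

    Dosage is the count of the named alternate allele; missing genotypes are
    nan and excluded from MAC/MAF denominators.  Multiallelic records are
    split into one site per alternate allele.
    """
    from cyvcf2 import VCF

    pheno = sample_phenotypes.set_index("sample_id")
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in pheno.index]
    if unknown:
        raise ValueError(
            f"samples in VCF absent from phenotype table: {', '.join(unknown)}"
        )

    samples = []
    for sid in vcf_samples:
        row = pheno.loc[sid]
        age = row.get("age")
        ancestry = row.get("ancestry")
        samples.append(
            SampleRecord(
                sample_id=sid,
                sex=row.get("sex", "female"),
                phenotype=row["phenotype"],
                age=None if age is None or pd.isna(age) else float(age),
                ancestry_label=None if ancestry is None or pd.isna(ancestry) else str(ancestry),
            )
        )

    variants, columns = [], []
    for rec in vcf:
        # genotypes: per sample [allele_a, allele_b, phased]; -1 = missing call
        gts = rec.genotypes
        for k, alt in enumerate(rec.ALT, start=1):
            dosage = np.full(len(vcf_samples), np.nan)
            for i, g in enumerate(gts):
                alleles = [a for a in g[:-1] if a >= 0]
                if alleles:
                    dosage[i] = float(sum(a == k for a in alleles))
            variants.append(
                VariantSite(chrom=str(rec.CHROM), pos=int(rec.POS), ref=rec.REF, alt=alt)
            )
            columns.append(dosage)
    vcf.close()

    G = (
        np.column_stack(columns)
        if columns
        else np.empty((len(vcf_samples), 0))
    )
    bundle = CohortBundle(samples=samples, variants=variants, genotypes=G)
    recompute_cohort_freqs(bundle)
    return bundle


def write_vcf(path, bundle: CohortBundle) -> None:
    """Write the bundle's genotypes as an uncompressed VCFv4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in bundle.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(bundle.sample_ids)
            + "\n"
        )
        for j, v in enumerate(bundle.variants):
            col = bundle.genotypes[:, j]
            gts = []
            for d in col:
                if np.isnan(d):
                    gts.append("./.")
                elif d == 0:
                    gts.append("0/0")
                elif d == 1:
                    gts.append("0/1")
                else:
                    gts.append("1/1")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation tables

#: columns of the per-variant annotation TSV; every further column whose name
#: looks like ``af_<source>_<population>`` is folded into VariantSite.pop_af.
VARIANT_TSV_KEY = ["chrom", "pos", "ref", "alt"]


def read_annotations(variant_tsv, gene_tsv, bundle: CohortBundle) -> CohortBundle:
    """Attach consequence/CADD/population frequencies and gene MSC/GDI records.

    Variants in the bundle absent from the table remain flagged unannotated;
    duplicate keys or frequencies outside [0,1] raise.
    """
    vtab = pd.read_csv(variant_tsv, sep="\t", dtype={"chrom": str})
    if vtab.duplicated(subset=VARIANT_TSV_KEY).any():
        dups = vtab[vtab.duplicated(subset=VARIANT_TSV_KEY, keep=False)]
        raise ValueError(f"duplicate variant keys in annotation table:\n{dups.head()}")
    af_cols = [c for c in vtab.columns if c.startswith("af_")]
    for c in af_cols:
        bad = vtab[c].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"allele frequency outside [0,1] in column {c}")

    lut = {}
    for row in vtab.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        lut[key] = row

    for v in bundle.variants:
        row = lut.get(v.key)
        if row is None:
            v.annotated = False
            continue
        v.gene = row.gene
        v.consequence = row.consequence
        cadd = getattr(row, "cadd", None)
        v.cadd = None if cadd is None or pd.isna(cadd) else float(cadd)
        v.pop_af = {}
        for c in af_cols:
            val = getattr(row, c)
            if not pd.isna(val):
                source, _, population = c[3:].partition("_")
                v.pop_af[(source, population)] = float(val)
        v.annotated = True

    gtab = pd.read_csv(gene_tsv, sep="\t")
    if gtab["symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in gene annotation table")
    bundle.gene_annotations = {
        row.symbol: GeneRecord(
            symbol=row.symbol,
            msc=None if pd.isna(row.msc) else float(row.msc),
            msc_ci95_lower=(
                None if pd.isna(row.msc_ci95_lower) else float(row.msc_ci95_lower)
            ),
            gdi=None if pd.isna(row.gdi) else float(row.gdi),
        )
        for row in gtab.itertuples(index=False)
    }
    return bundle


def write_variant_annotations(path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets, networks, distances, gene lists

def read_gmt(path, name=None) -> GeneSetCollection:
    """GMT: one set per line -- term, description, genes (tab-separated)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, desc, >=1 gene")
            sets[parts[0]] = (parts[1], parts[2:])
    return GeneSetCollection(name=name or str(path), sets=sets)


def write_gmt(path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for term in collection.terms():
            desc, genes = collection.sets[term]
            fh.write("\t".join([term, desc] + list(genes)) + "\n")


def read_edge_list(path) -> nx.Graph:
    """Weighted PPI edge list: geneA <tab> geneB <tab> weight, weight in [0,1]."""
    g = nx.Graph()
    tab = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "w"])
    for row in tab.itertuples(index=False):
        w = float(row.w)
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"edge weight {w} outside [0,1] for {row.a}-{row.b}")
        if row.a == row.b:
            raise ValueError(f"self-loop on {row.a}")
        g.add_edge(row.a, row.b, weight=w)
    return g


def write_edge_list(path, g: nx.Graph) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.6g}\n")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df)


def write_distance_matrix(path, dm: DistanceMatrix) -> None:
    dm.df.to_csv(path, sep="\t")


def read_gene_list(path) -> list:
    """Plain text, one gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Config and run manifest

def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int, inputs) -> dict:
    """Record config, seed and input checksums so a run is reproducible."""
    manifest = {
        "seed": int(seed),
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
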