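"""Shared domain containers used by every stage of the pipeline.

The unit of analysis is a :class:`CohortBundle`: sample records, variant
sites, an n_samples x n_variants dosage matrix (alternate-allele counts,
``nan`` for missing genotypes) and per-gene annotation records (MSC, GDI).
All stages consume and return these containers rather than raw files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class SampleRecord:
    """One cohort member. ``phenotype`` is 'case' or 'control'."""

    sample_id: str
    sex: str = "female"  # 'female' | 'male'
    phenotype: str = "control"  # 'case' | 'control'
    age: Optional[float] = None
    ancestry_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.phenotype not in ("case", "control"):
            raise ValueError(f"phenotype must be case/control, got {self.phenotype!r}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")


@dataclass
class VariantSite:
    """One biallelic site (1-based VCF coordinates).

    ``pop_af`` maps (source, population) -> reference-panel allele frequency,
    e.g. ('gnomAD', 'NFE') -> 5e-4.  ``cohort_maf`` is the folded in-cohort
    frequency, min(af, 1-af).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    cadd: Optional[float] = None
    pop_af: dict = field(default_factory=dict)
    cohort_mac: int = 0
    cohort_maf: float = 0.0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for key, af in self.pop_af.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"pop_af[{key}]={af} outside [0,1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_pop_af(self) -> float:
        """Maximum allele frequency over all reference populations (0 if unseen)."""
        return max(self.pop_af.values(), default=0.0)


@dataclass
class GeneRecord:
    """Per-gene deleteriousness annotations.

    msc_ci95_lower is the lower bound of the 95% CI of the gene's mutation
    significance cutoff (a CADD-scale threshold); gdi is the gene damage index.
    """

    symbol: str
    msc: Optional[float] = None
    msc_ci95_lower: Optional[float] = None
    gdi: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            self.msc is not None
            and self.msc_ci95_lower is not None
            and self.msc_ci95_lower > self.msc
        ):
            raise ValueError(f"{self.symbol}: msc_ci95_lower > msc")
        if self.gdi is not None and self.gdi < 0:
            raise ValueError(f"{self.symbol}: gdi must be >= 0")


@dataclass
class CohortBundle:
    """Genotypes plus sample/variant/gene metadata; the object every stage consumes."""

    samples: list  # of SampleRecord
    variants: list  # of VariantSite
    genotypes: np.ndarray  # samples x variants, float with nan = missing
    gene_annotations: dict = field(default_factory=dict)  # symbol -> GeneRecord

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.phenotype == "case" for s in self.samples])

    @property
    def phenotype(self) -> np.ndarray:
        """0/1 case indicator."""
        return self.case_mask.astype(float)

    def subset_samples(self, keep: np.ndarray) -> "CohortBundle":
        """New bundle restricted to a boolean mask or index array of samples."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        sub = CohortBundle(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            genotypes=self.genotypes[idx, :].copy(),
            gene_annotations=self.gene_annotations,
        )
        recompute_cohort_freqs(sub)
        return sub

    def gene_record(self, symbol: str) -> Optional[GeneRecord]:
        return self.gene_annotations.get(symbol)


def recompute_cohort_freqs(bundle: CohortBundle) -> None:
    """Refresh cohort_mac / cohort_maf from the dosage matrix.

    Missing genotypes are excluded from the allele-count denominator.
    """
    G = bundle.genotypes
    for j, v in enumerate(bundle.variants):
        col = G[:, j]
        obs = col[~np.isnan(col)]
        n_alleles = 2 * obs.size
        if n_alleles == 0:
            v.cohort_mac, v.cohort_maf = 0, 0.0
            continue
        alt_count = int(round(obs.sum()))
        af = alt_count / n_alleles
        v.cohort_mac = min(alt_count, n_alleles - alt_count)
        v.cohort_maf = min(af, 1.0 - af)


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (GMT semantics): term -> (description, genes)."""

    name: str
    sets: dict  # term_id -> (description, list of genes)

    def __post_init__(self) -> None:
        for term, (_desc, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"{self.name}/{term}: empty gene set")
            if len(set(genes)) != len(genes):
                raise ValueError(f"{self.name}/{term}: duplicate genes in set")

    def genes(self, term: str) -> list:
        return self.sets[term][1]

    def terms(self) -> list:
        return sorted(self.sets)


class DistanceMatrix:
    """Square symmetric gene-gene biological distance matrix (zero diagonal)."""

    def __init__(self, df: pd.DataFrame, tol: float = 1e-9):
        if df.shape[0] != df.shape[1]:
            raise ValueError("distance matrix must be square")
        if list(df.index) != list(df.columns):
            raise ValueError("distance matrix row/column labels differ")
        a = df.to_numpy(dtype=float)
        if np.nanmax(np.abs(a - a.T)) > tol:
            raise ValueError("distance matrix asymmetric beyond tolerance")
        if np.nanmin(a) < -tol:
            raise ValueError("negative distance")
        if np.nanmax(np.abs(np.diag(a))) > tol:
            raise ValueError("distance matrix diagonal must be zero")
        self.df = df
        self.genes = list(df.index)
        self._index = {g: i for i, g in enumerate(self.genes)}
        self.values = a

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene], :]
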