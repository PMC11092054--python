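import numpy as np
import pandas as pd
import pytest

from ibdpd.simulate import SimulationConfig, simulate_cohort
from ibdpd.types import CohortBundle, GeneRecord, SampleRecord, VariantSite


@pytest.fixture(scope="session")
def null_cohort():
    """Small two-population cohort with no causal genes."""
    cfg = SimulationConfig(
        n_cases=70, n_controls=430, n_genes=60, fst=0.05, seed=11
    )
    bundle, truth = simulate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def causal_cohort():
    """Cohort with a strong causal gene plus a planted 6-gene causal module
    (the module genes carry milder carrier odds ratios)."""
    cfg = SimulationConfig(
        n_cases=70,
        n_controls=430,
        n_genes=60,
        causal_genes={
            "G0001": 8.0,
            "G0002": 3.0,
            "G0003": 3.0,
            "G0004": 3.0,
            "G0005": 3.0,
            "G0006": 3.0,
        },
        seed=5,
    )
    bundle, truth = simulate_cohort(cfg)
    return cfg, bundle, truth


def make_toy_bundle():
    """Hand-built 4-sample, 3-variant bundle for exact-value tests."""
    samples = [
        SampleRecord("A", "female", "case"),
        SampleRecord("B", "male", "case"),
        SampleRecord("C", "female", "control"),
        SampleRecord("D", "male", "control"),
    ]
    variants = [
        VariantSite("1", 100, "A", "T", gene="G1", consequence="missense_variant",
                    cadd=25.0, pop_af={("gnomAD", "NFE"): 5e-4}, annotated=True),
        VariantSite("1", 200, "C", "G", gene="G1", consequence="synonymous_variant",
                    cadd=2.0, pop_af={("gnomAD", "NFE"): 1e-3}, annotated=True),
        VariantSite("1", 300, "G", "A", gene="G2", consequence="stop_gained",
                    cadd=40.0, pop_af={}, annotated=True),
    ]
    G = np.array(
        [[1.0, 0.0, 2.0],
         [0.0, 1.0, 0.0],
         [0.0, 0.0, np.nan],
         [1.0, 1.0, 0.0]]
    )
    genes = {
        "G1": GeneRecord("G1", msc=5.0, msc_ci95_lower=3.3, gdi=5.0),
        "G2": GeneRecord("G2", msc=4.0, msc_ci95_lower=2.0, gdi=8.0),
    }
    from ibdpd.types import recompute_cohort_freqs

    b = CohortBundle(samples=samples, variants=variants, genotypes=G,
                     gene_annotations=genes)
    recompute_cohort_freqs(b)
    return b


@pytest.fixture
def toy_bundle():
    return make_toy_bundle()


@pytest.fixture
def phenotype_frame():
    return pd.DataFrame(
        {
            "sample_id": ["A", "B", "C", "D"],
            "phenotype": ["case", "case", "control", "control"],
            "sex": ["female", "male", "female", "male"],
            "age": [60.0, 55.0, 62.0, 58.0],
        }
    )
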