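"""Generate the synthetic study inputs.

Emulates the discovery design -- a small IBD-PD case group against
1KGP-scale controls -- with two causal genes at carrier odds ratio 8,
a planted case-enriched PPI module, and two phecodes (a Parkinson's
phecode and a Crohn's phecode) whose carriers have elevated odds.
Writes VCF, annotation tables, network, distances, gene sets, ICD table
and the truth table under results/synthetic/.
"""

import sys
from pathlib import Path

from ibdpd.simulate import SimulationConfig, write_synthetic_inputs

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def default_config(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(
        n_cases=67,
        n_controls=426,
        n_genes=200,
        causal_genes={"G0001": 8.0, "G0002": 8.0},
        phecode_spec={
            "332": (0.03, 6.0, ["G0001"]),
            "555.1": (0.04, 6.0, ["G0002"]),
            "401.1": (0.25, 1.0, []),
        },
        seed=seed,
    )


def main(seed: int = 1) -> None:
    cfg = default_config(seed)
    objs = write_synthetic_inputs(OUT, cfg)
    b, t = objs["bundle"], objs["truth"]
    n_cases = int(b.case_mask.sum())
    print(f"cohort: {b.n_samples} samples ({n_cases} cases), {b.n_variants} variants")
    print(f"causal variants: {int(t['causal'].sum())} in {sorted(cfg.causal_genes)}")
    print(f"PPI: {objs['network'].number_of_nodes()} genes, "
          f"{objs['network'].number_of_edges()} edges")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
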