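"""Build the in-silico screen: reference genome, annotation, planted truth.

Writes a 100-kb random single-chromosome reference tiled with 150 genes
(~26 insertion clones per gene at 63% TA-site saturation), plants 5 genes
with a 30-fold survival advantage under treatment, and writes the pipeline
config.  Inputs land in scratch/analysis/inputs (sequence data); the design
summary table lands in results/.

Usage: python analysis/01_prepare_screen.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tnscreen import ScreenConfig, find_ta_sites
from tnscreen.config import DEFAULT_BARCODES
from tnscreen.pipeline import synthetic_reference
from tnscreen.genome import write_gene_gff3, write_genome_fasta
from tnscreen.simulate import FitnessMap

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "scratch" / "analysis" / "inputs"
RESULTS = ROOT / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    INPUTS.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)
    genome, catalog, ta = synthetic_reference(rng, 99_900, 150, gid=f"screen{args.seed}")
    write_genome_fasta(genome, INPUTS / "genome.fasta")
    genes = [f for f in catalog.features if f.kind == "gene"]
    write_gene_gff3(genes, genome, INPUTS / "genes.gff3")

    planted = sorted(
        genes[i].feature_id for i in rng.choice(len(genes), 5, replace=False)
    )
    FitnessMap({g: 30.0 for g in planted}).write_tsv(INPUTS / "fitness.tsv")

    screen = ScreenConfig(reads_per_sample=100_000, rng_seed=args.seed)
    config = {
        "genome_fasta": "genome.fasta",
        "genes_gff3": "genes.gff3",
        "fitness_tsv": "fitness.tsv",
        "screen": screen.to_dict(),
        "barcodes": dict(DEFAULT_BARCODES),
    }
    (INPUTS / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    sites_per_gene = len(ta) * screen.saturation * np.mean(
        [g.length for g in genes]
    ) / genome.length
    design = pd.DataFrame(
        [
            ("genome_length_bp", genome.length),
            ("n_genes", len(genes)),
            ("n_ta_sites", len(ta)),
            ("saturation", screen.saturation),
            ("expected_clones_per_gene", round(sites_per_gene, 1)),
            ("planted_resistant_genes", ";".join(planted)),
            ("resistance_multiplier", 30.0),
            ("survival_bactericidal", screen.survival_bactericidal),
            ("survival_subbactericidal", screen.survival_subbactericidal),
            ("growth_factor_control", screen.growth_factor_control),
            ("bottleneck_control", screen.colony_bottlenecks["control"]),
            ("bottleneck_sub", screen.colony_bottlenecks["sub"]),
            ("bottleneck_bactericidal", screen.colony_bottlenecks["bactericidal"]),
            ("n_replicates", screen.n_replicates),
            ("reads_per_sample", screen.reads_per_sample),
            ("seed", args.seed),
        ],
        columns=["parameter", "value"],
    )
    design.to_csv(RESULTS / "screen_design.tsv", sep="\t", index=False)
    print(f"reference: {genome.length} bp, {len(genes)} genes, {len(ta)} TA sites "
          f"(~{sites_per_gene:.0f} expected clones/gene)")
    print(f"planted resistant genes (multiplier 30): {', '.join(planted)}")
    print(f"inputs in {INPUTS}; design table in {RESULTS/'screen_design.tsv'}")


if __name__ == "__main__":
    main()
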