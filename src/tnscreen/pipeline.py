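"""End-to-end orchestration: simulate -> demux -> map -> count -> analyze -> report.

A run is driven by a single YAML config holding the input paths and the
:class:`~tnscreen.config.ScreenConfig`, writes every stage table plus a JSON
run manifest into one output directory, and is byte-reproducible given the
same seed.  One FASTQ is written per biological replicate; the three
treatment groups share the file and are separated by their group barcode,
mirroring group-barcoded junction sequencing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .config import DEFAULT_BARCODES, GROUPS, ScreenConfig, sample_name
from .fitness import analyze_screen, filter_min_sites, rank_hits
from .genome import (
    Feature,
    GenomeModel,
    build_catalog,
    find_ta_sites,
    read_gene_features,
    read_genome_fasta,
    write_gene_gff3,
    write_genome_fasta,
)
from .readproc import build_tag_index, count_sites, demultiplex, map_reads, read_fastq
from .simulate import (
    CloneTable,
    FitnessMap,
    generate_reads,
    simulate_colony_bottleneck,
    simulate_library,
    simulate_selection,
    write_fastq,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run exactly."""

    config: dict
    inputs: dict
    outputs: dict
    rng_seed: int
    stage_counts: dict
    version: str
    timestamp: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def load_run_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    for key in ("genome_fasta", "genes_gff3"):
        if key not in raw:
            raise ConfigError(f"config missing required key {key!r}")
        p = (Path(path).parent / raw[key]).resolve()
        if not p.exists():
            raise ConfigError(f"{key} points to missing file {p}")
        raw[key] = str(p)
    try:
        raw["screen"] = ScreenConfig.from_dict(raw.get("screen", {}))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid screen config: {e}") from e
    raw.setdefault("barcodes", dict(DEFAULT_BARCODES))
    if "fitness_tsv" in raw and raw["fitness_tsv"]:
        p = (Path(path).parent / raw["fitness_tsv"]).resolve()
        if not p.exists():
            raise ConfigError(f"fitness_tsv points to missing file {p}")
        raw["fitness_tsv"] = str(p)
    return raw


def load_fitness_tsv(path) -> FitnessMap:
    df = pd.read_csv(path, sep="\t")
    return FitnessMap(dict(zip(df["feature_id"], df["multiplier"])))


def run_pipeline(config_path, outdir, seed: int | None = None, make_plots: bool = True) -> RunManifest:
    """Execute every stage in order; any stage failure aborts with its name.

    Returns the written :class:`RunManifest`.  Read/site/feature counts are
    logged at each stage boundary so conservation can be audited.
    """
    cfg = load_run_config(config_path)
    screen: ScreenConfig = cfg["screen"]
    if seed is not None:
        screen.rng_seed = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(screen.rng_seed)
    stage_counts: dict = {}

    # --- reference ---------------------------------------------------------
    genome = read_genome_fasta(cfg["genome_fasta"])
    genes = read_gene_features(cfg["genes_gff3"])
    catalog = build_catalog(genes, genome.id, genome.length)
    ta_index = find_ta_sites(genome)
    catalog.write_tsv(outdir / "feature_catalog.tsv")
    stage_counts["reference"] = {
        "genome_length": genome.length,
        "ta_sites": len(ta_index),
        "genes": sum(f.kind == "gene" for f in catalog.features),
        "intergenic": sum(f.kind == "intergenic" for f in catalog.features),
    }

    fitness = (
        load_fitness_tsv(cfg["fitness_tsv"]) if cfg.get("fitness_tsv") else FitnessMap()
    )

    # --- simulate ----------------------------------------------------------
    library = simulate_library(ta_index, screen, rng, catalog)
    library.write_tsv(outdir / "library_clones.tsv", catalog)
    stage_counts["library"] = {
        "clones": len(library),
        "saturation_realized": len(library) / max(len(ta_index), 1),
    }
    barcodes = cfg["barcodes"]
    fastq_paths = {}
    truth_frames = []
    for rep in range(1, screen.n_replicates + 1):
        reads_out = []
        for group in GROUPS:
            sample = sample_name(group, rep)
            selected = simulate_selection(library, fitness, screen, group, rng, catalog)
            pooled = simulate_colony_bottleneck(
                selected, screen.colony_bottlenecks[group], rng
            )
            truth = pooled.frame[["ta_position", "orientation", "abundance"]].copy()
            truth["sample"] = sample
            truth_frames.append(truth)
            reads_out.extend(
                generate_reads(pooled, genome, screen, barcodes[group], rng, sample)
            )
        path = outdir / f"reads_rep{rep}.fastq"
        n = write_fastq(iter(reads_out), path)
        fastq_paths[rep] = path
        stage_counts[f"fastq_rep{rep}"] = {"reads": n}
    pd.concat(truth_frames).to_csv(
        outdir / "post_bottleneck_truth.tsv", sep="\t", index=False
    )

    # --- demux / map / count -----------------------------------------------
    tag_index = build_tag_index(genome, ta_index, screen.tag_length)
    mapped: dict[str, list] = {}
    for rep, path in fastq_paths.items():
        demux = demultiplex(read_fastq(path), barcodes, max_mismatches=1)
        assert demux.total == stage_counts[f"fastq_rep{rep}"]["reads"]
        stage_counts[f"demux_rep{rep}"] = {
            "assigned": dict(demux.counts), "rejected": demux.rejected,
        }
        for group, reads in demux.assigned.items():
            hits, summary = map_reads(reads, tag_index)
            sample = sample_name(group, rep)
            mapped[sample] = hits
            stage_counts[f"map_{sample}"] = {
                "mapped_unique": summary.mapped_unique,
                "ambiguous": summary.ambiguous,
                "unmapped": summary.unmapped,
            }
    site_counts = count_sites(mapped)
    site_counts.write_tsv(outdir / "site_counts.tsv")
    stage_counts["sites"] = {
        "distinct_sites": int(len(site_counts.collapsed())),
        "totals": {k: int(v) for k, v in site_counts.sample_totals().items()},
    }

    # --- analyze -----------------------------------------------------------
    collapsed = site_counts.collapsed()
    outputs = {
        "feature_catalog": "feature_catalog.tsv",
        "library_clones": "library_clones.tsv",
        "site_counts": "site_counts.tsv",
    }
    for treated in ("bactericidal", "sub"):
        table = analyze_screen(collapsed, catalog, screen, treated)
        table.to_csv(outdir / f"fitness_{treated}.tsv", sep="\t", index=False)
        filtered, removed = filter_min_sites(table, screen.min_sites)
        hits = rank_hits(filtered, screen.alpha, "resistant")
        hits.to_csv(outdir / f"hits_{treated}.tsv", sep="\t", index=False)
        outputs[f"fitness_{treated}"] = f"fitness_{treated}.tsv"
        outputs[f"hits_{treated}"] = f"hits_{treated}.tsv"
        stage_counts[f"analyze_{treated}"] = {
            "features": len(table),
            "filtered_out": removed,
            "resistant_hits": len(hits),
        }
        if make_plots:
            plot_si_scatter(filtered, outdir / f"si_scatter_{treated}.png",
                            title=f"{treated} vs control")

    manifest = RunManifest(
        config={**{k: v for k, v in cfg.items() if k != "screen"},
                "screen": screen.to_dict()},
        inputs={"genome_fasta": cfg["genome_fasta"], "genes_gff3": cfg["genes_gff3"]},
        outputs=outputs,
        rng_seed=screen.rng_seed,
        stage_counts=stage_counts,
        version=_version,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def plot_si_scatter(table: pd.DataFrame, path, title: str = "") -> None:
    """SI vs significance scatter: each dot one feature, hits highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.log2(table["mean_si"].to_numpy(dtype=float))
    y = -np.log10(np.clip(table["p_value"].to_numpy(dtype=float), 1e-300, 1.0))
    hit = (table["hit_call"] == "resistant").to_numpy()
    ax.scatter(x[~hit], y[~hit], s=8, c="grey", alpha=0.6, label="other")
    ax.scatter(x[hit], y[hit], s=14, c="crimson", label="resistant hit")
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, c="k")
    ax.axvline(0, ls=":", lw=0.8, c="k")
    ax.set_xlabel("log2 mean SI")
    ax.set_ylabel("-log10 P")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Toy fixture


def _random_genome(rng: np.random.Generator, length: int, gid: str) -> GenomeModel:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = lut[rng.integers(0, 4, length)].tobytes().decode("ascii")
    return GenomeModel(gid, seq)


def synthetic_reference(
    rng: np.random.Generator,
    genome_length: int,
    n_genes: int,
    gene_fraction: float = 0.9,
    gid: str = "synthetic",
):
    """Random genome tiled with equal-length genes separated by intergenic gaps.

    Returns ``(genome, catalog, ta_index)``.  A uniform-random genome has a
    TA at ~1/16 of positions, so gene span sets the expected insertion sites
    per gene (a 666-bp span at 63% saturation carries ~26 clones, the
    density of a saturated mariner library).
    """
    genome = _random_genome(rng, genome_length, gid)
    span = genome_length // n_genes
    glen = max(2, int(span * gene_fraction))
    genes = [
        Feature(f"g{i:04d}", "gene", i * span, i * span + glen,
                "+" if i % 2 == 0 else "-")
        for i in range(n_genes)
    ]
    catalog = build_catalog(genes, genome.id, genome.length)
    return genome, catalog, find_ta_sites(genome)


def make_toy_screen(
    seed: int,
    outdir,
    genome_length: int = 5_000,
    n_genes: int = 40,
    n_resistant: int = 3,
    resistance_multiplier: float = 30.0,
) -> dict:
    """Write a deterministic toy dataset: genome, annotation, config, truth.

    A random genome is tiled with ``n_genes`` equal genes separated by short
    intergenic gaps; ``n_resistant`` genes are planted with a survival
    multiplier of ``resistance_multiplier`` under treatment.  The screen
    parameters are scaled down (small bottlenecks and read counts) so the
    full pipeline finishes in seconds while keeping every stage nontrivial.
    Returns the paths of everything written, including ``truth`` listing the
    planted resistant genes.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _random_genome(rng, genome_length, f"toy{seed}")
    write_genome_fasta(genome, outdir / "genome.fasta")

    gene_span = genome_length // n_genes
    gap = max(4, gene_span // 10)
    genes = [
        Feature(f"g{i:03d}", "gene", i * gene_span, (i + 1) * gene_span - gap,
                "+" if i % 2 == 0 else "-")
        for i in range(n_genes)
    ]
    write_gene_gff3(genes, genome, outdir / "genes.gff3")

    planted = sorted(
        genes[i].feature_id
        for i in rng.choice(n_genes, size=n_resistant, replace=False)
    )
    fitness = FitnessMap({fid: resistance_multiplier for fid in planted})
    fitness.write_tsv(outdir / "fitness.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("feature_id\tmultiplier\n")
        for fid in planted:
            fh.write(f"{fid}\t{resistance_multiplier}\n")

    screen = ScreenConfig(
        reads_per_sample=20_000,
        colony_bottlenecks={"control": 20_000, "sub": 2_000, "bactericidal": 500},
        rng_seed=seed,
    )
    config = {
        "genome_fasta": "genome.fasta",
        "genes_gff3": "genes.gff3",
        "fitness_tsv": "fitness.tsv",
        "screen": screen.to_dict(),
        "barcodes": dict(DEFAULT_BARCODES),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {
        "config": outdir / "config.yaml",
        "genome_fasta": outdir / "genome.fasta",
        "genes_gff3": outdir / "genes.gff3",
        "fitness_tsv": outdir / "fitness.tsv",
        "truth": outdir / "truth.tsv",
        "planted": list(planted),
    }
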