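"""Reusable screen-level experiments at desk scale.

Each function runs one complete in-silico experiment under the study
conditions (63% saturation, 3 replicates, the stated survival fractions and
colony bottlenecks) and returns the measured quantities, so that drivers,
tests and reproduction scripts all execute the same code path.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_BARCODES, ScreenConfig
from .fitness import analyze_screen, filter_min_sites, rank_hits
from .genome import find_ta_sites
from .pipeline import synthetic_reference
from .readproc import build_tag_index, count_sites, demultiplex, map_reads, read_fastq
from .simulate import (
    FitnessMap,
    generate_reads,
    simulate_library,
    simulate_screen_counts,
    write_fastq,
)


def neutral_si_identity(seed: int = 0, total_reads: int = 10_000) -> dict:
    """SI of a feature whose read frequency is identical in treated and control.

    Builds a two-sample site-count table in which one gene holds the same
    fraction of each sample's total reads, then computes raw Dval
    (pseudocount 0) for both samples and their ratio.  The result is exactly
    1 regardless of sequencing depth: Dval normalises each sample by its own
    total, so equal frequencies give equal Dvals.
    """
    from .fitness import aggregate_by_feature, compute_dval, compute_predicted_reads, compute_si
    from .genome import Feature, build_catalog

    catalog = build_catalog([Feature("geneX", "gene", 0, 400)], "t1", 1000)
    # gene holds 40% of reads in both samples; control is 3x deeper
    counts = pd.DataFrame(
        {
            "treated": {100: int(0.4 * total_reads), 600: int(0.6 * total_reads)},
            "control": {100: int(1.2 * total_reads), 600: int(1.8 * total_reads)},
        }
    )
    counts.index.name = "ta_position"
    agg = aggregate_by_feature(counts, catalog)
    dvals = {}
    for s in ("treated", "control"):
        pred = compute_predicted_reads(
            agg.lengths.to_numpy(), agg.actual[s].sum(), catalog.genome_length
        )
        dvals[s] = compute_dval(agg.actual[s].to_numpy(), pred, 0.0)
    si = compute_si(dvals["treated"], dvals["control"])
    gene_si = float(si[list(agg.actual.index).index("geneX")])
    return {"si": gene_si, "total_reads": total_reads}


def saturation_recovery(
    seed: int,
    genome_length: int = 100_000,
    reads_per_sample: int = 200_000,
    workdir=None,
) -> dict:
    """Library saturation measured through the full read pipeline.

    Simulates a library at 63% TA-site saturation on a random genome, emits
    error-free junction reads to FASTQ, then demultiplexes, maps and counts
    them, and reports the fraction of TA sites with a nonzero mapped count
    alongside the exact binomial 99% interval for the realized number of
    TA sites.
    """
    rng = np.random.default_rng(seed)
    cfg = ScreenConfig(
        reads_per_sample=reads_per_sample, read_error_rate=0.0, rng_seed=seed
    )
    genome, _catalog, ta = synthetic_reference(rng, genome_length, 100, gid=f"sat{seed}")
    library = simulate_library(ta, cfg, rng)

    def _run(dirpath) -> pd.DataFrame:
        path = Path(dirpath) / "reads.fastq"
        write_fastq(
            generate_reads(library, genome, cfg, DEFAULT_BARCODES["control"],
                           rng, "control_rep1"),
            path,
        )
        demux = demultiplex(read_fastq(path), DEFAULT_BARCODES, max_mismatches=1)
        index = build_tag_index(genome, ta, cfg.tag_length)
        hits, _summary = map_reads(demux.assigned["control"], index)
        return count_sites({"control_rep1": hits}).collapsed()

    if workdir is None:
        with tempfile.TemporaryDirectory() as d:
            collapsed = _run(d)
    else:
        collapsed = _run(workdir)

    n_ta = len(ta)
    occupied = int((collapsed["control_rep1"] > 0).sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], n_ta, 0.63) / n_ta
    return {
        "occupied_fraction": occupied / n_ta,
        "occupied_sites": occupied,
        "n_ta_sites": n_ta,
        "n_clones": len(library),
        "ci99": (float(lo), float(hi)),
    }


def dval_centering(seed: int = 0) -> dict:
    """Max deviation of the length-weighted mean raw Dval from 1, per sample."""
    from .fitness import aggregate_by_feature, compute_dval, compute_predicted_reads

    rng = np.random.default_rng(seed)
    _genome, catalog, ta = synthetic_reference(rng, 40_000, 60)
    cfg = ScreenConfig(reads_per_sample=50_000, rng_seed=seed)
    lib = simulate_library(ta, cfg, rng, catalog)
    counts = simulate_screen_counts(lib, FitnessMap(), cfg, rng, catalog)
    agg = aggregate_by_feature(counts, catalog)
    devs = {}
    for s in counts.columns:
        pred = compute_predicted_reads(
            agg.lengths.to_numpy(), agg.actual[s].sum(), catalog.genome_length
        )
        dval = compute_dval(agg.actual[s].to_numpy(), pred, 0.0)
        devs[s] = float(
            abs((dval * agg.lengths.to_numpy()).sum() / catalog.genome_length - 1)
        )
    return {"max_abs_deviation": max(devs.values()), "per_sample": devs}


def roundtrip_exactness(seeds=range(10), genome_length: int = 30_000,
                        reads_per_sample: int = 10_000) -> dict:
    """Count sites discordant between pipeline output and simulator truth.

    With error-free reads and 16-bp tags every uniquely mappable read maps
    back to its source TA site, so the per-site counts must equal the
    multinomial read draws recorded in the read names exactly.  The rare
    tag collision (e.g. a reverse-complement-palindromic window, which makes
    one tag consistent with two (site, orientation) pairs) is intrinsically
    unresolvable; such sites are excluded from the comparison and returned
    in the collision list.
    """
    from .simulate import revcomp

    discordant = 0
    collisions: list = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        cfg = ScreenConfig(reads_per_sample=reads_per_sample, rng_seed=seed)
        genome, _cat, ta = synthetic_reference(rng, genome_length, 40, gid=f"rt{seed}")
        lib = simulate_library(ta, cfg, rng)
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "r.fastq"
            write_fastq(
                generate_reads(lib, genome, cfg, DEFAULT_BARCODES["control"],
                               rng, "s"),
                path,
            )
            truth: dict = {}
            for name, _s, _q in read_fastq(path):
                _x, p, o, _i = name.rsplit(":", 3)
                truth[(int(p), o)] = truth.get((int(p), o), 0) + 1
            demux = demultiplex(read_fastq(path), DEFAULT_BARCODES, 1)
            idx = build_tag_index(genome, ta, cfg.tag_length)
            hits, _ = map_reads(demux.assigned["control"], idx)
            observed = {
                k: int(v) for k, v in count_sites({"s": hits}).per_site["s"].items()
            }
        def _tag(p, o):
            return (
                genome.sequence[p : p + cfg.tag_length]
                if o == "+"
                else revcomp(genome.sequence[p + 2 - cfg.tag_length : p + 2])
            )

        keys = set(truth) | set(observed)
        for k in keys:
            if _tag(*k) in idx.ambiguous:
                collisions.append((seed, k))
                continue
            if truth.get(k, 0) != observed.get(k, 0):
                discordant += 1
    return {
        "discordant_sites": discordant,
        "n_runs": len(list(seeds)),
        "collisions": collisions,
    }


def null_calibration(
    seed: int,
    n_screens: int = 500,
    genome_length: int = 40_000,
    n_genes: int = 60,
    reads_per_sample: int = 50_000,
) -> dict:
    """Fraction of features called significant in all-neutral screens.

    Null screens use the sub-bactericidal arm (17% survival, 8,000-colony
    bottleneck) so per-feature counts stay in the regime where the
    log-ratio t-test's normality approximation is expected to hold.
    """
    master = np.random.default_rng(seed)
    _genome, catalog, ta = synthetic_reference(master, genome_length, n_genes)
    cfg = ScreenConfig(reads_per_sample=reads_per_sample, rng_seed=seed)
    fit = FitnessMap()
    n_tested = n_sig = 0
    for _ in range(n_screens):
        rng = np.random.default_rng(master.integers(2**31))
        lib = simulate_library(ta, cfg, rng, catalog)
        counts = simulate_screen_counts(
            lib, fit, cfg, rng, catalog, groups=("control", "sub")
        )
        table = analyze_screen(counts, catalog, cfg, "sub")
        kept, _ = filter_min_sites(table, cfg.min_sites)
        ok = np.isfinite(kept["p_value"])
        n_tested += int(ok.sum())
        n_sig += int((kept.loc[ok, "p_value"] <= 0.05).sum())
    return {
        "fraction_significant": n_sig / n_tested,
        "n_tested": n_tested,
        "n_screens": n_screens,
    }


def planted_recovery(
    seed: int,
    n_runs: int = 50,
    n_genes: int = 300,
    n_planted: int = 5,
    multiplier: float = 30.0,
) -> dict:
    """Recovery of planted resistance determinants under bactericidal selection.

    Each run simulates a fresh ~200-kb reference with 300 genes (~26
    insertion clones per gene at 63% saturation), plants ``n_planted`` genes
    with a 30-fold survival advantage, runs control and bactericidal arms
    through selection, the 230-colony bottleneck and sequencing for 3
    replicates, and asks whether every planted gene appears in the ranked
    resistant hit list at P <= 0.05.
    """
    master = np.random.default_rng(seed)
    success = 0
    min_si = np.inf
    for _ in range(n_runs):
        run_seed = int(master.integers(2**31))
        rng = np.random.default_rng(run_seed)
        _genome, catalog, ta = synthetic_reference(rng, n_genes * 666, n_genes)
        cfg = ScreenConfig(rng_seed=run_seed)
        genes = [f.feature_id for f in catalog.features if f.kind == "gene"]
        planted = [genes[i] for i in rng.choice(len(genes), n_planted, replace=False)]
        fit = FitnessMap({g: multiplier for g in planted})
        lib = simulate_library(ta, cfg, rng, catalog)
        counts = simulate_screen_counts(
            lib, fit, cfg, rng, catalog, groups=("control", "bactericidal")
        )
        table = analyze_screen(counts, catalog, cfg, "bactericidal")
        kept, _ = filter_min_sites(table, cfg.min_sites)
        hits = rank_hits(kept, cfg.alpha, "resistant")
        got = set(hits["feature_id"])
        planted_si = table.set_index("feature_id").loc[planted, "mean_si"]
        min_si = min(min_si, float(planted_si.min()))
        if all(p in got for p in planted) and (planted_si > 5).all():
            success += 1
    return {
        "success_fraction": success / n_runs,
        "n_runs": n_runs,
        "min_planted_mean_si": min_si,
    }


def si_expectation_mc(
    seed: int,
    n_draws: int = 10_000,
    class_frequency: float = 0.001,
    multiplier: float = 30.0,
) -> dict:
    """Monte-Carlo mean SI of a rare resistant class vs the closed form.

    For a class at initial frequency f with survival multiplier m over
    baseline survival s, the expected post-selection frequency is
    f*m*s / (f*m*s + (1-f)*s), so the expected SI (frequency fold-change
    relative to the neutral control) is m / (1 + f*(m-1)) — 29.15 for
    f = 0.001, m = 30.  Each draw pushes a two-class library through the
    Poisson selection stage for both arms and forms the SI from frequencies.
    """
    from .simulate import CloneTable, simulate_selection
    from .genome import Feature, build_catalog

    rng = np.random.default_rng(seed)
    cfg = ScreenConfig(rng_seed=seed)
    total = 1e6
    frame = pd.DataFrame(
        {
            "ta_position": [0, 10],
            "orientation": ["+", "+"],
            "feature_idx": [0, 1],
            "abundance": [class_frequency * total, (1 - class_frequency) * total],
        }
    )
    clones = CloneTable(frame)
    catalog = build_catalog(
        [Feature("res", "gene", 0, 5), Feature("neu", "gene", 5, 20)], "mc", 20
    )
    fit = FitnessMap({"res": multiplier})
    sis = np.empty(n_draws)
    for i in range(n_draws):
        t = simulate_selection(clones, fit, cfg, "bactericidal", rng, catalog)
        c = simulate_selection(clones, fit, cfg, "control", rng, catalog)
        ft = t.frame.set_index("ta_position")["abundance"]
        fc = c.frame.set_index("ta_position")["abundance"]
        f_t = ft.get(0, 0.0) / ft.sum()
        f_c = fc.get(0, 0.0) / fc.sum()
        sis[i] = f_t / f_c
    expected = multiplier / (1 + class_frequency * (multiplier - 1))
    return {
        "mc_mean_si": float(sis.mean()),
        "mc_se": float(sis.std(ddof=1) / np.sqrt(n_draws)),
        "expected_si": float(expected),
        "n_draws": n_draws,
    }
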