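"""Run the full screen pipeline on the prepared inputs.

Simulates the library, the three treatment arms (control, sub-bactericidal,
bactericidal) across 3 replicates, emits barcoded junction reads, then
demultiplexes, maps tags back to TA sites and counts reads per site, and
computes the survival-index tables.  All intermediates (FASTQ, site counts,
fitness tables) go to scratch/analysis/run; the stage-conservation summary
goes to results/read_processing_summary.tsv.

Usage: python analysis/02_run_pipeline.py
"""

from pathlib import Path

import pandas as pd

from tnscreen import run_pipeline

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "scratch" / "analysis" / "inputs"
RUN = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"


def main():
    config = INPUTS / "config.yaml"
    if not config.exists():
        raise SystemExit("run analysis/01_prepare_screen.py first")
    manifest = run_pipeline(config, RUN, make_plots=False)

    rows = []
    sc = manifest.stage_counts
    print(f"library: {sc['library']['clones']} clones "
          f"({sc['library']['saturation_realized']:.1%} of TA sites occupied)")
    for rep in (1, 2, 3):
        emitted = sc[f"fastq_rep{rep}"]["reads"]
        demux = sc[f"demux_rep{rep}"]
        for group, n in demux["assigned"].items():
            m = sc[f"map_{group}_rep{rep}"]
            rows.append(
                {
                    "replicate": rep,
                    "group": group,
                    "reads_emitted": emitted,
                    "demux_assigned": n,
                    "demux_rejected": demux["rejected"],
                    "mapped_unique": m["mapped_unique"],
                    "ambiguous": m["ambiguous"],
                    "unmapped": m["unmapped"],
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "read_processing_summary.tsv", sep="\t", index=False)
    mapped = summary["mapped_unique"].sum()
    total = summary.groupby("replicate")["reads_emitted"].first().sum()
    print(f"reads: {total} emitted, {mapped} uniquely mapped "
          f"({mapped/total:.2%}); {sc['sites']['distinct_sites']} distinct sites")
    print(f"intermediates in {RUN}; summary in "
          f"{RESULTS/'read_processing_summary.tsv'}")


if __name__ == "__main__":
    main()
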