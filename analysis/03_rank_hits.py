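"""Rank resistant hits and check recovery of the planted genes.

Reads the fitness tables the pipeline produced, applies the >= 3-site
filter and the P <= 0.05 cut, writes the per-feature tables and ranked
resistant hit lists for both treatment arms into results/, and reports
whether the 5 planted resistance determinants were recovered.

Usage: python analysis/03_rank_hits.py
"""

from pathlib import Path

import pandas as pd

from tnscreen import filter_min_sites, rank_hits

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "scratch" / "analysis" / "inputs"
RUN = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"

KEEP_COLS = [
    "feature_id", "kind", "length", "n_sites", "mean_si", "p_value",
    "q_value", "si_rep1", "si_rep2", "si_rep3", "hit_call",
]


def main():
    planted = set(pd.read_csv(INPUTS / "fitness.tsv", sep="\t")["feature_id"])
    for arm in ("bactericidal", "sub"):
        table = pd.read_csv(RUN / f"fitness_{arm}.tsv", sep="\t")
        table[KEEP_COLS].to_csv(RESULTS / f"fitness_{arm}.tsv", sep="\t",
                                index=False, float_format="%.4g")
        filtered, removed = filter_min_sites(table, 3)
        hits = rank_hits(filtered, 0.05, "resistant")
        hits[KEEP_COLS + ["rank"]].to_csv(
            RESULTS / f"hits_{arm}.tsv", sep="\t", index=False, float_format="%.4g"
        )
        got = list(hits["feature_id"])
        recovered = planted & set(got)
        print(f"[{arm}] {len(filtered)} features tested ({removed} below 3 sites); "
              f"{len(hits)} resistant hits at P<=0.05")
        print(f"[{arm}] planted genes recovered: {len(recovered)}/{len(planted)}; "
              f"top 5 by SI: {', '.join(got[:5])}")
        top = hits.head(5)[["feature_id", "mean_si", "p_value", "n_sites"]]
        print(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
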