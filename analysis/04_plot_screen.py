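"""SI-versus-significance scatter for both treatment arms.

One dot per feature passing the >= 3-site filter; resistant hits
(P <= 0.05, mean SI > 1) highlighted.  Figures land in results/figures/.

Usage: python analysis/04_plot_screen.py
"""

from pathlib import Path

import pandas as pd

from tnscreen import filter_min_sites
from tnscreen.pipeline import plot_si_scatter

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "scratch" / "analysis" / "run"
FIGURES = ROOT / "results" / "figures"


def main():
    FIGURES.mkdir(parents=True, exist_ok=True)
    for arm in ("bactericidal", "sub"):
        table = pd.read_csv(RUN / f"fitness_{arm}.tsv", sep="\t")
        filtered, _ = filter_min_sites(table, 3)
        out = FIGURES / f"si_scatter_{arm}.png"
        plot_si_scatter(filtered, out, title=f"{arm} vs control")
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
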