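"""Per-feature survival-index statistics.

For each feature (gene or intergenic region) and sample:

* ``predicted = total_mapped_reads x feature_length / catalog_total_length``
  — the read count expected if insertions were uniform along the genome;
* ``Dval = actual / predicted`` — the feature's normalised representation
  in that library (length-weighted mean Dval is exactly 1 per sample);
* ``SI = Dval(treated) / Dval(control)`` — the survival index.  SI = 1 is
  neutral, SI > 1 marks resistant insertion mutants, SI < 1 sensitive ones.

SI is computed per replicate; replicates are combined as the geometric mean
and tested with a two-tailed one-sample t-test of ln(SI) against 0 (the
paired-test equivalent on log Dvals).  Features with fewer than ``min_sites``
distinct insertion sites across the compared samples are excluded from
testing, because too few independent clones make a frequency change
unreliable.  A small pseudocount keeps Dval defined for features emptied by
the bactericidal selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig, sample_name
from .genome import FeatureCatalog

logger = logging.getLogger(__name__)


@dataclass
class FeatureAggregate:
    """Actual reads per feature per sample, plus per-site presence for n_sites."""

    actual: pd.DataFrame          # index feature_id (catalog order), columns samples
    lengths: pd.Series            # feature lengths, same index
    kinds: pd.Series
    site_feature: pd.Series       # index ta_position -> feature_id (observed sites)
    presence: pd.DataFrame        # index ta_position, bool per sample (count > 0)

    def n_sites(self, samples: list[str]) -> pd.Series:
        """Distinct positions with a read in >= 1 of ``samples``, per feature."""
        any_hit = self.presence[samples].any(axis=1)
        hit_positions = self.site_feature[any_hit]
        counts = hit_positions.value_counts()
        return counts.reindex(self.actual.index, fill_value=0).astype(int)


def aggregate_by_feature(
    collapsed_counts: pd.DataFrame, catalog: FeatureCatalog
) -> FeatureAggregate:
    """Sum per-position read counts into the tiling feature catalog.

    ``collapsed_counts``: index = ta_position (orientations already summed),
    one integer column per sample.  Every position must fall inside the
    genome; the tiling catalog guarantees each belongs to exactly one
    feature (an insertion is assigned to the feature containing the T of
    its TA site).
    """
    feature_ids = pd.Index([f.feature_id for f in catalog.features], name="feature_id")
    lengths = pd.Series([f.length for f in catalog.features], index=feature_ids)
    kinds = pd.Series([f.kind for f in catalog.features], index=feature_ids)

    if collapsed_counts.empty:
        actual = pd.DataFrame(
            0, index=feature_ids, columns=collapsed_counts.columns, dtype=np.int64
        )
        empty_pos = pd.Index([], name="ta_position")
        return FeatureAggregate(
            actual, lengths, kinds,
            pd.Series(dtype=object, index=empty_pos),
            pd.DataFrame(index=empty_pos, columns=collapsed_counts.columns, dtype=bool),
        )

    positions = collapsed_counts.index.to_numpy()
    fidx = catalog.feature_index_of(positions)
    fid_per_pos = pd.Series(feature_ids[fidx], index=collapsed_counts.index)
    actual = (
        collapsed_counts.groupby(fid_per_pos.to_numpy()).sum()
        .reindex(feature_ids, fill_value=0)
        .astype(np.int64)
    )
    presence = collapsed_counts > 0
    return FeatureAggregate(actual, lengths, kinds, fid_per_pos, presence)


def compute_predicted_reads(
    feature_length: float, total_mapped_reads: float, catalog_total_length: float
):
    """Expected reads under uniform insertion density: T x len / L."""
    if catalog_total_length <= 0:
        raise ValueError("catalog total length must be positive")
    return total_mapped_reads * np.asarray(feature_length) / catalog_total_length


def compute_dval(actual, predicted, pseudocount: float = 0.0):
    """Dval = (actual + pseudocount) / (predicted + pseudocount)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if (actual < 0).any():
        raise ValueError("negative read counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (predicted <= 0).any():
        raise ValueError("predicted reads must be positive when pseudocount is 0")
    return (actual + pseudocount) / (predicted + pseudocount)


def compute_si(dval_treated, dval_control):
    """Survival index: Dval(treated) / Dval(control).

    Where ``dval_control`` is 0 (possible only with pseudocount 0) the SI is
    undefined and returned as NaN; callers exclude such features from
    testing and report them.
    """
    dt = np.asarray(dval_treated, dtype=float)
    dc = np.asarray(dval_control, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(dc > 0, dt / np.where(dc > 0, dc, 1.0), np.nan)
    return si


def replicate_significance(log_si) -> float:
    """Two-tailed one-sample t-test of ln(SI) against 0 across replicates.

    Equivalent to a paired t-test of ln Dval(treated) vs ln Dval(control).
    Degenerate cases: zero variance with zero mean returns p = 1 (null
    exactly satisfied); zero variance with nonzero mean returns p = 0.0
    (below machine resolution — callers flag these rows).
    """
    x = np.asarray(log_si, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 replicates with finite log SI")
    if np.ptp(x) == 0.0:
        return 1.0 if x[0] == 0.0 else 0.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def filter_min_sites(
    table: pd.DataFrame, min_sites: int = 3
) -> tuple[pd.DataFrame, int]:
    """Retain features with >= ``min_sites`` distinct insertion sites (inclusive)."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    keep = table["n_sites"] >= min_sites
    removed = int((~keep).sum())
    logger.info("min-sites filter: %d features removed, %d retained",
                removed, int(keep.sum()))
    return table[keep].copy(), removed


def analyze_screen(
    collapsed_counts: pd.DataFrame,
    catalog: FeatureCatalog,
    config: ScreenConfig,
    treated_group: str,
    control_group: str = "control",
    replicates: list[int] | None = None,
) -> pd.DataFrame:
    """Full per-feature fitness table for one treated-vs-control comparison.

    Columns: feature metadata; per-sample actual/predicted/raw Dval
    (pseudocount 0); per-replicate SI (pseudocounted Dvals); geometric mean
    SI; one-sample t-test P on ln SI; BH q-value over the tested features;
    ``passes_min_sites``; ``hit_call`` in {resistant, sensitive, ns,
    untested}.  ``n_sites`` is the union of distinct insertion positions
    over all compared samples.
    """
    reps = replicates or list(range(1, config.n_replicates + 1))
    t_samples = [sample_name(treated_group, r) for r in reps]
    c_samples = [sample_name(control_group, r) for r in reps]
    agg = aggregate_by_feature(collapsed_counts, catalog)
    L = float(catalog.genome_length)
    totals = agg.actual.sum(axis=0)

    out = pd.DataFrame(
        {
            "feature_id": agg.actual.index,
            "kind": agg.kinds.to_numpy(),
            "length": agg.lengths.to_numpy(),
        }
    ).set_index("feature_id")
    out["n_sites"] = agg.n_sites(t_samples + c_samples)

    si_cols = []
    for r, ts, cs in zip(reps, t_samples, c_samples):
        for s in (ts, cs):
            pred = compute_predicted_reads(agg.lengths.to_numpy(), totals[s], L)
            out[f"actual_{s}"] = agg.actual[s].to_numpy()
            out[f"predicted_{s}"] = pred
            out[f"dval_raw_{s}"] = compute_dval(agg.actual[s].to_numpy(), pred, 0.0)
        dt = compute_dval(
            agg.actual[ts].to_numpy(), out[f"predicted_{ts}"].to_numpy(),
            config.pseudocount,
        )
        dc = compute_dval(
            agg.actual[cs].to_numpy(), out[f"predicted_{cs}"].to_numpy(),
            config.pseudocount,
        )
        col = f"si_rep{r}"
        out[col] = compute_si(dt, dc)
        si_cols.append(col)

    log_si = np.log(out[si_cols].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        out["mean_si"] = np.exp(np.nanmean(log_si, axis=1))

    pvals = np.full(len(out), np.nan)
    degenerate = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(log_si):
        finite = row[np.isfinite(row)]
        if finite.size >= 2:
            pvals[i] = replicate_significance(finite)
            degenerate[i] = np.ptp(finite) == 0.0 and finite[0] != 0.0
    out["p_value"] = pvals
    out["p_degenerate"] = degenerate

    out["passes_min_sites"] = out["n_sites"] >= config.min_sites
    tested = out["passes_min_sites"] & np.isfinite(out["p_value"])
    qvals = np.full(len(out), np.nan)
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        qvals[tested.to_numpy()] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["q_value"] = qvals

    call = np.where(
        ~tested, "untested",
        np.where(
            out["p_value"] > config.alpha, "ns",
            np.where(out["mean_si"] > 1, "resistant",
                     np.where(out["mean_si"] < 1, "sensitive", "ns")),
        ),
    )
    out["hit_call"] = call
    return out.reset_index()


def rank_hits(
    table: pd.DataFrame, alpha: float = 0.05, direction: str = "resistant"
) -> pd.DataFrame:
    """Significant features on the requested side of SI = 1, ranked by effect.

    ``direction='resistant'`` keeps mean SI > 1 sorted descending (strongest
    enrichment first); ``'sensitive'`` keeps mean SI < 1 sorted ascending.
    Input should already be min-sites filtered.
    """
    if direction not in ("resistant", "sensitive"):
        raise ValueError(f"direction must be resistant|sensitive, got {direction!r}")
    ok = (table["p_value"] <= alpha) & np.isfinite(table["p_value"])
    if direction == "resistant":
        ok &= table["mean_si"] > 1
        hits = table[ok].sort_values("mean_si", ascending=False)
    else:
        ok &= table["mean_si"] < 1
        hits = table[ok].sort_values("mean_si", ascending=True)
    hits = hits.copy()
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits
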