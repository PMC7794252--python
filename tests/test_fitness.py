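"""Survival-index statistics: aggregation, Dval, SI, filtering, significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tnscreen import (
    Feature,
    ScreenConfig,
    aggregate_by_feature,
    analyze_screen,
    build_catalog,
    compute_dval,
    compute_predicted_reads,
    compute_si,
    filter_min_sites,
    rank_hits,
    replicate_significance,
)


@pytest.fixture
def two_feature_catalog():
    return build_catalog([Feature("gene1", "gene", 0, 10)], "x", 20)
    # catalog: gene1 [0,10) + IG_gene1_end [10,20)


def _counts(d: dict, samples=("s",)):
    df = pd.DataFrame(
        {s: pd.Series({p: v for p, v in d.get(s, {}).items()}, dtype=np.int64)
         for s in samples}
    ).fillna(0).astype(np.int64)
    df.index.name = "ta_position"
    return df


class TestAggregate:
    def test_counts_summed_into_containing_feature(self, two_feature_catalog):
        agg = aggregate_by_feature(_counts({"s": {4: 5, 12: 2}}), two_feature_catalog)
        assert agg.actual.loc["gene1", "s"] == 5
        assert agg.actual.loc["IG_gene1_end", "s"] == 2
        assert agg.n_sites(["s"]).tolist() == [1, 1]

    def test_empty_counts_give_all_zero(self, two_feature_catalog):
        empty = _counts({"s": {}})
        agg = aggregate_by_feature(empty, two_feature_catalog)
        assert (agg.actual["s"] == 0).all()

    def test_boundary_site_belongs_to_next_feature(self, two_feature_catalog):
        agg = aggregate_by_feature(_counts({"s": {10: 7}}), two_feature_catalog)
        assert agg.actual.loc["gene1", "s"] == 0
        assert agg.actual.loc["IG_gene1_end", "s"] == 7

    def test_feature_totals_conserve_mapped_reads(self, two_feature_catalog):
        rng = np.random.default_rng(0)
        d = {int(p): int(c) for p, c in zip(rng.integers(0, 20, 30),
                                            rng.integers(1, 50, 30))}
        agg = aggregate_by_feature(_counts({"s": d}), two_feature_catalog)
        assert agg.actual["s"].sum() == sum(d.values())


class TestPredictedReads:
    def test_stated_formula(self):
        assert compute_predicted_reads(1_000, 10_000, 100_000) == 100

    def test_whole_genome_feature_predicts_total(self):
        assert compute_predicted_reads(5_000, 777, 5_000) == 777

    def test_tiling_catalog_sums_to_total(self):
        lengths = np.array([100, 250, 650])
        pred = compute_predicted_reads(lengths, 4242, lengths.sum())
        assert pred.sum() == pytest.approx(4242)

    def test_zero_catalog_length_rejected(self):
        with pytest.raises(ValueError):
            compute_predicted_reads(10, 100, 0)


class TestDval:
    @pytest.mark.parametrize(
        "actual,predicted,pc,expected",
        [
            (200, 100, 0.0, 2.0),
            (100, 100, 0.0, 1.0),
            (0, 100, 0.5, 0.5 / 100.5),  # = 0.004975...
        ],
    )
    def test_examples(self, actual, predicted, pc, expected):
        assert compute_dval(actual, predicted, pc) == pytest.approx(expected, rel=1e-9)

    def test_pseudocount_zero_example_value(self):
        assert compute_dval(0, 100, 0.5) == pytest.approx(0.004975, abs=5e-7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_dval(-1, 100, 0.0)


class TestSI:
    def test_equal_dvals_give_neutral_si(self):
        assert compute_si(0.73, 0.73) == 1.0

    def test_ratio(self):
        assert compute_si(2.0, 0.5) == 4.0

    def test_zero_treated_dval_classified_sensitive(self):
        si = compute_si(compute_dval(0, 100, 0.5), 1.0)
        assert 0 < si < 0.01

    def test_zero_control_dval_flagged_nan(self):
        assert np.isnan(compute_si(1.0, 0.0))


class TestSignificance:
    def test_closed_form_t_cdf_df2(self):
        """ln SI (0.5, 0.7, 0.6): t = 10.392, two-tailed p = 1 - t/sqrt(2+t^2)."""
        p = replicate_significance([0.5, 0.7, 0.6])
        t = 6 * np.sqrt(3)
        expected = 1 - t / np.sqrt(2 + t**2)
        assert expected == pytest.approx(0.00914, abs=1e-5)
        assert p == pytest.approx(expected, rel=1e-6)

    def test_exact_null_gives_p_one(self):
        assert replicate_significance([0.0, 0.0, 0.0]) == 1.0

    def test_zero_variance_nonzero_mean_degenerate(self):
        assert replicate_significance([0.3, 0.3, 0.3]) == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_significance([0.5])


class TestFilterAndRank:
    def _table(self, n_sites, si, p):
        return pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(len(n_sites))],
             "n_sites": n_sites, "mean_si": si, "p_value": p}
        )

    def test_min_sites_inclusive_bound(self):
        t = self._table([1, 2, 3, 5], [1, 1, 1, 1], [0.5] * 4)
        kept, removed = filter_min_sites(t, 3)
        assert len(kept) == 2 and removed == 2
        kept1, _ = filter_min_sites(t, 1)
        assert len(kept1) == 4

    def test_rank_hits_direction_and_threshold(self):
        t = self._table([5, 5, 5, 5], [4.0, 4.0, 0.3, 6.0], [0.01, 0.2, 0.01, 0.04])
        hits = rank_hits(t, 0.05, "resistant")
        assert hits["feature_id"].tolist() == ["f3", "f0"]
        assert hits["rank"].tolist() == [1, 2]
        sens = rank_hits(t, 0.05, "sensitive")
        assert sens["feature_id"].tolist() == ["f2"]


class TestScreenInvariants:
    @pytest.fixture
    def catalog(self):
        genes = [Feature(f"g{i}", "gene", i * 100, i * 100 + 80) for i in range(10)]
        return build_catalog(genes, "x", 1000)

    def _random_counts(self, rng, samples, positions=None):
        positions = positions if positions is not None else rng.choice(
            1000, size=120, replace=False
        )
        df = pd.DataFrame(
            {s: rng.integers(0, 200, len(positions)) for s in samples},
            index=np.sort(positions),
        )
        df.index.name = "ta_position"
        return df

    def test_length_weighted_mean_dval_is_one(self, catalog):
        """Sum(actual) = Sum(predicted) forces the length-weighted mean raw
        Dval to equal 1 for every sample."""
        rng = np.random.default_rng(5)
        counts = self._random_counts(rng, ["a", "b"])
        agg = aggregate_by_feature(counts, catalog)
        L = catalog.genome_length
        for s in ("a", "b"):
            pred = compute_predicted_reads(
                agg.lengths.to_numpy(), agg.actual[s].sum(), L
            )
            dval = compute_dval(agg.actual[s].to_numpy(), pred, 0.0)
            weighted = (dval * agg.lengths.to_numpy()).sum() / L
            assert weighted == pytest.approx(1.0, abs=1e-9)

    def test_depth_invariance_of_raw_dval_and_si(self, catalog):
        """Scaling one sample's counts by an integer leaves raw Dvals and SI
        unchanged."""
        rng = np.random.default_rng(6)
        counts = self._random_counts(rng, ["t", "c"])
        scaled = counts.copy()
        scaled["t"] = scaled["t"] * 7
        L = catalog.genome_length

        def dvals(cnt, s):
            agg = aggregate_by_feature(cnt, catalog)
            pred = compute_predicted_reads(
                agg.lengths.to_numpy(), agg.actual[s].sum(), L
            )
            return compute_dval(agg.actual[s].to_numpy(), pred, 0.0)

        np.testing.assert_allclose(dvals(counts, "t"), dvals(scaled, "t"), rtol=1e-12)
        si_a = compute_si(dvals(counts, "t"), dvals(counts, "c"))
        si_b = compute_si(dvals(scaled, "t"), dvals(scaled, "c"))
        np.testing.assert_allclose(si_a, si_b, rtol=1e-12)

    @given(st.integers(2, 9), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_depth_invariance_property(self, factor, seed):
        catalog = build_catalog(
            [Feature(f"g{i}", "gene", i * 100, i * 100 + 80) for i in range(10)],
            "x", 1000,
        )
        rng = np.random.default_rng(seed)
        counts = self._random_counts(rng, ["t"])
        agg = aggregate_by_feature(counts, catalog)
        pred = compute_predicted_reads(
            agg.lengths.to_numpy(), agg.actual["t"].sum(), 1000
        )
        d1 = compute_dval(agg.actual["t"].to_numpy(), pred, 0.0)
        agg2 = aggregate_by_feature(counts * factor, catalog)
        pred2 = compute_predicted_reads(
            agg2.lengths.to_numpy(), agg2.actual["t"].sum(), 1000
        )
        d2 = compute_dval(agg2.actual["t"].to_numpy(), pred2, 0.0)
        np.testing.assert_allclose(d1, d2, rtol=1e-12)


class TestAnalyzeScreen:
    def test_neutral_feature_gets_si_one_and_hit_calls(self):
        catalog = build_catalog(
            [Feature("g0", "gene", 0, 100), Feature("g1", "gene", 100, 200)],
            "x", 200,
        )
        rng = np.random.default_rng(1)
        cfg = ScreenConfig(n_replicates=2, pseudocount=0.5)
        # identical treated/control counts in both replicates -> SI 1, p = 1
        pos = np.sort(rng.choice(200, 40, replace=False))
        base = rng.integers(5, 50, 40)
        counts = pd.DataFrame(
            {
                "bactericidal_rep1": base, "control_rep1": base,
                "bactericidal_rep2": base, "control_rep2": base,
            },
            index=pos,
        )
        counts.index.name = "ta_position"
        table = analyze_screen(counts, catalog, cfg, "bactericidal")
        assert np.allclose(table["mean_si"], 1.0)
        assert (table["p_value"] == 1.0).all()
        assert (table["hit_call"] == "ns").all()
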