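"""Screen simulator: library saturation, selection, bottleneck, read emission."""

import numpy as np
import pytest
from scipy import stats

from tnscreen import (
    Feature,
    FitnessMap,
    GenomeModel,
    ScreenConfig,
    build_catalog,
    find_ta_sites,
    generate_reads,
    simulate_colony_bottleneck,
    simulate_library,
    simulate_selection,
)
from tnscreen.simulate import CloneTable, revcomp, write_fastq

from conftest import random_genome


def _uniform_clones(n, abundance=100.0):
    import pandas as pd

    return CloneTable(
        pd.DataFrame(
            {
                "ta_position": np.arange(n) * 10,
                "orientation": ["+"] * n,
                "feature_idx": -1,
                "abundance": float(abundance),
            }
        )
    )


class TestSimulateLibrary:
    def test_saturation_one_occupies_every_site(self):
        rng = np.random.default_rng(0)
        g = random_genome(rng, 2000)
        ta = find_ta_sites(g)
        lib = simulate_library(ta, ScreenConfig(saturation=1.0), rng)
        assert len(lib) == len(ta)

    def test_saturation_zero_gives_empty_library(self):
        rng = np.random.default_rng(0)
        ta = find_ta_sites(random_genome(rng, 2000))
        assert len(simulate_library(ta, ScreenConfig(saturation=0.0), rng)) == 0

    def test_saturation_within_exact_binomial_99_interval(self):
        """Occupied fraction over 10,000 TA sites stays in the binomial 99% band."""
        from tnscreen.genome import TASiteIndex

        n = 10_000
        ta = TASiteIndex(np.arange(n) * 3)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.63)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lib = simulate_library(ta, ScreenConfig(saturation=0.63), rng)
            assert lo <= len(lib) <= hi

    def test_saturation_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(saturation=1.5)

    def test_at_most_one_clone_per_site_orientation(self):
        rng = np.random.default_rng(1)
        ta = find_ta_sites(random_genome(rng, 5000))
        lib = simulate_library(ta, ScreenConfig(), rng)
        assert not lib.frame.duplicated(["ta_position", "orientation"]).any()


class TestSimulateSelection:
    def test_control_scales_by_growth_factor(self):
        """With all multipliers 1, control expectation is exactly x20 per clone."""
        clones = _uniform_clones(2000, 1000.0)
        cfg = ScreenConfig()
        rng = np.random.default_rng(0)
        out = simulate_selection(clones, FitnessMap(), cfg, "control", rng)
        mean = out.frame["abundance"].sum() / 2000
        # Poisson(20000) per clone, 2000 clones: mean within 5 sigma
        se = np.sqrt(20_000 / 2000)
        assert abs(mean - 20_000) < 5 * se

    def test_resistant_clone_frequency_fold_change_matches_closed_form(self):
        """f=0.001, m=30, s=0.005: expected post-selection frequency 0.02914."""
        import pandas as pd

        total = 1e6
        frame = pd.DataFrame(
            {
                "ta_position": [0, 10],
                "orientation": ["+", "+"],
                "feature_idx": [0, 1],
                "abundance": [0.001 * total, 0.999 * total],
            }
        )
        clones = CloneTable(frame)
        cat = build_catalog(
            [Feature("res", "gene", 0, 5), Feature("neu", "gene", 5, 20)], "x", 20
        )
        fit = FitnessMap({"res": 30.0})
        cfg = ScreenConfig()
        rng = np.random.default_rng(123)
        freqs = []
        for _ in range(3000):
            out = simulate_selection(clones, fit, cfg, "bactericidal", rng, cat)
            ab = out.frame.set_index("ta_position")["abundance"]
            freqs.append(ab.get(0, 0.0) / ab.sum())
        expected = 0.001 * 0.15 / (0.001 * 0.15 + 0.999 * 0.005)
        assert expected == pytest.approx(0.02914, abs=2e-5)
        mc = np.mean(freqs)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(mc - expected) < 4 * se + 1e-4

    def test_total_survival_matches_baseline(self):
        clones = _uniform_clones(5000, 200.0)
        cfg = ScreenConfig()
        rng = np.random.default_rng(5)
        out = simulate_selection(clones, FitnessMap(), cfg, "bactericidal", rng)
        expected_total = 0.005 * 200.0 * 5000
        assert abs(out.total_abundance - expected_total) < 5 * np.sqrt(expected_total)

    def test_unknown_group_rejected(self):
        clones = _uniform_clones(10)
        with pytest.raises(ValueError, match="unknown group"):
            simulate_selection(
                clones, FitnessMap(), ScreenConfig(), "mock", np.random.default_rng(0)
            )

    def test_multiplier_survival_clipped_at_one(self, caplog):
        import pandas as pd

        clones = CloneTable(
            pd.DataFrame(
                {"ta_position": [0], "orientation": ["+"], "feature_idx": [0],
                 "abundance": [1e6]}
            )
        )
        cat = build_catalog([Feature("r", "gene", 0, 10)], "x", 10)
        fit = FitnessMap({"r": 1000.0})  # 1000 x 0.17 > 1
        rng = np.random.default_rng(0)
        out = simulate_selection(clones, fit, ScreenConfig(), "sub", rng, cat)
        # survival clipped to 1: expectation 1e6, not 1.7e8
        assert out.total_abundance < 1.1e6


class TestBottleneck:
    def test_single_survivor_takes_all_colonies(self):
        clones = _uniform_clones(1)
        out = simulate_colony_bottleneck(clones, 230, np.random.default_rng(0))
        assert out.total_abundance == 230

    def test_pigeonhole_on_tight_bottleneck(self):
        clones = _uniform_clones(10_000)
        out = simulate_colony_bottleneck(clones, 230, np.random.default_rng(0))
        assert len(out) <= 230
        assert out.total_abundance == 230

    def test_uniform_library_counts_in_multinomial_band(self):
        """1,000 uniform clones, 100,000 colonies: marginals ~ Binom(1e5, 1e-3)."""
        clones = _uniform_clones(1000)
        out = simulate_colony_bottleneck(clones, 100_000, np.random.default_rng(42))
        counts = out.frame["abundance"].to_numpy()
        lo, hi = stats.binom.ppf([0.005, 0.995], 100_000, 1e-3)
        inside = ((counts >= lo) & (counts <= hi)).mean()
        # ~99% of marginals inside their own 99% interval
        assert inside > 0.97

    def test_extinct_library_rejected(self):
        clones = _uniform_clones(5, abundance=0.0)
        clones.frame["abundance"] = 0.0
        with pytest.raises(ValueError, match="extinct"):
            simulate_colony_bottleneck(clones, 10, np.random.default_rng(0))


class TestGenerateReads:
    @pytest.fixture
    def one_clone(self):
        import pandas as pd

        def make(orientation):
            return CloneTable(
                pd.DataFrame(
                    {"ta_position": [4], "orientation": [orientation],
                     "feature_idx": [-1], "abundance": [10.0]}
                )
            )

        return make

    def test_forward_tag_convention(self, tag_genome, one_clone):
        # (+) clone at p=4, 6-bp window would read genome[4:10] == "TAGGCT";
        # the 12-bp tag extends the same window
        cfg = ScreenConfig(tag_length=12, reads_per_sample=5)
        genome = GenomeModel("g", tag_genome.sequence + "TTTTTT")
        reads = list(generate_reads(one_clone("+"), genome, cfg, "ACGTAC",
                                    np.random.default_rng(0), "s", 5))
        assert len(reads) == 5
        for _name, seq, _q in reads:
            tag = seq[6:]
            assert tag.startswith("TAGGCT")
            assert tag == genome.sequence[4:16]

    def test_reverse_tag_convention(self, tag_genome, one_clone):
        # (-) clone at p=4: revcomp(genome[p+2-L : p+2]); with the 6-bp window
        # this is revcomp("AACGTA") = "TACGTT"
        assert revcomp(tag_genome.sequence[0:6]) == "TACGTT"
        padded = GenomeModel("g", "TTTTTT" + tag_genome.sequence)
        import pandas as pd

        clone = CloneTable(
            pd.DataFrame({"ta_position": [10], "orientation": ["-"],
                          "feature_idx": [-1], "abundance": [3.0]})
        )
        cfg = ScreenConfig(tag_length=12, reads_per_sample=4)
        for _n, seq, _q in generate_reads(clone, padded, cfg, "ACGTAC",
                                          np.random.default_rng(0), "s", 4):
            tag = seq[6:]
            assert tag == revcomp(padded.sequence[0:12])
            assert tag.startswith("TA")

    def test_every_tag_anchored_at_ta(self):
        rng = np.random.default_rng(11)
        g = random_genome(rng, 5000)
        ta = find_ta_sites(g)
        cfg = ScreenConfig(reads_per_sample=2000)
        lib = simulate_library(ta, cfg, rng)
        for _n, seq, _q in generate_reads(lib, g, cfg, "ACGTAC", rng, "s", 2000):
            assert seq[6:8] == "TA"

    def test_error_free_tags_match_genome_at_true_site(self):
        rng = np.random.default_rng(2)
        g = random_genome(rng, 3000)
        cfg = ScreenConfig(reads_per_sample=500)
        lib = simulate_library(find_ta_sites(g), cfg, rng)
        for name, seq, _q in generate_reads(lib, g, cfg, "ACGTAC", rng, "s", 500):
            _s, pos, orient, _i = name.rsplit(":", 3)
            p, tag = int(pos), seq[6:]
            if orient == "+":
                assert tag == g.sequence[p : p + 16]
            else:
                assert tag == revcomp(g.sequence[p + 2 - 16 : p + 2])

    def test_fastq_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = ScreenConfig(reads_per_sample=1000, rng_seed=9)
        out = []
        for run in range(2):
            rng = np.random.default_rng(cfg.rng_seed)
            g = random_genome(rng, 4000)
            lib = simulate_library(find_ta_sites(g), cfg, rng)
            path = tmp_path / f"r{run}.fastq"
            write_fastq(generate_reads(lib, g, cfg, "ACGTAC", rng, "s"), path)
            out.append(path.read_bytes())
        assert out[0] == out[1]


def test_frequency_conservation_through_neutral_chain():
    """All multipliers 1: clone frequency is unbiased through selection +
    bottleneck + sequencing (Monte-Carlo mean over replicates)."""
    from tnscreen.simulate import simulate_sample_counts
    import pandas as pd

    rng = np.random.default_rng(21)
    g = random_genome(rng, 20_000)
    lib = simulate_library(find_ta_sites(g), ScreenConfig(), rng)
    f0 = lib.frame["abundance"].to_numpy() / lib.total_abundance
    cfg = ScreenConfig(reads_per_sample=50_000)
    freqs = np.zeros(len(lib))
    n_rep = 40
    for _ in range(n_rep):
        counts = simulate_sample_counts(lib, FitnessMap(), cfg, "control", rng)
        freqs += counts / counts.sum()
    freqs /= n_rep
    # unbiasedness: mean absolute relative deviation shrinks with replicates;
    # check aggregate closeness rather than per-clone noise
    corr = np.corrcoef(f0, freqs)[0, 1]
    assert corr > 0.95
    assert abs(freqs.sum() - 1) < 1e-12
    assert np.mean(freqs - f0) == pytest.approx(0.0, abs=1e-6)
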