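"""Generative model: chemostat arithmetic, intercross, selection, counts."""

import math

import numpy as np
import pandas as pd
import pytest

from driftmap import PARENTS
from driftmap.markers import classify_markers
from driftmap.simulate import (FounderHaplotypes, QTL, SimConfig,
                               emit_depth_tables, emit_de_table,
                               generations_in_phase, pooled_counts_one_sample,
                               simulate_experiment, simulate_founder_pool,
                               simulate_selection_experiment)


class TestGenerationsInPhase:
    @pytest.mark.parametrize("d, hours, expected", [
        (0.10, 46.0, 0.10 * 46 / math.log(2)),  # the pool's chemostat phase
        (0.06, 0.0, 0.0),
        (math.log(2), 1.0, 1.0),  # one doubling per hour
    ])
    def test_values(self, d, hours, expected):
        assert generations_in_phase(d, hours) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            generations_in_phase(0.0, 10.0)
        with pytest.raises(ValueError):
            generations_in_phase(-0.1, 10.0)


class TestFounderPool:
    def test_no_intercross_gives_exact_quarter_frequencies(self):
        conf = SimConfig(n_chromosomes=1, chrom_length=50_000, pop_size=200,
                         intercross_generations=0, seed=0)
        _, pop = simulate_founder_pool(conf)
        f = pop.frequencies()
        assert np.all(f == 0.25)

    def test_intercrossed_pool_stays_balanced_in_expectation(self):
        conf = SimConfig(n_chromosomes=2, chrom_length=500_000, pop_size=1000,
                         marker_spacing=1000, seed=3)
        _, pop = simulate_founder_pool(conf)
        means = pop.frequencies().mean(axis=0)
        assert np.all(np.abs(means - 0.25) < 0.05)

    def test_same_seed_reproduces_population(self):
        conf = SimConfig(n_chromosomes=1, chrom_length=100_000, pop_size=150, seed=9)
        _, pop_a = simulate_founder_pool(conf)
        _, pop_b = simulate_founder_pool(conf)
        for chrom in pop_a.ancestry:
            assert np.array_equal(pop_a.ancestry[chrom], pop_b.ancestry[chrom])

    def test_small_pool_refused(self):
        with pytest.raises(ValueError, match="drift"):
            simulate_founder_pool(SimConfig(pop_size=50))

    def test_every_marker_is_segregating(self):
        conf = SimConfig(n_chromosomes=1, chrom_length=100_000, pop_size=150, seed=2)
        founders, _ = simulate_founder_pool(conf)
        # classify_markers raises on non-segregating sites
        classified = classify_markers(founders.table[["chrom", "pos", *PARENTS]])
        assert len(classified) == founders.n_markers


class TestSelection:
    def test_selection_tracks_single_locus_recursion(self):
        """Haploid selection at one locus follows p' = p(1+s)/(1+ps)."""
        conf = SimConfig(n_chromosomes=1, chrom_length=20_000, marker_spacing=2_000,
                         pop_size=100_000, intercross_generations=0,
                         qtls=[QTL("chr1", 9_000, "NA", 0.2)], replicates=1, seed=5)
        founders, pop = simulate_founder_pool(conf)
        truth = simulate_selection_experiment(pop, conf)
        m = founders.marker_index("chr1", 9_000)
        na = PARENTS.index("NA")
        p = 0.25
        expected = {"T0": p}
        for time, gens in (("T1", truth.generations["batch_realized"]),
                           ("T2", truth.generations["chemostat_realized"])):
            for _ in range(int(gens)):
                p = p * 1.2 / (1 + p * 0.2)
            expected[time] = p
        for time in ("T0", "T1", "T2"):
            observed = truth.freqs[("SM60", 1, time)][m, na]
            assert observed == pytest.approx(expected[time], abs=0.02)
        # favored-parent frequency rises monotonically through the phases
        course = [truth.freqs[("SM60", 1, t)][m, na] for t in ("T0", "T1", "T2")]
        assert course[0] < course[1] < course[2]
        # the control condition is untouched by selection
        ctrl = truth.freqs[("SM300", 1, "T2")][m, na]
        assert ctrl == pytest.approx(0.25, abs=0.02)

    def test_qtl_off_marker_rejected(self):
        conf = SimConfig(n_chromosomes=1, chrom_length=20_000, pop_size=150,
                         intercross_generations=0,
                         qtls=[QTL("chr1", 1_234, "NA", 0.2)], seed=0)
        _, pop = simulate_founder_pool(conf)
        with pytest.raises(ValueError, match="marker"):
            simulate_selection_experiment(pop, conf)

    def test_truth_frequencies_sum_to_one(self, tiny_bundle):
        for f in tiny_bundle.truth.freqs.values():
            assert np.max(np.abs(f.sum(axis=1) - 1)) < 1e-12

    def test_infinite_census_neutral_frequencies_constant(self, tiny_bundle):
        t0 = tiny_bundle.truth.freqs[("SM60", 1, "T0")]
        t2 = tiny_bundle.truth.freqs[("SM60", 1, "T2")]
        assert np.array_equal(t0, t2)


def _constant_private_founders(n_sites: int, chrom_len: int = 10_000_000):
    """Marker table of private-NA sites only (G private, A shared)."""
    table = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_sites + 1) * 100,
        "NA": "G", "SA": "A", "WA": "A", "WE": "A",
        "class": "private-NA",
    })
    return FounderHaplotypes(table=table, chrom_lengths={"chr1": chrom_len})


class TestPooledCounts:
    def test_high_coverage_recovers_truth(self):
        founders = _constant_private_founders(300)
        freq = np.tile([0.25, 0.25, 0.25, 0.25], (300, 1))
        rng = np.random.default_rng(0)
        df = pooled_counts_one_sample(freq, founders, coverage=1e6, rho=0.0, rng=rng)
        g = df[df["allele"] == "G"].set_index("pos")["count"]
        depth = df.groupby("pos")["count"].sum()
        assert np.max(np.abs(g / depth - 0.25)) < 0.005

    def test_zero_depth_sites_emitted_with_zero_counts(self):
        founders = _constant_private_founders(500)
        freq = np.tile([0.25, 0.25, 0.25, 0.25], (500, 1))
        rng = np.random.default_rng(1)
        df = pooled_counts_one_sample(freq, founders, coverage=0.5, rho=0.0, rng=rng)
        depth = df.groupby("pos")["count"].sum()
        assert (depth == 0).any()  # sites are present, flagged by zero depth
        assert set(df["pos"]) == set(founders.table["pos"])

    def test_overdispersion_matches_beta_binomial_variance(self):
        """At fixed depth n the count-fraction variance is
        p(1-p)(1+(n-1)ρ)/n, far above the binomial p(1-p)/n."""
        n_sites, rho, p = 20_000, 0.1, 0.25
        founders = _constant_private_founders(n_sites)
        freq = np.tile([p, 0.25, 0.25, 0.25], (n_sites, 1))
        rng = np.random.default_rng(7)
        df = pooled_counts_one_sample(freq, founders, coverage=100, rho=rho, rng=rng)
        g = df[df["allele"] == "G"].set_index("pos")["count"]
        depth = df.groupby("pos")["count"].sum()
        at100 = depth[depth == 100].index
        frac = (g.loc[at100] / 100).to_numpy()
        bb_var = p * (1 - p) * (1 + 99 * rho) / 100
        binom_var = p * (1 - p) / 100
        assert frac.var() > 3 * binom_var
        assert frac.var() == pytest.approx(bb_var, rel=0.35)

    def test_bad_rho_rejected(self):
        founders = _constant_private_founders(10)
        freq = np.tile([0.25, 0.25, 0.25, 0.25], (10, 1))
        with pytest.raises(ValueError, match="rho"):
            pooled_counts_one_sample(freq, founders, 50, rho=1.0,
                                     rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            SimConfig(overdispersion=-0.1)

    def test_unnormalized_frequencies_rejected(self):
        founders = _constant_private_founders(5)
        freq = np.tile([0.5, 0.25, 0.25, 0.25], (5, 1))
        with pytest.raises(ValueError, match="sum to 1"):
            pooled_counts_one_sample(freq, founders, 50, 0.0,
                                     np.random.default_rng(0))


class TestSideChannels:
    def test_de_table_plants_configured_counts(self):
        conf = SimConfig(seed=0)
        de, truth = emit_de_table(conf, np.random.default_rng(0))
        assert (truth["direction"] == "down").sum() == 111
        assert (truth["direction"] == "up").sum() == 76
        strict = de[de["log2_ratio"].abs() >= 3]
        assert (strict["log2_ratio"] < 0).sum() == 26
        assert (strict["log2_ratio"] > 0).sum() == 24

    def test_zero_mito_loss_keeps_ratio_flat(self):
        conf = SimConfig(n_chromosomes=1, chrom_length=100_000,
                         mito_loss_per_gen=0.0, seed=0)
        gens = {"batch_realized": 5, "chemostat_realized": 7}
        _, truth = emit_depth_tables(conf, gens, np.random.default_rng(0))
        assert len({round(v, 12) for v in truth.values()}) == 1

    def test_mito_loss_decays_in_treatment_only(self):
        conf = SimConfig(n_chromosomes=1, chrom_length=100_000,
                         mito_loss_per_gen=0.1, seed=0)
        gens = {"batch_realized": 5, "chemostat_realized": 7}
        _, truth = emit_depth_tables(conf, gens, np.random.default_rng(0))
        assert truth[("SM60", "T0")] > truth[("SM60", "T1")] > truth[("SM60", "T2")]
        assert truth[("SM300", "T0")] == truth[("SM300", "T2")]
        assert truth[("SM60", "T2")] == pytest.approx(
            conf.mito_base_ratio * 0.9 ** 12)


class TestDeterminism:
    def test_full_experiment_reproducible(self, tiny_config, tiny_bundle):
        again = simulate_experiment(tiny_config)
        pd.testing.assert_frame_equal(tiny_bundle.counts[0].counts,
                                      again.counts[0].counts)
        pd.testing.assert_frame_equal(tiny_bundle.de_table, again.de_table)
        pd.testing.assert_frame_equal(tiny_bundle.depth, again.depth)
        for key, f in tiny_bundle.truth.freqs.items():
            assert np.array_equal(f, again.truth.freqs[key])
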