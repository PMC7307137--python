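"""Marker classification and windowed parental-frequency estimation."""

import numpy as np
import pandas as pd
import pytest

from driftmap import PARENTS
from driftmap._util import window_starts
from driftmap.frequency import (FrequencyTrack, mean_parent_frequency,
                                window_frequencies)
from driftmap.markers import classify_markers, classify_site, site_parent_frequency
from driftmap.simulate import SampleCounts

from conftest import build_track


class TestClassify:
    @pytest.mark.parametrize("alleles, expected", [
        ({"NA": "G", "SA": "A", "WA": "A", "WE": "A"}, "private-NA"),
        ({"NA": "A", "SA": "A", "WA": "A", "WE": "T"}, "private-WE"),
        ({"NA": "G", "SA": "G", "WA": "A", "WE": "A"}, "split-2-2"),
        ({"NA": "G", "SA": "A", "WA": "T", "WE": "A"}, "other"),
    ])
    def test_patterns(self, alleles, expected):
        assert classify_site(alleles) == expected

    def test_requires_four_parents(self):
        with pytest.raises(ValueError, match="4 parents"):
            classify_site({"NA": "G", "SA": "A", "WA": "A"})

    def test_rejects_monomorphic_site(self):
        with pytest.raises(ValueError, match="not segregating"):
            classify_site({p: "A" for p in PARENTS})

    def test_table_classification_and_sorting_check(self):
        table = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 50],
                              "NA": ["G", "A"], "SA": ["A", "A"],
                              "WA": ["A", "C"], "WE": ["A", "C"]})
        with pytest.raises(ValueError, match="increasing"):
            classify_markers(table)
        ok = classify_markers(table.sort_values("pos").reset_index(drop=True))
        assert list(ok["class"]) == ["split-2-2", "private-NA"]


class TestSiteFrequency:
    def test_private_site_direct_ratio(self):
        row = {"class": "private-NA", "NA": "G", "SA": "A", "WA": "A", "WE": "A"}
        assert site_parent_frequency({"G": 25, "A": 75}, row) == {"NA": 0.25}

    def test_fixed_private_site(self):
        row = {"class": "private-WE", "NA": "A", "SA": "A", "WA": "A", "WE": "T"}
        assert site_parent_frequency({"T": 100}, row) == {"WE": 1.0}

    def test_split_site_pair_sums(self):
        row = {"class": "split-2-2", "NA": "G", "SA": "G", "WA": "A", "WE": "A"}
        out = site_parent_frequency({"G": 60, "A": 40}, row)
        assert out == {"NA+SA": 0.6, "WA+WE": 0.4}

    def test_zero_depth_is_missing_not_zero(self):
        row = {"class": "private-SA", "NA": "A", "SA": "G", "WA": "A", "WE": "A"}
        out = site_parent_frequency({}, row)
        assert np.isnan(out["SA"])


class TestWindowGeometry:
    @pytest.mark.parametrize("length, expected", [
        (2_000_000, (2_000_000 - 10_000) // 2_000 + 1),
        (10_000, 1),
        (11_000, 2),  # flush final window at start 1000
        (12_000, 2),
    ])
    def test_window_count_matches_half_open_convention(self, length, expected):
        starts = window_starts(length, 10_000, 2_000)
        assert len(starts) == expected
        assert int(np.ceil((length - 10_000) / 2_000)) + 1 == expected

    def test_window_smaller_than_step_rejected(self):
        with pytest.raises(ValueError):
            window_starts(100_000, 1_000, 2_000)


def _hand_fixture():
    """A 5-site single-window fixture with hand-computable frequencies."""
    table = pd.DataFrame({
        "chrom": "chr1",
        "pos": [1_001, 3_001, 5_001, 7_001, 9_001],
        "NA": ["G", "A", "A", "A", "G"],
        "SA": ["A", "G", "A", "A", "G"],
        "WA": ["A", "A", "G", "A", "A"],
        "WE": ["A", "A", "A", "G", "A"],
    })
    # classes: private-NA, private-SA, private-WA, private-WE, split-2-2
    counts = pd.DataFrame([
        ("chr1", 1_001, "G", 30), ("chr1", 1_001, "A", 70),   # x_NA=0.30 d=100
        ("chr1", 3_001, "G", 10), ("chr1", 3_001, "A", 30),   # x_SA=0.25 d=40
        ("chr1", 5_001, "G", 12), ("chr1", 5_001, "A", 48),   # x_WA=0.20 d=60
        ("chr1", 7_001, "G", 50), ("chr1", 7_001, "A", 150),  # x_WE=0.25 d=200
        ("chr1", 9_001, "G", 55), ("chr1", 9_001, "A", 45),   # split, unused
    ], columns=["chrom", "pos", "allele", "count"])
    sample = SampleCounts(replicate=1, condition="SM60", time="T0", counts=counts)
    return table, sample


class TestWindowFrequencies:
    def test_single_window_matches_hand_computation(self):
        table, sample = _hand_fixture()
        track = window_frequencies([sample], table, window=10_000, step=10_000,
                                   chrom_lengths={"chr1": 10_000})
        expected = np.array([0.30, 0.25, 0.20, 0.25])
        expected = expected / expected.sum()
        assert track.freq[0, :, 0] == pytest.approx(expected, abs=1e-12)
        assert track.freq[0, :, 0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_depth_weighted_average_equals_bruteforce_oracle(self, tiny_bundle):
        """Window estimates equal a site-by-site brute-force recomputation."""
        table = tiny_bundle.founders.table
        sc = tiny_bundle.counts[0]
        track = window_frequencies([sc], table, window=10_000, step=2_000,
                                   chrom_lengths=tiny_bundle.founders.chrom_lengths)
        counts = sc.counts
        depth_by_site = counts.groupby(["chrom", "pos"])["count"].sum()
        rng = np.random.default_rng(0)
        checked = 0
        for w in rng.choice(np.flatnonzero(~track.mask[:, 0]), 12, replace=False):
            chrom = track.windows.at[w, "chrom"]
            start, end = track.windows.at[w, "start"], track.windows.at[w, "end"]
            est = np.zeros(4)
            for j, parent in enumerate(PARENTS):
                cls = f"private-{parent}"
                sub = table[(table["chrom"] == chrom) & (table["class"] == cls)
                            & (table["pos"] - 1 >= start) & (table["pos"] - 1 < end)]
                num = den = 0.0
                for rec in sub.to_dict("records"):
                    d = depth_by_site.get((chrom, rec["pos"]), 0)
                    if d == 0:
                        continue
                    k = counts[(counts["chrom"] == chrom)
                               & (counts["pos"] == rec["pos"])
                               & (counts["allele"] == rec[parent])]["count"].sum()
                    num += d * (k / d)
                    den += d
                est[j] = num / den
            est = est / est.sum()
            assert track.freq[w, :, 0] == pytest.approx(est, abs=1e-12)
            checked += 1
        assert checked == 12

    def test_unmasked_windows_sum_to_one(self, tiny_track):
        sums = np.nansum(tiny_track.freq, axis=1)
        live = ~tiny_track.mask
        assert np.max(np.abs(sums[live] - 1)) < 1e-9

    def test_window_without_private_sites_for_a_parent_is_masked(self):
        table, sample = _hand_fixture()
        table2 = table.drop(index=0).reset_index(drop=True)  # remove the NA site
        track = window_frequencies([sample], table2, window=10_000, step=10_000,
                                   chrom_lengths={"chr1": 10_000})
        assert bool(track.mask[0, 0])
        assert np.isnan(track.freq[0, :, 0]).all()

    def test_high_coverage_limit_recovers_truth_per_window(self):
        from driftmap.simulate import SimConfig, simulate_experiment

        conf = SimConfig(n_chromosomes=1, chrom_length=100_000, marker_spacing=500,
                         pop_size=200, coverage=1e5, overdispersion=0.0,
                         replicates=1, seed=6, apply_drift=False,
                         n_de_down=0, n_de_up=0, n_de_down_strict=0,
                         n_de_up_strict=0, n_background_genes=0, n_ase_outliers=0)
        bundle = simulate_experiment(conf)
        track = window_frequencies(bundle.counts[:1], bundle.founders.table,
                                   chrom_lengths=bundle.founders.chrom_lengths)
        truth = bundle.truth.freqs[("SM60", 1, "T0")]
        table = bundle.founders.table
        for w in np.flatnonzero(~track.mask[:, 0]):
            start, end = track.windows.at[w, "start"], track.windows.at[w, "end"]
            est_truth = np.zeros(4)
            for j, parent in enumerate(PARENTS):
                sel = ((table["class"] == f"private-{parent}")
                       & (table["pos"] - 1 >= start) & (table["pos"] - 1 < end))
                est_truth[j] = truth[sel.to_numpy(), j].mean()
            est_truth = est_truth / est_truth.sum()
            assert np.max(np.abs(track.freq[w, :, 0] - est_truth)) < 0.005


class TestTrackRoundtripAndMeans:
    def test_tsv_roundtrip_preserves_frequencies(self, tiny_track, tmp_path):
        path = tmp_path / "track.tsv"
        tiny_track.write_tsv(path)
        back = FrequencyTrack.read_tsv(path)
        assert back.n_windows == tiny_track.n_windows
        s = tiny_track.sample_index("SM60_R2_T1")
        s2 = back.sample_index("SM60_R2_T1")
        np.testing.assert_allclose(back.freq[:, :, s2], tiny_track.freq[:, :, s],
                                   atol=1e-9, equal_nan=True)

    def test_balanced_pool_means_near_quarter(self, tiny_track):
        means, diag = mean_parent_frequency(tiny_track, "SM60_R1_T0")
        assert np.all(np.abs(means - 0.25) < 0.05)
        assert diag["max_mean"] < 0.32

    def test_clonal_pool_mean_is_one(self):
        f = np.zeros((8, 4))
        f[:, PARENTS.index("WE")] = 1.0
        track = build_track({("SM60", 1, "T0"): f})
        means, diag = mean_parent_frequency(track, "SM60_R1_T0")
        assert means["WE"] == 1.0
        assert diag["max_parent"] == "WE"

    def test_all_masked_raises(self):
        f = np.full((4, 4), np.nan)
        track = build_track({("SM60", 1, "T0"): f})
        with pytest.raises(ValueError, match="masked"):
            mean_parent_frequency(track, "SM60_R1_T0")
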