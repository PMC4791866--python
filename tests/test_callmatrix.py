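import numpy as np
import pandas as pd
import pytest

from cnaprofiler import callmatrix as cm
from cnaprofiler.segmentation import brute_force_caller, call_aberrations
from cnaprofiler.synthetic import make_probe_map


def make_calls(values, samples=None):
    values = np.asarray(values, dtype=np.int8)
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=samples)


class TestSegmentsToTernary:
    def test_no_segments_all_zero(self, probe_map_100):
        calls = cm.segments_to_ternary({}, probe_map_100, ["A", "B"])
        assert calls.shape == (100, 2)
        assert (calls.to_numpy() == 0).all()

    def test_single_gain_projects_three_probes(self, probe_map_100):
        v = np.zeros(100)
        v[3:6] = 0.6
        segs = call_aberrations(v, probe_map_100, 0.1, sample_id="A")
        calls = cm.segments_to_ternary({"A": segs, "B": []}, probe_map_100, ["A", "B"])
        assert calls["A"].sum() == 3
        assert (calls["A"].to_numpy()[3:6] == 1).all()
        assert (calls["B"] == 0).all()

    def test_oracle_and_main_caller_give_identical_matrices(self, probe_map_100, rng):
        for _ in range(10):
            v = rng.normal(0, 0.1, 100)
            a = rng.integers(0, 80)
            v[a : a + 12] -= 0.6
            m1 = cm.segments_to_ternary(
                {"A": call_aberrations(v, probe_map_100, 0.1, sample_id="A")},
                probe_map_100, ["A"])
            m2 = cm.segments_to_ternary(
                {"A": brute_force_caller(v, probe_map_100, 0.1, sample_id="A")},
                probe_map_100, ["A"])
            pd.testing.assert_frame_equal(m1, m2)


class TestRegionSize:
    @pytest.mark.parametrize(
        "start,stop,size",
        [
            (78_765_816, 79_106_841, 341_025),
            (212_228_277, 212_570_219, 341_942),
            (5, 6, 1),
        ],
    )
    def test_half_open_length(self, start, stop, size):
        assert cm.region_size(start, stop) == size

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            cm.region_size(10, 10)


class TestRoundPercent:
    @pytest.mark.parametrize(
        "count,total,expected", [(9, 40, 22.5), (5, 7, 71.4), (6, 40, 15.0)]
    )
    def test_one_decimal_half_up(self, count, total, expected):
        assert cm.round_percent(count, total) == expected

    def test_integer_display_rule(self):
        assert cm.round_percent(7, 24, decimals=0) == 29
        assert cm.round_percent(1, 8, decimals=1) == 12.5

    def test_half_up_not_bankers(self):
        assert cm.round_percent(1, 8, decimals=0) == 13  # 12.5 rounds up


class TestFrequencyTable:
    def test_recurrent_run_merged_and_counted(self, probe_map_100):
        n_samples = 40
        values = np.zeros((100, n_samples), dtype=np.int8)
        values[20:30, :9] = -1  # 9/40 = 22.5% > 10%
        calls = make_calls(values)
        regions = cm.frequency_table(calls, probe_map_100, list(calls.columns), "loss")
        assert len(regions) == 1
        r = regions[0]
        assert (r.first_probe, r.last_probe) == (20, 29)
        assert r.count == 9
        assert r.percent == 22.5
        assert r.size_bp == 10_000

    def test_below_threshold_not_reported(self, probe_map_100):
        values = np.zeros((100, 40), dtype=np.int8)
        values[10:15, :4] = 1  # 10% is not strictly above 10%
        calls = make_calls(values)
        assert cm.frequency_table(calls, probe_map_100, list(calls.columns), "gain") == []

    def test_carriers_must_span_entire_run(self, probe_map_100):
        values = np.zeros((100, 10), dtype=np.int8)
        values[10:20, :3] = -1
        values[15:20, 3] = -1  # partial carrier does not count for the run
        calls = make_calls(values)
        regions = cm.frequency_table(calls, probe_map_100, list(calls.columns), "loss")
        assert len(regions) == 1
        assert regions[0].count == 3
        assert regions[0].percent == 30.0

    def test_runs_split_at_chromosome_boundary(self, probe_map_2x50):
        values = np.zeros((100, 5), dtype=np.int8)
        values[45:55, :] = 1
        calls = make_calls(values)
        regions = cm.frequency_table(calls, probe_map_2x50, list(calls.columns), "gain")
        assert [(r.first_probe, r.last_probe) for r in regions] == [(45, 49), (50, 54)]
        assert [r.chromosome for r in regions] == ["1", "2"]

    def test_raising_threshold_shrinks_regions(self, probe_map_100, rng):
        values = (rng.random((100, 20)) < 0.3).astype(np.int8)
        calls = make_calls(values)
        group = list(calls.columns)
        low = cm.frequency_table(calls, probe_map_100, group, "gain", min_percent=10)
        high = cm.frequency_table(calls, probe_map_100, group, "gain", min_percent=25)
        low_probes = {p for r in low for p in range(r.first_probe, r.last_probe + 1)}
        high_probes = {p for r in high for p in range(r.first_probe, r.last_probe + 1)}
        assert high_probes <= low_probes

    def test_empty_group_rejected(self, probe_map_100):
        calls = make_calls(np.zeros((100, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            cm.frequency_table(calls, probe_map_100, [], "loss")


class TestConcomitantSamples:
    def test_single_region_equals_carrier_set(self, probe_map_100):
        values = np.zeros((100, 6), dtype=np.int8)
        values[10:20, [0, 2, 4]] = -1
        calls = make_calls(values)
        regions = cm.frequency_table(calls, probe_map_100, list(calls.columns), "loss")
        assert cm.concomitant_samples(regions, calls) == {"S0", "S2", "S4"}

    def test_disjoint_carriers_give_empty_set(self, probe_map_100):
        values = np.zeros((100, 6), dtype=np.int8)
        values[10:20, :3] = -1
        values[40:50, 3:] = -1
        calls = make_calls(values)
        regions = cm.frequency_table(calls, probe_map_100, list(calls.columns), "loss")
        assert len(regions) == 2
        assert cm.concomitant_samples(regions, calls) == set()

    def test_planted_shared_regions_recovered(self, probe_map_100, rng):
        """Samples sharing every one of several regions are recovered exactly."""
        values = np.zeros((100, 20), dtype=np.int8)
        shared = [0, 3, 7, 11, 15, 19]
        blocks = [(5, 9), (20, 24), (40, 44), (60, 64), (80, 84)]
        for f, l in blocks:
            values[f : l + 1, shared] = -1
        # extra carriers of single regions only
        values[5:10, 1] = -1
        values[20:25, 2] = -1
        calls = make_calls(values)
        regions = cm.frequency_table(calls, probe_map_100, list(calls.columns), "loss")
        assert len(regions) == len(blocks)
        expected = {f"S{i}" for i in shared}
        assert cm.concomitant_samples(regions, calls) == expected


class TestPrivateAlterations:
    def test_reported_when_absent_from_background(self, probe_map_100):
        values = np.zeros((100, 10), dtype=np.int8)
        values[30:40, :3] = -1  # group A carriers
        calls = make_calls(values)
        a, b = ["S0", "S1", "S2"], [f"S{i}" for i in range(3, 10)]
        regions = cm.private_alterations(calls, probe_map_100, a, b)
        assert len(regions) == 1
        assert regions[0].count == 3
        assert regions[0].direction == "loss"

    def test_any_background_overlap_suppresses(self, probe_map_100):
        values = np.zeros((100, 10), dtype=np.int8)
        values[30:40, :3] = -1
        values[35, 5] = 1  # any alteration of a B sample disqualifies the probe
        calls = make_calls(values)
        a, b = ["S0", "S1", "S2"], [f"S{i}" for i in range(3, 10)]
        regions = cm.private_alterations(calls, probe_map_100, a, b)
        assert [(r.first_probe, r.last_probe) for r in regions] == [(30, 34), (36, 39)]

    def test_min_carriers_one_gives_per_sample_private_calls(self, probe_map_100):
        values = np.zeros((100, 4), dtype=np.int8)
        values[10:15, 0] = 1
        calls = make_calls(values)
        regions = cm.private_alterations(calls, probe_map_100, ["S0", "S1"],
                                         ["S2", "S3"], min_carriers_a=1)
        assert len(regions) == 1 and regions[0].carriers == ["S0"]

    def test_overlapping_groups_rejected(self, probe_map_100):
        calls = make_calls(np.zeros((100, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            cm.private_alterations(calls, probe_map_100, ["S0"], ["S0", "S1"])


class TestGenesInRegions:
    def region(self, chrom, start, stop):
        return cm.RecurrentRegion(chromosome=chrom, start=start, stop=stop,
                                  first_probe=0, last_probe=0, direction="loss")

    def test_contained_gene_included(self, tiny_gene_annotation):
        (r,) = cm.genes_in_regions([self.region("1", 0, 2000)], tiny_gene_annotation)
        assert r.genes == ["GA"]

    def test_abutting_gene_excluded(self, tiny_gene_annotation):
        (r,) = cm.genes_in_regions([self.region("1", 0, 10_000)], tiny_gene_annotation)
        assert r.genes == ["GA"]  # GB starts exactly at region stop

    def test_matches_quadratic_scan_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(300)],
                "chromosome": rng.choice(["1", "2", "3"], 300),
                "start": rng.integers(0, 100_000, 300),
            }
        )
        genes["stop"] = genes["start"] + rng.integers(1, 5_000, 300)
        for _ in range(200):
            chrom = str(rng.choice(["1", "2", "3"]))
            start = int(rng.integers(0, 100_000))
            stop = start + int(rng.integers(1, 10_000))
            (r,) = cm.genes_in_regions([self.region(chrom, start, stop)], genes)
            expected = [
                row.gene
                for row in genes.itertuples()
                if row.chromosome == chrom and row.start < stop and row.stop > start
            ]
            assert sorted(r.genes) == sorted(expected)


class TestFrequencyTrack:
    def test_zero_matrix_zero_track(self, probe_map_100):
        calls = make_calls(np.zeros((100, 3), dtype=np.int8))
        track = cm.frequency_track(calls, probe_map_100)
        assert track["n_gain"].sum() == 0 and track["n_loss"].sum() == 0

    def test_counts_conserved(self, probe_map_100, rng):
        values = rng.integers(-1, 2, size=(100, 8)).astype(np.int8)
        calls = make_calls(values)
        track = cm.frequency_track(calls, probe_map_100)
        assert track["n_gain"].sum() + track["n_loss"].sum() == (values != 0).sum()
        assert track.loc[0, "n_loss"] == (values[0] == -1).sum()
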