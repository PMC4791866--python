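import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from cnaprofiler import callmatrix as cm
from cnaprofiler import clustering as cl
from cnaprofiler.normalization import estimate_noise_sd
from cnaprofiler.segmentation import call_cohort
from cnaprofiler.synthetic import default_config, make_probe_map, simulate_cohort


class TestProbeFilter:
    def test_default_threshold_is_three_samples(self):
        calls = pd.DataFrame(
            {"A": [1, 1, 0], "B": [1, -1, 0], "C": [0, 1, 0], "D": [0, 0, 0]}
        )
        # probe 0 altered in 2 samples, probe 1 in 3, probe 2 in 0
        assert list(cl.filter_informative_probes(calls)) == [1]

    def test_zero_threshold_keeps_all(self):
        calls = pd.DataFrame({"A": [0, 0], "B": [0, 1]})
        assert list(cl.filter_informative_probes(calls, min_altered=0)) == [0, 1]


class TestHammingDistance:
    def test_identical_vectors(self):
        assert cl.hamming_distance([1, 0, -1], [1, 0, -1]) == 0

    def test_loss_vs_gain_counts_once(self):
        assert cl.hamming_distance((-1, 0, 1), (1, 0, 1)) == 1

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(200):
            x = rng.integers(-1, 2, 50)
            y = rng.integers(-1, 2, 50)
            expected = sum(1 for a, b in zip(x, y) if a != b)
            assert cl.hamming_distance(x, y) == expected

    def test_is_a_metric_on_random_triples(self, rng):
        for _ in range(200):
            x, y, z = (rng.integers(-1, 2, 40) for _ in range(3))
            dxy = cl.hamming_distance(x, y)
            dyz = cl.hamming_distance(y, z)
            dxz = cl.hamming_distance(x, z)
            assert dxy == cl.hamming_distance(y, x)
            assert dxz <= dxy + dyz
            assert (dxy == 0) == bool(np.all(x == y))


class TestClusterSamples:
    def test_duplicated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        block_a = rng.integers(-1, 2, 60)
        block_b = rng.integers(-1, 2, 60)
        calls = pd.DataFrame(
            {"A1": block_a, "A2": block_a, "A3": block_a,
             "B1": block_b, "B2": block_b}
        )
        result = cl.cluster_samples(calls, min_altered=0, k=2)
        labels = result.labels
        assert labels["A1"] == labels["A2"] == labels["A3"]
        assert labels["B1"] == labels["B2"]
        assert labels["A1"] != labels["B1"]

    def test_worked_five_sample_instance_matches_scipy_heights(self):
        """Complete-linkage merge heights agree with an independent
        implementation on a tie-free 5-sample instance."""
        rng = np.random.default_rng(42)
        calls = pd.DataFrame(
            rng.integers(-1, 2, size=(60, 5)), columns=list("ABCDE")
        )
        result = cl.cluster_samples(calls, min_altered=0, k=2)
        Z = linkage(result.distances, method="complete")
        np.testing.assert_allclose(
            np.sort(result.merges[:, 2]), np.sort(Z[:, 2])
        )

    def test_complete_linkage_height_by_hand(self):
        # distances: d(A,B)=1, d(A,C)=4, d(B,C)=5 -> merge A,B at 1; then C at 5
        calls = pd.DataFrame(
            {"A": [1, 0, 0, 1, 1], "B": [1, 1, 0, 1, 1], "C": [0, 0, 1, -1, 0]}
        )
        result = cl.cluster_samples(calls, min_altered=0, k=1)
        assert list(result.merges[:, 2]) == [1.0, 5.0]

    def test_sample_order_invariance(self, rng):
        calls = pd.DataFrame(rng.integers(-1, 2, size=(80, 12)),
                             columns=[f"S{i:02d}" for i in range(12)])
        r1 = cl.cluster_samples(calls, min_altered=0, k=3)
        r2 = cl.cluster_samples(calls[list(reversed(calls.columns))],
                                min_altered=0, k=3)
        assert r1.labels == r2.labels

    def test_fewer_samples_than_k_rejected(self):
        calls = pd.DataFrame({"A": [1], "B": [0]})
        with pytest.raises(ValueError):
            cl.cluster_samples(calls, k=3)

    def test_filter_monotonicity_shrinks_distances(self, rng):
        calls = pd.DataFrame(rng.integers(-1, 2, size=(100, 8)))
        calls.columns = [f"S{i}" for i in range(8)]
        d_lo = cl.cluster_samples(calls, min_altered=0, k=2).distances
        d_hi = cl.cluster_samples(calls, min_altered=4, k=2).distances
        assert np.all(d_hi <= d_lo)

    def test_planted_cluster_templates_recovered(self):
        """Hamming/complete-linkage clustering recovers the four planted
        burden/direction templates at moderate noise (one seed; the 20-seed
        replication runs in the acceptance suite)."""
        cfg = default_config(seed=9)
        matrix, metadata, _truth = simulate_cohort(cfg)
        pm = make_probe_map(cfg.n_chromosomes, cfg.probes_per_chromosome,
                            cfg.probe_spacing_bp)
        chroms = pm["chromosome"].to_numpy()
        sigmas = {s: estimate_noise_sd(matrix[s].to_numpy(), chroms)
                  for s in matrix.columns}
        segments = call_cohort(matrix, pm, sigmas)
        calls = cm.segments_to_ternary(segments, pm, list(matrix.columns))
        result = cl.cluster_samples(calls, min_altered=3, k=4)
        truth_labels = metadata.set_index("sample_id")["true_cluster"]
        pred = [result.labels[s] for s in result.sample_ids]
        true = [truth_labels[s] for s in result.sample_ids]
        assert adjusted_rand_score(true, pred) >= 0.9


class TestDetectOutliers:
    def test_planted_distant_sample_flagged(self, rng):
        # three tight blocks (within 0, between ~10) and one sample that
        # disagrees with everything at every probe
        common = rng.integers(-1, 2, size=100)
        variants = []
        for b in range(3):
            v = common.copy()
            v[b * 10 : b * 10 + 5] = (v[b * 10 : b * 10 + 5] + 2) % 3 - 1
            variants.append(v)
        calls = pd.DataFrame({f"S{i}": variants[i % 3] for i in range(9)})
        calls["OUT"] = (common + 2) % 3 - 1  # shifts every ternary value
        result = cl.detect_outliers(calls, min_altered=0, k=3)
        assert result.outliers == {"OUT"}
        assert set(result.labels) == set(calls.columns) - {"OUT"}

    def test_well_separated_data_has_no_outliers(self, rng):
        block = rng.integers(-1, 2, size=(50, 2))
        calls = pd.DataFrame(
            {f"A{i}": block[:, 0] for i in range(3)}
            | {f"B{i}": block[:, 1] for i in range(3)}
        )
        result = cl.detect_outliers(calls, min_altered=0, k=2)
        assert result.outliers == set()

    def test_zero_cap_disables_removal(self, rng):
        calls = pd.DataFrame(rng.integers(-1, 2, size=(60, 6)),
                             columns=[f"S{i}" for i in range(6)])
        result = cl.detect_outliers(calls, min_altered=0, k=3,
                                    max_outlier_cluster_size=0)
        assert result.outliers == set()


def test_newick_export_parses(rng):
    calls = pd.DataFrame(rng.integers(-1, 2, size=(40, 6)),
                         columns=[f"S{i}" for i in range(6)])
    result = cl.cluster_samples(calls, min_altered=0, k=2)
    text = result.to_newick()
    assert text.endswith(";")
    assert text.count("(") == 5  # n-1 internal nodes
    for s in calls.columns:
        assert s in text
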