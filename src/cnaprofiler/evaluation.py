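"""Replicated benchmark experiments on simulated cohorts.

These routines measure how well the pipeline recovers planted truth under
the default study conditions: caller-vs-oracle agreement, probe-level
recovery of planted aberrations, adjusted-Rand recovery of the planted
cluster structure, and calibration/power of the log-rank comparison.
They are used by the test suite and the reproduction script; problem
sizes are arguments so both can choose their replication.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import callmatrix as cm
from .clustering import cluster_samples
from .cohort_stats import logrank_test
from .normalization import estimate_noise_sd
from .segmentation import brute_force_caller, call_aberrations, call_cohort
from .synthetic import default_config, make_probe_map, simulate_cohort, simulate_survival

__all__ = [
    "caller_oracle_agreement",
    "cluster_recovery_aris",
    "logrank_power_fraction",
    "logrank_type1_error",
    "planted_recovery_f1",
]


def caller_oracle_agreement(n_profiles: int = 200, n_probes: int = 100,
                            sigma: float = 0.1, seed: int = 0) -> float:
    """Fraction of random planted profiles on which the recursive caller and
    the exhaustive greedy oracle emit identical segment lists."""
    pm = make_probe_map(1, n_probes, 1000)
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_profiles):
        v = rng.normal(0.0, sigma, n_probes)
        for _ in range(rng.integers(0, 4)):
            a = int(rng.integers(0, max(n_probes - 20, 1)))
            w = int(rng.integers(5, 20))
            v[a : a + w] += rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.8)
        main = call_aberrations(v, pm, sigma)
        oracle = brute_force_caller(v, pm, sigma)
        if [(s.first_probe, s.last_probe, s.call) for s in main] == \
           [(s.first_probe, s.last_probe, s.call) for s in oracle]:
            agree += 1
    return agree / n_profiles


def planted_recovery_f1(n_seeds: int = 20, n_profiles: int = 10,
                        n_probes: int = 600, sigma: float = 0.1,
                        seed: int = 0) -> float:
    """Pooled probe-level F1 of directed calls against planted truth.

    Profiles carry 2–4 planted blocks of >= 10 probes with |log2| in
    [0.3, 0.8] on Gaussian noise of the given sigma; noise is re-estimated
    from each profile before calling.  A probe counts as a true positive
    when the called direction matches the planted one.
    """
    pm = make_probe_map(4, n_probes // 4, 43_000)
    chroms = pm["chromosome"].to_numpy()
    tp = fp = fn = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        for _ in range(n_profiles):
            truth = np.zeros(n_probes, dtype=int)
            v = rng.normal(0.0, sigma, n_probes)
            for _ in range(int(rng.integers(2, 5))):
                w = int(rng.integers(10, 31))
                a = int(rng.integers(0, n_probes - w))
                if truth[max(a - 2, 0) : a + w + 2].any():
                    continue  # keep planted blocks disjoint and separated
                amp = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.8))
                v[a : a + w] += amp
                truth[a : a + w] = 1 if amp > 0 else -1
            sd = estimate_noise_sd(v, chroms)
            called = np.zeros(n_probes, dtype=int)
            for seg in call_aberrations(v, pm, sd):
                called[seg.first_probe : seg.last_probe + 1] = (
                    1 if seg.call == "gain" else -1
                )
            tp += int(np.sum((called != 0) & (called == truth)))
            fp += int(np.sum((called != 0) & (called != truth)))
            fn += int(np.sum((truth != 0) & (called == 0)))
    return 2 * tp / (2 * tp + fp + fn)


def _call_matrix_for(cfg):
    pm = make_probe_map(cfg.n_chromosomes, cfg.probes_per_chromosome,
                        cfg.probe_spacing_bp)
    matrix, metadata, _truth = simulate_cohort(cfg)
    chroms = pm["chromosome"].to_numpy()
    sigmas = {s: estimate_noise_sd(matrix[s].to_numpy(), chroms)
              for s in matrix.columns}
    segments = call_cohort(matrix, pm, sigmas)
    calls = cm.segments_to_ternary(segments, pm, list(matrix.columns))
    return calls, metadata


def cluster_recovery_aris(n_seeds: int = 20, seed: int = 0,
                          k: int = 4, min_altered: int = 3) -> list[float]:
    """Adjusted Rand index of recovered vs planted clusters per seed, under
    the default 47-sample / 4-template study conditions."""
    aris = []
    for s in range(n_seeds):
        cfg = default_config(seed=seed + s)
        calls, metadata = _call_matrix_for(cfg)
        result = cluster_samples(calls, min_altered=min_altered, k=k)
        truth = metadata.set_index("sample_id")["true_cluster"]
        pred = [result.labels[x] for x in result.sample_ids]
        true = [int(truth[x]) for x in result.sample_ids]
        aris.append(float(adjusted_rand_score(true, pred)))
    return aris


def logrank_type1_error(n_reps: int = 1000, n: int = 47, k: int = 4,
                        hazard: float = 0.15, horizon: float = 10.0,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Omnibus log-rank rejection rate under equal hazards (type-I error)."""
    rng = np.random.default_rng(seed)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    group = np.repeat(np.arange(1, k + 1), sizes)
    rejections = 0
    for _ in range(n_reps):
        t = rng.exponential(1.0 / hazard, n)
        e = np.ones(n, dtype=int)
        res = logrank_test(t, e, group, horizon_years=horizon, one_vs_rest=False)
        rejections += res["omnibus"].p_value < alpha
    return rejections / n_reps


def logrank_power_fraction(n_seeds: int = 20, base_hazard: float = 0.08,
                           ratio: float = 4.0, high_cluster: int = 2,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of simulated cohorts in which the high-hazard cluster's
    one-vs-rest log-rank test rejects at ``alpha``.

    Cohorts follow the default study conditions except that one cluster's
    exponential hazard is ``ratio`` times the others', mirroring a
    poor-survival cluster.
    """
    hazards = {c: base_hazard for c in (1, 2, 3, 4)}
    hazards[high_cluster] = base_hazard * ratio
    hits = 0
    for s in range(n_seeds):
        cfg = replace(default_config(seed=seed + s), survival_hazards=hazards)
        _matrix, metadata, _truth = simulate_cohort(cfg)
        metadata = simulate_survival(metadata, cfg)
        res = logrank_test(metadata["survival_time"], metadata["event"],
                           metadata["true_cluster"], horizon_years=cfg.censor_time)
        hits += res["one_vs_rest"][high_cluster].p_value < alpha
    return hits / n_seeds
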