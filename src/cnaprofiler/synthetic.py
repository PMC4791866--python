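"""Synthetic aCGH cohorts with known ground truth.

The generator emulates the statistical structure of a hereditary breast
cancer aCGH cohort: 47 tumors (40 BRCAX, 3 BRCA1-mutated, 4
BRCA2-mutated) measured on an evenly spaced probe grid, falling into four
latent clusters that differ in the type and burden of copy-number
alteration (two loss-heavy templates, one gain-heavy, one quiet),
group-private alterations carried only by the mutation-carrier samples, a
designated BRCA1-locus deletion in a configurable fraction of
BRCA1-IHC-negative samples, i.i.d. Gaussian probe noise on a
piecewise-constant log2 signal, and cluster-dependent exponential
survival with administrative censoring.

Planted amplitudes default to +/-0.45–0.58 log2 units — single-copy
changes attenuated by normal-cell admixture, as seen in FFPE tumor aCGH —
with probe noise sigma = 0.1.  Overlapping planted regions add.  All
randomness derives from a single integer seed through documented
:class:`numpy.random.SeedSequence` spawns, so identical configs reproduce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClusterTemplate",
    "CohortConfig",
    "PlantedRegion",
    "TruthSet",
    "default_config",
    "default_templates",
    "make_probe_map",
    "simulate_cohort",
    "simulate_survival",
    "truth_to_frame",
]


@dataclass(frozen=True)
class PlantedRegion:
    """A contiguous probe run with a constant planted log2 amplitude."""

    first_probe: int  # inclusive global probe index
    last_probe: int
    amplitude: float  # log2 units; sign encodes direction

    @property
    def direction(self) -> str:
        return "gain" if self.amplitude > 0 else "loss"

    @property
    def n_probes(self) -> int:
        return self.last_probe - self.first_probe + 1


@dataclass(frozen=True)
class ClusterTemplate:
    cluster_id: int
    regions: tuple[PlantedRegion, ...]


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_brcax: int = 40
    n_brca1: int = 3
    n_brca2: int = 4
    n_chromosomes: int = 6
    probes_per_chromosome: int = 150
    probe_spacing_bp: int = 43_000
    cluster_templates: tuple[ClusterTemplate, ...] | None = None
    private_regions_brca1: tuple[PlantedRegion, ...] = ()
    private_regions_brca2: tuple[PlantedRegion, ...] = ()
    brca1_locus: PlantedRegion | None = None
    brca1_ihc_negative_fraction: float = 0.5
    brca1_deletion_fraction: float = 0.29
    noise_sd: float = 0.1
    wave_amplitude: float = 0.0  # optional sinusoidal artifact, off by default
    wave_period_probes: int = 50
    survival_hazards: dict[int, float] = field(
        default_factory=lambda: {1: 0.06, 2: 0.25, 3: 0.04, 4: 0.08}
    )
    censor_time: float = 10.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_brcax + self.n_brca1 + self.n_brca2

    @property
    def n_probes(self) -> int:
        return self.n_chromosomes * self.probes_per_chromosome

    def resolved(self) -> "CohortConfig":
        """Config with defaults for the grid-dependent fields filled in."""
        cfg = self
        fully_default = cfg.cluster_templates is None
        if fully_default:
            cfg = replace(cfg, cluster_templates=default_templates(cfg))
        if fully_default and not cfg.private_regions_brca1 and not cfg.private_regions_brca2:
            cfg = replace(
                cfg,
                private_regions_brca1=_default_private(cfg, which=0),
                private_regions_brca2=_default_private(cfg, which=1),
            )
        if cfg.brca1_locus is None:
            ppc = cfg.probes_per_chromosome
            lo = (cfg.n_chromosomes - 1) * ppc + ppc // 2
            cfg = replace(
                cfg, brca1_locus=PlantedRegion(lo, min(lo + 9, cfg.n_probes - 1), -0.5)
            )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("n_brcax", "n_brca1", "n_brca2", "n_chromosomes",
                     "probes_per_chromosome", "probe_spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.brca1_deletion_fraction <= 1:
            raise ValueError("brca1_deletion_fraction must lie in [0, 1]")
        if any(h <= 0 for h in self.survival_hazards.values()):
            raise ValueError("survival hazards must be positive")
        if self.censor_time < 0:
            raise ValueError("censor_time must be non-negative")
        regions = list(self.private_regions_brca1) + list(self.private_regions_brca2)
        if self.cluster_templates:
            for t in self.cluster_templates:
                regions.extend(t.regions)
        if self.brca1_locus is not None:
            regions.append(self.brca1_locus)
        for r in regions:
            if r.amplitude == 0:
                raise ValueError("planted region amplitude must be nonzero")
            if not (0 <= r.first_probe <= r.last_probe < self.n_probes):
                raise ValueError(
                    f"planted region [{r.first_probe}, {r.last_probe}] outside "
                    f"the {self.n_probes}-probe map"
                )

    def to_yaml(self, path) -> None:
        def region(r):
            return {"first_probe": r.first_probe, "last_probe": r.last_probe,
                    "amplitude": r.amplitude}

        cfg = self.resolved()
        payload = {
            "n_brcax": cfg.n_brcax, "n_brca1": cfg.n_brca1, "n_brca2": cfg.n_brca2,
            "n_chromosomes": cfg.n_chromosomes,
            "probes_per_chromosome": cfg.probes_per_chromosome,
            "probe_spacing_bp": cfg.probe_spacing_bp,
            "cluster_templates": [
                {"cluster_id": t.cluster_id, "regions": [region(r) for r in t.regions]}
                for t in cfg.cluster_templates
            ],
            "private_regions_brca1": [region(r) for r in cfg.private_regions_brca1],
            "private_regions_brca2": [region(r) for r in cfg.private_regions_brca2],
            "brca1_locus": region(cfg.brca1_locus),
            "brca1_ihc_negative_fraction": cfg.brca1_ihc_negative_fraction,
            "brca1_deletion_fraction": cfg.brca1_deletion_fraction,
            "noise_sd": cfg.noise_sd,
            "wave_amplitude": cfg.wave_amplitude,
            "wave_period_probes": cfg.wave_period_probes,
            "survival_hazards": {int(k): float(v) for k, v in cfg.survival_hazards.items()},
            "censor_time": cfg.censor_time,
            "seed": cfg.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def region(d):
            return PlantedRegion(d["first_probe"], d["last_probe"], d["amplitude"])

        raw["cluster_templates"] = tuple(
            ClusterTemplate(t["cluster_id"], tuple(region(r) for r in t["regions"]))
            for t in raw.get("cluster_templates", [])
        ) or None
        raw["private_regions_brca1"] = tuple(region(r) for r in raw.get("private_regions_brca1", []))
        raw["private_regions_brca2"] = tuple(region(r) for r in raw.get("private_regions_brca2", []))
        if raw.get("brca1_locus"):
            raw["brca1_locus"] = region(raw["brca1_locus"])
        raw["survival_hazards"] = {int(k): float(v) for k, v in raw["survival_hazards"].items()}
        return cls(**raw)


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort."""

    segments_by_sample: dict[str, list[PlantedRegion]]
    cluster_by_sample: dict[str, int]

    def validate(self, n_probes: int) -> None:
        if set(self.segments_by_sample) != set(self.cluster_by_sample):
            raise ValueError("truth cluster ids must cover all samples")
        for segs in self.segments_by_sample.values():
            for r in segs:
                if not (0 <= r.first_probe <= r.last_probe < n_probes):
                    raise ValueError("truth segment outside the probe map")


def make_probe_map(n_chromosomes: int, probes_per_chromosome: int,
                   spacing_bp: int) -> pd.DataFrame:
    """Evenly spaced probe grid: per chromosome, starts 0, s, 2s, ...

    Each probe covers ``[start, start + spacing_bp)`` so consecutive probes
    tile the chromosome without gaps.
    """
    if n_chromosomes <= 0 or probes_per_chromosome <= 0 or spacing_bp <= 0:
        raise ValueError("all probe-map arguments must be positive")
    rows = []
    for c in range(1, n_chromosomes + 1):
        for i in range(probes_per_chromosome):
            rows.append(
                {
                    "probe_id": f"P{c:02d}_{i:04d}",
                    "chromosome": str(c),
                    "start": i * spacing_bp,
                    "stop": (i + 1) * spacing_bp,
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "start", "stop"])


def default_templates(cfg: CohortConfig) -> tuple[ClusterTemplate, ...]:
    """Four cluster templates differing in alteration type and burden.

    Clusters 1 and 2 are loss-heavy (disjoint region sets), cluster 3 is
    quiet (a single small loss), cluster 4 is gain-heavy — the loss/gain/
    burden structure hierarchical clustering is expected to recover.
    """
    ppc = cfg.probes_per_chromosome
    n = cfg.n_probes
    width = max(8, ppc // 10)

    def reg(chrom, frac, amp):
        first = (chrom - 1) * ppc + int(frac * ppc)
        last = min(first + width - 1, n - 1)
        return PlantedRegion(first, last, amp)

    c = cfg.n_chromosomes
    t1 = ClusterTemplate(1, (reg(1, 0.10, -0.5), reg(1, 0.60, -0.5),
                             reg(min(2, c), 0.30, -0.5), reg(min(3, c), 0.70, -0.55)))
    t2 = ClusterTemplate(2, (reg(min(2, c), 0.75, -0.5), reg(min(3, c), 0.15, -0.55),
                             reg(min(4, c), 0.45, -0.5), reg(min(4, c), 0.80, -0.5)))
    t3 = ClusterTemplate(3, (reg(min(5, c), 0.20, -0.5),))
    t4 = ClusterTemplate(4, (reg(1, 0.35, 0.45), reg(min(2, c), 0.05, 0.5),
                             reg(min(5, c), 0.60, 0.45), reg(min(6, c), 0.25, 0.5)))
    return (t1, t2, t3, t4)


def _default_private(cfg: CohortConfig, which: int) -> tuple[PlantedRegion, ...]:
    """Region sets planted only in BRCA1 (which=0) or BRCA2 (which=1) carriers."""
    ppc = cfg.probes_per_chromosome
    n = cfg.n_probes
    width = max(8, ppc // 12)
    chrom = cfg.n_chromosomes  # park private regions on the last chromosome
    frac = 0.05 if which == 0 else 0.75
    first = (chrom - 1) * ppc + int(frac * ppc)
    return (PlantedRegion(first, min(first + width - 1, n - 1), -0.5),)


def default_config(**overrides) -> CohortConfig:
    """The default study conditions, with optional field overrides."""
    return CohortConfig(**overrides).resolved()


def _sample_ids(cfg: CohortConfig) -> tuple[list[str], list[str]]:
    ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    groups = (["BRCAX"] * cfg.n_brcax + ["BRCA1"] * cfg.n_brca1
              + ["BRCA2"] * cfg.n_brca2)
    return ids, groups


def simulate_cohort(config: CohortConfig):
    """Simulate one cohort; returns (ratio_matrix, metadata, truth).

    Each sample's log2 profile is the sum of its planted region amplitudes
    plus i.i.d. Gaussian(0, noise_sd) probe noise (plus the optional wave
    artifact).  Cluster templates are assigned round-robin within each
    germline group so the four clusters come out of similar size.
    """
    cfg = config.resolved()
    probe_map = make_probe_map(cfg.n_chromosomes, cfg.probes_per_chromosome,
                               cfg.probe_spacing_bp)
    ids, groups = _sample_ids(cfg)
    templates = cfg.cluster_templates
    root = np.random.SeedSequence(cfg.seed)
    meta_seed, *noise_seeds = root.spawn(1 + cfg.n_samples)
    meta_rng = np.random.default_rng(meta_seed)

    truth_segments: dict[str, list[PlantedRegion]] = {}
    cluster_of: dict[str, int] = {}
    profiles = np.zeros((cfg.n_probes, cfg.n_samples))

    # receptor / IHC status
    er = meta_rng.random(cfg.n_samples) < 0.55
    pr = meta_rng.random(cfg.n_samples) < 0.50
    her2 = meta_rng.random(cfg.n_samples) < 0.15
    ihc_neg = meta_rng.random(cfg.n_samples) < cfg.brca1_ihc_negative_fraction
    neg_idx = np.flatnonzero(ihc_neg)
    n_del = int(round(cfg.brca1_deletion_fraction * len(neg_idx)))
    del_idx = set(
        meta_rng.choice(neg_idx, size=n_del, replace=False).tolist()
    ) if n_del else set()

    for s, (sid, group) in enumerate(zip(ids, groups)):
        tpl = templates[s % len(templates)]
        cluster_of[sid] = tpl.cluster_id
        planted = list(tpl.regions)
        if group == "BRCA1":
            planted += list(cfg.private_regions_brca1)
        elif group == "BRCA2":
            planted += list(cfg.private_regions_brca2)
        if s in del_idx:
            planted.append(cfg.brca1_locus)
        truth_segments[sid] = planted
        signal = np.zeros(cfg.n_probes)
        for r in planted:
            signal[r.first_probe : r.last_probe + 1] += r.amplitude
        rng = np.random.default_rng(noise_seeds[s])
        noise = rng.normal(0.0, cfg.noise_sd, cfg.n_probes) if cfg.noise_sd > 0 \
            else np.zeros(cfg.n_probes)
        wave = (
            cfg.wave_amplitude
            * np.sin(2 * np.pi * np.arange(cfg.n_probes) / cfg.wave_period_probes)
            if cfg.wave_amplitude else 0.0
        )
        profiles[:, s] = signal + noise + wave

    matrix = pd.DataFrame(profiles, index=probe_map["probe_id"].to_numpy(),
                          columns=ids)
    matrix.index.name = "probe_id"

    def status(flag):
        return "positive" if flag else "negative"

    metadata = pd.DataFrame(
        {
            "sample_id": ids,
            "germline_group": groups,
            "ER": [status(x) for x in er],
            "PR": [status(x) for x in pr],
            "HER2": [status(x) for x in her2],
            "BRCA1_IHC": ["negative" if x else "positive" for x in ihc_neg],
            "true_cluster": [cluster_of[s] for s in ids],
        }
    )
    truth = TruthSet(segments_by_sample=truth_segments, cluster_by_sample=cluster_of)
    truth.validate(cfg.n_probes)
    return matrix, metadata, truth


def simulate_survival(metadata: pd.DataFrame, config: CohortConfig,
                      cluster_column: str = "true_cluster") -> pd.DataFrame:
    """Attach exponential survival with censoring at ``censor_time``.

    Each sample's event time is Exponential(hazard of its cluster); times
    beyond the censoring horizon are recorded as censored at the horizon.
    Reproducible: the survival stream is a dedicated spawn of the config
    seed.
    """
    cfg = config.resolved()
    if cluster_column not in metadata.columns:
        raise ValueError(f"metadata lacks a '{cluster_column}' column")
    clusters = metadata[cluster_column].to_numpy()
    missing = sorted({int(c) for c in clusters} - set(cfg.survival_hazards))
    if missing:
        raise ValueError(f"no survival hazard configured for cluster(s) {missing}")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(
        1 + cfg.n_samples + 1)[-1])
    hazards = np.array([cfg.survival_hazards[int(c)] for c in clusters])
    raw = rng.exponential(1.0 / hazards)
    out = metadata.copy()
    censored = raw > cfg.censor_time
    out["survival_time"] = np.where(censored, cfg.censor_time, raw)
    out["event"] = np.where(censored, 0, 1)
    return out


def truth_to_frame(truth: TruthSet, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Planted segments as a SEG-like table (sample, coordinates, amplitude)."""
    rows = []
    for sid in sorted(truth.segments_by_sample):
        for r in truth.segments_by_sample[sid]:
            rows.append(
                {
                    "sample_id": sid,
                    "chromosome": probe_map["chromosome"].iloc[r.first_probe],
                    "start": int(probe_map["start"].iloc[r.first_probe]),
                    "stop": int(probe_map["stop"].iloc[r.last_probe]),
                    "n_probes": r.n_probes,
                    "mean_log2": r.amplitude,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start", "stop", "n_probes",
                       "mean_log2"],
    )
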