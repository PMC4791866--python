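"""End-to-end cohort analysis: input → centering → calling → tables →
clustering → instability/survival statistics → enrichment.

``run`` executes every stage on either a simulated cohort (a
:class:`~cnaprofiler.synthetic.CohortConfig`) or on-disk inputs, writes
each stage's artifact into the output directory as TSV, and returns a
manifest of paths plus the parameter echo.  Re-running with the same
config and seed reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import callmatrix as cm
from . import cohort_stats as cs
from . import io_formats as iof
from .clustering import detect_outliers
from .enrichment import hypergeometric_enrich
from .normalization import estimate_noise_sd, iterative_recenter
from .segmentation import call_cohort, segments_to_frame
from .synthetic import (
    CohortConfig,
    make_probe_map,
    simulate_cohort,
    simulate_survival,
    truth_to_frame,
)

__all__ = ["RunConfig", "run", "synthetic_gene_annotation", "synthetic_gene_sets"]

log = logging.getLogger("cnaprofiler")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synthetic`` or (``probe_map_path`` + ``ratio_path`` +
    ``metadata_path``) must be set.
    """

    outdir: str = "results"
    synthetic: CohortConfig | None = None
    probe_map_path: str | None = None
    ratio_path: str | None = None
    metadata_path: str | None = None
    gene_annotation_path: str | None = None
    gmt_path: str | None = None
    score_threshold: float = 4.0
    min_abs_log2: float = 0.2
    min_altered: int = 3
    k: int = 4
    max_outlier_cluster_size: int = 1
    horizon_years: float = 10.0
    min_percent: float = 10.0
    min_carriers_a: int = 2
    welch: bool = False
    recenter: bool = True
    center_tol: float = 1e-4
    max_center_iter: int = 10
    seed: int = 0

    def validate(self) -> None:
        real = all(p is not None for p in
                   (self.probe_map_path, self.ratio_path, self.metadata_path))
        if (self.synthetic is None) == (not real):
            raise ValueError(
                "set exactly one of: a synthetic cohort config, or probe map "
                "+ ratio matrix + metadata paths"
            )
        if self.score_threshold <= 0 or self.min_abs_log2 < 0:
            raise ValueError("calling thresholds out of range")
        if self.k < 1 or self.min_altered < 0 or self.min_carriers_a < 1:
            raise ValueError("clustering/table parameters out of range")


def synthetic_gene_annotation(probe_map: pd.DataFrame,
                              probes_per_gene: int = 5) -> pd.DataFrame:
    """Synthetic gene annotation tiling the probe map (plumbing for the
    enrichment stage of simulated runs; gene names carry no biology)."""
    rows = []
    g = 0
    for chrom, sub in probe_map.groupby("chromosome", sort=False):
        for i in range(0, len(sub), probes_per_gene):
            block = sub.iloc[i : i + probes_per_gene]
            g += 1
            rows.append(
                {"gene": f"G{g:04d}", "chromosome": chrom,
                 "start": int(block["start"].iloc[0]),
                 "stop": int(block["stop"].iloc[-1])}
            )
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "stop"])


def synthetic_gene_sets(annotation: pd.DataFrame, seed: int,
                        n_sets: int = 8, set_size: int = 12) -> iof.GeneSetCollection:
    """Synthetic gene sets drawn from a gene annotation (plumbing for the
    enrichment stage of simulated runs)."""
    rng = np.random.default_rng(seed)
    genes = annotation["gene"].to_numpy()
    sets = {}
    descriptions = {}
    for i in range(1, n_sets + 1):
        members = sorted(rng.choice(genes, size=min(set_size, len(genes)),
                                    replace=False).tolist())
        sets[f"SET{i:02d}"] = members
        descriptions[f"SET{i:02d}"] = "synthetic gene set"
    return iof.GeneSetCollection(sets=sets, descriptions=descriptions)


def _write(df: pd.DataFrame, path: Path, manifest: dict, key: str,
           float_format=iof.FLOAT_FMT, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format, na_rep="NA")
    manifest["outputs"][key] = str(path)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "outputs": {}}

    try:
        # ---- stage: input -------------------------------------------------
        if config.synthetic is not None:
            cfg = config.synthetic.resolved()
            log.info("simulating cohort: %d samples, %d probes, seed %d",
                     cfg.n_samples, cfg.n_probes, cfg.seed)
            probe_map = make_probe_map(cfg.n_chromosomes, cfg.probes_per_chromosome,
                                       cfg.probe_spacing_bp)
            matrix, metadata, truth = simulate_cohort(cfg)
            metadata = simulate_survival(metadata, cfg)
            iof.write_probe_map(probe_map, out / "probe_map.tsv")
            manifest["outputs"]["probe_map"] = str(out / "probe_map.tsv")
            iof.write_ratio_matrix(matrix, out / "ratio_matrix.tsv")
            manifest["outputs"]["ratio_matrix"] = str(out / "ratio_matrix.tsv")
            _write(truth_to_frame(truth, probe_map), out / "truth_segments.tsv",
                   manifest, "truth_segments")
            cfg.to_yaml(out / "cohort_config.yaml")
            manifest["outputs"]["cohort_config"] = str(out / "cohort_config.yaml")
            annotation = synthetic_gene_annotation(probe_map)
            gene_sets = synthetic_gene_sets(annotation, cfg.seed)
        else:
            probe_map = iof.read_probe_map(config.probe_map_path)
            matrix = iof.read_ratio_matrix(config.ratio_path, probe_map)
            metadata = iof.read_metadata(config.metadata_path)
            annotation = (iof.read_gene_annotation(config.gene_annotation_path)
                          if config.gene_annotation_path else None)
            gene_sets = iof.read_gmt(config.gmt_path) if config.gmt_path else None
        iof.write_metadata(metadata, out / "metadata.tsv")
        manifest["outputs"]["metadata"] = str(out / "metadata.tsv")

        # ---- stage: normalization ----------------------------------------
        chroms = probe_map["chromosome"].to_numpy()
        sigmas: dict[str, float] = {}
        centered = {}
        for sample in matrix.columns:
            profile = matrix[sample].to_numpy()
            if config.recenter:
                profile = iterative_recenter(
                    profile, probe_map,
                    score_threshold=config.score_threshold,
                    min_abs_log2=config.min_abs_log2,
                    max_iter=config.max_center_iter, tol=config.center_tol,
                )
            sigma = estimate_noise_sd(profile, chroms)
            sigmas[sample] = max(sigma, 1e-6)  # guard: noise-free input
            centered[sample] = profile
        centered_matrix = pd.DataFrame(centered, index=matrix.index)
        _write(pd.DataFrame({"sample_id": list(sigmas), "sigma": list(sigmas.values())}),
               out / "noise_estimates.tsv", manifest, "noise_estimates")

        # ---- stage: segmentation -----------------------------------------
        segments = call_cohort(centered_matrix, probe_map, sigmas,
                               score_threshold=config.score_threshold,
                               min_abs_log2=config.min_abs_log2)
        seg_frame = pd.concat(
            [segments_to_frame(s) for s in segments.values()], ignore_index=True
        ) if segments else segments_to_frame([])
        _write(seg_frame, out / "calls.seg.tsv", manifest, "calls")
        log.info("called %d segments across %d samples", len(seg_frame), len(matrix.columns))

        # ---- stage: call matrix and tables -------------------------------
        calls = cm.segments_to_ternary(segments, probe_map, list(matrix.columns))
        _write(calls, out / "call_matrix.tsv", manifest, "call_matrix", index=True)
        _write(cm.frequency_track(calls, probe_map), out / "frequency_track.tsv",
               manifest, "frequency_track")

        groups = {g: metadata.loc[metadata["germline_group"] == g, "sample_id"].tolist()
                  for g in ("BRCAX", "BRCA1", "BRCA2")}
        region_genes: list[str] = []
        for direction in ("loss", "gain"):
            if not groups["BRCAX"]:
                break
            regions = cm.frequency_table(calls, probe_map, groups["BRCAX"],
                                         direction, min_percent=config.min_percent)
            if annotation is not None:
                cm.genes_in_regions(regions, annotation)
                region_genes += [g for r in regions for g in r.genes]
            _write(cm.regions_to_frame(regions),
                   out / f"recurrent_{direction}_BRCAX.tsv", manifest,
                   f"recurrent_{direction}_BRCAX")
        carriers = groups["BRCA1"] + groups["BRCA2"]
        if carriers and groups["BRCAX"]:
            private = cm.private_alterations(calls, probe_map, carriers,
                                             groups["BRCAX"],
                                             min_carriers_a=config.min_carriers_a)
            if annotation is not None:
                cm.genes_in_regions(private, annotation)
            _write(cm.regions_to_frame(private), out / "private_carrier_regions.tsv",
                   manifest, "private_carrier_regions")

        # ---- stage: clustering -------------------------------------------
        result = detect_outliers(calls, min_altered=config.min_altered, k=config.k,
                                 max_outlier_cluster_size=config.max_outlier_cluster_size)
        labels = pd.DataFrame(
            {"sample_id": result.sample_ids,
             "cluster": [result.labels.get(s, 0) for s in result.sample_ids],
             "outlier": [int(s in result.outliers) for s in result.sample_ids]}
        )
        _write(labels, out / "cluster_labels.tsv", manifest, "cluster_labels")
        (out / "cluster_tree.nwk").write_text(result.to_newick() + "\n")
        manifest["outputs"]["cluster_tree"] = str(out / "cluster_tree.nwk")
        log.info("clustered into %d groups (%d outliers removed)",
                 config.k, len(result.outliers))

        # ---- stage: instability ------------------------------------------
        instability = cs.instability_counts(segments)
        instability = instability.merge(labels, on="sample_id")
        _write(instability, out / "instability.tsv", manifest, "instability")
        t_rows = []
        clustered = instability[instability["outlier"] == 0]
        for a, b in combinations(sorted(clustered["cluster"].unique()), 2):
            xa = clustered.loc[clustered["cluster"] == a, "n_total"]
            xb = clustered.loc[clustered["cluster"] == b, "n_total"]
            if len(xa) < 2 or len(xb) < 2:
                continue
            try:
                res = cs.two_sample_t_test(xa, xb, pooled=not config.welch)
            except ValueError:
                continue
            t_rows.append({"cluster_a": a, "cluster_b": b,
                           "t": res.statistic, "df": res.df, "p": res.p_value})
        ttests = pd.DataFrame(t_rows, columns=["cluster_a", "cluster_b", "t", "df", "p"])
        if len(ttests):
            from .enrichment import bh_adjust
            ttests["q_bh"] = bh_adjust(ttests["p"].to_numpy())
        _write(ttests, out / "instability_tests.tsv", manifest, "instability_tests")

        # ---- stage: survival ---------------------------------------------
        if "survival_time" in metadata.columns and metadata["survival_time"].notna().any():
            surv = metadata.merge(labels, on="sample_id")
            surv = surv[(surv["outlier"] == 0) & surv["survival_time"].notna()]
            km_rows = []
            for c, sub in surv.groupby("cluster"):
                t, e = cs.administrative_censor(sub["survival_time"], sub["event"],
                                                config.horizon_years)
                curve = cs.km_estimate(t, e)
                curve.insert(0, "cluster", c)
                km_rows.append(curve)
            _write(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv",
                   manifest, "km_curves")
            lr = cs.logrank_test(surv["survival_time"], surv["event"],
                                 surv["cluster"], horizon_years=config.horizon_years)
            lr_rows = [{"comparison": "omnibus", "statistic": lr["omnibus"].statistic,
                        "df": lr["omnibus"].df, "p": lr["omnibus"].p_value}]
            for g, res in lr["one_vs_rest"].items():
                lr_rows.append({"comparison": f"cluster_{g}_vs_rest",
                                "statistic": res.statistic, "df": res.df,
                                "p": res.p_value})
            _write(pd.DataFrame(lr_rows), out / "logrank_tests.tsv", manifest,
                   "logrank_tests")

        # ---- stage: enrichment -------------------------------------------
        if annotation is not None and gene_sets is not None and region_genes:
            universe = _array_universe(annotation, probe_map)
            gene_list = sorted(set(region_genes) & universe)
            if gene_list:
                enr = hypergeometric_enrich(gene_list, gene_sets, universe)
                _write(enr, out / "enrichment.tsv", manifest, "enrichment")

        manifest["parameters"] = {
            k: v for k, v in asdict(config).items() if k != "synthetic"
        }
        if config.synthetic is not None:
            manifest["parameters"]["synthetic_seed"] = config.synthetic.seed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        manifest["outputs"]["manifest"] = str(out / "manifest.json")
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()


def _array_universe(annotation: pd.DataFrame, probe_map: pd.DataFrame) -> set[str]:
    """Genes overlapping any probe: the array-constrained background."""
    universe = set()
    for chrom, sub in annotation.groupby("chromosome", sort=False):
        probes = probe_map[probe_map["chromosome"].astype(str) == str(chrom)]
        if not len(probes):
            continue
        starts = probes["start"].to_numpy()
        stops = probes["stop"].to_numpy()
        for gene, gs, ge in zip(sub["gene"], sub["start"], sub["stop"]):
            if np.any((starts < ge) & (stops > gs)):
                universe.add(gene)
    return universe
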