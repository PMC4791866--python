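"""Ternary call matrices and recurrent-region tables.

Called segments are projected onto the probe grid as a ternary matrix
(per probe and sample: -1 loss, 0 unaltered, +1 gain).  Cohort-level
summaries are derived probe-wise:

* ``frequency_table`` — regions altered in more than a given percentage of
  a sample group (the "recurrent aberration" tables an aCGH cohort study
  reports), as maximal runs of consecutive probes above the threshold;
* ``private_alterations`` — regions altered in several samples of one
  group and in none of another (e.g. alterations private to germline
  mutation carriers);
* ``genes_in_regions`` — gene symbols whose half-open interval overlaps a
  region by at least 1 bp;
* ``frequency_track`` — per-probe gain/loss counts for genome-wide plots.

Percentages are reported to one decimal with round-half-up, matching how
such tables are conventionally printed (a value that is an integer may be
displayed without the decimal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "RecurrentRegion",
    "concomitant_samples",
    "frequency_table",
    "frequency_track",
    "genes_in_regions",
    "private_alterations",
    "region_size",
    "regions_to_frame",
    "round_percent",
    "segments_to_ternary",
]


@dataclass
class RecurrentRegion:
    """A maximal run of probes recurrently altered in one direction."""

    chromosome: str
    start: int  # bp, half-open
    stop: int
    first_probe: int  # inclusive global probe indices
    last_probe: int
    direction: str  # "loss" | "gain"
    carriers: list[str] = field(default_factory=list)
    group_size: int = 0
    genes: list[str] = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return region_size(self.start, self.stop)

    @property
    def count(self) -> int:
        return len(self.carriers)

    @property
    def percent(self) -> float:
        return round_percent(self.count, self.group_size)


def round_percent(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-up to ``decimals`` places.

    Tables report one decimal (the printed-table rule); in-text figures are
    often printed as integers, i.e. ``decimals=0``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(100 * count) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def region_size(start_bp: int, stop_bp: int) -> int:
    """Length of a half-open genomic interval in bp (stop - start)."""
    if stop_bp <= start_bp:
        raise ValueError(f"stop ({stop_bp}) must exceed start ({start_bp})")
    return int(stop_bp) - int(start_bp)


def segments_to_ternary(segments, probe_map: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Project per-sample segments onto the probe grid as {-1, 0, +1} calls.

    ``segments`` maps sample id -> list of Segment (or is a flat list of
    Segment objects); probes inside a loss become -1, inside a gain +1.
    """
    calls = pd.DataFrame(
        np.zeros((len(probe_map), len(sample_ids)), dtype=np.int8),
        index=probe_map["probe_id"].to_numpy(),
        columns=list(sample_ids),
    )
    if isinstance(segments, dict):
        items = [(sid, seg) for sid, segs in segments.items() for seg in segs]
    else:
        items = [(seg.sample_id, seg) for seg in segments]
    col_pos = {s: k for k, s in enumerate(calls.columns)}
    values = calls.to_numpy()
    for sid, seg in items:
        if sid not in col_pos:
            raise ValueError(f"segment for unknown sample '{sid}'")
        sl = slice(seg.first_probe, seg.last_probe + 1)
        if np.any(values[sl, col_pos[sid]] != 0):
            raise ValueError(f"overlapping segments for sample '{sid}'")
        values[sl, col_pos[sid]] = 1 if seg.call == "gain" else -1
    return calls


def _runs(mask: np.ndarray):
    """Maximal runs of True as (first, last) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    firsts = np.concatenate([[idx[0]], idx[breaks + 1]])
    lasts = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(firsts.tolist(), lasts.tolist()))


def _split_by_chromosome(first: int, last: int, chroms: np.ndarray):
    """Split an inclusive probe run at chromosome boundaries."""
    out = []
    lo = first
    for k in range(first + 1, last + 1):
        if chroms[k] != chroms[lo]:
            out.append((lo, k - 1))
            lo = k
    out.append((lo, last))
    return out


def _make_region(probe_map, first, last, direction, carriers, group_size):
    return RecurrentRegion(
        chromosome=str(probe_map["chromosome"].iloc[first]),
        start=int(probe_map["start"].iloc[first]),
        stop=int(probe_map["stop"].iloc[last]),
        first_probe=int(first),
        last_probe=int(last),
        direction=direction,
        carriers=sorted(carriers),
        group_size=group_size,
    )


def frequency_table(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    group: list[str],
    direction: str,
    min_percent: float = 10.0,
) -> list[RecurrentRegion]:
    """Regions altered in (strictly) more than ``min_percent`` % of ``group``.

    Probe-wise carrier percentages are thresholded, runs of consecutive
    qualifying probes on one chromosome are merged, and a region's carrier
    set is the samples altered at *every* probe of the run.
    """
    if not group:
        raise ValueError("group must be non-empty")
    missing = [s for s in group if s not in calls.columns]
    if missing:
        raise ValueError(f"group sample(s) not in call matrix: {missing}")
    target = 1 if direction == "gain" else -1
    sub = calls[list(group)].to_numpy()
    hit = sub == target
    percent = 100.0 * hit.sum(axis=1) / len(group)
    chroms = probe_map["chromosome"].to_numpy()
    regions = []
    for first, last in _runs(percent > min_percent):
        for f, l in _split_by_chromosome(first, last, chroms):
            full = hit[f : l + 1].all(axis=0)
            carriers = [group[k] for k in np.flatnonzero(full)]
            regions.append(_make_region(probe_map, f, l, direction, carriers, len(group)))
    return regions


def concomitant_samples(regions: list[RecurrentRegion], calls: pd.DataFrame) -> set[str]:
    """Samples carrying every listed region (correct direction, every probe)."""
    if not regions:
        raise ValueError("need at least one region")
    out = None
    for r in regions:
        target = 1 if r.direction == "gain" else -1
        block = calls.iloc[r.first_probe : r.last_probe + 1] == target
        carriers = set(calls.columns[block.all(axis=0)])
        out = carriers if out is None else out & carriers
    return out


def private_alterations(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_carriers_a: int = 2,
) -> list[RecurrentRegion]:
    """Regions altered in >= ``min_carriers_a`` samples of A and 0 of B.

    Any alteration of a B sample at a probe (either direction)
    disqualifies that probe.  Runs are built per direction and merged as in
    ``frequency_table``; carrier counts require carriage over the full run.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = calls[list(group_a)].to_numpy()
    b = calls[list(group_b)].to_numpy() if group_b else np.zeros((len(calls), 0), dtype=np.int8)
    b_clean = (b != 0).sum(axis=1) == 0
    chroms = probe_map["chromosome"].to_numpy()
    regions = []
    for direction, target in (("loss", -1), ("gain", 1)):
        hit = a == target
        ok = (hit.sum(axis=1) >= min_carriers_a) & b_clean
        for first, last in _runs(ok):
            for f, l in _split_by_chromosome(first, last, chroms):
                full = hit[f : l + 1].all(axis=0)
                carriers = [group_a[k] for k in np.flatnonzero(full)]
                regions.append(
                    _make_region(probe_map, f, l, direction, carriers, len(group_a))
                )
    regions.sort(key=lambda r: r.first_probe)
    return regions


def genes_in_regions(
    regions: list[RecurrentRegion], gene_annotation: pd.DataFrame
) -> list[RecurrentRegion]:
    """Attach gene symbols overlapping each region by >= 1 bp (half-open).

    Mutates and returns ``regions``; genes abutting at the region boundary
    (gene.start == region.stop) do not overlap.
    """
    g_chrom = gene_annotation["chromosome"].astype(str).to_numpy()
    g_start = gene_annotation["start"].to_numpy()
    g_stop = gene_annotation["stop"].to_numpy()
    g_name = gene_annotation["gene"].to_numpy()
    for r in regions:
        sel = (g_chrom == str(r.chromosome)) & (g_start < r.stop) & (g_stop > r.start)
        r.genes = list(g_name[sel])
    return regions


def frequency_track(calls: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Per-probe cohort gain and loss counts (genome-plot track, TSV-ready)."""
    values = calls.to_numpy()
    return pd.DataFrame(
        {
            "probe_id": probe_map["probe_id"].to_numpy(),
            "chromosome": probe_map["chromosome"].to_numpy(),
            "start": probe_map["start"].to_numpy(),
            "stop": probe_map["stop"].to_numpy(),
            "n_gain": (values == 1).sum(axis=1),
            "n_loss": (values == -1).sum(axis=1),
        }
    )


def regions_to_frame(regions: list[RecurrentRegion]) -> pd.DataFrame:
    """Recurrent regions as a printable table (one row per region)."""
    rows = [
        {
            "chromosome": r.chromosome,
            "start": r.start,
            "stop": r.stop,
            "size_bp": r.size_bp,
            "direction": r.direction,
            "n_carriers": r.count,
            "percent": r.percent,
            "carriers": ",".join(r.carriers),
            "genes": ",".join(r.genes),
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "stop", "size_bp", "direction",
            "n_carriers", "percent", "carriers", "genes",
        ],
    )
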