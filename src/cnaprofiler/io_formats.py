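"""Readers and writers for the on-disk artifacts of an aCGH cohort analysis.

Every tabular artifact is UTF-8, tab-delimited, one header line (GMT files
have no header).  Genomic coordinates are 0-based half-open ``[start, stop)``
throughout, so an interval's length is exactly ``stop - start``.

In-memory containers are plain :class:`pandas.DataFrame` objects with fixed
column sets, validated on read and before write:

* probe map     — ``probe_id, chromosome, start, stop`` (the measurement grid)
* ratio matrix  — index ``probe_id``, one float column per sample (log2 ratios)
* metadata      — ``sample_id, germline_group, ER, PR, HER2, BRCA1_IHC,
  survival_time, event`` (+ optional ``cluster_label`` and extras)
* gene annotation — ``gene, chromosome, start, stop``
* segments      — SEG-like: ``sample_id, chromosome, start, stop, n_probes,
  mean_log2, score, call``
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneSetCollection",
    "chromosome_sort_key",
    "load_example_cohort",
    "read_gene_annotation",
    "read_gmt",
    "read_metadata",
    "read_probe_map",
    "read_ratio_matrix",
    "read_segments",
    "validate_metadata",
    "validate_probe_map",
    "write_gene_annotation",
    "write_gmt",
    "write_metadata",
    "write_probe_map",
    "write_ratio_matrix",
    "write_segments",
]

FLOAT_FMT = "%.6g"  # documented round-trip precision: 6 significant digits

PROBE_MAP_COLUMNS = ["probe_id", "chromosome", "start", "stop"]
SEGMENT_COLUMNS = [
    "sample_id", "chromosome", "start", "stop",
    "n_probes", "mean_log2", "score", "call",
]
STATUS_VALUES = {"positive", "negative", "unknown"}
GERMLINE_GROUPS = {"BRCAX", "BRCA1", "BRCA2"}

_CANONICAL_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
_CHROM_RANK = {c: i for i, c in enumerate(_CANONICAL_CHROMS)}


class FormatError(ValueError):
    """A file violates the artifact format contract."""


def chromosome_sort_key(chrom: str):
    """Sort key placing 1..22, X, Y, MT in genomic order, ``chr`` prefix ignored.

    Unknown names sort after the canonical ones, lexicographically (a warning
    is emitted by the readers when that fallback is used).
    """
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    rank = _CHROM_RANK.get(name.upper())
    if rank is None:
        return (1, str(chrom))
    return (0, rank)


def _known_chrom(chrom: str) -> bool:
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() in _CHROM_RANK


def _read_tsv(path, required, name):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name} file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _to_int(series, path, col):
    out = pd.to_numeric(series.replace("", np.nan), errors="coerce")
    bad = out.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(f"{path}: non-integer value in column '{col}' at line {line}")
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# probe map

def validate_probe_map(pm: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_MAP_COLUMNS if c not in pm.columns]
    if missing:
        raise FormatError(f"probe map missing column(s) {missing}")
    if pm["probe_id"].duplicated().any():
        dup = pm.loc[pm["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe_id '{dup}' in probe map")
    if (pm["stop"] <= pm["start"]).any():
        raise FormatError("probe map has probes with stop <= start")
    if (pm["start"] < 0).any():
        raise FormatError("probe map has negative start coordinates")
    keys = [chromosome_sort_key(c) for c in pm["chromosome"]]
    order = sorted(range(len(pm)), key=lambda i: (keys[i], int(pm["start"].iloc[i])))
    if order != list(range(len(pm))):
        raise FormatError("probe map is not sorted by (chromosome, start)")
    return pm


def read_probe_map(path) -> pd.DataFrame:
    df = _read_tsv(path, PROBE_MAP_COLUMNS, "probe map")
    df = df[PROBE_MAP_COLUMNS].copy()
    df["start"] = _to_int(df["start"], path, "start")
    df["stop"] = _to_int(df["stop"], path, "stop")
    unknown = sorted({c for c in df["chromosome"].unique() if not _known_chrom(c)})
    if unknown:
        warnings.warn(
            f"unrecognised chromosome name(s) {unknown}; "
            "falling back to lexicographic ordering for them"
        )
    return validate_probe_map(df.reset_index(drop=True))


def write_probe_map(pm: pd.DataFrame, path) -> None:
    validate_probe_map(pm)
    pm[PROBE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ratio matrix

def read_ratio_matrix(path, probe_map: pd.DataFrame, max_missing_frac: float = 0.5) -> pd.DataFrame:
    df = _read_tsv(path, ["probe_id"], "ratio matrix")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id '{dup}'")
    df = df.set_index("probe_id")
    extra = set(df.index) - set(probe_map["probe_id"])
    if extra:
        raise FormatError(f"{path}: probe(s) not in probe map, e.g. {sorted(extra)[:3]}")
    if set(df.index) != set(probe_map["probe_id"]):
        missing = set(probe_map["probe_id"]) - set(df.index)
        raise FormatError(f"{path}: probe(s) missing from matrix, e.g. {sorted(missing)[:3]}")
    values = df.replace("NA", np.nan).apply(pd.to_numeric, errors="raise")
    values = values.reindex(probe_map["probe_id"])  # align rows to grid order
    frac = values.isna().mean(axis=0)
    bad = frac[frac > max_missing_frac]
    if len(bad):
        raise FormatError(
            f"{path}: sample(s) exceed missing-value cap {max_missing_frac}: "
            f"{list(bad.index)}"
        )
    return values


def write_ratio_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep="NA")


# ---------------------------------------------------------------------------
# cohort metadata

def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "germline_group", "ER", "PR", "HER2", "BRCA1_IHC"]
    missing = [c for c in required if c not in md.columns]
    if missing:
        raise FormatError(f"metadata missing column(s) {missing}")
    if md["sample_id"].duplicated().any():
        dup = md.loc[md["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id '{dup}' in metadata")
    bad_group = set(md["germline_group"]) - GERMLINE_GROUPS
    if bad_group:
        raise FormatError(f"unknown germline group(s) {sorted(bad_group)}")
    for col in ["ER", "PR", "HER2", "BRCA1_IHC"]:
        bad = set(md[col]) - STATUS_VALUES
        if bad:
            raise FormatError(f"column '{col}' has non-status value(s) {sorted(bad)}")
    if "survival_time" in md.columns:
        has_time = md["survival_time"].notna()
        if (md["survival_time"].dropna() < 0).any():
            raise FormatError("negative survival_time in metadata")
        if "event" not in md.columns or md.loc[has_time, "event"].isna().any():
            raise FormatError("event flag required wherever survival_time is present")
        bad_ev = set(md.loc[has_time, "event"].astype(int)) - {0, 1}
        if bad_ev:
            raise FormatError(f"event flag must be 0/1, got {sorted(bad_ev)}")
    return md


def read_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample_id", "germline_group"], "metadata")
    for col in ["ER", "PR", "HER2", "BRCA1_IHC"]:
        if col in df.columns:
            df[col] = df[col].replace({"ND": "unknown", "NA": "unknown", "": "unknown"})
    for col in ["survival_time", "event"]:
        if col in df.columns:
            col_vals = df[col].mask(df[col].isin(["NA", ""]))
            df[col] = pd.to_numeric(col_vals, errors="raise")
    return validate_metadata(df.reset_index(drop=True))


def write_metadata(md: pd.DataFrame, path) -> None:
    validate_metadata(md)
    md.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")


def load_example_cohort() -> pd.DataFrame:
    """Clinical annotations of the packaged 47-tumor hereditary breast cancer
    cohort (40 BRCAX, 3 BRCA1-mutated, 4 BRCA2-mutated samples; ER/PR/HER2 and
    BRCA1 immunohistochemistry status).  Survival columns are not available
    and read as missing."""
    ref = resources.files("cnaprofiler.data") / "hereditary_breast_cohort.tsv"
    with resources.as_file(ref) as path:
        return read_metadata(path)


# ---------------------------------------------------------------------------
# gene annotation

def read_gene_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene", "chromosome", "start", "stop"], "gene annotation")
    df = df[["gene", "chromosome", "start", "stop"]].copy()
    df["start"] = _to_int(df["start"], path, "start")
    df["stop"] = _to_int(df["stop"], path, "stop")
    if (df["stop"] <= df["start"]).any():
        line = int(np.flatnonzero((df["stop"] <= df["start"]).to_numpy())[0]) + 2
        raise FormatError(f"{path}: gene with stop <= start at line {line}")
    keys = [chromosome_sort_key(c) for c in df["chromosome"]]
    order = sorted(range(len(df)), key=lambda i: (keys[i], int(df["start"].iloc[i])))
    return df.iloc[order].reset_index(drop=True)


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes[["gene", "chromosome", "start", "stop"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)

@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set '{name}' is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set '{name}' has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GMT file not found: {path}")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT needs name, description, >=1 gene")
        name, desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate set name '{name}'")
        if not members:
            raise FormatError(f"{path}: line {lineno}: set '{name}' has no members")
        if len(set(members)) != len(members):
            raise FormatError(f"{path}: line {lineno}: duplicate member in set '{name}'")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + list(members))
        for name, members in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# called segments (SEG-like)

def read_segments(path) -> pd.DataFrame:
    df = _read_tsv(path, SEGMENT_COLUMNS, "segments")
    df = df[SEGMENT_COLUMNS].copy()
    for col in ["start", "stop", "n_probes"]:
        df[col] = _to_int(df[col], path, col)
    for col in ["mean_log2", "score"]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = set(df["call"]) - {"loss", "gain"}
    if bad:
        raise FormatError(f"{path}: unknown call value(s) {sorted(bad)}")
    return df


def write_segments(segments: pd.DataFrame, path) -> None:
    segments[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
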