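"""Readers and writers for the plain-text study formats.

All inputs are delimited text: per-subject time-series tables (T rows x N
regions, optional header of region labels), a region-label TSV (index, name,
optional x/y/z), and a subject manifest TSV (subject_id, file, group, age,
sex, optional updrs_motor).  Connectivity matrices cache as square TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .net_build import RoiTimeSeries, ZConnectivity

__all__ = [
    "read_timeseries",
    "read_regions",
    "read_manifest",
    "write_connectivity",
    "read_connectivity",
    "write_tidy_metrics",
]

MANIFEST_REQUIRED = ("subject_id", "file", "group", "age", "sex")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(
    path: str | Path,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
    region_labels: list[str] | None = None,
) -> RoiTimeSeries:
    """Read one subject's T x N series; a non-numeric first row is a header."""
    path = Path(path)
    sep = _sep_for(path)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = first.iloc[0].map(lambda v: isinstance(v, str)).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    labels = list(df.columns.astype(str)) if has_header else None
    if region_labels is not None:
        if labels is not None and labels != list(region_labels):
            raise ValueError(f"{path.name}: header labels disagree with region file")
        labels = list(region_labels)
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_labels=labels or [],
    )


def read_regions(path: str | Path) -> pd.DataFrame:
    """Region-label table with columns index, name (+ optional x, y, z)."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    for col in ("index", "name"):
        if col not in df.columns:
            raise ValueError(f"region file missing required column {col!r}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Validated subject manifest: two group levels, unique subject ids."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {', '.join(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id(s): {', '.join(map(str, dup.unique()))}")
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"manifest must contain exactly two group labels, got {levels}")
    bad_sex = set(df["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex code(s): {sorted(bad_sex)}")
    if "updrs_motor" not in df.columns:
        df = df.assign(updrs_motor=np.nan)
    return df


def write_connectivity(conn: ZConnectivity, path: str | Path) -> None:
    pd.DataFrame(conn.z, columns=conn.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_connectivity(path: str | Path) -> ZConnectivity:
    df = pd.read_csv(path, sep="\t")
    return ZConnectivity(z=df.to_numpy(dtype=float), region_labels=list(df.columns))


def write_tidy_metrics(rows: list[dict], path: str | Path) -> None:
    """Long-format metric table: subject_id, sparsity, metric, region, value."""
    pd.DataFrame(rows, columns=["subject_id", "sparsity", "metric", "region", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
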