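"""File formats: genotype TSV, daily-series CSV, tidy trait CSV, segment
BED-like TSV, and JSON reports.

All tables are plain text with headers and round-trip losslessly (floats
written with 17 significant digits). Segment exports use 1-based closed
coordinates, stated in the file's comment header, which deviates from the
half-open BED convention.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .genotypes import META_COLS, VALID_CODES, SegmentMatrix

FLOAT_FMT = "%.17g"


def _require_nonempty(path: Path) -> None:
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"input file is empty: {path}")


# ---------------------------------------------------------------------------
# genotypes

def write_genotypes(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.DataFrame:
    """Read a marker table, validating structure and genotype codes."""
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    if df.empty:
        raise ParseError(f"no marker rows in {path}")
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    lines = [c for c in df.columns if c not in META_COLS]
    if not lines:
        raise ParseError(f"{path}: no line columns")
    for ln in lines:
        col = df[ln].astype(str)
        bad = ~col.isin(VALID_CODES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: invalid genotype code {col.iloc[row]!r} at "
                f"marker {df['marker_id'].iloc[row]!r}, line {ln!r} "
                f"(data row {row + 1})")
    df["chrom"] = df["chrom"].astype(int)
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# phenotypes

def write_table(df: pd.DataFrame, path, *, sep=",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_daily(path) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path)
    need = {"plant", "day", "temp", "biomass_fw", "leaf_area", "water",
            "leaves"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_plants(path) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path)
    missing = {"plant", "line", "treatment"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["treatment"].isin(["ww", "wd", "seedling"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: unknown treatment "
                         f"{df['treatment'].iloc[row]!r} (data row {row + 1})")
    return df


def read_traits(path) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path)
    missing = {"plant", "line", "treatment", "trait", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# segments and matrices

SEGMENT_HEADER = ("# introgression segments; coordinates are 1-based closed "
                  "(not BED half-open)\n")


def write_segments(segments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(SEGMENT_HEADER)
        segments[["chrom", "start_bp", "end_bp", "line", "state",
                  "label"]].to_csv(fh, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    return pd.read_csv(path, sep="\t", comment="#")


def write_segment_matrix(sm: SegmentMatrix, path) -> None:
    out = sm.meta.join(sm.matrix)
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


META_MATRIX_COLS = ["chrom", "start_bp", "end_bp", "state", "label",
                    "length_mb"]


def read_segment_matrix(path) -> SegmentMatrix:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t", index_col="segment_id")
    missing = set(META_MATRIX_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    meta = df[META_MATRIX_COLS].copy()
    matrix = df.drop(columns=META_MATRIX_COLS).astype(np.int8)
    return SegmentMatrix(meta=meta, matrix=matrix)


def write_clusters_json(clusters, path) -> None:
    payload = [{
        "id": cl.id,
        "members": cl.members,
        "chrom": cl.chrom,
        "start_bp": cl.start_bp,
        "end_bp": cl.end_bp,
        "traits": {t: int(s) for t, s in sorted(cl.traits.items())},
    } for cl in clusters]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# hashing / manifest

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
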