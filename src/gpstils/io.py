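"""Readers and writers for the pipeline's on-disk artifacts.

All tables are UTF-8 delimited text with a header row.  Pixel
coordinates are at 20x magnification, origin top-left, and every
patch/tile interval is half-open ``[x0, x0 + side)``.

Formats
-------
nuclei table
    CSV ``slide_id,x,y,cell_class``; classes are mapped to the canonical
    vocabulary {neoplastic, lymphocyte, stromal, necrotic, other}.
patch table
    CSV ``slide_id,x0,y0,pattern`` with pattern one of the five LUAD
    growth patterns or ``non_tumour``; patches on one slide must not
    overlap.
clinical table
    TSV (comma also accepted)
    ``patient_id,os_months,os_event,age,sex,stage,smoking,grade``.
slide map
    CSV ``slide_id,patient_id``.
feature matrix
    CSV, one row per patient, columns sorted lexicographically; writing
    then reading reproduces the values bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tiles import CELL_CLASSES, NON_TUMOUR, PATTERNS

#: default mapping from a PanNuke-style detector vocabulary to the
#: canonical classes; "inflammatory" nuclei stand in for lymphocytes.
DEFAULT_CLASS_MAPPING: dict[str, str] = {
    **{c: c for c in CELL_CLASSES},
    "inflammatory": "lymphocyte",
    "connective": "stromal",
    "dead": "necrotic",
    "non-neoplastic epithelial": "other",
    "epithelial": "other",
}

_VALID_PATTERNS = frozenset(PATTERNS) | {NON_TUMOUR}


class FormatError(ValueError):
    """A table does not match the expected dialect or vocabulary."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_nuclei_table(path: str | Path,
                      class_mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a nuclei detection table into canonical form.

    Unknown cell classes are never dropped silently: any class absent
    from ``class_mapping`` (default: PanNuke-style vocabulary) raises a
    :class:`FormatError` listing the offending values.
    """
    mapping = dict(DEFAULT_CLASS_MAPPING if class_mapping is None else class_mapping)
    df = pd.read_csv(path)
    _require_columns(df, ["slide_id", "x", "y", "cell_class"], "nuclei table")
    raw = df["cell_class"].astype(str).str.strip().str.lower()
    unknown = sorted(set(raw) - set(mapping))
    if unknown:
        raise FormatError(
            f"nuclei table contains unmapped cell classes: {', '.join(unknown)}; "
            "extend class_mapping to cover them")
    out = pd.DataFrame({
        "slide_id": df["slide_id"].astype(str),
        "x": pd.to_numeric(df["x"], errors="coerce"),
        "y": pd.to_numeric(df["y"], errors="coerce"),
        "cell_class": raw.map(mapping),
    })
    bad = ~(np.isfinite(out["x"]) & np.isfinite(out["y"])
            & (out["x"] >= 0) & (out["y"] >= 0))
    if bad.any():
        raise FormatError(
            f"nuclei table has {int(bad.sum())} row(s) with non-finite or "
            "negative coordinates")
    return out


def read_patch_table(path: str | Path, patch_side: int = 1792) -> pd.DataFrame:
    """Read a growth-pattern patch table; validates vocabulary and overlap."""
    df = pd.read_csv(path)
    _require_columns(df, ["slide_id", "x0", "y0", "pattern"], "patch table")
    out = pd.DataFrame({
        "slide_id": df["slide_id"].astype(str),
        "x0": pd.to_numeric(df["x0"]),
        "y0": pd.to_numeric(df["y0"]),
        "pattern": df["pattern"].astype(str).str.strip().str.lower().str.replace("-", "_"),
    })
    bad = sorted(set(out["pattern"]) - _VALID_PATTERNS)
    if bad:
        raise FormatError(f"patch table contains unknown pattern(s): {', '.join(bad)}")
    validate_patches_disjoint(out, patch_side)
    return out


def validate_patches_disjoint(patches: pd.DataFrame, patch_side: int) -> None:
    """Raise if any two equal-sized patches on one slide overlap."""
    for slide, grp in patches.groupby("slide_id"):
        g = grp.sort_values(["x0", "y0"]).reset_index(drop=True)
        x0 = g["x0"].to_numpy(float)
        y0 = g["y0"].to_numpy(float)
        for i in range(len(g)):
            j = i + 1
            while j < len(g) and x0[j] - x0[i] < patch_side:
                if abs(y0[j] - y0[i]) < patch_side:
                    raise FormatError(
                        f"patch table has overlapping patches on slide {slide!r} "
                        f"(origins ({x0[i]:g},{y0[i]:g}) and ({x0[j]:g},{y0[j]:g}))")
                j += 1


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical table (TSV; comma also accepted)."""
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, ["patient_id", "os_months", "os_event"], "clinical table")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].unique()
        raise FormatError(f"clinical table has duplicate patient_id(s): {', '.join(dupes)}")
    df["os_months"] = pd.to_numeric(df["os_months"])
    df["os_event"] = pd.to_numeric(df["os_event"]).astype(int)
    if not df["os_event"].isin([0, 1]).all():
        raise FormatError("os_event must be 0 or 1")
    if (df["os_months"] < 0).any():
        raise FormatError("os_months must be non-negative")
    return df


def read_slide_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["slide_id", "patient_id"], "slide map")
    out = df[["slide_id", "patient_id"]].astype(str)
    if out["slide_id"].duplicated().any():
        raise FormatError("slide map assigns some slide_id to multiple patients")
    return out


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> None:
    """Write a patient feature matrix (rows indexed by patient_id).

    Columns are emitted in lexicographic order; values round-trip
    bit-exactly through :func:`read_feature_matrix`.  Missing values
    (an inconsistent feature set across patients) are an error.
    """
    if not len(features):
        raise FormatError("refusing to write an empty feature matrix")
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise FormatError(
            f"feature matrix has missing values in column(s): {', '.join(map(str, bad))}")
    out = features[sorted(features.columns)].copy()
    out.index.name = "patient_id"
    # default float formatting uses repr(), which round-trips exactly
    out.to_csv(path)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id").sort_index(axis=1)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
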