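"""Tile-level scoring of nuclei detections.

Each classified tissue patch (1792 px square at 20x magnification, i.e.
448 px at 5x) is partitioned into a 4x4 grid of 16 equal non-overlapping
tiles of 448 px at 20x.  Nuclei are assigned to tiles by centroid
membership in half-open intervals ``[x0, x0 + side)``, so a nucleus on a
shared edge lands in exactly one tile.  Tiles are then labelled:

* *invalid* if they contain fewer than ``min_nuclei`` nuclei in total —
  such tiles contribute to no category and never carry the necrosis flag;
* *sTILs* if they contain at least ``stil_min_lymphocytes`` lymphocytes
  and strictly more stromal than neoplastic nuclei (stroma dominance is
  evaluated first; see :class:`ScoringThresholds.stils_precedence`);
* *TILs* if they contain at least ``til_min_neoplastic`` neoplastic
  nuclei and at least ``til_min_lymphocytes`` lymphocytes;
* *neither* otherwise.

Independently of the TILs/sTILs category, a valid tile is flagged
necrotic when it contains at least ``necrosis_min`` necrotic nuclei.

Per patch the module emits a three-feature vector: the number of TILs,
sTILs and necrotic tiles among the 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical nuclei classes used throughout the package
CELL_CLASSES = ("neoplastic", "lymphocyte", "stromal", "necrotic", "other")

#: the five LUAD architectural growth patterns
PATTERNS = ("lepidic", "acinar", "papillary", "micropapillary", "solid")

#: label for classified patches that are not tumour tissue
NON_TUMOUR = "non_tumour"

#: tile categories
TILS, STILS, NEITHER = "TILs", "sTILs", "neither"

_COUNT_COLS = [f"n_{c}" for c in CELL_CLASSES]


@dataclass(frozen=True)
class ScoringThresholds:
    """Empirical nuclei-count thresholds for tile classification.

    All counts refer to nuclei centroids inside one 448 px tile at 20x.
    """

    min_nuclei: int = 10              # below this a tile is not considered
    til_min_neoplastic: int = 20
    til_min_lymphocytes: int = 5
    stil_min_lymphocytes: int = 5
    necrosis_min: int = 15
    tile_side_px20: int = 448
    tiles_per_patch_side: int = 4
    #: evaluate the sTILs (stroma-dominant) definition before TILs when a
    #: tile satisfies both; flipping gives TILs precedence instead.
    stils_precedence: bool = True

    def __post_init__(self) -> None:
        for name in ("min_nuclei", "til_min_neoplastic", "til_min_lymphocytes",
                     "stil_min_lymphocytes", "necrosis_min", "tile_side_px20",
                     "tiles_per_patch_side"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"threshold {name!r} must be a positive integer, got {v!r}")

    @property
    def patch_side_px20(self) -> int:
        """Side length in pixels (20x) of a full patch."""
        return self.tile_side_px20 * self.tiles_per_patch_side

    @property
    def tiles_per_patch(self) -> int:
        return self.tiles_per_patch_side ** 2


@dataclass(frozen=True)
class TileCounts:
    """Per-class nuclei counts inside one tile."""

    n_neoplastic: int = 0
    n_lymphocyte: int = 0
    n_stromal: int = 0
    n_necrotic: int = 0
    n_other: int = 0

    @property
    def n_total(self) -> int:
        return (self.n_neoplastic + self.n_lymphocyte + self.n_stromal
                + self.n_necrotic + self.n_other)


@dataclass(frozen=True)
class TileLabel:
    valid: bool
    category: str            # TILs / sTILs / neither
    necrotic_flag: bool


def tile_grid(x0: float, y0: float, patch_side: int | None = None,
              thresholds: ScoringThresholds | None = None) -> list[tuple[float, float, float, float]]:
    """Bounds of the equal square tiles partitioning one patch.

    Returns ``tiles_per_patch_side**2`` half-open bounds
    ``(x0, y0, x1, y1)`` in row-major order (left-to-right, then
    top-to-bottom).  The union of the tiles is exactly the patch and
    pairwise intersections are empty.

    Raises ``ValueError`` when ``patch_side`` is not divisible by the
    grid dimension.
    """
    thresholds = thresholds or ScoringThresholds()
    n = thresholds.tiles_per_patch_side
    if patch_side is None:
        patch_side = thresholds.patch_side_px20
    if patch_side % n:
        raise ValueError(
            f"patch side {patch_side} not divisible into {n}x{n} equal tiles")
    side = patch_side // n
    return [(x0 + j * side, y0 + i * side, x0 + (j + 1) * side, y0 + (i + 1) * side)
            for i in range(n) for j in range(n)]


def count_tile(nuclei: pd.DataFrame, bounds: tuple[float, float, float, float]) -> TileCounts:
    """Count nuclei of one slide whose centroid lies in a half-open tile."""
    x0, y0, x1, y1 = bounds
    inside = nuclei[(nuclei["x"] >= x0) & (nuclei["x"] < x1)
                    & (nuclei["y"] >= y0) & (nuclei["y"] < y1)]
    c = inside["cell_class"].value_counts()
    return TileCounts(**{f"n_{k}": int(c.get(k, 0)) for k in CELL_CLASSES})


def classify_tile(counts: TileCounts, thresholds: ScoringThresholds | None = None) -> TileLabel:
    """Label one tile as TILs / sTILs / neither with a necrosis flag."""
    t = thresholds or ScoringThresholds()
    if counts.n_total < t.min_nuclei:
        return TileLabel(valid=False, category=NEITHER, necrotic_flag=False)
    is_stil = (counts.n_lymphocyte >= t.stil_min_lymphocytes
               and counts.n_stromal > counts.n_neoplastic)
    is_til = (counts.n_neoplastic >= t.til_min_neoplastic
              and counts.n_lymphocyte >= t.til_min_lymphocytes)
    if t.stils_precedence:
        category = STILS if is_stil else (TILS if is_til else NEITHER)
    else:
        category = TILS if is_til else (STILS if is_stil else NEITHER)
    return TileLabel(valid=True, category=category,
                     necrotic_flag=counts.n_necrotic >= t.necrosis_min)


def patch_vector(labels: list[TileLabel], thresholds: ScoringThresholds | None = None) -> tuple[int, int, int]:
    """(n_til_tiles, n_stil_tiles, n_necrotic_tiles) for one patch."""
    t = thresholds or ScoringThresholds()
    if len(labels) != t.tiles_per_patch:
        raise ValueError(
            f"expected {t.tiles_per_patch} tile labels, got {len(labels)}")
    return (sum(l.category == TILS for l in labels),
            sum(l.category == STILS for l in labels),
            sum(l.necrotic_flag for l in labels))


# ---------------------------------------------------------------------------
# vectorised cohort-level scoring


def classify_counts(counts: pd.DataFrame, thresholds: ScoringThresholds | None = None) -> pd.DataFrame:
    """Vectorised :func:`classify_tile` over a table of tile counts.

    ``counts`` needs columns ``n_neoplastic, n_lymphocyte, n_stromal,
    n_necrotic, n_other``; returns a copy with ``valid``, ``category``
    and ``necrotic_flag`` columns appended.
    """
    t = thresholds or ScoringThresholds()
    out = counts.copy()
    total = sum(out[c] for c in _COUNT_COLS)
    valid = total >= t.min_nuclei
    is_stil = (out["n_lymphocyte"] >= t.stil_min_lymphocytes) & (out["n_stromal"] > out["n_neoplastic"])
    is_til = (out["n_neoplastic"] >= t.til_min_neoplastic) & (out["n_lymphocyte"] >= t.til_min_lymphocytes)
    category = np.full(len(out), NEITHER, dtype=object)
    if t.stils_precedence:
        category[np.asarray(is_til)] = TILS
        category[np.asarray(is_stil)] = STILS
    else:
        category[np.asarray(is_stil)] = STILS
        category[np.asarray(is_til)] = TILS
    category[~np.asarray(valid)] = NEITHER
    out["valid"] = np.asarray(valid)
    out["category"] = category
    out["necrotic_flag"] = np.asarray(valid & (out["n_necrotic"] >= t.necrosis_min))
    return out


def tile_counts_from_nuclei(nuclei: pd.DataFrame, patches: pd.DataFrame,
                            thresholds: ScoringThresholds | None = None) -> pd.DataFrame:
    """Per-tile class counts for every patch, from nucleus centroids.

    Only tiles containing at least one nucleus appear as rows; absent
    tiles have all-zero counts and are implied.  Nuclei outside every
    labelled patch are ignored.

    Returns columns ``slide_id, x0, y0, tile_ix`` (row-major index in
    ``0..tiles_per_patch-1``) plus the five ``n_<class>`` counts.
    """
    t = thresholds or ScoringThresholds()
    side = t.patch_side_px20
    empty = pd.DataFrame(columns=["slide_id", "x0", "y0", "tile_ix", *_COUNT_COLS])
    if not len(nuclei) or not len(patches):
        return empty

    aligned = ((patches["x0"] % side == 0) & (patches["y0"] % side == 0)).all()
    if aligned:
        assigned = _assign_grid(nuclei, patches, side)
    else:
        assigned = _assign_general(nuclei, patches, side)
    if not len(assigned):
        return empty

    rel_x = assigned["x"] - assigned["x0"]
    rel_y = assigned["y"] - assigned["y0"]
    col = (rel_x // t.tile_side_px20).astype(int)
    row = (rel_y // t.tile_side_px20).astype(int)
    assigned = assigned.assign(tile_ix=row * t.tiles_per_patch_side + col)

    counts = (assigned.groupby(["slide_id", "x0", "y0", "tile_ix", "cell_class"], observed=True)
              .size().unstack("cell_class", fill_value=0))
    for c in CELL_CLASSES:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(CELL_CLASSES)]
    counts.columns = _COUNT_COLS
    return counts.reset_index()


def _assign_grid(nuclei: pd.DataFrame, patches: pd.DataFrame, side: int) -> pd.DataFrame:
    """Fast path: all patch origins on the regular patch grid."""
    nuc = nuclei.assign(x0=(nuclei["x"] // side).astype(np.int64) * side,
                        y0=(nuclei["y"] // side).astype(np.int64) * side)
    keys = patches[["slide_id", "x0", "y0"]].astype({"x0": np.int64, "y0": np.int64})
    return nuc.merge(keys, on=["slide_id", "x0", "y0"], how="inner")


def _assign_general(nuclei: pd.DataFrame, patches: pd.DataFrame, side: int) -> pd.DataFrame:
    """General path: arbitrary (non-overlapping) patch origins."""
    parts = []
    for slide, pat in patches.groupby("slide_id"):
        nuc = nuclei[nuclei["slide_id"] == slide]
        if not len(nuc):
            continue
        for _, p in pat.iterrows():
            m = ((nuc["x"] >= p.x0) & (nuc["x"] < p.x0 + side)
                 & (nuc["y"] >= p.y0) & (nuc["y"] < p.y0 + side))
            if m.any():
                parts.append(nuc[m].assign(x0=p.x0, y0=p.y0))
    if not parts:
        return pd.DataFrame(columns=[*nuclei.columns, "x0", "y0"])
    return pd.concat(parts, ignore_index=True)


def score_patches(nuclei: pd.DataFrame, patches: pd.DataFrame,
                  thresholds: ScoringThresholds | None = None) -> pd.DataFrame:
    """TILs/sTILs/necrosis tile counts for every classified patch.

    Returns one row per patch: ``slide_id, x0, y0, pattern,
    n_til_tiles, n_stil_tiles, n_necrotic_tiles, n_valid_tiles``.
    Patches with no detected nuclei score zero on every feature.
    """
    t = thresholds or ScoringThresholds()
    tile_counts = tile_counts_from_nuclei(nuclei, patches, t)
    return score_patches_from_tile_counts(tile_counts, patches, t)


def score_patches_from_tile_counts(tile_counts: pd.DataFrame, patches: pd.DataFrame,
                                   thresholds: ScoringThresholds | None = None) -> pd.DataFrame:
    """As :func:`score_patches`, starting from per-tile class counts."""
    t = thresholds or ScoringThresholds()
    base = patches[["slide_id", "x0", "y0", "pattern"]].copy()
    if len(tile_counts):
        labelled = classify_counts(tile_counts, t)
        agg = (labelled.assign(is_til=labelled["category"] == TILS,
                               is_stil=labelled["category"] == STILS)
               .groupby(["slide_id", "x0", "y0"], observed=True)
               .agg(n_til_tiles=("is_til", "sum"),
                    n_stil_tiles=("is_stil", "sum"),
                    n_necrotic_tiles=("necrotic_flag", "sum"),
                    n_valid_tiles=("valid", "sum"))
               .reset_index())
        out = base.merge(agg, on=["slide_id", "x0", "y0"], how="left")
    else:
        out = base.assign(n_til_tiles=0, n_stil_tiles=0,
                          n_necrotic_tiles=0, n_valid_tiles=0)
    for c in ("n_til_tiles", "n_stil_tiles", "n_necrotic_tiles", "n_valid_tiles"):
        out[c] = out[c].fillna(0).astype(int)
    return out
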