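"""Patient-level growth-pattern-specific TILs (GPS-TILs) features.

For each patient, the per-patch tile counts of the three immune signals
(TILs tiles, sTILs tiles, necrotic tiles) are aggregated with four
statistics over the patches of each scope:

========== =========== ==========================================
statistic   field name  meaning ascribed to it
========== =========== ==========================================
minimum     presence    baseline level across all patches
maximum     density     the densest single patch
mean        abundance   overall level
SD          dispersion  spatial heterogeneity between patches
========== =========== ==========================================

Scopes are the four retained growth patterns (lepidic, acinar,
papillary, solid) plus ``overall`` (all retained tumour patches).
Micropapillary patches are excluded by default — both from their own
scope and from ``overall`` — because of their scarcity; a config switch
restores them.  The SD uses the population convention (divisor ``n``)
so a single-patch scope gives dispersion 0.  A scope with no patches is
zero-filled: an absent pattern contributes zero observed immune tiles.

Feature names are ``{scope}_{signal}_{stat}`` with signals
``tils, stils, necrosis``, plus ``pct_{pattern}`` growth-pattern
percentages over the five patterns.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .tiles import NON_TUMOUR, PATTERNS

#: statistic label -> underlying aggregation over per-patch tile counts
STATS = ("presence", "density", "abundance", "dispersion")  # min, max, mean, SD
SIGNALS = {"tils": "n_til_tiles", "stils": "n_stil_tiles", "necrosis": "n_necrotic_tiles"}
#: growth patterns retained as pattern-specific feature scopes
RETAINED_PATTERNS = ("lepidic", "acinar", "papillary", "solid")
SCOPES = (*RETAINED_PATTERNS, "overall")

#: the available feature selections and their column counts (before
#: appending pattern percentages or grade)
SELECTIONS = ("overall", "gps_tils", "overall+pct", "gps_tils+pct", "gps_tils+grade")


def feature_names(config: PipelineConfig | None = None) -> list[str]:
    """All feature names of a full PatientFeatureSet, sorted."""
    scopes = SCOPES if (config is None or config.exclude_micropapillary) \
        else (*PATTERNS, "overall")
    names = [f"{sc}_{sig}_{st}" for sc in scopes for sig in SIGNALS for st in STATS]
    names += [f"pct_{p}" for p in PATTERNS]
    return sorted(names)


def pattern_percentages(patches: pd.DataFrame) -> dict[str, float]:
    """Percent of tumour patches carrying each growth pattern.

    Non-tumour patches are excluded from numerator and denominator.
    Requires at least one tumour patch.
    """
    tumour = patches[patches["pattern"] != NON_TUMOUR]
    if not len(tumour):
        raise ValueError("pattern percentages need at least one tumour patch")
    counts = tumour["pattern"].value_counts()
    n = len(tumour)
    return {p: 100.0 * counts.get(p, 0) / n for p in PATTERNS}


def four_stats(values) -> tuple[float, float, float, float]:
    """(presence, density, abundance, dispersion) of integer tile counts.

    Mean and population SD are computed from exact integer sums
    (``S/n`` and ``sqrt((n*Q - S^2)/n^2)``), so the result is a pure
    function of the multiset of counts, reproducible bit-for-bit by any
    independent implementation of the same closed forms.
    """
    vals = [int(v) for v in values]
    if not vals:
        return (0.0, 0.0, 0.0, 0.0)
    n = len(vals)
    s = sum(vals)
    q = sum(v * v for v in vals)
    return (float(min(vals)), float(max(vals)), s / n,
            math.sqrt((n * q - s * s) / (n * n)))


def aggregate_patient(scored_patches: pd.DataFrame,
                      config: PipelineConfig | None = None,
                      patient_id: str = "?") -> dict[str, float]:
    """GPS-TILs feature set for one patient from scored patch vectors.

    ``scored_patches`` holds all patches from all slides of the patient
    (columns ``pattern, n_til_tiles, n_stil_tiles, n_necrotic_tiles``).
    Patch order is irrelevant.  A patient with no tumour patches is an
    error naming the patient.
    """
    config = config or PipelineConfig()
    tumour = scored_patches[scored_patches["pattern"] != NON_TUMOUR]
    if not len(tumour):
        raise ValueError(f"patient {patient_id!r} has no tumour patches")
    pct = pattern_percentages(scored_patches)

    if config.exclude_micropapillary:
        retained = tumour[tumour["pattern"] != "micropapillary"]
        scopes: tuple[str, ...] = SCOPES
    else:
        retained = tumour
        scopes = (*PATTERNS, "overall")

    out: dict[str, float] = {f"pct_{p}": v for p, v in pct.items()}
    for scope in scopes:
        sub = retained if scope == "overall" else retained[retained["pattern"] == scope]
        for sig, col in SIGNALS.items():
            stats = four_stats(sub[col])
            for st, v in zip(STATS, stats):
                out[f"{scope}_{sig}_{st}"] = v
    return out


def _grouped_stats(df: pd.DataFrame, keys: list[str]) -> dict[str, pd.DataFrame]:
    """Vectorised :func:`four_stats` per group, exact integer sums."""
    cols = list(SIGNALS.values())
    work = df[keys + cols].astype({c: "int64" for c in cols})
    g = work.groupby(keys, observed=True)
    n = g.size()
    s = g[cols].sum()
    q = work.assign(**{c: work[c] ** 2 for c in cols}).groupby(keys, observed=True)[cols].sum()
    mean = s.div(n, axis=0)
    disp = np.sqrt((q.mul(n, axis=0) - s.pow(2)).div(n.pow(2), axis=0))
    return {"presence": g[cols].min().astype(float), "density": g[cols].max().astype(float),
            "abundance": mean, "dispersion": disp}


def aggregate_cohort(scored_patches: pd.DataFrame, slide_map: pd.DataFrame,
                     config: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature matrix for every patient in the slide map.

    Vectorised over the cohort; numerically identical to calling
    :func:`aggregate_patient` per patient.  Patients whose slides carry
    no tumour patches raise, naming the patient.
    """
    config = config or PipelineConfig()
    merged = scored_patches.merge(slide_map, on="slide_id", how="left")
    if merged["patient_id"].isna().any():
        orphans = merged.loc[merged["patient_id"].isna(), "slide_id"].unique()
        raise ValueError(f"slides absent from slide map: {', '.join(map(str, orphans))}")
    patients = sorted(slide_map["patient_id"].unique())
    tumour = merged[merged["pattern"] != NON_TUMOUR]
    missing = sorted(set(patients) - set(tumour["patient_id"].unique()))
    if missing:
        raise ValueError(f"patient(s) with no tumour patches: {', '.join(missing)}")

    sig_of = {col: sig for sig, col in SIGNALS.items()}
    ct = (tumour.groupby(["patient_id", "pattern"], observed=True).size()
          .unstack("pattern", fill_value=0).reindex(columns=list(PATTERNS), fill_value=0)
          .reindex(patients, fill_value=0))
    pct = (ct * 100.0).div(ct.sum(axis=1), axis=0)
    out = pd.DataFrame({f"pct_{p}": pct[p] for p in PATTERNS}, index=patients)

    if config.exclude_micropapillary:
        retained = tumour[tumour["pattern"] != "micropapillary"]
        scopes: tuple[str, ...] = RETAINED_PATTERNS
    else:
        retained = tumour
        scopes = PATTERNS

    per_pattern = _grouped_stats(retained, ["patient_id", "pattern"])
    for st, frame in per_pattern.items():
        wide = frame.unstack("pattern")
        for col, sig in sig_of.items():
            for scope in scopes:
                key = (col, scope)
                series = wide[key] if key in wide.columns else pd.Series(dtype=float)
                out[f"{scope}_{sig}_{st}"] = series.reindex(patients).fillna(0.0)

    overall = _grouped_stats(retained, ["patient_id"])
    for st, frame in overall.items():
        for col, sig in sig_of.items():
            out[f"overall_{sig}_{st}"] = frame[col].reindex(patients).fillna(0.0)

    out = out.sort_index(axis=1)
    out.index.name = "patient_id"
    return out


def build_feature_matrix(features: pd.DataFrame, selection: str,
                         grades: pd.Series | None = None) -> pd.DataFrame:
    """Select model columns from a full patient feature table.

    Selections
    ----------
    ``overall``
        the 12 whole-tumour features (3 signals x 4 statistics)
    ``gps_tils``
        the 48 pattern-specific features (4 retained patterns x 12)
    ``overall+pct`` / ``gps_tils+pct``
        the above plus the 5 growth-pattern percentages
    ``gps_tils+grade``
        gps_tils plus an ordinal grade column (1/2/3, from ``grades``);
        patients with unknown/missing grade are dropped from this
        selection only.
    """
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; choose from {SELECTIONS}")
    pct_cols = sorted(c for c in features.columns if c.startswith("pct_"))
    overall_cols = sorted(c for c in features.columns if c.startswith("overall_"))
    gps_cols = sorted(c for c in features.columns
                      if c.split("_")[0] in RETAINED_PATTERNS)
    if selection == "overall":
        cols = overall_cols
    elif selection == "gps_tils":
        cols = gps_cols
    elif selection == "overall+pct":
        cols = sorted(overall_cols + pct_cols)
    elif selection == "gps_tils+pct":
        cols = sorted(gps_cols + pct_cols)
    else:  # gps_tils+grade
        if grades is None:
            raise ValueError("selection 'gps_tils+grade' needs a grades series")
        g = pd.to_numeric(grades, errors="coerce").reindex(features.index)
        keep = g.isin([1, 2, 3])
        out = features.loc[keep, gps_cols].copy()
        out["grade"] = g[keep].astype(float)
        return out.sort_index(axis=1)
    return features[cols].copy()


def normalized_tcr_diversity(clonotype_counts, tils_abundance: float) -> float:
    """TCR Shannon diversity normalised by log-transformed TILs abundance.

    Shannon diversity ``H = -sum p_i ln p_i`` over clonotype
    proportions, divided by ``ln(1 + tils_abundance)``; the +1 offset
    keeps the denominator positive for abundances at or below one.
    Separates lymphocyte *diversity* from sheer lymphocyte *abundance*.
    """
    counts = np.asarray(clonotype_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("clonotype counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("clonotype counts are all zero")
    if tils_abundance <= 0:
        raise ValueError("tils_abundance must be > 0")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log1p(tils_abundance)
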