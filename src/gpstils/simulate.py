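"""Synthetic LUAD cohort generator and brute-force oracles.

Emulates the statistical structure the analysis pipeline assumes,
without images: patients carry one or two diagnostic slides; each slide
is a grid of classified 1792 px patches whose growth-pattern labels are
drawn from a patient-specific Dirichlet composition over the five LUAD
patterns; each of the 16 tiles of a patch receives Poisson nuclei
counts per cell class, with patient-level log-normal multipliers on the
lymphocyte, stromal and necrotic intensities; nuclei are then placed
uniformly within their tile (the downstream scoring uses only per-tile
counts, so within-tile texture carries no information).  Overall
survival is exponential with a log-hazard linear in the patient's
latent infiltration variables, right-censored by an independent uniform
dropout time and a 60-month administrative horizon.

The default intensities give tile count distributions in which the
TILs/sTILs/necrosis thresholds are genuinely informative about the
latent multipliers (most tiles pass the 10-nucleus validity bar; the
20-neoplastic and 5-lymphocyte bars are crossed by a latent-dependent
fraction of tiles).  The micropapillary Dirichlet weight is small,
mirroring that pattern's scarcity in real cohorts.

The module also provides brute-force oracles (pure-Python enumeration,
independent of the vectorised pipeline) used to validate tile
classification and patient aggregation exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .tiles import CELL_CLASSES, NON_TUMOUR, PATTERNS

#: per-tile Poisson base intensities by pattern and cell class
DEFAULT_CLASS_RATES: dict[str, dict[str, float]] = {
    "lepidic":        {"neoplastic": 14, "lymphocyte": 4, "stromal": 8,  "necrotic": 0.5, "other": 2},
    "acinar":         {"neoplastic": 22, "lymphocyte": 4, "stromal": 10, "necrotic": 1.0, "other": 2},
    "papillary":      {"neoplastic": 20, "lymphocyte": 4, "stromal": 8,  "necrotic": 1.0, "other": 2},
    "micropapillary": {"neoplastic": 18, "lymphocyte": 5, "stromal": 6,  "necrotic": 1.5, "other": 2},
    "solid":          {"neoplastic": 35, "lymphocyte": 5, "stromal": 6,  "necrotic": 4.0, "other": 2},
    NON_TUMOUR:       {"neoplastic": 0,  "lymphocyte": 1, "stromal": 5,  "necrotic": 0.2, "other": 3},
}

#: hazard coefficients (per unit of latent log-multiplier) for a strong
#: protective infiltration effect with a harmful necrosis effect; the
#: implied hazard ratio per SD of log-infiltration is about exp(1.5*0.6).
STRONG_EFFECT_BETAS = (-1.5, 0.0, 1.0)
NULL_BETAS = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort."""

    n_patients: int = 100
    #: probability a patient contributes a second slide (multi-slide
    #: patients mirror the slide/patient ratio of diagnostic cohorts)
    two_slide_prob: float = 0.15
    patches_per_slide_mean: float = 40.0
    patches_per_slide_min: int = 5
    #: fraction of patches labelled non-tumour tissue
    non_tumour_frac: float = 0.1
    #: Dirichlet concentration over (lepidic, acinar, papillary,
    #: micropapillary, solid); micropapillary kept rare
    pattern_dirichlet_alpha: tuple[float, ...] = (1.0, 1.5, 1.0, 0.2, 1.0)
    class_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(r) for p, r in DEFAULT_CLASS_RATES.items()})
    #: SD of the patient-level log-normal lymphocyte multiplier
    infiltration_sd: float = 0.6
    #: SD of the per-pattern wiggle around the patient lymphocyte multiplier
    pattern_infiltration_sd: float = 0.25
    stromal_sd: float = 0.3
    necrosis_sd: float = 0.6
    #: (beta_lymphocyte, beta_stromal, beta_necrosis) on the latent
    #: patient log-multipliers; default is the global null
    hazard_betas: tuple[float, float, float] = NULL_BETAS
    baseline_hazard: float = 0.012   # events per month
    censor_uniform_max: float = 120.0
    admin_censor_months: float = 60.0
    seed: int = 0
    patch_side_px20: int = 1792
    tiles_per_patch_side: int = 4

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not all(a > 0 for a in self.pattern_dirichlet_alpha) \
                or len(self.pattern_dirichlet_alpha) != 5:
            raise ValueError("pattern_dirichlet_alpha must be 5 positive values")
        for p, rates in self.class_rates.items():
            if any(v < 0 for v in rates.values()):
                raise ValueError(f"negative class rate for pattern {p!r}")
        if self.baseline_hazard <= 0 or self.censor_uniform_max <= 0 \
                or self.admin_censor_months <= 0:
            raise ValueError("hazard and censoring parameters must be > 0")
        if not 0 <= self.two_slide_prob <= 1 or not 0 <= self.non_tumour_frac < 1:
            raise ValueError("two_slide_prob in [0,1], non_tumour_frac in [0,1)")

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass
class SyntheticCohort:
    """All artifacts of one generated cohort, as pipeline-ready tables."""

    nuclei: pd.DataFrame | None      # slide_id,x,y,cell_class (None on counts-only runs)
    patches: pd.DataFrame            # slide_id,x0,y0,pattern
    tile_counts: pd.DataFrame        # slide_id,x0,y0,tile_ix,n_<class>...
    clinical: pd.DataFrame           # patient_id,os_months,os_event,covariates
    slide_map: pd.DataFrame          # slide_id,patient_id
    ground_truth: pd.DataFrame       # latent variables per patient


def generate_cohort(config: CohortConfig, with_nuclei: bool = True) -> SyntheticCohort:
    """Draw one cohort; fully reproducible from ``config.seed``.

    With ``with_nuclei=False`` nucleus coordinates are not materialised
    (the per-tile counts are identical either way), which makes large
    replicate studies cheap.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:04d}" for i in range(n)]

    comp = rng.dirichlet(config.pattern_dirichlet_alpha, size=n)
    u_lymph = rng.normal(0.0, config.infiltration_sd, size=n)
    w_lymph = rng.normal(0.0, config.pattern_infiltration_sd, size=(n, len(PATTERNS)))
    u_stromal = rng.normal(0.0, config.stromal_sd, size=n)
    u_necro = rng.normal(0.0, config.necrosis_sd, size=n)
    b = config.hazard_betas
    eta = b[0] * u_lymph + b[1] * u_stromal + b[2] * u_necro

    # survival: exponential with patient-specific rate, censored by an
    # independent uniform dropout and the administrative horizon
    t_event = rng.exponential(1.0 / (config.baseline_hazard * np.exp(eta)))
    t_cens = np.minimum(rng.uniform(0.0, config.censor_uniform_max, size=n),
                        config.admin_censor_months)
    os_months = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    n_slides = 1 + (rng.random(n) < config.two_slide_prob).astype(int)

    patch_rows, slide_rows = [], []
    for i, pid in enumerate(pids):
        for s in range(n_slides[i]):
            slide = f"{pid}-S{s}"
            slide_rows.append((slide, pid))
            n_patch = max(config.patches_per_slide_min,
                          int(rng.poisson(config.patches_per_slide_mean)))
            ncol = int(np.ceil(np.sqrt(n_patch)))
            is_nt = rng.random(n_patch) < config.non_tumour_frac
            pats = np.array(PATTERNS, dtype=object)[
                rng.choice(len(PATTERNS), size=n_patch, p=comp[i])]
            pats[is_nt] = NON_TUMOUR
            if (pats == NON_TUMOUR).all():      # keep >= 1 tumour patch per patient
                pats[0] = PATTERNS[int(rng.choice(len(PATTERNS), p=comp[i]))]
            for k in range(n_patch):
                patch_rows.append((slide, (k % ncol) * config.patch_side_px20,
                                   (k // ncol) * config.patch_side_px20, pats[k], i))
    patches = pd.DataFrame(patch_rows, columns=["slide_id", "x0", "y0", "pattern", "_pi"])

    tile_counts = _draw_tile_counts(patches, comp, u_lymph, w_lymph, u_stromal,
                                    u_necro, config, rng)
    nuclei = _place_nuclei(tile_counts, config, rng) if with_nuclei else None
    patches = patches.drop(columns="_pi")

    clinical = _draw_clinical(pids, os_months, os_event, comp, rng)
    gt = pd.DataFrame({
        "patient_id": pids,
        **{f"comp_{p}": comp[:, j] for j, p in enumerate(PATTERNS)},
        "u_lymphocyte": u_lymph, "u_stromal": u_stromal, "u_necrosis": u_necro,
        **{f"w_lymph_{p}": w_lymph[:, j] for j, p in enumerate(PATTERNS)},
        "eta": eta,
        "t_event": t_event,
    })
    gt["true_high_risk"] = (gt["eta"] > gt["eta"].median()).astype(int)

    return SyntheticCohort(
        nuclei=nuclei, patches=patches, tile_counts=tile_counts,
        clinical=clinical,
        slide_map=pd.DataFrame(slide_rows, columns=["slide_id", "patient_id"]),
        ground_truth=gt)


def _draw_tile_counts(patches: pd.DataFrame, comp, u_lymph, w_lymph, u_stromal,
                      u_necro, config: CohortConfig, rng) -> pd.DataFrame:
    n_tiles = config.tiles_per_patch_side ** 2
    pat_idx = {p: j for j, p in enumerate(PATTERNS)}
    reps = patches.loc[patches.index.repeat(n_tiles)].reset_index(drop=True)
    reps["tile_ix"] = np.tile(np.arange(n_tiles), len(patches))

    pi = reps["_pi"].to_numpy()
    pj = reps["pattern"].map(pat_idx).fillna(0).to_numpy(int)
    tumour = (reps["pattern"] != NON_TUMOUR).to_numpy()
    lam = {}
    for cls in CELL_CLASSES:
        base = reps["pattern"].map({p: r[cls] for p, r in config.class_rates.items()}).to_numpy(float)
        if cls == "lymphocyte":
            mult = np.where(tumour, np.exp(u_lymph[pi] + w_lymph[pi, pj]), 1.0)
        elif cls == "stromal":
            mult = np.exp(u_stromal[pi])
        elif cls == "necrotic":
            mult = np.exp(u_necro[pi])
        else:
            mult = 1.0
        lam[cls] = base * mult
    out = reps[["slide_id", "x0", "y0", "tile_ix"]].copy()
    for cls in CELL_CLASSES:
        out[f"n_{cls}"] = rng.poisson(lam[cls])
    return out


def _place_nuclei(tile_counts: pd.DataFrame, config: CohortConfig, rng) -> pd.DataFrame:
    side = config.patch_side_px20 // config.tiles_per_patch_side
    col = tile_counts["tile_ix"].to_numpy() % config.tiles_per_patch_side
    row = tile_counts["tile_ix"].to_numpy() // config.tiles_per_patch_side
    tx0 = tile_counts["x0"].to_numpy() + col * side
    ty0 = tile_counts["y0"].to_numpy() + row * side
    parts = []
    for cls in CELL_CLASSES:
        cnt = tile_counts[f"n_{cls}"].to_numpy()
        total = int(cnt.sum())
        if not total:
            continue
        ix = np.repeat(np.arange(len(tile_counts)), cnt)
        parts.append(pd.DataFrame({
            "slide_id": tile_counts["slide_id"].to_numpy()[ix],
            "x": tx0[ix] + rng.uniform(0, side, size=total),
            "y": ty0[ix] + rng.uniform(0, side, size=total),
            "cell_class": cls,
        }))
    nuclei = pd.concat(parts, ignore_index=True)
    return nuclei.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def _draw_clinical(pids, os_months, os_event, comp, rng) -> pd.DataFrame:
    n = len(pids)
    from .grading import assign_grade  # report grade mimics pattern-based grading
    grades = []
    for i in range(n):
        pct = {p: 100.0 * comp[i, j] for j, p in enumerate(PATTERNS)}
        # renormalise away float drift so the grader's sum check passes
        s = sum(pct.values())
        pct = {p: v * 100.0 / s for p, v in pct.items()}
        g = assign_grade(pct).grade
        r = rng.random()
        if r < 0.10:
            grades.append("unknown")
        elif r < 0.25:        # inter-observer disagreement
            grades.append(str(int(np.clip(g + rng.choice([-1, 1]), 1, 3))))
        else:
            grades.append(str(g))
    return pd.DataFrame({
        "patient_id": pids,
        "os_months": os_months,
        "os_event": os_event,
        "age": np.round(rng.normal(65.0, 10.0, size=n), 1),
        "sex": rng.choice(["female", "male"], size=n),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=[0.55, 0.25, 0.15, 0.05]),
        "smoking": rng.choice(["never", "former", "current"], size=n, p=[0.2, 0.5, 0.3]),
        "grade": grades,
    })


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write all cohort tables as pipeline-ready text files."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if cohort.nuclei is not None:
        paths["nuclei"] = str(outdir / "nuclei.csv")
        cohort.nuclei.to_csv(paths["nuclei"], index=False)
    paths["patches"] = str(outdir / "patches.csv")
    cohort.patches.to_csv(paths["patches"], index=False)
    paths["clinical"] = str(outdir / "clinical.tsv")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    paths["slide_map"] = str(outdir / "slide_map.csv")
    cohort.slide_map.to_csv(paths["slide_map"], index=False)
    paths["ground_truth"] = str(outdir / "ground_truth.csv")
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# brute-force oracles (pure Python, independent of the vectorised pipeline)


def literal_tile_label(n_neoplastic: int, n_lymphocyte: int, n_stromal: int,
                       n_necrotic: int, n_other: int) -> tuple[bool, str, bool]:
    """Literal restatement of the tile rules with hard-coded thresholds.

    Returns ``(valid, category, necrotic_flag)``.  Deliberately written
    as plain conditionals, independent of :mod:`gpstils.tiles`, to serve
    as a cross-check oracle.
    """
    total = n_neoplastic + n_lymphocyte + n_stromal + n_necrotic + n_other
    if total < 10:                      # "not considered"
        return (False, "neither", False)
    if n_lymphocyte >= 5 and n_stromal > n_neoplastic:
        category = "sTILs"
    elif n_neoplastic >= 20 and n_lymphocyte >= 5:
        category = "TILs"
    else:
        category = "neither"
    return (True, category, n_necrotic >= 15)


def oracle_patient_features(cohort: SyntheticCohort,
                            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Recompute every patient's feature set by direct enumeration.

    Walks nuclei one by one into tiles (no vectorised shortcuts),
    labels tiles with :func:`literal_tile_label`, and aggregates with
    the :mod:`statistics` module.  Requires a cohort generated with
    nuclei.  Used to assert exact pipeline equivalence.
    """
    if cohort.nuclei is None:
        raise ValueError("oracle needs a cohort generated with nuclei")
    config = config or PipelineConfig()
    t = config.thresholds
    side, n_side = t.patch_side_px20, t.tiles_per_patch_side
    tile_side = side // n_side

    nuclei_by_slide: dict[str, list[tuple[float, float, str]]] = {}
    for r in cohort.nuclei.itertuples(index=False):
        nuclei_by_slide.setdefault(r.slide_id, []).append((r.x, r.y, r.cell_class))
    slide_owner = dict(zip(cohort.slide_map["slide_id"], cohort.slide_map["patient_id"]))

    per_patient: dict[str, list[tuple[str, int, int, int]]] = {}
    for patch in cohort.patches.itertuples(index=False):
        pid = slide_owner[patch.slide_id]
        tiles = [[0, 0, 0, 0, 0] for _ in range(n_side * n_side)]
        cls_ix = {c: k for k, c in enumerate(CELL_CLASSES)}
        for (x, y, cls) in nuclei_by_slide.get(patch.slide_id, []):
            if patch.x0 <= x < patch.x0 + side and patch.y0 <= y < patch.y0 + side:
                col = int((x - patch.x0) // tile_side)
                row = int((y - patch.y0) // tile_side)
                tiles[row * n_side + col][cls_ix[cls]] += 1
        n_til = n_stil = n_nec = 0
        for counts in tiles:
            valid, cat, flag = literal_tile_label(*counts)
            n_til += cat == "TILs"
            n_stil += cat == "sTILs"
            n_nec += flag
        per_patient.setdefault(pid, []).append((patch.pattern, n_til, n_stil, n_nec))

    scope_list = ["lepidic", "acinar", "papillary", "solid", "overall"] \
        if config.exclude_micropapillary else [*PATTERNS, "overall"]
    rows = {}
    for pid in sorted(per_patient):
        vecs = per_patient[pid]
        tumour = [v for v in vecs if v[0] != NON_TUMOUR]
        feats: dict[str, float] = {}
        for j, p in enumerate(PATTERNS):
            feats[f"pct_{p}"] = 100.0 * sum(v[0] == p for v in tumour) / len(tumour)
        retained = [v for v in tumour if v[0] != "micropapillary"] \
            if config.exclude_micropapillary else tumour
        for scope in scope_list:
            sub = retained if scope == "overall" else [v for v in retained if v[0] == scope]
            for k, sig in ((1, "tils"), (2, "stils"), (3, "necrosis")):
                vals = [int(v[k]) for v in sub]
                if vals:
                    m, s, q = len(vals), sum(vals), sum(v * v for v in vals)
                    feats[f"{scope}_{sig}_presence"] = float(min(vals))
                    feats[f"{scope}_{sig}_density"] = float(max(vals))
                    feats[f"{scope}_{sig}_abundance"] = s / m
                    # population SD from exact integer sums
                    feats[f"{scope}_{sig}_dispersion"] = math.sqrt((m * q - s * s) / (m * m))
                else:
                    for st in ("presence", "density", "abundance", "dispersion"):
                        feats[f"{scope}_{sig}_{st}"] = 0.0
        rows[pid] = feats
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    out.index.name = "patient_id"
    return out
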