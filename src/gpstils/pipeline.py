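"""End-to-end orchestration: tables in, stratification report out."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .features import aggregate_cohort, build_feature_matrix
from .grading import assign_grades
from .io import write_feature_matrix, write_json, write_table
from .survival import StratificationReport, stratify_cohort
from .tiles import score_patches


def run_pipeline(nuclei: pd.DataFrame, patches: pd.DataFrame,
                 clinical: pd.DataFrame, slide_map: pd.DataFrame,
                 config: PipelineConfig | None = None) -> dict:
    """Score tiles, build patient features, grade, and stratify.

    Returns a dict of artifacts: ``scored_patches``, ``features``
    (full patient feature table), ``grades``, ``matrix`` (the model
    design matrix per ``config.feature_selection``) and ``report``
    (:class:`~gpstils.survival.StratificationReport`).
    """
    config = config or PipelineConfig()
    scored = score_patches(nuclei, patches, config.thresholds)
    return run_pipeline_from_scored(scored, clinical, slide_map, config)


def run_pipeline_from_scored(scored: pd.DataFrame, clinical: pd.DataFrame,
                             slide_map: pd.DataFrame,
                             config: PipelineConfig | None = None) -> dict:
    """As :func:`run_pipeline`, starting from scored patch vectors."""
    config = config or PipelineConfig()
    features = aggregate_cohort(scored, slide_map, config)
    grades = assign_grades(features)
    keep = features.index.intersection(clinical["patient_id"])
    matrix = build_feature_matrix(features.loc[keep], config.feature_selection,
                                  grades=grades["grade"])
    clin = clinical[clinical["patient_id"].isin(matrix.index)]
    report = stratify_cohort(matrix, clin, config)
    return {"scored_patches": scored, "features": features, "grades": grades,
            "matrix": matrix, "report": report}


def write_artifacts(artifacts: dict, outdir: str | Path,
                    config: PipelineConfig | None = None) -> dict[str, str]:
    """Write pipeline artifacts plus a machine-readable run log."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = str(outdir / name)
        return paths[name]

    write_table(artifacts["scored_patches"], _p("scored_patches.csv"))
    write_feature_matrix(artifacts["features"], _p("features.csv"))
    artifacts["grades"].to_csv(_p("grades.csv"))
    write_feature_matrix(artifacts["matrix"], _p("matrix.csv"))
    report: StratificationReport = artifacts["report"]
    write_json(report.to_dict(), _p("stratification.json"))
    km = pd.concat([c.assign(group=g) for g, c in report.km_curves.items()],
                   ignore_index=True)
    write_table(km, _p("km_curves.csv"))
    report.cv.assignments.to_csv(_p("risk_groups.csv"))
    write_json({"config": config.to_dict(), "seed": config.random_seed,
                "gpstils_version": __version__}, _p("run_log.json"))
    return paths
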