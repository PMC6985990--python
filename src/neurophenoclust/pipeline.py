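"""End-to-end orchestration of the phenotyping pipeline.

Stages (dependency order): ``simulate`` → ``features`` → ``cluster`` →
``compare`` → ``survival``, plus an optional ``phantom`` demo that runs a
small head phantom through volumetrics and shape extraction.  Each stage
writes TSV/JSON outputs into its own subdirectory of the run directory;
later stages load their inputs back from disk, so stages can be run
separately.  A manifest records package version, seed, config hash and
per-stage row counts.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, feature_matrix, subgroup_stats, survival
from . import volumetrics, wmh_shape
from .config import RunConfig
from .synthetic_data import (
    CohortSpec,
    HazardSpec,
    default_head_spec,
    make_head_phantom,
    simulate_cohort,
    simulate_followup,
)
from .synthetic_data.survival_sim import OUTCOMES, subgroup_style_log_hr

log = logging.getLogger("neurophenoclust")

STAGES = ("phantom", "simulate", "features", "cluster", "compare", "survival")


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    p = Path(cfg.out_dir) / stage
    p.mkdir(parents=True, exist_ok=True)
    return p


def _update_manifest(cfg: RunConfig, stage: str, info: dict) -> None:
    path = Path(cfg.out_dir) / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": json.loads(cfg.to_json()),
        "stages": {},
    }
    manifest["stages"][stage] = info
    path.write_text(json.dumps(manifest, indent=2, default=str))


def stage_phantom(cfg: RunConfig) -> dict:
    """Small head phantom through volumetrics and WMH shape extraction."""
    out = _stage_dir(cfg, "phantom")
    spec = default_head_spec(seed=cfg.seed)
    seg, truth, lobe_map = make_head_phantom(spec)
    seg.to_nifti(out / "head_labels.nii")
    truth.to_csv(out / "construction_truth.tsv", sep="\t", index=False)

    vols = volumetrics.compute_volumes(seg)
    fracs = volumetrics.compute_fractions(vols)
    pd.DataFrame([vars(fracs)]).to_csv(out / "fractions.tsv", sep="\t", index=False)
    volumetrics.volumes_table({"phantom": vols}).to_csv(out / "volumes.tsv", sep="\t")

    lesions = wmh_shape.lesion_shapes(
        seg.mask("wmh"), seg.mask("ventricles"), seg.spacing,
        rule=cfg.lesion_class_rule,
    )
    lesion_df = pd.DataFrame([vars(l) for l in lesions])
    lesion_df.to_csv(out / "lesion_shapes.tsv", sep="\t", index=False)
    summary = wmh_shape.aggregate_patient(lesions)
    summary.to_csv(out / "patient_shape_summary.tsv", sep="\t")
    info = {"n_lesions": len(lesions), "icv_ml": vols.icv}
    _update_manifest(cfg, "phantom", info)
    return info


def stage_simulate(cfg: RunConfig) -> dict:
    """Synthetic cohort, enrollment manifest with exclusions, follow-up."""
    out = _stage_dir(cfg, "simulate")
    n_excluded = cfg.n_no_mri + cfg.n_missing_sequences + cfg.n_artefacts
    manifest = pd.DataFrame({
        "patient_id": [f"E{i:04d}" for i in range(1, cfg.n_patients + n_excluded + 1)],
        "no_mri": [True] * cfg.n_no_mri + [False] * (cfg.n_patients + n_excluded - cfg.n_no_mri),
        "missing_sequence": [False] * cfg.n_no_mri + [True] * cfg.n_missing_sequences
        + [False] * (cfg.n_patients + cfg.n_artefacts),
        "artefact": [False] * (cfg.n_no_mri + cfg.n_missing_sequences)
        + [True] * cfg.n_artefacts + [False] * cfg.n_patients,
    })
    report = volumetrics.apply_exclusions(manifest)
    manifest.to_csv(out / "enrollment_manifest.tsv", sep="\t", index=False)
    (out / "exclusion_report.json").write_text(json.dumps({
        "n_enrolled": report.n_enrolled, "n_no_mri": report.n_no_mri,
        "n_missing_sequences": report.n_missing_sequences,
        "n_artefacts": report.n_artefacts, "n_included": report.n_included,
    }, indent=2))
    if report.n_included != cfg.n_patients:
        raise RuntimeError("exclusion accounting does not match the cohort size")

    spec = CohortSpec(
        n_patients=cfg.n_patients, n_clusters=cfg.n_clusters,
        min_separation=cfg.min_separation, seed=cfg.seed,
    )
    features, meta, _labels = simulate_cohort(spec)
    features.to_csv(out / "features.tsv", sep="\t")
    meta.to_csv(out / "meta.tsv", sep="\t")

    hspec = HazardSpec(
        subgroup_log_hr=subgroup_style_log_hr(cfg.n_clusters), seed=cfg.seed + 1
    )
    followup = simulate_followup(meta, hspec)
    followup.to_csv(out / "followup.tsv", sep="\t", index=False)
    info = {"n_included": report.n_included, "n_enrolled": report.n_enrolled,
            "n_features": features.shape[1]}
    _update_manifest(cfg, "simulate", info)
    return info


def stage_features(cfg: RunConfig) -> dict:
    """Impute the simulated feature table (already in normalized space).

    The cohort generator draws features directly in normalized units
    (centroids in SD units), so this stage records an identity scaling
    and only fills missing entries; ``normalize_features`` is applied to
    raw feature tables such as the phantom-derived ones.
    """
    sim = Path(cfg.out_dir) / "simulate"
    table = pd.read_csv(sim / "features.tsv", sep="\t", index_col="patient_id")
    matrix = feature_matrix.as_normalized(table)
    imputed = feature_matrix.impute_missing(matrix)
    out = _stage_dir(cfg, "features")
    imputed.data.to_csv(out / "normalized.tsv", sep="\t")
    (out / "scaling.json").write_text(json.dumps(
        {"scaling": imputed.scaling, "imputation": imputed.imputation}, indent=2
    ))
    info = {"n_rows": len(imputed.data), "n_imputed": sum(imputed.imputation.values()),
            "columns": list(imputed.data.columns)}
    _update_manifest(cfg, "features", info)
    return info


def stage_cluster(cfg: RunConfig) -> dict:
    """Ward tree, cut selection, age-ordered subgroups, rendered outputs."""
    matrix = pd.read_csv(
        Path(cfg.out_dir) / "features" / "normalized.tsv", sep="\t",
        index_col="patient_id",
    )
    meta = pd.read_csv(
        Path(cfg.out_dir) / "simulate" / "meta.tsv", sep="\t", index_col="patient_id"
    )
    tree = clustering.ward_linkage(matrix)
    k, metrics = clustering.select_k(tree, matrix, cfg.k_range, force_k=cfg.force_k)
    labels = clustering.cut_tree(tree, k)
    assignment = clustering.renumber_by_age(labels, meta["age"], index=matrix.index)

    out = _stage_dir(cfg, "cluster")
    metrics.to_csv(out / "cut_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(tree.linkage, columns=["child_a", "child_b", "height", "size"]).to_csv(
        out / "linkage.tsv", sep="\t", index=False
    )
    assignment.labels.rename("subgroup").to_csv(out / "assignment.tsv", sep="\t")
    clustering.render_outputs(tree, assignment, matrix, out)
    sizes = assignment.labels.value_counts().sort_index()
    info = {"chosen_k": int(k), "sizes": sizes.to_dict(),
            "mean_ages": assignment.mean_ages}
    _update_manifest(cfg, "cluster", info)
    return info


def stage_compare(cfg: RunConfig) -> dict:
    """Between-subgroup comparison of raw features (ANCOVA/multinomial)."""
    sim = Path(cfg.out_dir) / "simulate"
    table = pd.read_csv(sim / "features.tsv", sep="\t", index_col="patient_id")
    meta = pd.read_csv(sim / "meta.tsv", sep="\t", index_col="patient_id")
    assignment = pd.read_csv(
        Path(cfg.out_dir) / "cluster" / "assignment.tsv", sep="\t",
        index_col="patient_id",
    )["subgroup"]
    covariates = meta[list(cfg.covariates)]
    discrete = tuple(c for c in table.columns if c.startswith("cortical_infarct_"))
    ref = min(assignment.unique())
    results = subgroup_stats.compare_table(
        table, assignment, covariates, discrete=discrete, reference=ref
    )
    out = _stage_dir(cfg, "compare")
    results.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    info = {"n_variables": len(results),
            "n_significant": int((results["p_value"] < 0.05).sum())}
    _update_manifest(cfg, "compare", info)
    return info


def stage_survival(cfg: RunConfig) -> dict:
    """Code outcomes and estimate subgroup hazard ratios vs the reference."""
    followup = pd.read_csv(
        Path(cfg.out_dir) / "simulate" / "followup.tsv", sep="\t"
    )
    assignment = pd.read_csv(
        Path(cfg.out_dir) / "cluster" / "assignment.tsv", sep="\t",
        index_col="patient_id",
    )["subgroup"]
    followup = followup.set_index("patient_id")
    followup["subgroup"] = assignment.reindex(followup.index)
    followup = followup.reset_index()
    followup["cause_of_death"] = followup["cause_of_death"].fillna("")
    records = survival.code_events(followup)

    reference = cfg.resolved_reference()
    present = set(followup["subgroup"].unique())
    reference = tuple(g for g in reference if g in present) or (min(present),)

    estimates = []
    for outcome in OUTCOMES:
        rec = records[records["outcome"] == outcome].reset_index(drop=True)
        design = survival.build_reference(rec["subgroup"], reference)
        estimates.extend(
            survival.fit_cox(rec, design, covariates=cfg.covariates,
                             ties=cfg.tie_handling)
        )
    out = _stage_dir(cfg, "survival")
    records.to_csv(out / "records.tsv", sep="\t", index=False)
    table = survival.forest_plot(estimates, out / "forest.png")
    table.to_csv(out / "estimates.tsv", sep="\t", index=False)
    summary = survival.summarize_outcomes(records)
    (out / "outcome_summary.json").write_text(json.dumps(summary, indent=2))
    info = {"reference": list(reference), **summary}
    _update_manifest(cfg, "survival", info)
    return info


_STAGE_FUNCS = {
    "phantom": stage_phantom,
    "simulate": stage_simulate,
    "features": stage_features,
    "cluster": stage_cluster,
    "compare": stage_compare,
    "survival": stage_survival,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages (all of them by default) in order."""
    if stages is None:
        stages = tuple(s for s in STAGES if s != "phantom" or cfg.phantom_demo)
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    results = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        try:
            results[stage] = _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return results
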