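"""Stage orchestration: detect -> morphometry -> metrics -> statistics.

Each stage is a pure function over the library modules; the CLI wraps
these. Every output directory gets a provenance sidecar (criteria, seed,
input description) so that reruns with equal provenance are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, morphometry, stats as cstats
from .core import (
    IntensityVolume,
    VoxelMask,
    WORKING_SPACING_MM,
    condition_wm_mask,
    reslice_isotropic,
    reslice_mask,
)
from .detection import CandidateCriteria
from .phantom import CONTROL_SESSIONS, PRE_SESSIONS, simulate_image_cohort


def detect_session(
    vol: IntensityVolume,
    brain: VoxelMask,
    wm: VoxelMask,
    crit: CandidateCriteria | None = None,
    target_mm: float = WORKING_SPACING_MM,
    reslice: bool = True,
):
    """Full single-session detection.

    Reslices to the working grid, conditions the WM mask, applies the
    candidate criteria, clusters, computes shape descriptors and the
    morphological constraint filter. Returns (records, label map,
    candidate map, conditioned WM mask).
    """
    crit = crit or CandidateCriteria()
    if reslice:
        vol = reslice_isotropic(vol, target_mm, mode="linear")
        brain = reslice_mask(brain, target_mm)
        wm = reslice_mask(wm, target_mm)
    wm_cond = condition_wm_mask(wm)
    cand = detection.detect_candidates(vol, wm_cond, brain, crit)
    clusters = detection.cluster_candidates(cand, crit)
    voxel_lists = detection.cluster_voxel_lists(clusters)
    records = morphometry.describe_clusters(voxel_lists, vol.spacing)
    records = morphometry.apply_morphological_constraints(records, crit)
    return records, clusters, cand, wm_cond


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": r.cluster_id,
            "n_voxels": r.n_voxels,
            "volume_mm3": r.volume_mm3,
            "length_mm": r.length_mm,
            "width_mm": r.width_mm,
            "linearity": r.linearity,
            "centroid_x_mm": r.centroid_mm[0],
            "centroid_y_mm": r.centroid_mm[1],
            "centroid_z_mm": r.centroid_mm[2],
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "n_voxels",
            "volume_mm3",
            "length_mm",
            "width_mm",
            "linearity",
            "centroid_x_mm",
            "centroid_y_mm",
            "centroid_z_mm",
        ],
    )


def image_cohort_metrics(
    n_subjects: int = 6,
    sessions: int = 2,
    seed: int = 0,
    crit: CandidateCriteria | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Simulate an image-level cohort and run detection on every session.

    Returns one row per subject-session with the five PVS outcomes; the
    phantoms carry no ventricles, so ventricular fields are absent.
    """
    bundle = simulate_image_cohort(
        n_subjects=n_subjects, sessions=sessions, seed=seed, **sim_kwargs
    )
    rows = []
    for item in bundle:
        records, _, _, wm_cond = detect_session(
            item["volume"], item["brain"], item["wm"], crit, reslice=False
        )
        voxvol = item["volume"].voxel_volume_mm3
        m = morphometry.session_metrics(
            records,
            wm_volume_cm3=wm_cond.data.sum() * voxvol / 1000.0,
            subject_id=item["subject_id"],
            session=item["session"],
        )
        rows.append(m)
    return morphometry.metrics_to_frame(rows)


def stats_report(
    table: pd.DataFrame,
    metrics,
    covariates=cstats.DEFAULT_COVARIATES,
    control_sessions=CONTROL_SESSIONS,
) -> dict:
    """Reliability gate, change models per retained metric, and contrasts.

    Gated metrics never reach a model; they appear only in the exclusion
    list of the returned report dict.
    """
    rel_report, retained, excluded = cstats.reliability_gate(
        table, metrics, astronaut_sessions=PRE_SESSIONS,
        control_sessions=control_sessions,
    )
    report: dict = {
        "reliability": rel_report,
        "retained_metrics": retained,
        "excluded_metrics": excluded,
        "change_models": {},
        "intercept_models": {},
        "exclusion_log": {},
    }
    for m in retained:
        delta, log = cstats.prepost_delta(table, m)
        report["exclusion_log"][m] = log
        if len(delta) < 3:
            continue
        report["intercept_models"][m] = cstats.fit_change_model(
            delta, outcome="delta", predictors=(), name=m
        )
        report["change_models"][m] = cstats.stepwise_aic(
            delta, outcome="delta", predictors=list(covariates), name=m
        )
    try:
        report["demographics"] = cstats.group_contrasts(
            table[table["cohort"] == "astronaut"]
        )
    except (ValueError, KeyError):
        report["demographics"] = []
    return report


def change_models_frame(report: dict) -> pd.DataFrame:
    """Flatten stepwise change models into one coefficient table."""
    rows = []
    for m, res in report["change_models"].items():
        for term, row in res.coef_table.iterrows():
            rows.append(
                {
                    "outcome": m,
                    "term": term,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "t": row["t"],
                    "p": row["p"],
                    "r2": res.r2,
                    "r2_adj": res.r2_adj,
                    "shapiro_p": res.shapiro_p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def provenance(config: dict) -> dict:
    """Stable provenance record: sorted-key JSON hash of the config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "pvskit_version": "0.1.0",
    }


def write_provenance(path: Path, config: dict) -> None:
    Path(path).write_text(
        json.dumps(provenance(config), sort_keys=True, indent=1, default=str)
        + "\n"
    )


def criteria_dict(crit: CandidateCriteria) -> dict:
    return dataclasses.asdict(crit)


def run_all(outdir: Path, seed: int = 0, n_subjects: int = 4, sessions: int = 2,
            crit: CandidateCriteria | None = None) -> dict[str, Path]:
    """End-to-end simulated run: image cohort -> detection -> metrics table.

    Deterministic for a fixed seed and config: every float is written with
    repr-precision via pandas so reruns are byte-identical.
    """
    crit = crit or CandidateCriteria()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = image_cohort_metrics(
        n_subjects=n_subjects, sessions=sessions, seed=seed, crit=crit
    )
    metrics_path = outdir / "session_metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t", index=False)
    icc_rows = []
    for m in ["total_pvs_volume_mL", "total_pvs_number"]:
        wide = metrics.pivot_table(
            index="subject_id", columns="session", values=m, aggfunc="first"
        )
        try:
            r = cstats.icc3k(wide, m)
            icc_rows.append({"metric": m, "icc3k": r.icc3k, "n": r.n, "k": r.k})
        except ValueError:
            icc_rows.append({"metric": m, "icc3k": np.nan, "n": len(wide), "k": wide.shape[1]})
    icc_path = outdir / "reliability.tsv"
    pd.DataFrame(icc_rows).to_csv(icc_path, sep="\t", index=False)
    write_provenance(
        outdir / "provenance.json",
        {"seed": seed, "n_subjects": n_subjects, "sessions": sessions,
         "criteria": criteria_dict(crit), "stage": "run_all"},
    )
    return {"metrics": metrics_path, "reliability": icc_path,
            "provenance": outdir / "provenance.json"}
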