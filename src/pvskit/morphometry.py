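"""Cluster shape descriptors, morphological constraints and session metrics.

Each candidate cluster is summarized by four descriptors: total volume
(voxel count times voxel volume), length and width (extent of voxel-center
projections onto the first and second principal axes of the coordinate
covariance, plus one voxel edge so a single voxel has physical size), and
linearity (the leading covariance eigenvalue over the eigenvalue sum; 1 for
a perfect line, 1/3 for an isotropic blob). Clusters that are narrower than
16.41 mm and at least 0.8 linear are kept as putative PVS.

The per-session outcomes are the five PVS metrics — total PVS volume (mL),
total PVS number, and the median per-PVS volume, length and width — plus
ventricular volume, with head-size normalization of the totals by the
subject's average pre-flight white-matter volume and of ventricular volume
by average baseline total intracranial volume. Medians are deliberately not
normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Alternative linearity definition (1 - lambda2/lambda1) selectable in
#: :func:`shape_descriptors`.
LINEARITY_MODES = ("eigen_fraction", "axis_ratio")


@dataclass
class ClusterRecord:
    """Shape summary of one putative perivascular space."""

    cluster_id: int
    n_voxels: int
    volume_mm3: float
    length_mm: float
    width_mm: float
    linearity: float
    centroid_mm: tuple[float, float, float]
    principal_axis: tuple[float, float, float]


def shape_descriptors(
    voxels: np.ndarray,
    spacing,
    cluster_id: int = 0,
    linearity_mode: str = "eigen_fraction",
) -> ClusterRecord:
    """Compute volume, length, width and linearity for one voxel cluster.

    Parameters
    ----------
    voxels : (n, 3) integer array
        Voxel indices of the cluster members.
    spacing : per-axis voxel size, mm
    linearity_mode : {"eigen_fraction", "axis_ratio"}
        ``eigen_fraction`` is lambda1/(lambda1+lambda2+lambda3);
        ``axis_ratio`` is 1 - lambda2/lambda1.

    A single voxel is defined to have linearity 1 and length = width = one
    voxel edge.
    """
    if linearity_mode not in LINEARITY_MODES:
        raise ValueError(f"unknown linearity_mode {linearity_mode!r}")
    voxels = np.atleast_2d(np.asarray(voxels))
    if voxels.shape[0] < 1:
        raise ValueError("cluster must contain at least one voxel")
    sp = np.asarray(spacing, dtype=np.float64)
    edge = float(sp.min())
    coords = voxels * sp  # voxel-center physical coordinates
    centroid = coords.mean(axis=0)
    n = len(voxels)
    volume = n * float(np.prod(sp))

    if n == 1:
        return ClusterRecord(
            cluster_id=cluster_id,
            n_voxels=1,
            volume_mm3=volume,
            length_mm=edge,
            width_mm=edge,
            linearity=1.0,
            centroid_mm=tuple(centroid),
            principal_axis=(1.0, 0.0, 0.0),
        )

    centered = coords - centroid
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    total = evals.sum()
    if total <= 0:  # duplicate coordinates; treat as a point
        lin = 1.0
    elif linearity_mode == "eigen_fraction":
        lin = float(evals[0] / total)
    else:
        lin = 1.0 - float(evals[1] / evals[0]) if evals[0] > 0 else 1.0

    proj1 = centered @ evecs[:, 0]
    proj2 = centered @ evecs[:, 1]
    length = float(proj1.max() - proj1.min()) + edge
    width = float(proj2.max() - proj2.min()) + edge
    if width > length:  # guard against eigenvector degeneracy at ties
        length, width = width, length
    return ClusterRecord(
        cluster_id=cluster_id,
        n_voxels=n,
        volume_mm3=volume,
        length_mm=length,
        width_mm=width,
        linearity=lin,
        centroid_mm=tuple(centroid),
        principal_axis=tuple(evecs[:, 0]),
    )


def describe_clusters(voxel_lists, spacing, linearity_mode="eigen_fraction"):
    """Shape descriptors for a list of clusters, labeled 1..n in order."""
    return [
        shape_descriptors(v, spacing, cluster_id=i + 1, linearity_mode=linearity_mode)
        for i, v in enumerate(voxel_lists)
    ]


def apply_morphological_constraints(records, crit) -> list[ClusterRecord]:
    """Keep clusters with width < max_width_mm and linearity >= min_linearity.

    The width bound is strict, the linearity bound inclusive; input order is
    preserved.
    """
    return [
        r
        for r in records
        if r.width_mm < crit.max_width_mm and r.linearity >= crit.min_linearity
    ]


@dataclass
class SubjectSessionMetrics:
    """The five PVS outcomes plus volumetric denominators for one session.

    Medians are NaN when no PVS was detected; normalized fields are NaN
    until :func:`normalize_metrics` is applied.
    """

    subject_id: str = ""
    session: str = ""
    total_pvs_volume_mL: float = 0.0
    total_pvs_number: int = 0
    median_pvs_volume_mm3: float = math.nan
    median_pvs_length_mm: float = math.nan
    median_pvs_width_mm: float = math.nan
    wm_volume_cm3: float = math.nan
    ventricular_volume_mL: float = math.nan
    tiv_mL: float = math.nan
    norm_total_pvs_volume: float = math.nan
    norm_total_pvs_number: float = math.nan
    norm_ventricular_volume: float = math.nan


METRIC_COLUMNS = [
    "total_pvs_volume_mL",
    "total_pvs_number",
    "median_pvs_volume_mm3",
    "median_pvs_length_mm",
    "median_pvs_width_mm",
    "wm_volume_cm3",
    "ventricular_volume_mL",
    "tiv_mL",
    "norm_total_pvs_volume",
    "norm_total_pvs_number",
    "norm_ventricular_volume",
]


def session_metrics(
    records,
    wm_volume_cm3=math.nan,
    ventricular_volume_mL=math.nan,
    tiv_mL=math.nan,
    subject_id: str = "",
    session: str = "",
) -> SubjectSessionMetrics:
    """Aggregate post-filter cluster records into the per-session outcomes."""
    for name, v in (
        ("wm_volume_cm3", wm_volume_cm3),
        ("ventricular_volume_mL", ventricular_volume_mL),
        ("tiv_mL", tiv_mL),
    ):
        if not math.isnan(v) and v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    m = SubjectSessionMetrics(
        subject_id=subject_id,
        session=session,
        wm_volume_cm3=float(wm_volume_cm3),
        ventricular_volume_mL=float(ventricular_volume_mL),
        tiv_mL=float(tiv_mL),
    )
    m.total_pvs_number = len(records)
    m.total_pvs_volume_mL = sum(r.volume_mm3 for r in records) / 1000.0
    if records:
        m.median_pvs_volume_mm3 = float(np.median([r.volume_mm3 for r in records]))
        m.median_pvs_length_mm = float(np.median([r.length_mm for r in records]))
        m.median_pvs_width_mm = float(np.median([r.width_mm for r in records]))
    return m


def normalize_metrics(
    m: SubjectSessionMetrics, baseline_wm_cm3: float, baseline_tiv_mL: float
) -> SubjectSessionMetrics:
    """Head-size normalization of the totals; medians pass through unchanged.

    Total PVS volume (mm^3) and number are divided by the average pre-flight
    white-matter volume (cm^3); ventricular volume by the average baseline
    total intracranial volume.
    """
    if baseline_wm_cm3 <= 0 or baseline_tiv_mL <= 0:
        raise ValueError("normalization denominators must be positive")
    return replace(
        m,
        norm_total_pvs_volume=m.total_pvs_volume_mL * 1000.0 / baseline_wm_cm3,
        norm_total_pvs_number=m.total_pvs_number / baseline_wm_cm3,
        norm_ventricular_volume=m.ventricular_volume_mL / baseline_tiv_mL,
    )


def metrics_to_frame(metrics: list[SubjectSessionMetrics]) -> pd.DataFrame:
    """One row per subject-session, columns in the canonical order."""
    rows = [
        {"subject_id": m.subject_id, "session": m.session}
        | {c: getattr(m, c) for c in METRIC_COLUMNS}
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=["subject_id", "session"] + METRIC_COLUMNS)
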