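"""Synthetic 3D phantoms and longitudinal cohort tables with known truth.

No public MRI accession exists for the cohort this package models, so every
downstream stage is exercised against two generators:

* **Digital phantoms** — a white-matter box of uniform intensity with
  implanted tubular hypointensities (known centerline, radius and contrast),
  optional isotropic blob distractors and sub-threshold faint tubules, plus
  additive Gaussian noise. Ground truth enables recall/precision scoring of
  the detector and per-tubule morphometry error.

* **Cohort tables** — subject-level longitudinal metric tables with the
  statistical structure the analysis assumes: a latent per-subject baseline
  for each metric, group-specific pre-to-post-flight shifts applied to the
  post-return sessions, and independent session-level measurement noise.
  Controls carry no session effects, so the control table measures pure
  test-retest reliability.

The cohort simulator's defaults mirror the study design: 9 novice and
6 experienced astronauts scanned at L-180, L-60, R+4, R+30, R+90 and R+180,
and 11 controls scanned four times. Implanted tubules keep an aspect ratio
of at least 6:1, the elongation regime of MRI-visible white-matter PVS
(an isotropic blob is by definition not a PVS, and the morphological filter
would reject it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntensityVolume, VoxelMask
from .morphometry import ClusterRecord


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass
class TubuleSpec:
    """A straight tubular hypointensity with physical endpoints (mm)."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    contrast_frac: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not (0 < self.contrast_frac < 1):
            raise ValueError("contrast_frac must lie in (0, 1)")
        if self.length_mm <= 0:
            raise ValueError("tubule segment must have positive length")

    @property
    def length_mm(self) -> float:
        return float(
            np.linalg.norm(np.subtract(self.end_mm, self.start_mm))
        )


@dataclass
class BlobSpec:
    """An isotropic spherical distractor (linearity ~ 1/3)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    contrast_frac: float


@dataclass
class PhantomGroundTruth:
    """Everything needed to render a phantom and score detections."""

    tubules: list[TubuleSpec]
    distractors: list[BlobSpec] = field(default_factory=list)
    shape: tuple[int, int, int] = (56, 56, 56)
    wm_margin_vox: int = 4
    brain_margin_vox: int = 1
    wm_intensity: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0


def _point_segment_distance(points, a, b):
    """Distance from each point (n,3) to segment a-b (all mm)."""
    a = np.asarray(a, dtype=np.float64)
    ab = np.asarray(b, dtype=np.float64) - a
    denom = float(ab @ ab)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = a + np.outer(np.atleast_1d(t), ab)
    return np.linalg.norm(points - closest, axis=1)


def _box_mask(shape, margin):
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, n - margin) for n in shape)
    m[sl] = True
    return m


def render_phantom(
    gt: PhantomGroundTruth, spacing=(0.5, 0.5, 0.5)
) -> tuple[IntensityVolume, VoxelMask, VoxelMask]:
    """Rasterize a phantom: returns (intensity volume, brain mask, WM mask).

    WM voxels take ``wm_intensity``; a voxel belongs to a structure when its
    center is within the structure radius of the centerline (tubules,
    point-to-segment distance) or center (blobs), and its intensity is
    scaled by ``1 - contrast_frac``. Gaussian noise with sd ``noise_sd`` is
    added inside the brain mask. Identical seeds give identical volumes.
    """
    sp = np.asarray(spacing, dtype=np.float64)
    shape = gt.shape
    wm = _box_mask(shape, gt.wm_margin_vox)
    brain = _box_mask(shape, gt.brain_margin_vox)

    vol = np.where(brain, gt.wm_intensity, 0.0)

    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    coords = grid * sp  # voxel centers, mm

    def _paint(inside_flat, contrast, what):
        inside = inside_flat.reshape(shape)
        outside_wm = inside & ~wm
        if outside_wm.any():
            raise ValueError(f"{what} extends outside the white-matter mask")
        vol[inside] = gt.wm_intensity * (1.0 - contrast)

    for i, t in enumerate(gt.tubules):
        d = _point_segment_distance(coords, t.start_mm, t.end_mm)
        _paint(d <= t.radius_mm, t.contrast_frac, f"tubule {i}")
    for i, b in enumerate(gt.distractors):
        d = np.linalg.norm(coords - np.asarray(b.center_mm), axis=1)
        _paint(d <= b.radius_mm, b.contrast_frac, f"distractor {i}")

    if gt.noise_sd > 0:
        rng = np.random.default_rng(gt.seed)
        vol = vol + np.where(brain, rng.normal(0, gt.noise_sd, shape), 0.0)

    spacing_t = tuple(float(s) for s in sp)
    return (
        IntensityVolume(data=vol, spacing=spacing_t, origin_note=f"phantom seed={gt.seed}"),
        VoxelMask(data=brain.astype(np.uint8), spacing=spacing_t),
        VoxelMask(data=wm.astype(np.uint8), spacing=spacing_t),
    )


def random_phantom(
    seed: int,
    n_tubules: int | None = None,
    mean_tubules: float = 6.0,
    contrast_range=(0.25, 0.4),
    radius_range_mm=(0.5, 1.0),
    length_range_mm=(3.0, 10.0),
    min_aspect: float = 6.0,
    n_distractors: int = 0,
    n_faint: int = 0,
    faint_contrast: float = 0.10,
    shape=(56, 56, 56),
    spacing_mm: float = 0.5,
    noise_sd: float = 2.0,
    min_separation_mm: float = 4.0,
) -> PhantomGroundTruth:
    """Draw a phantom with randomly placed, well-separated structures.

    Tubule count is Poisson(``mean_tubules``) unless ``n_tubules`` is given;
    radius ~ U(radius_range) and length ~ U(max(length_min, min_aspect *
    radius), length_max), so implanted tubules are genuinely elongated.
    Structures keep a 2.5 mm margin inside the WM box and at least
    ``min_separation_mm`` between centerlines so detections are unambiguous.
    """
    rng = np.random.default_rng(seed)
    if n_tubules is None:
        n_tubules = int(rng.poisson(mean_tubules))
    wm_margin = 4
    inner_margin_mm = wm_margin * spacing_mm + 2.5
    lo = inner_margin_mm
    hi = [n * spacing_mm - inner_margin_mm for n in shape]

    tubules: list[TubuleSpec] = []
    segments: list[tuple[np.ndarray, np.ndarray]] = []

    def _far_enough(a, b):
        pts = a + np.linspace(0, 1, 12)[:, None] * (b - a)
        for sa, sb in segments:
            if _point_segment_distance(pts, sa, sb).min() < min_separation_mm:
                return False
        return True

    def _place(length, max_tries=200):
        for _ in range(max_tries):
            start = rng.uniform(lo, hi)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            end = start + direction * length
            if np.all(end >= lo) and np.all(end <= hi) and _far_enough(start, end):
                return start, end
        return None

    for _ in range(n_tubules):
        r = rng.uniform(*radius_range_mm)
        lmin = max(length_range_mm[0], min_aspect * r)
        length = rng.uniform(lmin, max(length_range_mm[1], lmin + 0.5))
        placed = _place(length)
        if placed is None:
            continue
        start, end = placed
        tubules.append(
            TubuleSpec(
                start_mm=tuple(start),
                end_mm=tuple(end),
                radius_mm=float(r),
                contrast_frac=float(rng.uniform(*contrast_range)),
            )
        )
        segments.append((start, end))

    for _ in range(n_faint):
        r = rng.uniform(*radius_range_mm)
        length = rng.uniform(max(3.0, min_aspect * r), 10.0)
        placed = _place(length)
        if placed is None:
            continue
        start, end = placed
        tubules.append(
            TubuleSpec(
                start_mm=tuple(start),
                end_mm=tuple(end),
                radius_mm=float(r),
                contrast_frac=float(faint_contrast),
            )
        )
        segments.append((start, end))

    distractors: list[BlobSpec] = []
    for _ in range(n_distractors):
        r = rng.uniform(1.5, 2.0)
        placed = _place(0.5)  # treat as a tiny segment for separation checks
        if placed is None:
            continue
        start, end = placed
        center = (start + end) / 2
        distractors.append(
            BlobSpec(
                center_mm=tuple(center),
                radius_mm=float(r),
                contrast_frac=float(rng.uniform(*contrast_range)),
            )
        )
        segments.append((start, end))

    return PhantomGroundTruth(
        tubules=tubules,
        distractors=distractors,
        shape=shape,
        wm_margin_vox=wm_margin,
        noise_sd=noise_sd,
        seed=seed,
    )


# --------------------------------------------------------------------------
# ground-truth scoring
# --------------------------------------------------------------------------

@dataclass
class DetectionScore:
    """Recall/precision of detected clusters against implanted tubules."""

    n_true: int
    n_detected: int
    n_matched_true: int
    n_matched_detected: int
    recall: float
    precision: float
    length_errors_mm: list[float]
    width_errors_mm: list[float]


def score_detection(
    gt: PhantomGroundTruth,
    detected: list[ClusterRecord],
    match_tolerance_mm: float = 1.0,
    detectable_contrast: float = 0.15,
) -> DetectionScore:
    """Match detected clusters to implanted tubules by centroid distance.

    A cluster matches a tubule when its centroid lies within
    ``match_tolerance_mm`` of the tubule's centerline segment. Only tubules
    with contrast above ``detectable_contrast`` count as ground-truth
    positives (faint tubules are implanted negatives). Per-match absolute
    length and width errors compare detected descriptors against the
    segment length and diameter.
    """
    true_tubules = [t for t in gt.tubules if t.contrast_frac > detectable_contrast]
    matched_true = np.zeros(len(true_tubules), dtype=bool)
    matched_det = np.zeros(len(detected), dtype=bool)
    length_err, width_err = [], []
    for j, rec in enumerate(detected):
        c = np.asarray(rec.centroid_mm)[None, :]
        for i, t in enumerate(true_tubules):
            d = _point_segment_distance(c, t.start_mm, t.end_mm)[0]
            if d <= match_tolerance_mm:
                matched_det[j] = True
                if not matched_true[i]:
                    matched_true[i] = True
                    length_err.append(abs(rec.length_mm - t.length_mm))
                    width_err.append(abs(rec.width_mm - 2 * t.radius_mm))
    n_true = len(true_tubules)
    n_det = len(detected)
    return DetectionScore(
        n_true=n_true,
        n_detected=n_det,
        n_matched_true=int(matched_true.sum()),
        n_matched_detected=int(matched_det.sum()),
        recall=float(matched_true.sum() / n_true) if n_true else float("nan"),
        precision=float(matched_det.sum() / n_det) if n_det else float("nan"),
        length_errors_mm=length_err,
        width_errors_mm=width_err,
    )


def count_correlation(true_counts, detected_counts):
    """Pearson r between true and detected PVS counts over a phantom batch."""
    r, p = stats.pearsonr(np.asarray(true_counts), np.asarray(detected_counts))
    return float(r), float(p)


# --------------------------------------------------------------------------
# cohort simulation (metric level)
# --------------------------------------------------------------------------

ASTRONAUT_SESSIONS = ["L-180", "L-60", "R+4", "R+30", "R+90", "R+180"]
PRE_SESSIONS = ["L-180", "L-60"]
POST_SESSIONS = ["R+4", "R+30", "R+90", "R+180"]
CONTROL_SESSIONS = ["C1", "C2", "C3", "C4"]

#: Default per-metric (baseline mean, between-subject sd, session noise sd).
#: Baselines are in the units the analysis uses (normalized totals in
#: mm^3 / cm^3 WM and count / cm^3 WM; medians raw; ventricles in mL / mL TIV).
DEFAULT_METRIC_PARAMS: dict[str, tuple[float, float, float]] = {
    "norm_total_pvs_volume": (1.00, 0.35, 0.08),
    "norm_total_pvs_number": (0.10, 0.035, 0.006),
    "median_pvs_volume_mm3": (7.0, 2.0, 2.0),
    "median_pvs_length_mm": (5.0, 0.8, 0.95),
    "median_pvs_width_mm": (2.0, 0.25, 0.38),
    "norm_ventricular_volume": (0.020, 0.005, 0.00005),
}

#: Default pre-to-post shifts per group (added to every post-return session).
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    "novice": {
        "norm_total_pvs_volume": 0.06,
        "norm_total_pvs_number": 0.001,
        "median_pvs_volume_mm3": 0.72,
        "median_pvs_length_mm": -0.01,
        "median_pvs_width_mm": 0.0,
        "norm_ventricular_volume": 0.0008,
    },
    "experienced": {
        "norm_total_pvs_volume": -0.10,
        "norm_total_pvs_number": -0.01,
        "median_pvs_volume_mm3": 0.29,
        "median_pvs_length_mm": 0.19,
        "median_pvs_width_mm": 0.0,
        "norm_ventricular_volume": 0.001,
    },
}


@dataclass
class CohortSimSpec:
    """Design of a simulated longitudinal cohort.

    ``metric_params`` maps metric -> (baseline mean, between-subject sd,
    session noise sd); ``group_effects`` maps group -> metric -> shift added
    to all post-return sessions. Covariate distributions follow the study's
    demographics table (ages in years, durations in days).
    """

    n_novice: int = 9
    n_experienced: int = 6
    n_control: int = 11
    metric_params: dict = field(
        default_factory=lambda: dict(DEFAULT_METRIC_PARAMS)
    )
    group_effects: dict = field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_GROUP_EFFECTS.items()
        }
    )
    n_sans: int = 6
    n_no_sans: int = 6
    n_sans_unknown: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_novice, self.n_experienced, self.n_control) < 0:
            raise ValueError("group sizes must be non-negative")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Generate a longitudinal metric table with known group effects.

    Per subject and metric: latent baseline ~ Normal(mean, between-sd); each
    session observation = baseline + group shift (post-return sessions of
    astronauts only) + Normal(0, session noise). Controls have no session
    effects. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    metrics = list(spec.metric_params)
    rows = []

    n_ast = spec.n_novice + spec.n_experienced
    sans_labels = (
        ["SANS"] * spec.n_sans
        + ["no-SANS"] * spec.n_no_sans
        + ["unknown"] * spec.n_sans_unknown
    )
    if len(sans_labels) < n_ast:
        sans_labels += ["unknown"] * (n_ast - len(sans_labels))
    sans_labels = list(rng.permutation(sans_labels[:n_ast]))

    subj_idx = 0
    for group, n in (("novice", spec.n_novice), ("experienced", spec.n_experienced)):
        for _ in range(n):
            sid = f"AST{subj_idx + 1:02d}"
            if group == "novice":
                age = rng.normal(43.98, 4.90)
                duration = rng.normal(166.78, 31.37)
                days_to_scan = max(1.0, rng.normal(4.83, 0.41))
                prior_days, prior_missions = 0.0, 0
            else:
                age = rng.normal(52.67, 4.18)
                duration = rng.normal(226.50, 71.21)
                days_to_scan = max(1.0, rng.normal(4.33, 1.41))
                prior_days = max(10.0, rng.normal(187.5, 151.67))
                prior_missions = max(1, int(rng.poisson(2.0)))
            sex = "F" if rng.random() < 0.27 else "M"
            baselines = {
                m: rng.normal(mu, sb)
                for m, (mu, sb, _) in spec.metric_params.items()
            }
            for session in ASTRONAUT_SESSIONS:
                row = {
                    "subject_id": sid,
                    "cohort": "astronaut",
                    "group": group,
                    "sans": sans_labels[subj_idx],
                    "session": session,
                    "age_at_launch_yr": age,
                    "sex": sex,
                    "mission_duration_d": duration,
                    "days_landing_to_scan_d": days_to_scan,
                    "prior_flight_days_d": prior_days,
                    "prior_missions": prior_missions,
                }
                for m in metrics:
                    _, _, se = spec.metric_params[m]
                    val = baselines[m] + rng.normal(0, se)
                    if session in POST_SESSIONS:
                        val += spec.group_effects.get(group, {}).get(m, 0.0)
                    row[m] = val
                rows.append(row)
            subj_idx += 1

    for i in range(spec.n_control):
        sid = f"CTL{i + 1:02d}"
        age = rng.normal(42.28, 10.60)
        sex = "F" if rng.random() < 0.27 else "M"
        baselines = {
            m: rng.normal(mu, sb) for m, (mu, sb, _) in spec.metric_params.items()
        }
        for session in CONTROL_SESSIONS:
            row = {
                "subject_id": sid,
                "cohort": "control",
                "group": "control",
                "sans": "unknown",
                "session": session,
                "age_at_launch_yr": age,
                "sex": sex,
                "mission_duration_d": np.nan,
                "days_landing_to_scan_d": np.nan,
                "prior_flight_days_d": 0.0,
                "prior_missions": 0,
            }
            for m in metrics:
                _, _, se = spec.metric_params[m]
                row[m] = baselines[m] + rng.normal(0, se)
            rows.append(row)

    return pd.DataFrame(rows)


def simulate_image_cohort(
    n_subjects: int = 6,
    sessions: int = 2,
    seed: int = 0,
    mean_tubules: float = 6.0,
    noise_sd: float = 2.0,
    shape=(56, 56, 56),
):
    """Image-level longitudinal mode: per subject, one fixed phantom geometry
    rendered once per session with fresh noise.

    Yields dicts with subject_id, session, ground truth and the rendered
    (volume, brain, wm) bundle. Small by design: intended for end-to-end
    smoke tests and reliability checks, not statistical power.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        geom_seed = int(rng.integers(0, 2**31 - 1))
        gt0 = random_phantom(
            geom_seed, mean_tubules=mean_tubules, noise_sd=noise_sd, shape=shape
        )
        for s in range(sessions):
            noise_seed = int(rng.integers(0, 2**31 - 1))
            gt = PhantomGroundTruth(
                tubules=gt0.tubules,
                distractors=gt0.distractors,
                shape=gt0.shape,
                wm_margin_vox=gt0.wm_margin_vox,
                brain_margin_vox=gt0.brain_margin_vox,
                wm_intensity=gt0.wm_intensity,
                noise_sd=noise_sd,
                seed=noise_seed,
            )
            vol, brain, wm = render_phantom(gt)
            out.append(
                {
                    "subject_id": f"S{i + 1:02d}",
                    "session": f"T{s + 1}",
                    "ground_truth": gt,
                    "volume": vol,
                    "brain": brain,
                    "wm": wm,
                }
            )
    return out
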