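"""Voxelwise candidate detection and clustering of putative perivascular spaces.

The detector marks a voxel as a PVS candidate when all three criteria hold:

(a) the voxel lies in the conditioned (eroded) white-matter mask;
(b) its intensity deficit relative to the mean of the surrounding voxels in
    a 4 mm sphere exceeds 15 percent;
(c) its intensity falls in the bottom fifth percentile of its neighbors in
    a 3 mm sphere.

Both neighborhoods exclude the center voxel and are restricted to the
skull-stripped brain support; neighborhoods are truncated at the volume
border. Candidate voxels are then grouped under 26-connectivity
(corner-to-corner) and components larger than 1 mm^3 are kept.

Rank ties are counted conservatively: a neighbor equal to the center does
not count as darker, so a voxel in a flat region has rank fraction 0 but is
rejected by the contrast criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .core import IntensityVolume, SphereOffsets, VoxelMask, sphere_offsets
from .morphometry import ClusterRecord


@dataclass
class CandidateCriteria:
    """All detection constants in one place.

    Defaults implement the published criteria on the 0.5 mm working grid:
    3 mm rank sphere, 4 mm contrast sphere, >15% intensity deficit, bottom
    5th percentile rank, >1 mm^3 cluster volume, <16.41 mm width,
    linearity >= 0.8.
    """

    rank_radius_mm: float = 3.0
    contrast_radius_mm: float = 4.0
    contrast_threshold_pct: float = 15.0
    rank_percentile: float = 5.0
    min_cluster_volume_mm3: float = 1.0
    max_width_mm: float = 16.41
    min_linearity: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.min_linearity <= 1):
            raise ValueError("min_linearity must lie in [0, 1]")
        if not (0 < self.rank_percentile < 100):
            raise ValueError("rank_percentile must lie in (0, 100)")
        for name in (
            "rank_radius_mm",
            "contrast_radius_mm",
            "contrast_threshold_pct",
            "min_cluster_volume_mm3",
            "max_width_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidateMap:
    """Candidate mask plus the per-voxel statistics that produced it."""

    mask: VoxelMask
    rank_fraction: np.ndarray = field(repr=False)
    contrast_pct: np.ndarray = field(repr=False)


@dataclass
class ClusterLabelMap:
    """26-connected candidate clusters, labeled 1..n (0 = background)."""

    labels: np.ndarray = field(repr=False)
    n_clusters: int = 0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)


def _shift_slices(shape, d):
    """Slices so that dst[sl_dst] aligns each voxel v with neighbor v + d."""
    sl_dst, sl_src = [], []
    for n, di in zip(shape, d):
        di = int(di)
        sl_dst.append(slice(max(0, -di), n - max(0, di)))
        sl_src.append(slice(max(0, di), n - max(0, -di)))
    return tuple(sl_dst), tuple(sl_src)


def neighborhood_rank_count(
    data: np.ndarray, support: np.ndarray, offs: SphereOffsets
) -> tuple[np.ndarray, np.ndarray]:
    """For every voxel, count neighbors strictly darker, and valid neighbors.

    Neighbors are the sphere offsets (center excluded) intersected with
    ``support`` and the volume bounds.
    """
    less = np.zeros(data.shape, dtype=np.int32)
    count = np.zeros(data.shape, dtype=np.int32)
    sup = support.astype(bool)
    for d in offs.offsets:
        if not d.any():
            continue
        sl_dst, sl_src = _shift_slices(data.shape, d)
        valid = sup[sl_src]
        count[sl_dst] += valid
        less[sl_dst] += valid & (data[sl_src] < data[sl_dst])
    return less, count


def neighborhood_mean(
    data: np.ndarray, support: np.ndarray, offs: SphereOffsets
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mean of neighbor intensities over sphere ∩ support.

    Returns (mean, count); mean is NaN where the neighborhood is empty.
    """
    total = np.zeros(data.shape, dtype=np.float64)
    count = np.zeros(data.shape, dtype=np.int32)
    sup = support.astype(bool)
    for d in offs.offsets:
        if not d.any():
            continue
        sl_dst, sl_src = _shift_slices(data.shape, d)
        valid = sup[sl_src]
        count[sl_dst] += valid
        total[sl_dst] += np.where(valid, data[sl_src], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def local_rank_fraction(
    vol: IntensityVolume,
    support: VoxelMask,
    center: tuple[int, int, int],
    radius_mm: float,
) -> float:
    """Fraction of sphere neighbors strictly darker than the center voxel.

    Returns NaN for an isolated voxel (empty neighborhood); such voxels are
    treated as non-candidates.
    """
    offs = sphere_offsets(radius_mm, vol.spacing)
    c = np.asarray(center)
    nbr = c + offs.offsets
    keep = np.all((nbr >= 0) & (nbr < np.array(vol.shape)), axis=1)
    keep &= np.any(offs.offsets != 0, axis=1)
    nbr = nbr[keep]
    vals = vol.data[tuple(nbr.T)]
    sup = support.data[tuple(nbr.T)]
    vals = vals[sup]
    if vals.size == 0:
        return float("nan")
    return float(np.count_nonzero(vals < vol.data[tuple(c)]) / vals.size)


def local_mean_contrast(
    vol: IntensityVolume,
    support: VoxelMask,
    center: tuple[int, int, int],
    radius_mm: float,
) -> float:
    """Percent intensity deficit of the center vs. its neighborhood mean.

    ``100 * (mean(neighbors) - I(center)) / mean(neighbors)``; positive when
    the center is hypointense. NaN when the neighborhood is empty or its
    mean is non-positive.
    """
    offs = sphere_offsets(radius_mm, vol.spacing)
    c = np.asarray(center)
    nbr = c + offs.offsets
    keep = np.all((nbr >= 0) & (nbr < np.array(vol.shape)), axis=1)
    keep &= np.any(offs.offsets != 0, axis=1)
    nbr = nbr[keep]
    vals = vol.data[tuple(nbr.T)]
    sup = support.data[tuple(nbr.T)]
    vals = vals[sup]
    if vals.size == 0:
        return float("nan")
    m = float(vals.mean())
    if m <= 0:
        return float("nan")
    return 100.0 * (m - float(vol.data[tuple(c)])) / m


def detect_candidates(
    vol: IntensityVolume,
    eroded_wm: VoxelMask,
    brain: VoxelMask,
    crit: CandidateCriteria | None = None,
) -> CandidateMap:
    """Apply candidate criteria (a)-(c) to every voxel of the working grid.

    Local statistics use the skull-stripped brain support; criterion (a)
    then restricts candidates to the conditioned white-matter mask. The
    returned rank and contrast grids are NaN outside the eroded WM mask.
    """
    crit = crit or CandidateCriteria()
    if not (eroded_wm.same_grid(vol) and brain.same_grid(vol)):
        raise ValueError("volume and masks must share grid shape and spacing")
    data = np.asarray(vol.data, dtype=np.float64)
    rank_offs = sphere_offsets(crit.rank_radius_mm, vol.spacing)
    con_offs = sphere_offsets(crit.contrast_radius_mm, vol.spacing)

    less, rcount = neighborhood_rank_count(data, brain.data, rank_offs)
    mean, ccount = neighborhood_mean(data, brain.data, con_offs)

    with np.errstate(invalid="ignore", divide="ignore"):
        rank_frac = np.where(rcount > 0, less / np.maximum(rcount, 1), np.nan)
        contrast = np.where(
            (ccount > 0) & (mean > 0), 100.0 * (mean - data) / mean, np.nan
        )

    wm = eroded_wm.data
    ok_rank = (rcount > 0) & (rank_frac <= crit.rank_percentile / 100.0)
    ok_con = (ccount > 0) & (mean > 0) & (contrast > crit.contrast_threshold_pct)
    cand = wm & ok_rank & ok_con

    rank_frac = np.where(wm, rank_frac, np.nan)
    contrast = np.where(wm, contrast, np.nan)
    return CandidateMap(
        mask=VoxelMask(data=cand.astype(np.uint8), spacing=vol.spacing),
        rank_fraction=rank_frac,
        contrast_pct=contrast,
    )


def cluster_candidates(
    cand: CandidateMap, crit: CandidateCriteria | None = None
) -> ClusterLabelMap:
    """Group candidate voxels (26-connectivity) and drop small components.

    Components must be strictly larger than ``min_cluster_volume_mm3``
    (9+ voxels on the 0.5 mm grid); survivors are relabeled 1..n.
    """
    crit = crit or CandidateCriteria()
    spacing = cand.mask.spacing
    voxel_vol = float(np.prod(spacing))
    labels = measure.label(cand.mask.data, connectivity=3)
    n = labels.max()
    if n == 0:
        return ClusterLabelMap(labels=labels, n_clusters=0, spacing=spacing)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes * voxel_vol > crit.min_cluster_volume_mm3) + 1
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return ClusterLabelMap(
        labels=remap[labels], n_clusters=len(keep), spacing=spacing
    )


def cluster_voxel_lists(clusters: ClusterLabelMap) -> list[np.ndarray]:
    """Voxel index arrays for labels 1..n, each of shape (n_voxels, 3)."""
    out = []
    for lab in range(1, clusters.n_clusters + 1):
        out.append(np.argwhere(clusters.labels == lab))
    return out


REVIEW_COLUMNS = [
    "cluster_id",
    "x",
    "y",
    "z",
    "n_voxels",
    "volume_mm3",
    "length_mm",
    "width_mm",
    "linearity",
    "decision",
]


def export_review_table(records: list[ClusterRecord], path) -> pd.DataFrame:
    """Write a TSV of putative PVS for manual accept/reject review.

    Every row defaults to ``accept``; a rater flips rows to ``reject`` and
    the edited file is re-applied with :func:`import_review_table`.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "cluster_id": r.cluster_id,
                "x": r.centroid_mm[0],
                "y": r.centroid_mm[1],
                "z": r.centroid_mm[2],
                "n_voxels": r.n_voxels,
                "volume_mm3": r.volume_mm3,
                "length_mm": r.length_mm,
                "width_mm": r.width_mm,
                "linearity": r.linearity,
                "decision": "accept",
            }
        )
    df = pd.DataFrame(rows, columns=REVIEW_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def import_review_table(records: list[ClusterRecord], path) -> list[ClusterRecord]:
    """Apply rater decisions: drop records whose row is marked ``reject``."""
    df = pd.read_csv(path, sep="\t")
    known = {r.cluster_id for r in records}
    unknown = set(df["cluster_id"]) - known
    if unknown:
        raise ValueError(f"review file references unknown labels {sorted(unknown)}")
    rejected = set(
        df.loc[df["decision"].str.strip().str.lower() == "reject", "cluster_id"]
    )
    return [r for r in records if r.cluster_id not in rejected]
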