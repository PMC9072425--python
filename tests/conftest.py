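"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive everything from first principles
(triple-loop sphere enumeration, per-voxel neighborhood gathering, explicit
sums of squares) so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pvskit import CandidateCriteria, random_phantom, render_phantom


def enumerate_sphere_offsets(radius_mm, spacing):
    """Triple-loop enumeration of integer offsets within a physical radius."""
    sx, sy, sz = spacing
    rx = int(math.floor(radius_mm / sx))
    ry = int(math.floor(radius_mm / sy))
    rz = int(math.floor(radius_mm / sz))
    out = []
    for dx in range(-rx, rx + 1):
        for dy in range(-ry, ry + 1):
            for dz in range(-rz, rz + 1):
                d2 = (dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2
                if d2 <= radius_mm**2 + 1e-12:
                    out.append((dx, dy, dz))
    return np.array(sorted(out), dtype=np.int64).reshape(-1, 3)


def brute_force_candidate_mask(data, wm, brain, spacing, crit=None):
    """Per-voxel evaluation of candidate criteria (a)-(c).

    Pads the volume so every sphere lookup is in bounds (padding carries
    brain=False, so truncation at the original border is preserved), then
    visits each WM voxel and gathers its two neighborhoods explicitly.
    """
    crit = crit or CandidateCriteria()
    pad = int(
        math.ceil(
            max(crit.rank_radius_mm, crit.contrast_radius_mm) / min(spacing)
        )
    )
    dp = np.pad(data.astype(np.float64), pad)
    bp = np.pad(brain.astype(bool), pad)
    shape_p = dp.shape
    strides = np.array(
        [shape_p[1] * shape_p[2], shape_p[2], 1], dtype=np.int64
    )
    df, bf = dp.ravel(), bp.ravel()

    def flat(offs):
        offs = offs[np.any(offs != 0, axis=1)]  # exclude center
        return offs @ strides

    f_rank = flat(enumerate_sphere_offsets(crit.rank_radius_mm, spacing))
    f_con = flat(enumerate_sphere_offsets(crit.contrast_radius_mm, spacing))

    out = np.zeros(data.shape, dtype=bool)
    for x, y, z in np.argwhere(wm.astype(bool)):
        idx = (x + pad) * strides[0] + (y + pad) * strides[1] + (z + pad)
        center = df[idx]

        nb = idx + f_rank
        sup = bf[nb]
        vals = df[nb][sup]
        if vals.size == 0:
            continue
        rank = np.count_nonzero(vals < center) / vals.size
        if rank > crit.rank_percentile / 100.0:
            continue

        nb = idx + f_con
        sup = bf[nb]
        vals = df[nb][sup]
        if vals.size == 0:
            continue
        m = vals.mean()
        if m <= 0:
            continue
        if 100.0 * (m - center) / m > crit.contrast_threshold_pct:
            out[x, y, z] = True
    return out


def icc3k_oracle(x):
    """Explicit two-way sums-of-squares ICC(3,k) on a complete n x k table."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_subj = 0.0
    for i in range(n):
        ss_subj += k * (x[i].mean() - grand) ** 2
    ss_sess = 0.0
    for j in range(k):
        ss_sess += n * (x[:, j].mean() - grand) ** 2
    ss_tot = ((x - grand) ** 2).sum()
    ms_r = ss_subj / (n - 1)
    ms_e = (ss_tot - ss_subj - ss_sess) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / ms_r


@pytest.fixture(scope="session")
def small_phantom():
    """One rendered phantom with tubules, blob distractors and a faint tubule."""
    gt = random_phantom(seed=3, n_tubules=5, n_distractors=2, n_faint=1)
    vol, brain, wm = render_phantom(gt)
    return gt, vol, brain, wm
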