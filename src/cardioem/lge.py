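"""Fuzzy c-means LGE classification and per-segment scar transmurality.

Late-gadolinium-enhanced (LGE) cMRI shows fibrotic myocardium as bright
voxels. Within a delineated myocardial mask, voxels are classified into two
classes (LGE vs non-LGE) by unsupervised two-class fuzzy c-means on
intensity; the class with the higher centre is always the LGE class, so the
result does not depend on initial centre ordering. Memberships are hardened
at 0.5 and converted to a per-segment transmurality: on each short-axis
slice, radial chords from endocardium to epicardium are binned by angle,
the LGE fraction of each chord is computed, and chord fractions are
averaged per AHA segment (in percent of wall thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .segments import LV_SEGMENTS

# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class LGEVolume:
    """Short-axis LGE image stack with myocardial mask and segment labels.

    ``labels`` holds the LV segment index (position in the AHA segment
    list) per voxel inside the mask and -1 elsewhere.
    """

    stack: np.ndarray          # (n_slices, h, w) float intensities
    mask: np.ndarray           # (n_slices, h, w) bool, myocardium
    labels: np.ndarray         # (n_slices, h, w) int, -1 outside mask
    slice_spacing: float = 8.0  # mm
    scar_truth: dict | None = None  # phantom ground truth, when synthetic

    def __post_init__(self) -> None:
        if self.stack.shape != self.mask.shape or self.stack.shape != self.labels.shape:
            raise ValidationError("LGE stack/mask/labels shapes differ")
        if self.mask.ndim != 3:
            raise ValidationError("LGE volume must be a 3-D stack")
        for k in range(self.mask.shape[0]):
            if not self.mask[k].any():
                raise ValidationError(f"LGE slice {k}: empty myocardial mask")
        if (self.labels[~self.mask] != -1).any():
            raise ValidationError("segment labels present outside the mask")


@dataclass
class FCMResult:
    """Two-class fuzzy c-means output."""

    memberships: np.ndarray    # (n, 2), rows sum to 1; column 1 = LGE class
    centers: np.ndarray        # (2,), ascending (centers[1] = LGE centre)
    n_iter: int
    converged: bool
    objective: list[float] = field(default_factory=list)

    @property
    def lge_hard(self) -> np.ndarray:
        """Hard LGE classification at membership 0.5."""
        return self.memberships[:, 1] >= 0.5


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------


def fcm2(intensities: np.ndarray, m: float = 2.0, tol: float = 1e-5,
         max_iter: int = 300, seed: int | None = None) -> FCMResult:
    """Two-class fuzzy c-means on a 1-D intensity sample.

    Standard alternating updates: centres are membership^m-weighted means;
    memberships are inverse-distance^(2/(m-1)) normalized per voxel. The
    Bezdek objective sum(u^m d^2) is checked to be non-increasing at every
    step. Initialization is deterministic (25th/75th intensity percentiles),
    so ``seed`` is accepted for interface uniformity but unused.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise ValidationError("fcm2: need at least two distinct intensity values")
    if m <= 1.0:
        raise ValidationError(f"fcm2: fuzzifier m = {m} must be > 1")
    centers = np.percentile(x, [25.0, 75.0]).astype(float)
    if centers[0] == centers[1]:
        centers = np.array([x.min(), x.max()], dtype=float)

    u = np.empty((x.size, 2))
    obj_hist: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = (x[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))  # distance^(-2/(m-1))
        u = inv / inv.sum(axis=1, keepdims=True)
        obj = float(np.sum((u ** m) * d2))
        if obj_hist and obj > obj_hist[-1] * (1.0 + 1e-9):
            raise SimulationError("fcm2: objective increased (internal error)")
        obj_hist.append(obj)
        um = u ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            converged = True
            break

    order = np.argsort(centers)
    centers = centers[order]
    u = u[:, order]
    return FCMResult(memberships=u, centers=centers, n_iter=it,
                     converged=converged, objective=obj_hist)


# ---------------------------------------------------------------------------
# Transmurality
# ---------------------------------------------------------------------------


def transmurality_by_segment(volume: LGEVolume, fcm: FCMResult | None = None,
                             lge_hard: np.ndarray | None = None,
                             n_angular_bins: int = 180) -> pd.Series:
    """Per-segment transmurality (% of wall thickness classified LGE).

    ``fcm`` must be the result of :func:`fcm2` on ``volume.stack[volume.mask]``
    (alternatively pass a precomputed hard classification of those voxels).
    Chords are angular bins around each slice's mask centroid; a chord's LGE
    fraction approximates the radial fraction of wall thickness occupied by
    scar, and fractions are averaged over chords and slices per segment.
    Segments without mask voxels are reported as NaN.
    """
    if lge_hard is None:
        if fcm is None:
            raise ValidationError("provide an FCMResult or a hard classification")
        lge_hard = fcm.lge_hard
    n_mask = int(volume.mask.sum())
    if lge_hard.shape[0] != n_mask:
        raise ValidationError(
            f"classification length {lge_hard.shape[0]} != mask voxels {n_mask}"
        )
    lge_vol = np.zeros(volume.mask.shape, dtype=bool)
    lge_vol[volume.mask] = lge_hard

    frac_sum = {s: 0.0 for s in LV_SEGMENTS}
    frac_n = {s: 0 for s in LV_SEGMENTS}
    n_slices, h, w = volume.mask.shape
    for k in range(n_slices):
        msk = volume.mask[k]
        ys, xs = np.nonzero(msk)
        cy, cx = ys.mean(), xs.mean()
        ang = np.arctan2(xs - cx, -(ys - cy))  # 0 at 12 o'clock, clockwise
        bins = np.floor((ang + np.pi) / (2.0 * np.pi) * n_angular_bins).astype(int)
        bins = np.clip(bins, 0, n_angular_bins - 1)
        # 1/r weights turn the annular voxel count into radial chord length
        # (voxel density per unit radius grows like r)
        radius = np.hypot(ys - cy, xs - cx)
        w = 1.0 / np.maximum(radius, 1e-6)
        lge_flat = lge_vol[k][msk]
        lab_flat = volume.labels[k][msk]
        for b in range(n_angular_bins):
            sel = bins == b
            if not sel.any():
                continue
            labs, counts = np.unique(lab_flat[sel], return_counts=True)
            seg_idx = int(labs[np.argmax(counts)])
            if seg_idx < 0 or seg_idx >= len(LV_SEGMENTS):
                continue
            seg = LV_SEGMENTS[seg_idx]
            frac_sum[seg] += float(np.sum(lge_flat[sel] * w[sel]) / np.sum(w[sel]))
            frac_n[seg] += 1

    out = {}
    for s in LV_SEGMENTS:
        out[s] = 100.0 * frac_sum[s] / frac_n[s] if frac_n[s] else np.nan
    return pd.Series(out, name="transmurality_pct")


def scar_analysis(volume: LGEVolume, m: float = 2.0, tol: float = 1e-5,
                  max_iter: int = 300) -> tuple[pd.Series, FCMResult]:
    """Full pipeline: FCM on masked intensities, then transmurality map."""
    fcm = fcm2(volume.stack[volume.mask], m=m, tol=tol, max_iter=max_iter)
    return transmurality_by_segment(volume, fcm), fcm
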