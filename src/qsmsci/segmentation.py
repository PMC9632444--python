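"""Threshold-based SCI segmentation, contralateral NAWM pairing and lesion location.

Two lesion definitions are applied to a generous seed ROI:

* FLAIR definition: keep voxels whose FLAIR intensity is at least
  1.02 x the mean cortical FLAIR intensity (hyperintense);
* FLAIR+T1w definition: additionally keep only voxels whose T1w intensity
  is at most 1.02 x the mean cortical T1w intensity (hypointense). A lesion
  "persists" under this stricter definition if any voxel survives and the
  3 mm size gate still passes.

Each retained lesion is paired with an equal-sized control ROI in normal
appearing white matter obtained by mirroring the lesion across the brain
midline and, if the mirrored position is invalid (outside WM or touching
any lesion), shifting it within the same transverse slices to the nearest
valid position (deterministic search, distance- then raster-ordered).

White matter is subdivided into periventricular / juxtacortical / deep
classes by percentiles of Euclidean distance maps to the ventricle and
cortex masks. The juxtacortical rule is implemented as cortex *proximity*
by default (voxels within the 25th percentile of the distance-to-cortex
map); the literal cortex-distal reading (above the 75th percentile) is
available via ``cortex_reading="distal"`` — both readings use the same
percentile machinery and precedence periventricular > juxtacortical > deep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

THRESHOLD_FACTOR = 1.02
MIN_DIMENSION_MM = 3.0

DEPTH_NONE, DEPTH_JUXTACORTICAL, DEPTH_PERIVENTRICULAR, DEPTH_DEEP = 0, 1, 2, 3
DEPTH_NAMES = {DEPTH_JUXTACORTICAL: "juxtacortical",
               DEPTH_PERIVENTRICULAR: "periventricular",
               DEPTH_DEEP: "deep"}


@dataclass
class LesionROI:
    mask: np.ndarray
    grid: str = "flair"                     # flair | t1w | gre
    definition: str = "FLAIR"               # FLAIR | FLAIR+T1w
    lobe: str = "other"
    depth_fractions: dict = field(default_factory=dict)
    volume_mm3: float = 0.0
    subject_id: str = ""
    lesion_id: int = -1
    excluded: bool = False
    reason: str = ""

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class LesionPair:
    sci: LesionROI
    nawm: LesionROI
    excluded: bool = False
    reason: str = ""


@dataclass
class DepthMap:
    labels: np.ndarray
    d_cortex: np.ndarray
    d_ventricle: np.ndarray


def cortical_mean(image: np.ndarray, cortex_mask: np.ndarray) -> float:
    """Arithmetic mean intensity over the cortical mask."""
    cortex_mask = np.asarray(cortex_mask, dtype=bool)
    if not cortex_mask.any():
        raise ValueError("cortex mask is empty")
    return float(np.asarray(image, dtype=float)[cortex_mask].mean())


def apply_flair_threshold(
    seed_roi: np.ndarray,
    flair: np.ndarray,
    cortex_mean: float,
    factor: float = THRESHOLD_FACTOR,
    **roi_kwargs,
) -> LesionROI:
    """Minimum-intensity threshold: keep seed voxels >= factor x cortical mean."""
    seed = np.asarray(seed_roi, dtype=bool)
    if not seed.any():
        raise ValueError("seed ROI is empty")
    retained = seed & (np.asarray(flair, dtype=float) >= factor * cortex_mean)
    roi = LesionROI(mask=retained, grid="flair", definition="FLAIR", **roi_kwargs)
    if not retained.any():
        roi.excluded = True
        roi.reason = "no hyperintense voxels above the FLAIR threshold"
    return roi


def apply_t1w_threshold(
    flair_roi: LesionROI,
    t1w: np.ndarray,
    cortex_mean_t1: float,
    factor: float = THRESHOLD_FACTOR,
) -> LesionROI:
    """Maximum-intensity threshold: keep voxels <= factor x cortical T1w mean.

    ``flair_roi.mask`` must already live on the T1w grid.
    """
    retained = flair_roi.mask & (np.asarray(t1w, dtype=float) <= factor * cortex_mean_t1)
    roi = LesionROI(mask=retained, grid="t1w", definition="FLAIR+T1w",
                    lobe=flair_roi.lobe, subject_id=flair_roi.subject_id,
                    lesion_id=flair_roi.lesion_id)
    if not retained.any():
        roi.excluded = True
        roi.reason = "did not persist under the T1w threshold"
    return roi


def size_gate(roi_mask: np.ndarray, voxel_size) -> tuple[bool, float]:
    """3 mm minimum greatest-dimension rule.

    Returns (passes, greatest axis-aligned extent in mm).
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        return False, 0.0
    vs = np.asarray(voxel_size, dtype=float)
    idx = np.nonzero(mask)
    extent = max((i.max() - i.min() + 1) * v for i, v in zip(idx, vs))
    return bool(extent >= MIN_DIMENSION_MM), float(extent)


def mirror_nawm(
    sci_roi: np.ndarray,
    wm_mask: np.ndarray,
    all_sci_masks,
    midline_axis: int = 0,
    max_shift: int = 20,
) -> tuple[np.ndarray | None, tuple[int, int], str]:
    """Mirror an SCI across the grid midline into contralateral NAWM.

    The reflected mask is translated within the same transverse slices
    (in-plane shifts only) to the nearest position fully inside white
    matter and disjoint from every SCI mask of the subject. Returns
    ``(mask or None, (dx, dy) shift, reason)``; voxel count is preserved
    whenever a mask is returned.
    """
    sci = np.asarray(sci_roi, dtype=bool)
    wm = np.asarray(wm_mask, dtype=bool)
    forbidden = np.zeros_like(wm)
    for m in all_sci_masks:
        forbidden |= np.asarray(m, dtype=bool)
    mirrored = np.flip(sci, axis=midline_axis)
    coords = np.array(np.nonzero(mirrored)).T  # (n, 3)
    shape = np.array(sci.shape)

    in_plane_axes = [ax for ax in range(3) if ax != 2][:2]
    if midline_axis == 2:  # degenerate configuration; shift in x-y regardless
        in_plane_axes = [0, 1]

    candidates = [(dx, dy) for dx in range(-max_shift, max_shift + 1)
                  for dy in range(-max_shift, max_shift + 1)]
    candidates.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]))
    for dx, dy in candidates:
        shift = np.zeros(3, dtype=int)
        shift[in_plane_axes[0]] = dx
        shift[in_plane_axes[1]] = dy
        c = coords + shift
        if np.any(c < 0) or np.any(c >= shape):
            continue
        ci = tuple(c.T)
        if np.all(wm[ci]) and not np.any(forbidden[ci]):
            out = np.zeros_like(sci)
            out[ci] = True
            return out, (dx, dy), ""
    return None, (0, 0), f"no valid contralateral NAWM position within +/-{max_shift} voxels"


def classify_wm_depth(
    wm_mask: np.ndarray,
    cortex_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    ventricle_percentile: float = 5.0,
    cortex_percentile: float = 25.0,
    cortex_reading: str = "proximity",
) -> DepthMap:
    """Partition WM into periventricular, juxtacortical and deep classes."""
    wm = np.asarray(wm_mask, dtype=bool)
    cortex = np.asarray(cortex_mask, dtype=bool)
    vent = np.asarray(ventricle_mask, dtype=bool)
    if not wm.any():
        raise ValueError("white matter mask is empty")
    if not cortex.any():
        raise ValueError("cortex mask is empty")
    if not vent.any():
        raise ValueError("ventricle mask is empty")
    if np.any(wm & cortex) or np.any(wm & vent) or np.any(cortex & vent):
        raise ValueError("masks must be disjoint")
    vs = np.asarray(voxel_size, dtype=float)
    d_cortex = ndimage.distance_transform_edt(~cortex, sampling=vs)
    d_vent = ndimage.distance_transform_edt(~vent, sampling=vs)

    labels = np.zeros(wm.shape, dtype=np.int8)
    pv_thr = np.percentile(d_vent[wm], ventricle_percentile)
    pv = wm & (d_vent <= pv_thr)
    if cortex_reading == "proximity":
        jc_thr = np.percentile(d_cortex[wm], cortex_percentile)
        jc = wm & ~pv & (d_cortex <= jc_thr)
    elif cortex_reading == "distal":
        jc_thr = np.percentile(d_cortex[wm], 100.0 - cortex_percentile)
        jc = wm & ~pv & (d_cortex >= jc_thr)
    else:
        raise ValueError("cortex_reading must be 'proximity' or 'distal'")
    labels[wm] = DEPTH_DEEP
    labels[jc] = DEPTH_JUXTACORTICAL
    labels[pv] = DEPTH_PERIVENTRICULAR
    return DepthMap(labels=labels, d_cortex=d_cortex, d_ventricle=d_vent)


def depth_fractions(roi_mask: np.ndarray, depth: DepthMap) -> dict:
    """Fraction of ROI voxels in each depth class (over classified voxels)."""
    mask = np.asarray(roi_mask, dtype=bool)
    lab = depth.labels[mask]
    lab = lab[lab != DEPTH_NONE]
    if lab.size == 0:
        return {}
    return {name: float(np.count_nonzero(lab == code) / lab.size)
            for code, name in DEPTH_NAMES.items()
            if np.count_nonzero(lab == code)}


def assign_lobe(roi_mask: np.ndarray, lobe_atlas: np.ndarray,
                names: dict | None = None) -> str:
    """Majority-vote lobe over ROI voxels; ties and off-atlas ROIs give 'other'."""
    names = names or {1: "frontal", 2: "parietal", 3: "occipital", 4: "temporal"}
    mask = np.asarray(roi_mask, dtype=bool)
    atlas = np.asarray(lobe_atlas)
    vals = atlas[mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        return "other"
    labels, counts = np.unique(vals, return_counts=True)
    top = counts.max()
    winners = labels[counts == top]
    if winners.size != 1:
        return "other"
    return names.get(int(winners[0]), "other")


def make_seed_roi(true_mask: np.ndarray, dilate_voxels: int = 2) -> np.ndarray:
    """Generous seed ROI emulating a manual drawing: truth dilated by N voxels."""
    return ndimage.binary_dilation(np.asarray(true_mask, dtype=bool),
                                   iterations=dilate_voxels)
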