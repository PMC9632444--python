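"""Resampling between the FLAIR, T1w and GRE grids.

Registration *estimation* is out of scope: transforms are constructed from
known grid-to-world affines (as simulated) or supplied by the user. The
analysis-defining steps implemented here are the application of an affine
with the stated interpolation modes and the post-interpolation exclusion
rule (lesions of two voxels or fewer in the native QSM/GRE space are
dropped, as they no longer meet the 3 mm criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Volume


@dataclass
class GridTransform:
    """Maps voxel coordinates of a target grid to voxel coordinates of a source grid.

    ``source_affine`` and ``target_affine`` are grid-to-world maps. An
    optional ``world_affine`` (e.g. a registration read from file) maps
    source-world to target-world coordinates and defaults to identity.
    """

    source_affine: np.ndarray
    target_affine: np.ndarray
    target_shape: tuple[int, int, int]
    world_affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.source_affine = np.asarray(self.source_affine, dtype=float)
        self.target_affine = np.asarray(self.target_affine, dtype=float)
        if self.world_affine is None:
            self.world_affine = np.eye(4)
        self.world_affine = np.asarray(self.world_affine, dtype=float)
        for name, aff in (("source", self.source_affine),
                          ("target", self.target_affine),
                          ("world", self.world_affine)):
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValueError(f"{name} affine is degenerate (non-invertible)")

    @property
    def voxel_map(self) -> np.ndarray:
        """4x4 matrix taking target voxel indices to source voxel indices."""
        return (np.linalg.inv(self.source_affine)
                @ np.linalg.inv(self.world_affine)
                @ self.target_affine)


def apply_affine(volume: np.ndarray, transform: GridTransform, mode: str = "trilinear") -> np.ndarray:
    """Pull-resample ``volume`` onto the transform's target grid.

    Each target voxel center is mapped through the inverse chain into the
    source grid and sampled there. ``mode`` is ``"nearest"`` (mandatory for
    masks, output stays binary) or ``"trilinear"``.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError("mode must be 'nearest' or 'trilinear'")
    order = 0 if mode == "nearest" else 1
    vol = np.asarray(volume)
    is_bool = vol.dtype == bool
    m = transform.voxel_map
    # scipy's affine_transform implements exactly this pull-resampling.
    out = ndimage.affine_transform(
        vol.astype(float),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=tuple(transform.target_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if is_bool:
        return out > 0.5
    return out


def resample_volume(vol: Volume, target: Volume | GridTransform, mode: str = "trilinear") -> Volume:
    """Convenience wrapper resampling a :class:`Volume` onto another volume's grid."""
    if isinstance(target, GridTransform):
        tr = target
        target_affine = tr.target_affine
        voxel_size = vol.voxel_size
    else:
        tr = GridTransform(
            source_affine=vol.affine,
            target_affine=target.affine,
            target_shape=tuple(target.data.shape),
        )
        target_affine = target.affine
        voxel_size = target.voxel_size
    data = apply_affine(vol.data, tr, mode=mode)
    return Volume(data=data, affine=target_affine, voxel_size=voxel_size)


def post_resample_gate(roi_on_gre_grid: np.ndarray, min_voxels: int = 3) -> tuple[bool, str]:
    """Exclusion rule applied after interpolation into the native GRE space.

    Returns ``(keep, reason)``; ROIs of ``min_voxels - 1`` voxels or fewer
    are excluded because they no longer meet the 3 mm size requirement.
    """
    n = int(np.count_nonzero(roi_on_gre_grid))
    if n == 0:
        return False, "empty after interpolation"
    if n < min_voxels:
        return False, f"{n} voxels after interpolation (<= {min_voxels - 1})"
    return True, ""
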