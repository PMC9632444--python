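"""Shared containers, constants and grid conventions.

Conventions used throughout the package:

* voxel indices are 0-based and refer to voxel centers;
* grid-to-world affines are RAS-like 4x4 matrices; by default the world
  origin sits at the geometric center of each field of view, so volumes
  simulated on different grids (GRE / FLAIR / T1w) are already aligned in
  world space and inter-grid transforms follow from the affines alone;
* the reduced gyromagnetic ratio is 42.577 MHz/T, i.e. 1 ppm of field
  shift corresponds to 127.731 Hz at 3 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: reduced gyromagnetic ratio of the proton, MHz/T
GAMMA_BAR_MHZ_PER_T = 42.577


def hz_per_ppm(b0_tesla: float) -> float:
    """Field shift in Hz corresponding to 1 ppm at the given field strength."""
    return GAMMA_BAR_MHZ_PER_T * b0_tesla


def center_affine(shape: Sequence[int], voxel_size: Sequence[float]) -> np.ndarray:
    """Grid-to-world affine placing the FOV center at the world origin."""
    shape = np.asarray(shape, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -vs * (shape - 1) / 2.0
    return aff


@dataclass
class Volume:
    """A 3D scalar volume on a known grid."""

    data: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


@dataclass
class AcquisitionProtocol:
    """ME-GRE acquisition parameters.

    Defaults follow the protocol the analysis targets: 7 echoes with
    TE1 = 3 ms and echo spacing 4 ms at 3 T, 1.15 mm isotropic voxels.
    ``snr`` is the signal-to-noise ratio of the first-echo white-matter
    magnitude; ``numpy.inf`` means noiseless. One seed governs every
    noise draw derived from the protocol.
    """

    b0_tesla: float = 3.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    echo_times_ms: tuple[float, ...] = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0)
    voxel_size_mm: tuple[float, float, float] = (1.15, 1.15, 1.15)
    n_coils: int = 1
    snr: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size == 0:
            raise ValueError("echo_times_ms must not be empty")
        if te.size > 1 and not np.all(np.diff(te) > 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        b0 = np.asarray(self.b0_direction, dtype=float)
        if not np.isclose(np.linalg.norm(b0), 1.0, atol=1e-6):
            raise ValueError("b0_direction must be a unit vector")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if not self.snr > 0:
            raise ValueError("snr must be positive")

    @property
    def echo_times_s(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms, dtype=float) / 1000.0

    @property
    def hz_per_ppm(self) -> float:
        return hz_per_ppm(self.b0_tesla)


@dataclass
class MultiEchoSeries:
    """Complex multi-echo series: (x, y, z, echo) or per-coil (coil, x, y, z, echo)."""

    data: np.ndarray
    echo_times_ms: tuple[float, ...]
    affine: np.ndarray
    voxel_size: tuple[float, float, float]
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    b0_tesla: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError("series data must be 4D (x,y,z,echo) or 5D (coil,x,y,z,echo)")
        if self.data.shape[-1] != len(self.echo_times_ms):
            raise ValueError("last axis must match the number of echoes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite values")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-1]

    @property
    def per_coil(self) -> bool:
        return self.data.ndim == 5

    @property
    def echo_times_s(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms, dtype=float) / 1000.0


@dataclass
class QuantitativeMap:
    """A reconstructed quantitative map (chi in ppm or R2* in 1/s)."""

    data: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float]
    mask: np.ndarray
    units: str = ""
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


def ellipsoid_mask(
    shape: Sequence[int],
    center_vox: Sequence[float],
    semi_axes_mm: Sequence[float],
    voxel_size: Sequence[float],
) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid given in voxel-center coordinates."""
    grids = np.ogrid[tuple(slice(0, int(n)) for n in shape)]
    q = np.zeros(tuple(int(n) for n in shape), dtype=float)
    for g, c, a, v in zip(grids, center_vox, semi_axes_mm, voxel_size):
        if a <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        q = q + (((g - c) * v) / a) ** 2
    return q <= 1.0
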