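"""Digital brain phantom and MR acquisition simulator.

The phantom is a nested-ellipsoid brain on the GRE grid (1.15 mm isotropic
by default): a cortical gray-matter shell around white matter, a central
CSF ventricle and two deep-gray nuclei. Ellipsoidal lesions are embedded in
white matter with configurable susceptibility and R2* offsets relative to
WM, a FLAIR contrast factor relative to the cortical mean and a prescribed
fraction of voxels below the T1w hypointensity threshold — the quantities
the downstream segmentation thresholds act on.

Tissue chi offsets and R2* defaults are calibrated to the group means the
analysis targets (NAWM R2* 19.2 1/s, lesion 16.7 1/s; lesion-vs-NAWM chi
offset +0.0086 ppm) so that recovery tests address those numbers; they are
working values for synthetic data, not claims about tissue truth.

The ME-GRE signal model per voxel and echo is

    S(TE) = M0 * exp(-R2* TE) * exp(i (phi0 + 2 pi * gamma_bar B0 * delta * 1e-6 * TE))

with delta the dipole-convolved field shift in ppm; complex Gaussian noise
is added at a stated first-echo white-matter SNR, governed by one seed.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from . import qsm
from .core import (AcquisitionProtocol, MultiEchoSeries, Volume,
                   center_affine, ellipsoid_mask)
from .resample import GridTransform, apply_affine

LABELS = {"background": 0, "wm": 1, "cortex": 2, "ventricle": 3, "deep_gm": 4}


@dataclass
class LesionSpec:
    """One ellipsoidal white-matter lesion."""

    center: tuple[float, float, float]          # voxel coordinates on the GRE grid
    semi_axes: tuple[float, float, float]       # mm
    delta_chi: float = 0.0086                   # ppm offset vs WM
    delta_r2star: float = -2.5                  # 1/s offset vs WM
    flair_contrast: float = 1.2                 # multiplicative factor vs cortical mean
    t1_pass_fraction: float = 1.0               # fraction of voxels below the T1w threshold

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if not 0.0 <= self.t1_pass_fraction <= 1.0:
            raise ValueError("t1_pass_fraction must lie in [0, 1]")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.15, 1.15, 1.15)
    brain_axes_fraction: float = 0.82           # brain semi-axes as fraction of FOV/2
    cortex_thickness_mm: float = 3.0
    ventricle_semi_axes_mm: tuple[float, float, float] = (5.0, 9.0, 5.0)
    deep_gm_radius_mm: float = 4.0
    deep_gm_offset_mm: float = 11.0             # +/- x offset of the two nuclei
    chi_ppm: dict = field(default_factory=lambda: {
        "background": 0.0, "wm": -0.03, "cortex": 0.0, "ventricle": 0.02, "deep_gm": 0.05})
    r2star_s_inv: dict = field(default_factory=lambda: {
        "background": 0.0, "wm": 19.2, "cortex": 15.0, "ventricle": 1.0, "deep_gm": 30.0})
    m0: dict = field(default_factory=lambda: {
        "background": 0.0, "wm": 850.0, "cortex": 900.0, "ventricle": 1000.0, "deep_gm": 850.0})
    lesions: tuple[LesionSpec, ...] = ()
    merge_overlapping: bool = False
    phi0_rad: float = 0.0


@dataclass
class TissuePhantom:
    label_grid: np.ndarray
    chi_map: np.ndarray
    r2star_map: np.ndarray
    m0_map: np.ndarray
    lesions: list[LesionSpec]
    lesion_masks: list[np.ndarray]
    brain_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    phi0_rad: float = 0.0

    @property
    def wm_mask(self) -> np.ndarray:
        return self.label_grid == LABELS["wm"]

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.label_grid == LABELS["cortex"]

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.label_grid == LABELS["ventricle"]


def build_phantom(config: PhantomConfig) -> TissuePhantom:
    """Rasterize the phantom geometry and embed the lesions.

    Raises ``ValueError`` naming the offending lesion index if a lesion
    extends outside white matter, and on overlapping lesions unless
    ``config.merge_overlapping`` is set (merged lesions never double-label
    a voxel: the earlier lesion keeps contested voxels).
    """
    shape = tuple(int(n) for n in config.shape)
    if min(shape) < 32:
        raise ValueError("phantom grid must be at least 32^3")
    vs = tuple(float(v) for v in config.voxel_size)
    fov = np.array(shape) * np.array(vs)
    center = (np.array(shape, dtype=float) - 1) / 2.0
    brain_axes = config.brain_axes_fraction * fov / 2.0

    labels = np.zeros(shape, dtype=np.int16)
    brain = ellipsoid_mask(shape, center, brain_axes, vs)
    labels[brain] = LABELS["cortex"]
    wm_axes = brain_axes - config.cortex_thickness_mm
    if np.any(wm_axes <= 0):
        raise ValueError("cortex thickness leaves no white matter")
    wm = ellipsoid_mask(shape, center, wm_axes, vs)
    labels[wm] = LABELS["wm"]
    vent = ellipsoid_mask(shape, center, config.ventricle_semi_axes_mm, vs)
    labels[vent & wm] = LABELS["ventricle"]
    for sign in (+1, -1):
        c = center + np.array([sign * config.deep_gm_offset_mm / vs[0], 0.0, 0.0])
        dgm = ellipsoid_mask(shape, c, (config.deep_gm_radius_mm,) * 3, vs)
        labels[dgm & (labels == LABELS["wm"])] = LABELS["deep_gm"]

    wm_mask = labels == LABELS["wm"]
    lesion_masks: list[np.ndarray] = []
    occupied = np.zeros(shape, dtype=bool)
    for i, spec in enumerate(config.lesions):
        m = ellipsoid_mask(shape, spec.center, spec.semi_axes, vs)
        if not m.any():
            raise ValueError(f"lesion {i} covers no voxels")
        if np.any(m & ~wm_mask):
            raise ValueError(f"lesion {i} extends outside white matter")
        if np.any(m & occupied):
            if not config.merge_overlapping:
                raise ValueError(f"lesion {i} overlaps an earlier lesion")
            m = m & ~occupied
        occupied |= m
        lesion_masks.append(m)

    chi = np.zeros(shape)
    r2s = np.zeros(shape)
    m0 = np.zeros(shape)
    for name, lab in LABELS.items():
        sel = labels == lab
        chi[sel] = config.chi_ppm[name]
        r2s[sel] = config.r2star_s_inv[name]
        m0[sel] = config.m0[name]
    for spec, m in zip(config.lesions, lesion_masks):
        chi[m] += spec.delta_chi
        r2s[m] += spec.delta_r2star

    return TissuePhantom(
        label_grid=labels,
        chi_map=chi,
        r2star_map=r2s,
        m0_map=m0,
        lesions=list(config.lesions),
        lesion_masks=lesion_masks,
        brain_mask=labels > 0,
        voxel_size=vs,
        affine=center_affine(shape, vs),
        phi0_rad=config.phi0_rad,
    )


def forward_field(chi_map: np.ndarray, b0_direction, voxel_size, pad: bool = True) -> np.ndarray:
    """Dipole-convolved field shift (ppm) from a susceptibility map (ppm)."""
    return qsm.field_from_chi(chi_map, voxel_size, b0_direction, pad=pad)


def _coil_sensitivities(shape, n_coils: int, rng: np.random.Generator):
    """Smooth low-order polynomial magnitudes with distinct constant phase per coil."""
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    mags = []
    phases = []
    for c in range(n_coils):
        coef = rng.uniform(-0.3, 0.3, size=3)
        mag = 1.0 + sum(co * g for co, g in zip(coef, grids))
        mags.append(np.clip(mag, 0.2, None))
        phases.append(2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2))
    return mags, phases


def simulate_megre(truth: TissuePhantom, protocol: AcquisitionProtocol) -> MultiEchoSeries:
    """Simulate the complex multi-echo gradient-echo acquisition."""
    te = protocol.echo_times_s
    delta_ppm = forward_field(truth.chi_map, protocol.b0_direction, truth.voxel_size)
    f_hz = delta_ppm * protocol.hz_per_ppm
    phase = truth.phi0_rad + 2 * np.pi * f_hz[..., None] * te
    mag = truth.m0_map[..., None] * np.exp(-truth.r2star_map[..., None] * te)
    signal = mag * np.exp(1j * phase)

    rng = np.random.default_rng(protocol.seed)
    wm = truth.wm_mask
    sigma = 0.0
    if np.isfinite(protocol.snr):
        sigma = float(mag[..., 0][wm].mean()) / protocol.snr

    if protocol.n_coils == 1:
        data = signal
        if sigma > 0:
            data = data + sigma * (rng.standard_normal(data.shape)
                                   + 1j * rng.standard_normal(data.shape))
        data4 = data
    else:
        mags, phases = _coil_sensitivities(truth.label_grid.shape, protocol.n_coils, rng)
        coils = []
        for m, p in zip(mags, phases):
            s = signal * m[..., None] * np.exp(1j * p)
            if sigma > 0:
                s = s + sigma * (rng.standard_normal(s.shape)
                                 + 1j * rng.standard_normal(s.shape))
            coils.append(s)
        data4 = np.stack(coils, axis=0)

    return MultiEchoSeries(
        data=data4,
        echo_times_ms=tuple(protocol.echo_times_ms),
        affine=truth.affine,
        voxel_size=truth.voxel_size,
        b0_direction=tuple(protocol.b0_direction),
        b0_tesla=protocol.b0_tesla,
    )


@dataclass
class ContrastConfig:
    """Structural-image tissue intensities (arbitrary units)."""

    flair: dict = field(default_factory=lambda: {
        "background": 0.0, "wm": 100.0, "cortex": 120.0, "ventricle": 30.0, "deep_gm": 115.0})
    t1w: dict = field(default_factory=lambda: {
        "background": 0.0, "wm": 110.0, "cortex": 100.0, "ventricle": 40.0, "deep_gm": 95.0})
    flair_voxel_size: tuple[float, float, float] = (0.65, 0.65, 1.0)
    t1w_voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    t1_hypo_factor: float = 0.90   # intensity of passing lesion voxels, x cortical mean
    t1_hyper_factor: float = 1.10  # intensity of non-passing lesion voxels
    seed: int = 0


@dataclass
class StructuralSim:
    flair: Volume
    t1w: Volume
    labels_flair: np.ndarray
    labels_t1w: np.ndarray
    lesion_masks_flair: list[np.ndarray]
    lesion_masks_t1w: list[np.ndarray]
    flair_cortex_mean: float
    t1w_cortex_mean: float
    flair_hyper_counts: list[int]
    t1_pass_counts: list[int]
    flair_to_gre: GridTransform
    t1w_to_gre: GridTransform


def _structural_grid(truth: TissuePhantom, voxel_size):
    fov = np.array(truth.label_grid.shape) * np.array(truth.voxel_size)
    shape = tuple(int(np.ceil(f / v)) for f, v in zip(fov, voxel_size))
    return shape, center_affine(shape, voxel_size)


def simulate_structural(truth: TissuePhantom, contrast: ContrastConfig | None = None) -> StructuralSim:
    """Simulate FLAIR and T1w volumes on their native grids.

    Lesion voxels on FLAIR are set to ``flair_contrast`` times the cortical
    mean; on T1w exactly ``round(t1_pass_fraction * n)`` voxels of each
    lesion are placed below the hypointensity threshold (deterministic given
    the contrast seed). Generator bookkeeping (per-lesion hyperintense and
    T1w-passing counts) is returned for oracle tests.
    """
    contrast = contrast or ContrastConfig()
    if contrast.t1w["wm"] < contrast.t1w["cortex"]:
        warnings.warn("T1w white matter below cortex violates the expected tissue ordering")

    rng = np.random.default_rng(contrast.seed)
    out = {}
    for name, vs, values in (("flair", contrast.flair_voxel_size, contrast.flair),
                             ("t1w", contrast.t1w_voxel_size, contrast.t1w)):
        shape, aff = _structural_grid(truth, vs)
        tr = GridTransform(source_affine=truth.affine, target_affine=aff, target_shape=shape)
        labels = np.rint(apply_affine(truth.label_grid.astype(float), tr, mode="nearest")).astype(np.int16)
        img = np.zeros(shape)
        for tissue, lab in LABELS.items():
            img[labels == lab] = values[tissue]
        lesion_masks = [apply_affine(m, tr, mode="nearest") for m in truth.lesion_masks]
        out[name] = dict(shape=shape, affine=aff, voxel_size=vs, labels=labels,
                         img=img, lesion_masks=lesion_masks)

    flair = out["flair"]
    flair_cortex_mean = float(flair["img"][flair["labels"] == LABELS["cortex"]].mean())
    flair_hyper_counts = []
    for spec, m in zip(truth.lesions, flair["lesion_masks"]):
        flair["img"][m] = spec.flair_contrast * flair_cortex_mean
        flair_hyper_counts.append(
            int(np.count_nonzero(flair["img"][m] >= 1.02 * flair_cortex_mean)))

    t1w = out["t1w"]
    t1w_cortex_mean = float(t1w["img"][t1w["labels"] == LABELS["cortex"]].mean())
    t1_pass_counts = []
    for spec, m in zip(truth.lesions, t1w["lesion_masks"]):
        idx = np.flatnonzero(m)
        k = int(round(spec.t1_pass_fraction * idx.size))
        chosen = rng.permutation(idx)[:k]
        vals = np.full(idx.size, contrast.t1_hyper_factor * t1w_cortex_mean)
        t1w["img"].flat[idx] = vals
        t1w["img"].flat[chosen] = contrast.t1_hypo_factor * t1w_cortex_mean
        t1_pass_counts.append(k)

    gre_shape = truth.label_grid.shape
    return StructuralSim(
        flair=Volume(flair["img"], flair["affine"], flair["voxel_size"]),
        t1w=Volume(t1w["img"], t1w["affine"], t1w["voxel_size"]),
        labels_flair=flair["labels"],
        labels_t1w=t1w["labels"],
        lesion_masks_flair=flair["lesion_masks"],
        lesion_masks_t1w=t1w["lesion_masks"],
        flair_cortex_mean=flair_cortex_mean,
        t1w_cortex_mean=t1w_cortex_mean,
        flair_hyper_counts=flair_hyper_counts,
        t1_pass_counts=t1_pass_counts,
        flair_to_gre=GridTransform(source_affine=flair["affine"], target_affine=truth.affine,
                                   target_shape=gre_shape),
        t1w_to_gre=GridTransform(source_affine=t1w["affine"], target_affine=truth.affine,
                                 target_shape=gre_shape),
    )


def standard_config(n_lesions: int = 10, shape=(64, 64, 64)) -> PhantomConfig:
    """The standard multi-lesion fixture used across the test-bench analyses.

    Ten right-hemisphere WM lesions with varied sizes and T1w pass
    fractions: includes fully persisting, partially persisting and
    non-persisting lesions plus one below the 3 mm size gate.
    """
    vs = (1.15, 1.15, 1.15)
    c = (np.array(shape) - 1) / 2.0
    # (dx, dy, dz) offsets in mm from the grid center; +x hemisphere only so
    # that mirrored contralateral positions are lesion-free by construction
    placements = [
        (10.0, 0.0, -8.0), (12.0, 8.0, 4.0), (9.0, -9.0, -5.0), (15.0, 6.0, -4.0),
        (8.0, -4.0, 9.0), (14.0, -8.0, 6.0), (11.0, 12.0, -6.0), (17.0, -1.0, -7.0),
        (9.0, 6.0, -10.0), (12.0, 2.0, 10.0),
    ]
    sizes = [(3.0, 3.0, 3.0), (2.5, 2.5, 2.5), (3.5, 2.5, 2.5), (2.5, 3.5, 2.5),
             (3.0, 2.5, 3.0), (2.5, 2.5, 3.5), (3.0, 3.0, 2.5), (2.5, 3.0, 3.0),
             (1.2, 1.2, 1.2), (3.5, 3.5, 3.5)]
    fracs = [1.0, 0.5, 0.0, 0.7, 0.3, 1.0, 0.5, 0.0, 1.0, 0.6]
    lesions = []
    for (dx, dy, dz), ax, fr in list(zip(placements, sizes, fracs))[:n_lesions]:
        center = (c[0] + dx / vs[0], c[1] + dy / vs[1], c[2] + dz / vs[2])
        lesions.append(LesionSpec(center=center, semi_axes=ax, t1_pass_fraction=fr))
    return PhantomConfig(shape=tuple(shape), voxel_size=vs, lesions=tuple(lesions))


def _save_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def write_dataset(truth: TissuePhantom, series: MultiEchoSeries,
                  structurals: StructuralSim, out_dir, protocol: AcquisitionProtocol | None = None) -> dict:
    """Write the simulated dataset to ``out_dir`` and return a file manifest.

    Per coil and echo one magnitude and one phase NIfTI; truth volumes, the
    structural volumes, a JSON sidecar with protocol and affines, and the
    lesion-spec CSV. A partial write is cleaned up before re-raising.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"echo_files": [], "volumes": {}}
    try:
        data = series.data if series.per_coil else series.data[None]
        for ci in range(data.shape[0]):
            for ei in range(series.n_echoes):
                for kind, arr in (("mag", np.abs(data[ci, ..., ei])),
                                  ("phase", np.angle(data[ci, ..., ei]))):
                    p = out / f"{kind}_coil{ci:02d}_echo{ei:02d}.nii.gz"
                    _save_nifti(arr, series.affine, p)
                    written.append(p)
                    manifest["echo_files"].append(p.name)
        for name, arr, aff in (
            ("chi_truth", truth.chi_map, truth.affine),
            ("r2star_truth", truth.r2star_map, truth.affine),
            ("m0_truth", truth.m0_map, truth.affine),
            ("labels", truth.label_grid, truth.affine),
            ("brain_mask", truth.brain_mask, truth.affine),
            ("flair", structurals.flair.data, structurals.flair.affine),
            ("t1w", structurals.t1w.data, structurals.t1w.affine),
        ):
            p = out / f"{name}.nii.gz"
            _save_nifti(np.asarray(arr, dtype=float), aff, p)
            written.append(p)
            manifest["volumes"][name] = p.name

        sidecar = {
            "echo_times_ms": list(series.echo_times_ms),
            "b0_direction": list(series.b0_direction),
            "b0_tesla": series.b0_tesla,
            "voxel_size_gre_mm": list(series.voxel_size),
            "affine_gre": np.asarray(truth.affine).tolist(),
            "affine_flair": np.asarray(structurals.flair.affine).tolist(),
            "affine_t1w": np.asarray(structurals.t1w.affine).tolist(),
            "n_lesions": len(truth.lesions),
            "phi0_rad": truth.phi0_rad,
        }
        if protocol is not None:
            sidecar["protocol"] = {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in asdict(protocol).items()
                                   if np.isfinite(np.asarray(v, dtype=float)).all()
                                   or not isinstance(v, float)}
        p = out / "sidecar.json"
        p.write_text(json.dumps(sidecar, indent=1))
        written.append(p)
        manifest["sidecar"] = p.name

        p = out / "lesions.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "cx", "cy", "cz", "ax", "ay", "az",
                        "delta_chi", "delta_r2star", "flair_contrast", "t1_pass_fraction"])
            for i, L in enumerate(truth.lesions):
                w.writerow([i, *L.center, *L.semi_axes, L.delta_chi,
                            L.delta_r2star, L.flair_contrast, L.t1_pass_fraction])
        written.append(p)
        manifest["lesions_csv"] = p.name
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return manifest


def read_dataset(out_dir) -> dict:
    """Read back a written dataset; arrays round-trip exactly (float64 on disk)."""
    out = Path(out_dir)
    sidecar = json.loads((out / "sidecar.json").read_text())
    result = {"sidecar": sidecar, "volumes": {}}
    # NIfTI headers hold affines in float32; the sidecar keeps full precision
    exact = {"flair": np.asarray(sidecar["affine_flair"]),
             "t1w": np.asarray(sidecar["affine_t1w"])}
    gre_affine = np.asarray(sidecar["affine_gre"])
    for p in sorted(out.glob("*.nii.gz")):
        name = p.name.replace(".nii.gz", "")
        img = nib.load(str(p))
        result["volumes"][name] = (np.asarray(img.dataobj, dtype=np.float64),
                                   exact.get(name, gre_affine))
    with open(out / "lesions.csv") as fh:
        result["lesions"] = list(csv.DictReader(fh))
    return result
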