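"""End-to-end orchestration: simulate -> reconstruct -> segment -> pair -> summarize.

One run simulates a single-subject phantom acquisition, reconstructs chi
and R2* maps, applies both lesion definitions, pairs each retained lesion
with a mirrored contralateral NAWM ROI on the GRE grid and produces the
per-lesion record table plus the lesion-vs-NAWM statistics. Given the same
config and seed the outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fieldmap, qsm, r2star, segmentation, stats
from .core import AcquisitionProtocol
from .phantom import (ContrastConfig, PhantomConfig, LesionSpec, build_phantom,
                      simulate_megre, simulate_structural, standard_config,
                      write_dataset, LABELS)
from .resample import apply_affine, post_resample_gate

log = logging.getLogger("qsmsci")

DEFINITIONS = ("FLAIR", "FLAIR+T1w")


@dataclass
class RunConfig:
    seed: int = 7
    snr: float = np.inf
    n_coils: int = 1
    alpha: float = qsm.DEFAULT_ALPHA
    flair_threshold_factor: float = segmentation.THRESHOLD_FACTOR
    t1w_threshold_factor: float = segmentation.THRESHOLD_FACTOR
    ventricle_percentile: float = 5.0
    cortex_percentile: float = 25.0
    cortex_reading: str = "proximity"
    definitions: tuple[str, ...] = DEFINITIONS
    echo_times_ms: tuple[float, ...] = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0)
    b0_tesla: float = 3.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    phantom: PhantomConfig | None = None
    subject_id: str = "sub-01"
    group: str = "SCA"
    age_years: float = 20.6
    out_dir: str | None = None
    save_figures: bool = False

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(
            b0_tesla=self.b0_tesla, b0_direction=self.b0_direction,
            echo_times_ms=self.echo_times_ms, n_coils=self.n_coils,
            snr=self.snr, seed=self.seed)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violated invariants (empty means the config is ok)."""
    v = []
    if not config.alpha > 0:
        v.append("alpha must be > 0")
    te = np.asarray(config.echo_times_ms, dtype=float)
    if te.size == 0:
        v.append("echo_times_ms must not be empty")
    elif te.size > 1 and not np.all(np.diff(te) > 0):
        v.append("echo_times_ms must be strictly increasing")
    if not np.isclose(np.linalg.norm(config.b0_direction), 1.0, atol=1e-6):
        v.append("b0_direction must be a unit vector")
    if not config.snr > 0:
        v.append("snr must be positive")
    for name in ("flair_threshold_factor", "t1w_threshold_factor"):
        if not getattr(config, name) > 0:
            v.append(f"{name} must be > 0")
    for name in ("ventricle_percentile", "cortex_percentile"):
        if not 0 < getattr(config, name) < 100:
            v.append(f"{name} must lie in (0, 100)")
    bad = set(config.definitions) - set(DEFINITIONS)
    if bad:
        v.append(f"unknown definitions: {sorted(bad)}")
    if not config.definitions:
        v.append("definition set must not be empty")
    if config.cortex_reading not in ("proximity", "distal"):
        v.append("cortex_reading must be 'proximity' or 'distal'")
    return v


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; phantom.lesions rows become LesionSpec."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ph = raw.pop("phantom", None)
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    if ph is not None:
        lesions = tuple(LesionSpec(**{k: tuple(x) if isinstance(x, list) else x
                                      for k, x in l.items()})
                        for l in ph.pop("lesions", []))
        ph = {k: tuple(v) if isinstance(v, list) else v for k, v in ph.items()}
        cfg.phantom = PhantomConfig(lesions=lesions, **ph)
    return cfg


def synthetic_lobe_atlas(label_grid: np.ndarray) -> np.ndarray:
    """Quadrant-based lobe labels (1 frontal, 2 parietal, 3 occipital, 4 temporal).

    A stand-in for an anatomical parcellation: the brain is split by the
    grid-center y/z planes, which is sufficient to exercise majority-vote
    lobe assignment on synthetic data.
    """
    shape = label_grid.shape
    atlas = np.zeros(shape, dtype=np.int8)
    brain = label_grid > 0
    jj, kk = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    cy, cz = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    quad = np.where(jj >= cy, np.where(kk >= cz, 1, 2), np.where(kk >= cz, 4, 3))
    atlas[:] = quad[None, :, :]
    atlas[~brain] = 0
    return atlas


def reconstruct_maps(series, brain_mask, alpha: float = qsm.DEFAULT_ALPHA):
    """Coil-combine, fit+unwrap the field, remove background and invert; fit R2*."""
    combined = fieldmap.combine_coils(series)
    fr = fieldmap.fit_field_nonlinear(combined, mask=brain_mask)
    dte = np.min(np.diff(combined.echo_times_s))
    unwrapped, _ = fieldmap.unwrap_field(fr.total_field_hz, fr.mask, period=1.0 / dte)
    aligned, _ = fieldmap.align_to_b0(unwrapped, combined.b0_direction)
    mask_aligned, _ = fieldmap.align_to_b0(brain_mask, combined.b0_direction,
                                           interpolation="nearest")
    field_ppm = qsm.hz_to_ppm(aligned, combined.b0_tesla)
    # after realignment the grid z-axis is parallel to B0 by construction
    local = qsm.remove_background_pdf(field_ppm, mask_aligned, (0.0, 0.0, 1.0),
                                      combined.voxel_size)
    chi = qsm.invert_tikhonov(local, alpha=alpha)
    r2map = r2star.fit_r2star_loglinear(np.abs(combined.data),
                                        combined.echo_times_ms, mask=brain_mask)
    return {"field": fr, "field_unwrapped_hz": unwrapped, "local": local,
            "chi": chi, "r2star": r2map}


def segment_lesions(truth, structurals, config: RunConfig):
    """Apply both definitions to the seed ROIs and pair lesions with NAWM.

    Returns per-definition lists of (lesion_id, LesionPair-or-None, reason)
    with every ROI resampled onto the GRE grid.
    """
    flair = structurals.flair.data
    t1w = structurals.t1w.data
    cortex_mean_flair = segmentation.cortical_mean(
        flair, structurals.labels_flair == LABELS["cortex"])
    cortex_mean_t1 = segmentation.cortical_mean(
        t1w, structurals.labels_t1w == LABELS["cortex"])
    depth = segmentation.classify_wm_depth(
        truth.wm_mask, truth.cortex_mask, truth.ventricle_mask,
        voxel_size=truth.voxel_size,
        ventricle_percentile=config.ventricle_percentile,
        cortex_percentile=config.cortex_percentile,
        cortex_reading=config.cortex_reading)
    atlas = synthetic_lobe_atlas(truth.label_grid)

    flair_to_t1 = _between(structurals.flair.affine, structurals.t1w.affine,
                           structurals.t1w.data.shape)

    per_def: dict[str, list] = {d: [] for d in config.definitions}
    gre_masks: dict[str, list] = {d: [] for d in config.definitions}
    for i, seed_true in enumerate(structurals.lesion_masks_flair):
        seed = segmentation.make_seed_roi(seed_true, dilate_voxels=2)
        roi_f = segmentation.apply_flair_threshold(
            seed, flair, cortex_mean_flair, factor=config.flair_threshold_factor,
            subject_id=config.subject_id, lesion_id=i)
        rois = {}
        if "FLAIR" in config.definitions:
            rois["FLAIR"] = (roi_f, structurals.flair_to_gre,
                             structurals.flair.voxel_size)
        if "FLAIR+T1w" in config.definitions:
            roi_on_t1 = segmentation.LesionROI(
                mask=apply_affine(roi_f.mask, flair_to_t1, mode="nearest"),
                grid="t1w", definition="FLAIR", subject_id=config.subject_id,
                lesion_id=i, excluded=roi_f.excluded, reason=roi_f.reason)
            roi_t = segmentation.apply_t1w_threshold(
                roi_on_t1, t1w, cortex_mean_t1, factor=config.t1w_threshold_factor)
            if roi_f.excluded:
                roi_t.excluded, roi_t.reason = True, roi_f.reason
            rois["FLAIR+T1w"] = (roi_t, structurals.t1w_to_gre,
                                 structurals.t1w.voxel_size)

        for definition, (roi, to_gre, vs) in rois.items():
            if roi.excluded:
                per_def[definition].append((i, None, roi.reason))
                continue
            ok, extent = segmentation.size_gate(roi.mask, vs)
            if not ok:
                per_def[definition].append(
                    (i, None, f"greatest dimension {extent:.2f} mm < 3 mm"))
                continue
            mask_gre = apply_affine(roi.mask, to_gre, mode="nearest")
            keep, reason = post_resample_gate(mask_gre)
            if not keep:
                per_def[definition].append((i, None, reason))
                continue
            roi_gre = segmentation.LesionROI(
                mask=mask_gre, grid="gre", definition=definition,
                subject_id=config.subject_id, lesion_id=i,
                lobe=segmentation.assign_lobe(mask_gre, atlas),
                volume_mm3=float(mask_gre.sum() * np.prod(truth.voxel_size)))
            gre_masks[definition].append(mask_gre)
            per_def[definition].append((i, roi_gre, ""))

    results: dict[str, list] = {d: [] for d in config.definitions}
    for definition in config.definitions:
        all_masks = gre_masks[definition]
        for i, roi_gre, reason in per_def[definition]:
            if roi_gre is None:
                results[definition].append((i, None, reason))
                continue
            nawm_mask, shift, why = segmentation.mirror_nawm(
                roi_gre.mask, truth.wm_mask, all_masks)
            if nawm_mask is None:
                results[definition].append((i, None, why))
                continue
            nawm = segmentation.LesionROI(
                mask=nawm_mask, grid="gre", definition=definition,
                subject_id=config.subject_id, lesion_id=i)
            results[definition].append(
                (i, segmentation.LesionPair(sci=roi_gre, nawm=nawm), ""))
    return results, depth


def _between(src_affine, tgt_affine, tgt_shape):
    from .resample import GridTransform
    return GridTransform(source_affine=src_affine, target_affine=tgt_affine,
                         target_shape=tuple(tgt_shape))


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; deterministic given config + seed."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    t0 = time.time()
    stage = "phantom"
    try:
        ph_cfg = config.phantom or standard_config()
        truth = build_phantom(ph_cfg)
        protocol = config.protocol()
        log.info("phantom built: %d lesions", len(truth.lesions))

        stage = "simulate"
        series = simulate_megre(truth, protocol)
        structurals = simulate_structural(truth, ContrastConfig(seed=config.seed))

        stage = "reconstruct"
        maps = reconstruct_maps(series, truth.brain_mask, alpha=config.alpha)

        stage = "segment"
        seg, depth = segment_lesions(truth, structurals, config)

        stage = "stats"
        records, exclusions = [], []
        for definition, items in seg.items():
            for i, pair, reason in items:
                if pair is None:
                    exclusions.append({"lesion_id": i, "definition": definition,
                                       "reason": reason})
                    continue
                rec, _ = stats.roi_means(
                    pair, chi_map=maps["chi"].chi_ppm,
                    r2star_map=maps["r2star"].r2star_s_inv, depth_map=depth,
                    voxel_size=truth.voxel_size, subject_id=config.subject_id,
                    group=config.group, age_years=config.age_years)
                records.append(rec)
        records_df = stats.records_to_dataframe(records)
        statistics = {}
        for definition in config.definitions:
            sub = records_df[records_df["definition"] == definition] \
                if len(records_df) else records_df
            if len(sub) < 2:
                continue
            statistics[definition] = {
                "chi": stats.paired_delta(sub["mean_chi_sci"], sub["mean_chi_nawm"]),
                "r2star": stats.paired_delta(sub["mean_r2s_sci"], sub["mean_r2s_nawm"]),
                "bland_altman_chi": {k: v for k, v in stats.bland_altman(
                    sub["mean_chi_sci"], sub["mean_chi_nawm"]).items()
                    if k in ("bias", "sd", "loa_lower", "loa_upper")},
                "n_lesions": int(len(sub)),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_records": len(records_df),
        "n_excluded": len(exclusions),
        "elapsed_s": round(time.time() - t0, 2),
    }
    out = {"manifest": manifest, "records": records_df, "statistics": statistics,
           "exclusions": exclusions, "maps": maps, "truth": truth,
           "structurals": structurals, "series": series}
    if config.out_dir:
        d = Path(config.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        records_df.to_csv(d / "records.csv", index=False)
        (d / "statistics.json").write_text(json.dumps(statistics, indent=1, default=float))
        (d / "exclusions.json").write_text(json.dumps(exclusions, indent=1))
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        write_dataset(truth, series, structurals, d / "dataset", protocol=protocol)
    return out
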