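"""Lesion thresholds, size gate, NAWM mirroring, depth classes and lobes."""

import numpy as np
import pytest

from qsmsci import segmentation as seg
from qsmsci.core import ellipsoid_mask


class TestCorticalMean:
    def test_means(self):
        img = np.full((8, 8, 8), 100.0)
        cortex = np.zeros((8, 8, 8), dtype=bool)
        cortex[:2] = True
        assert seg.cortical_mean(img, cortex) == 100.0
        img[:1] = 80.0
        img[1:2] = 120.0
        assert seg.cortical_mean(img, cortex) == 100.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            seg.cortical_mean(np.ones((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool))

    def test_phantom_cortex_mean_matches_generator(self, structurals):
        from qsmsci.phantom import LABELS
        mean = seg.cortical_mean(structurals.flair.data,
                                 structurals.labels_flair == LABELS["cortex"])
        assert np.isclose(mean, structurals.flair_cortex_mean)


class TestThresholds:
    def setup_method(self):
        self.seed = np.zeros((10, 10, 10), dtype=bool)
        self.seed[3:7, 3:7, 3:7] = True

    def test_boundary_voxel_exactly_at_threshold_retained(self):
        flair = np.zeros((10, 10, 10))
        flair[self.seed] = 1.02 * 100.0  # exactly at threshold
        roi = seg.apply_flair_threshold(self.seed, flair, 100.0)
        assert roi.n_voxels == self.seed.sum()
        assert not roi.excluded

    def test_subthreshold_seed_excluded(self):
        flair = np.full((10, 10, 10), 90.0)
        roi = seg.apply_flair_threshold(self.seed, flair, 100.0)
        assert roi.excluded and roi.n_voxels == 0
        assert "hyperintense" in roi.reason

    def test_t1w_boundary_and_persistence(self):
        flair_roi = seg.LesionROI(mask=self.seed.copy(), grid="t1w")
        t1 = np.full((10, 10, 10), 1.02 * 100.0)  # exactly at max threshold
        roi = seg.apply_t1w_threshold(flair_roi, t1, 100.0)
        assert roi.n_voxels == self.seed.sum()
        t1[:] = 120.0  # everything too bright: lesion does not persist
        roi = seg.apply_t1w_threshold(flair_roi, t1, 100.0)
        assert roi.excluded and "persist" in roi.reason

    def test_threshold_monotonicity(self):
        # FLAIR+T1w subset of FLAIR subset of seed; raising the factor never
        # increases the retained count
        rng = np.random.default_rng(0)
        flair = rng.uniform(90, 140, (10, 10, 10))
        t1 = rng.uniform(80, 130, (10, 10, 10))
        counts = []
        for factor in (1.0, 1.02, 1.05, 1.1, 1.2):
            roi = seg.apply_flair_threshold(self.seed, flair, 100.0, factor=factor)
            counts.append(roi.n_voxels)
            assert np.all(self.seed[roi.mask])
            strict = seg.apply_t1w_threshold(roi, t1, 100.0)
            assert np.all(roi.mask[strict.mask])
        assert np.all(np.diff(counts) <= 0)

    def test_phantom_retention_matches_generator(self, standard_truth, structurals):
        # only lesion voxels are hyperintense by construction, so the FLAIR
        # threshold must retain exactly the true lesion voxels inside the
        # generous seed (including any neighbouring lesion's voxels it grazes)
        all_lesions = np.zeros_like(structurals.lesion_masks_flair[0])
        for m in structurals.lesion_masks_flair:
            all_lesions |= m
        for i, true_mask in enumerate(structurals.lesion_masks_flair):
            seed_roi = seg.make_seed_roi(true_mask, dilate_voxels=2)
            roi = seg.apply_flair_threshold(seed_roi, structurals.flair.data,
                                            structurals.flair_cortex_mean)
            assert np.array_equal(roi.mask, seed_roi & all_lesions)
            assert roi.n_voxels >= structurals.flair_hyper_counts[i]


class TestSizeGate:
    @pytest.mark.parametrize("extent_vox,voxel,passes,mm", [
        (3, 1.15, True, 3.45),   # 3 collinear voxels on the GRE grid
        (2, 1.0, False, 2.0),
        (4, 1.0, True, 4.0),     # 1x1x4 line at 1 mm slices
    ])
    def test_greatest_dimension_rule(self, extent_vox, voxel, passes, mm):
        roi = np.zeros((8, 8, 8), dtype=bool)
        roi[2, 2, 2:2 + extent_vox] = True
        ok, extent = seg.size_gate(roi, (voxel, voxel, voxel))
        assert ok is passes
        assert np.isclose(extent, mm)

    def test_empty_roi_fails(self):
        assert seg.size_gate(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))[0] is False


class TestMirrorNawm:
    def setup_method(self):
        self.wm = np.zeros((32, 32, 8), dtype=bool)
        self.wm[4:28, 4:28, :] = True
        self.sci = np.zeros_like(self.wm)
        self.sci[22:25, 14:17, 3:5] = True  # right-hemisphere lesion

    def test_clean_contralateral_is_pure_reflection(self):
        nawm, shift, reason = seg.mirror_nawm(self.sci, self.wm, [self.sci])
        assert reason == "" and shift == (0, 0)
        assert np.array_equal(nawm, np.flip(self.sci, axis=0))
        assert nawm.sum() == self.sci.sum()

    def test_contralateral_twin_forces_disjoint_shift(self):
        twin = np.flip(self.sci, axis=0)
        nawm, shift, reason = seg.mirror_nawm(self.sci, self.wm, [self.sci, twin])
        assert reason == ""
        assert shift != (0, 0)
        assert not np.any(nawm & twin) and not np.any(nawm & self.sci)
        assert nawm.sum() == self.sci.sum()
        assert np.all(self.wm[nawm])
        # same transverse slices: z extent unchanged
        assert np.array_equal(np.unique(np.nonzero(nawm)[2]),
                              np.unique(np.nonzero(self.sci)[2]))

    def test_no_valid_position_is_reported(self):
        tight_wm = self.sci.copy()  # contralateral side has no WM at all
        nawm, _, reason = seg.mirror_nawm(self.sci, tight_wm, [self.sci],
                                          max_shift=3)
        assert nawm is None and "no valid" in reason


@pytest.fixture(scope="module")
def slab():
    # slab geometry: ventricle plane at x=0..1, cortex plane at x=30..31
    shape = (32, 16, 16)
    vent = np.zeros(shape, dtype=bool)
    vent[:2] = True
    cortex = np.zeros(shape, dtype=bool)
    cortex[30:] = True
    wm = np.zeros(shape, dtype=bool)
    wm[2:30] = True
    return wm, cortex, vent


class TestDepthClassification:
    def test_adjacent_to_ventricle_is_periventricular(self, slab):
        wm, cortex, vent = slab
        d = seg.classify_wm_depth(wm, cortex, vent)
        assert np.all(d.labels[2] == seg.DEPTH_PERIVENTRICULAR)
        assert np.all(d.labels[15] == seg.DEPTH_DEEP)

    def test_periventricular_fraction_matches_percentile(self, slab):
        wm, cortex, vent = slab
        d = seg.classify_wm_depth(wm, cortex, vent, ventricle_percentile=5.0)
        frac = (d.labels == seg.DEPTH_PERIVENTRICULAR).sum() / wm.sum()
        # brute force: 5th percentile of the distance map over 28 slabs
        # selects ceil(0.05 * 28) = 2 slabs
        assert np.isclose(frac, 2.0 / 28.0)

    def test_classes_partition_wm(self, slab):
        wm, cortex, vent = slab
        for reading in ("proximity", "distal"):
            d = seg.classify_wm_depth(wm, cortex, vent, cortex_reading=reading)
            assert np.all((d.labels != seg.DEPTH_NONE) == wm)

    def test_depth_precedence_and_readings_differ(self, slab):
        wm, cortex, vent = slab
        prox = seg.classify_wm_depth(wm, cortex, vent, cortex_reading="proximity")
        dist = seg.classify_wm_depth(wm, cortex, vent, cortex_reading="distal")
        # proximity reading: juxtacortical voxels hug the cortex plane
        jc = prox.labels == seg.DEPTH_JUXTACORTICAL
        assert np.all(prox.d_cortex[jc] <= prox.d_cortex[prox.labels == seg.DEPTH_DEEP].min())
        assert not np.array_equal(prox.labels, dist.labels)

    def test_empty_masks_rejected(self, slab):
        wm, cortex, vent = slab
        with pytest.raises(ValueError):
            seg.classify_wm_depth(wm, np.zeros_like(cortex), vent)
        with pytest.raises(ValueError):
            seg.classify_wm_depth(wm, cortex, np.zeros_like(vent))


class TestAssignLobe:
    def test_majority_tie_and_outside(self):
        atlas = np.zeros((8, 8, 8), dtype=int)
        atlas[:4] = 1   # frontal
        atlas[4:] = 2   # parietal
        roi = np.zeros((8, 8, 8), dtype=bool)
        roi[2:5] = True  # 2 frontal slabs, 1 parietal
        assert seg.assign_lobe(roi, atlas) == "frontal"
        roi[:] = False
        roi[3:5] = True  # exact 50/50
        assert seg.assign_lobe(roi, atlas) == "other"
        assert seg.assign_lobe(roi, np.zeros((8, 8, 8), dtype=int)) == "other"


def test_standard_fixture_persistence_equals_brute_force(standard_truth, structurals):
    """Strict-definition persistence on the 10-lesion fixture vs direct count."""
    thr = 1.02 * structurals.t1w_cortex_mean
    persist_brute = sum(
        1 for mask in structurals.lesion_masks_t1w
        if np.count_nonzero(structurals.t1w.data[mask] <= thr) >= 1)
    persist_seg = 0
    for true_mask_f, true_mask_t in zip(structurals.lesion_masks_flair,
                                        structurals.lesion_masks_t1w):
        roi_t = seg.LesionROI(mask=true_mask_t, grid="t1w")
        strict = seg.apply_t1w_threshold(roi_t, structurals.t1w.data,
                                         structurals.t1w_cortex_mean)
        if not strict.excluded:
            persist_seg += 1
    assert persist_seg == persist_brute
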