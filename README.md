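# qsmsci

Quantitative MRI analysis of silent cerebral infarcts (SCI): a tested,
end-to-end pipeline that simulates a multi-contrast brain acquisition,
reconstructs magnetic susceptibility (χ) and R2\* maps, segments white-matter
lesions under two radiological definitions, pairs each lesion with a mirrored
contralateral normal-appearing-white-matter (NAWM) control region, and
computes the lesion-vs-NAWM statistics.

## Who this is for

SCI are FLAIR-hyperintense white-matter lesions (≥ 3 mm in greatest
dimension) found in neurologically asymptomatic people — the most common
radiological abnormality in sickle cell anemia. Their tissue composition is
poorly understood. Quantitative susceptibility mapping (QSM) and R2\*
relaxometry probe it non-invasively: myelin is diamagnetic, so myelin loss or
added water raises χ toward zero while lowering R2\*. This package is for
researchers who want a reproducible, fully synthetic test bench for that
analysis: every stage has ground truth, so each estimator and each filtering
rule can be validated quantitatively.

## The model

The multi-echo gradient-echo (ME-GRE) signal per voxel and echo time TE is

    S(TE) = M0 · exp(−R2* · TE) · exp(i(φ0 + 2π f TE)),   f = γ̄ B0 δ · 10⁻⁶

where δ (ppm) is the dipole-convolved field shift of the susceptibility map,
with k-space kernel D(k) = 1/3 − k_z²/|k|² (D(0) = 0) in the B0-aligned
frame. The reconstruction chain is: phase-difference coil combination →
voxelwise Gauss–Newton fit of the complex model → Laplacian/DCT phase
unwrapping → realignment with B0 → projection-onto-dipole-fields (PDF)
background removal → Tikhonov-regularized dipole inversion

    χ̂ = argmin ‖W(Dχ − f)‖² + α‖χ‖²,   α = 0.013 (L-curve selectable),

with the standard global correction for regularization-induced
underestimation. R2\* comes from an ordinary least-squares fit of
ln S against TE (7 echoes, TE₁ = 3 ms, ΔTE = 4 ms at 3 T).

Segmentation applies the two SCI definitions to a generous seed ROI: keep
FLAIR voxels ≥ 1.02 × mean cortical FLAIR intensity (SIT-trial definition),
optionally also require T1w ≤ 1.02 × mean cortical T1w intensity (stringent
definition), enforce the 3 mm rule, resample into the native GRE grid with
nearest-neighbour interpolation, drop ROIs of ≤ 2 voxels, and mirror each
lesion across the mid-sagittal plane into NAWM (shifting in-plane away from
any contralateral lesion). Statistics: paired t-tests, Bland–Altman limits of
agreement, ln(age) residualization, sequential ANOVA over ln(age), disease
group, lobe and ln(volume), Tukey HSD, and Pearson correlations with
cognition scores.

## Worked example

```sh
python analysis/01_simulate_phantom.py        # phantom + acquisitions
python analysis/02_reconstruct_maps.py        # chi and R2* maps
python analysis/03_segment_and_pair.py        # definitions, gates, NAWM pairs
python analysis/04_lesion_vs_nawm_statistics.py
```

The noiseless standard run prints:

```
FLAIR: 9/10 lesions kept (greatest dimension 2.60 mm < 3 mm)
FLAIR+T1w: 7/10 lesions kept (did not persist under the T1w threshold, ...)
FLAIR (n=9): delta-chi = +0.0089 ppm (t=88.36), delta-R2* = -2.50 1/s
FLAIR+T1w (n=7): delta-chi = +0.0089 ppm (t=76.48), delta-R2* = -2.50 1/s
```

The phantom embeds lesions that are +0.0086 ppm less diamagnetic and
−2.5 s⁻¹ slower-relaxing than surrounding white matter. The pipeline
recovers the R2\* contrast exactly (the noiseless log-linear fit is
analytically exact) and the χ contrast to within a few percent — the small
excess reflects residual dipole-inversion bias at α = 0.013. One lesion
fails the 3 mm gate; two more lack any T1w-hypointense voxel and do not
persist under the stringent definition, mimicking the large drop in lesion
count and volume the stricter definition causes on real data.

Equivalent shell entry points: `qsmsci simulate|reconstruct|segment|stats|run-all`.

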