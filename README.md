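# parotidseg

Segmentation toolkit for parotid-like organs-at-risk in planning CT,
built around three valid-convolution U-Net variants (2-D, orthogonal-view
2-D ensemble, 3-D) with two class-balancing training strategies, tiled
full-volume inference, majority-vote fusion, largest-connected-component
postprocessing, and a Dice / signed average-surface-distance evaluation
suite. Synthetic CT-like phantoms with exact ground truth make the whole
pipeline testable end-to-end without clinical data.

Everything runs on CPU with NumPy: the U-Nets (including the backward
pass, batch normalization and Adam) are implemented in
`parotidseg.netarch` and verified against finite differences, so no deep
learning framework is required.

## Highlights

- **Exact architecture arithmetic** — `valid_output_size`,
  `receptive_field`, `min_input_for_output` trace the encoder/decoder
  symbolically. The default 3-level network has a 44-voxel receptive field
  per axis (44×44×88 mm at 1×1×2 mm spacing) and maps a 72×72×56 input
  patch to a 32×32×16 classified center; both facts are cross-checked
  against the constructed network (occlusion probing / actual tensor
  extents).
- **Class balancing** — ROI-restricted slice sampling (5-slice margin in
  view direction, 25-voxel transverse restriction for sagittal/coronal
  views) for 2-D training, and controlled batch composition (exactly 50%
  foreground-overlapping patches per minibatch) for 3-D training.
- **Valid-convolution inference** — tiled prediction equals whole-volume
  prediction exactly, because every output voxel depends only on its own
  mirrored-padded context.
- **Evaluation** — Dice overlap, signed average surface distance in mm
  (positive = overestimation of the reference), Wilcoxon signed-rank
  comparisons, and a nested-subset training-set-size experiment runner.

## CLI

```sh
# generate a phantom cohort with ground-truth masks + manifest CSV
parotidseg phantom --n 30 --out cohort/ --seed 0

# resample to 2 mm slice spacing and mask out the treatment couch
parotidseg preprocess --in ct.nii.gz --out ct_2mm.nii.gz --z-spacing 2.0 --remove-couch

# train (3-D balanced-patch model by default; config via YAML)
parotidseg train --manifest cohort/manifest.csv --out model.npz

# segment a volume (single 3-D model, or a 2-D axial/coronal/sagittal ensemble)
parotidseg predict --model model.npz --in ct_2mm.nii.gz --out seg.nii.gz
parotidseg predict --ensemble a.npz c.npz s.npz --in ct_2mm.nii.gz --out seg.nii.gz

# per-case Dice / signed ASSD for matching files in two directories
parotidseg evaluate --pred preds/ --ref refs/ --out results.csv

# training-set-size experiment on nested subsets
parotidseg size-experiment --manifest cohort/manifest.csv --sizes 5,10,15 --out curves.csv
```

Volumes are read and written as NIfTI (`.nii`, `.nii.gz`) or MetaImage
(`.mha`/`.mhd`); arrays are handled internally in `(x, y, z)` order with
`x` the patient left-right axis.

## Layout

| module | contents |
| --- | --- |
| `parotidseg.volume_io` | `VolumeGrid`/`BinaryMask`, NIfTI + MetaImage I/O, transverse Lanczos resampling, nearest-neighbor mask resampling, couch removal, sagittal mirroring |
| `parotidseg.netarch` | `ArchSpec`/`PatchSpec` tracing, NumPy U-Net with backward pass, soft Dice loss, checkpoints, receptive-field probing |
| `parotidseg.sampling` | ROI computation, slice/patch samplers, nested training subsets |
| `parotidseg.inference_fusion` | tiled 2-D/3-D prediction, majority-vote ensembling, threshold + largest-component postprocessing |
| `parotidseg.metrics` | Dice, border sets, signed distances, ASSD, Wilcoxon, size-experiment runner |
| `parotidseg.phantom` | CT-like phantom generator (body, lateralized glands, distractors, couch, streaks, noise) |
| `parotidseg.training` | Adam, balanced-patch and ROI-slice training loops, batch-norm recalibration |
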