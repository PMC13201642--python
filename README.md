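# wmhkit

A tested library and CLI for the classical computational stack of
white-matter-hyperintensity (WMH) segmentation in brain MRI:

- **Synthetic brain phantoms** (`wmhkit.phantom`) — reproducible 3-D volumes
  with known tissue labels (background, brain B, vessel V, suspected WMH,
  definite WMH), hyperintense lesions, thin vessels, additive noise and a
  smooth bias field, so the whole pipeline is testable without any dataset.
- **Intensity standardization & candidate-lesion detection**
  (`wmhkit.preprocess`) — per-class statistics (N_C, μ_C, σ_C, histogram PDF),
  modal intensity N_PDF, shifted contrast-stretch bounds
  P_min = μ_T′ − 3σ_T and P_max = μ_V′ + 3σ_V, a piecewise rescale of
  [P_min, P_max] onto [1, 255] (0 elsewhere), median/Gaussian denoising,
  z-score + min-max normalization, an adaptive threshold
  T_WMH = μ_B + k·σ_B, morphological opening, lesion volume, tissue-weighted
  composition, and the 200×200 @ 0.5 mm in-plane geometry standardization.
- **Blockwise-DCT image fusion and toy super-resolution**
  (`wmhkit.fusion_sr`) — orthonormal 8×8 DCT, per-block quality
  BQ = (high-band AC energy)/(low-band AC energy) over the JPEG zigzag order,
  winner-takes-the-block fusion with 3×3 majority-vote consistency
  verification, variance-gated patch routing, Sobel enhancement, and a
  three-block convolutional SR mapping trained by particle-swarm search.
- **Particle swarm optimization** (`wmhkit.pso`) — constant-inertia PSO
  (v′ = θv + αε₁(g* − x) + βε₂(x* − x), clamped, reflected at bounds) with
  adapters that tune the segmentation threshold multiplier and opening radius
  against a reference mask.
- **Evaluation metrics** (`wmhkit.metrics`) — weighted Dice loss with
  distance-based weight maps (weight 2 on definite WMH, 1 + f(dis) on the
  suspected rim), DSC, HD95, precision/recall/F1 (voxel- and lesion-level),
  average volume difference, PSNR/MSE, SSIM, and the Universal Quality Index,
  all with explicit defined-ness flags on degenerate inputs.
- **Pipeline & CLI** (`wmhkit.pipeline`, `wmhkit.cli`) — an end-to-end
  phantom → preprocess → PSO-tune → segment → evaluate run with strict YAML
  config validation, NIfTI I/O, and a checksummed manifest for exact
  reproducibility.

## Worked example

Run the full pipeline on a noise-free phantom with two large confluent
lesions and let PSO tune the threshold multiplier k and the opening radius:

```python
import json
from wmhkit import pipeline

cfg = {
    "seed": 2,
    "phantom": {"shape": [48, 48, 32], "noise_sd": 0.0, "bias_amplitude": 0.0,
                "n_punctate": 0, "n_confluent": 2,
                "lesion_radius_range": [5.5, 7.0]},
    "pso": {"n_particles": 6, "max_iter": 8},
}
run = pipeline.RunConfig.from_dict(cfg, out_dir="demo_run")
pipeline.run_pipeline(run)
print(json.load(open("demo_run/params.json")))
print(json.load(open("demo_run/report.json")))
```

which prints (abridged):

```
{"k": 1.4156424698726073, "structuring_radius": 1, "best_loss": 0.0}
{"dsc": 1.0, "hd95": 0.0, "precision": 1.0, "recall": 1.0,
 "f1": 1.0, "avd": 0.0, "dice_loss": 0.0}
```

The tuned threshold sits between the normalized brain and lesion intensity
levels, so the adaptive threshold plus a radius-1 opening recovers the
definite-lesion truth mask exactly: Dice similarity 1.0, 95th-percentile
Hausdorff distance 0 mm, volume error 0 %. On noisy phantoms the same run
reports the full battery of imperfect values, each flagged if undefined.

The same flow is available from the shell:

```bash
wmhkit phantom --out run/ --seed 2
wmhkit run --config cfg.yaml --out run/ --seed 2
wmhkit evaluate --pred run/segmented.nii.gz --truth truth.nii.gz --out report.json
```

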