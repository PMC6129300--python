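# histobench

Benchmarking toolkit for **serial-section 3D histology reconstruction**.

Reconstructing a tissue volume from serial sections means registering a
series of 2D whole-slide images of consecutive physical slices. Different
registration algorithms make very different errors — residual misalignment
between neighboring sections, gradual drift that straightens genuinely
curved anatomy (the "banana problem"), tissue shrinkage — and comparing
algorithms fairly requires a metric panel that separates these effects.
`histobench` provides that panel, three classic baseline aligners, a
ground-truthed synthetic data generator, and an automated hyperparameter
tuner, for researchers developing or selecting 3D histology reconstruction
methods.

## The evaluation model

Let **X**<sub>j,i</sub> be the position of landmark *j* on section *i*
after registration (landmarks travel through any third-party pipeline as
colored disks in companion images, because color survives resampling while
coordinates usually cannot be exported). The panel computes:

- **TRE** (target registration error), per pair of adjacent sections:
  TRE<sub>j,i</sub> = ‖**X**<sub>j,i</sub> − **X**<sub>j,i+1</sub>‖, in µm
  — direct residual misalignment.
- **ATRE** (accumulated TRE), measuring drift through the stack, in two
  variants: ATRE<sub>k</sub> = ‖Σ<sub>i≤k</sub> Σ<sub>j</sub>
  (**X**<sub>j,i</sub> − **X**<sub>j,i+1</sub>)/P‖ for pairwise
  annotations, and the in-plane deviation ‖**X**<sub>j,i</sub> −
  **Y**<sub>j,i</sub>‖ of through-stack fiducials from least-squares 3D
  lines **Y** for column annotations.
- **Jaccard** index |A∩B|/|A∪B| of adjacent tissue masks and **ΔA-%**, the
  relative change in tissue area per section.
- Masked **pixel-wise similarity** (RMSE, NCC, MI, NMI) over overlapping
  tissue pixels only.
- **GLCM smoothness**: Haralick contrast f₂ and correlation f₃ of a single
  across-section gray-level co-occurrence matrix summed over the volume.

TRE, ATRE, Jaccard and ΔA-% are essentially invariant to image resolution;
pixel-wise and GLCM metrics are resolution- and content-dependent and only
comparable within one dataset and scale.

Baseline aligners: **LS** (closed-form least-squares/Procrustes fit to
landmark correspondences), **OPT** (intensity MSE minimization over an
image pyramid) and **SIFT** feature matching with RANSAC. Sequential
pairwise transforms are composed outward from a reference section and
re-applied to mask and landmark stacks; transforms from external tools can
be imported from CSV and scored by the same panel. A reconstruction whose
output canvas grows more than fivefold in either dimension is flagged as a
failure. The tuner minimizes mean pairwise TRE with Gaussian-process
Bayesian optimization (Matérn 5/2 ARD kernel, expected improvement, 2·d
space-filling seed points) or plain random search / grid sweep.

## Worked example

```python
from histobench import (PhantomSpec, generate_phantom, register_stack,
                        opt_aligner, ls_aligner)
from histobench.benchmark import evaluate_alignment

spec = PhantomSpec(n_sections=8, image_size=(192, 192),
                   tissue_radii=(70, 55), curvature_amplitude=5,
                   max_translation=6, max_rotation=4, seed=5)
data = generate_phantom(spec)          # tissue, masks, landmarks, truth

for name, method in [("LS ", ls_aligner(data.landmarks.for_observer(1))),
                     ("OPT", opt_aligner(model="rigid"))]:
    alignment = register_stack(data.tissue, method, reference_index=3)
    report, _, _ = evaluate_alignment(
        alignment, data.tissue, data.masks, data.landmark_stacks(1),
        data.colormap, pairwise_design=True)
    print(name, f"mean TRE {report['TRE'].mean:5.2f} um  "
                f"Jaccard {report['Jaccard'].mean:.3f}")
```

prints

```
LS  mean TRE  1.95 um  Jaccard 0.916
OPT mean TRE  5.58 um  Jaccard 0.982
```

LS, which sees the landmarks, reaches the accuracy floor set by annotation
jitter (~2 px-equivalent here); intensity-based OPT is a few times worse in
TRE but produces the tightest mask overlap — exactly the kind of trade-off
the panel is built to expose. The unregistered stack scores 13.4 µm mean
TRE on the same phantom.

The same run from the shell:

```bash
histobench synth --sections 8 --size 192 --seed 5 --out data/
histobench register --method ls --in data/tissue \
    --landmarks data/landmarks.csv --out transforms.csv
histobench bench run config.toml     # full aligner x resolution table
histobench tune --method opt --space space.json --budget 15 --out trace.csv
```

`bench run` writes `summary.csv` (one row per method × resolution with
µ/max/σ of TRE and ATRE, mean Jaccard, RMSE, f₂, ΔA-%), `metrics_long.csv`
(every per-pair value) and `trajectories.csv` (per-section landmark drift
for 3D trajectory plots).

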