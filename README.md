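# muscleseg

Automatic myofibre segmentation for H&E-stained transverse sections of
adult skeletal muscle, built around coherence-enhancing diffusion
filtering, plus the evaluation statistics used in muscle-biopsy
morphometry.

Detecting variation in fibre size is a first step in diagnosing most
neuromuscular disorders, and it requires segmenting each fibre from the
connective tissue (endomysium/perimysium) that surrounds it. Manual
tracing is slow and operator-dependent; simple thresholding cannot
separate touching fibres; and deformable-model methods struggle with
noisy interiors and weak boundaries. This package implements a
four-stage pipeline that is robust to both:

1. **Pre-processing** — rank-2 non-negative matrix factorisation in
   optical-density space un-mixes the eosin (fibre) and haematoxylin
   (nuclei) stains; the eosin image is rendered so boundaries are light
   and fibre interiors dark, then contrast-limited adaptive histogram
   equalisation sharpens local contrast.
2. **Coherence-enhancing diffusion (CED)** — the image evolves under
   ∂u/∂t = div(D∇u), where D is built per pixel from the structure
   tensor J_ρ = G_ρ∗(∇u_σ∇u_σᵀ): eigenvalue c₁ ≈ 0 across coherent
   structure and c₁ + (1−c₁)·exp(−c₂/(μ₁−μ₂)²) → 1 along it. Boundary
   lines are smoothed along themselves (closing gaps) while myofibril
   speckle inside fibres is flattened.
3. **Morphological filtering** — Otsu threshold (boundary = light),
   removal of components < 750 px, disk-4 closing, complement to get
   the fibre mask.
4. **Marker-controlled watershed** — markers from a 10-px erosion
   (with a distance-peak fallback for thin fibres), flooded on the
   negated Euclidean distance transform to split touching fibres;
   sub-threshold and border-touching regions are then dropped.

Evaluation follows the conventions of the field: one-to-one fibre
accuracy TP/(TP+FP+FN), fragmentation F = p/n (over-segmentation),
congealment C = q/n (under-segmentation), per-image misclassification
percentages with a kernel-smoothed CDF, minor-axis fibre diameters in
µm, and the variability coefficient VC = 1000·sd/mean (VC < 250 is
clinically normal).

Because curated H&E sections with traced ground truth are not freely
available, the package ships a seeded synthetic generator: Voronoi
tessellations of jittered seed points rendered as pink polygonal
fibres with pale endomysial boundaries, peripheral nuclei, speckle
noise at three severities, and optional weakened boundary segments —
with exact label masks by construction. See `docs/methods.md` for the
full model description and its limitations.

## Worked example

```bash
python examples/segment_synthetic_section.py
```

```text
generated 60 fibres on a 512x512 canvas at 0.899 um/px
segmented fibres        : 36 (truth: 36)
fibre accuracy          : 1.000   (matched fibres / all regions; 1.0 = every fibre found once)
fragmentation F         : 0.000   (fraction of fibres split in two or more)
congealment C           : 0.000   (fraction of fibres merged with a neighbour)
misclassification       : 0.36%  (pixel-level disagreement with truth)
mean minor-axis diameter: 53.0 um
variability coefficient : 151.8    (1000*sd/mean of diameters; < 250 is clinically normal)
```

On this low-noise section every one of the 36 interior fibres (60
generated, minus those touching the image border, which are excluded
from scoring on both sides) is recovered exactly once, with no splits
or merges; pixel-level disagreement with the exact ground truth is a
third of a percent, and the diameter statistics land in the normal
adult range. The other scripts in `examples/` demonstrate the CED
filter on a noisy line grid, the evaluation statistics on hand-built
split/merge fixtures, and dataset generation.

The same functionality is available from the shell:

```bash
muscleseg synth --out data/ --n 5 --noise medium --seed 42
muscleseg segment data/synthetic_0042.tiff --out labels.png --overlay overlay.png
muscleseg evaluate pred_dir/ gt_dir/ --out report.json --csv report.csv
muscleseg dump-config --out pipeline.yaml    # all tunables, with defaults
```

## Library surface

```python
from muscleseg import (
    SyntheticSpec, generate_muscle_image,   # synthetic sections + truth
    preprocess, ced, segment,               # the pipeline, whole or by stage
    evaluate, remove_border_fibres,         # scoring
    PipelineConfig, load_config,            # configuration
)
```

Every stage (stain un-mixing, CLAHE, structure tensor, diffusion step,
Otsu, closing, watershed, each metric) is an importable function with
its own contract, so stages can be tested, swapped, or inspected
independently (`muscleseg segment --dump-intermediates` writes one
image per stage).

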