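# gliamorph

Per-cell image quantification of myeloid-cell activation in brain tissue:
segmentation of Iba1+ cells from two-channel confocal stacks, shape-gated
classification into activation states, masked Tmem119 marker-intensity
measurement with a soma/ramification split, plus ddCt qPCR arithmetic —
all exercisable on a built-in synthetic scene generator with per-cell
ground truth.

## The problem

After traumatic brain injury, microglia leave their surveillant ramified
shape and become hypertrophic or ameboid, and blood-borne macrophages
infiltrate the lesion. Iba1 labels all of these myeloid cells, while
Tmem119 is proposed as a microglia-specific marker whose immunoreactivity
collapses in activated cells. Quantifying that collapse requires a
reproducible per-cell pipeline: segment every Iba1+ cell, classify its
morphology, and measure marker signal inside its outline. Because raw
tissue images are rarely redistributable, this package ships a generator
that synthesizes realistic two-channel fields with known ground truth, so
the whole chain is testable end to end.

## The measurements

For each segmented cell footprint the pipeline computes

- **area** `A` (µm²) — pixel count × (pixel size)²;
- **circularity** `C = 4πA / P²`, with perimeter `P` from a sub-pixel
  boundary polygon, clipped at 1 (1 = perfect circle, → 0 for branched
  shapes);
- **class** by fixed gates: *hypertrophic* if `A ≥ 250 µm²`; else
  *ameboid* if `C > 0.16`; else *ramified*. Cells with `C > 0.5` carry a
  *putative infiltrated* flag;
- **marker intensity** — mean gray value of the background-subtracted
  (rolling ball, radius 20 px) Tmem119 projection inside the Iba1
  outline, reported for the whole footprint, the soma (outline opened
  with a 2 µm disk, cutting all ramifications), and the process pixels.

The image chain is: max-intensity z-projection → channel split → Iba1:
rolling-ball 50 px background subtraction, 3×3 mean smoothing, unsharp
mask → constant gray-level threshold → connected components →
morphometry; Tmem119 gets only the rolling-ball 20 px subtraction before
intensity measurement.

The qPCR module implements relative quantification with multiple
reference genes: `CT_ref = mean(CT_refs)`, `ΔCT = CT_ref − CT_goi`,
`ΔΔCT = ΔCT_treated − ΔCT_control`, fold change `E^ΔΔCT` (efficiency
`E = 2` by default). A sample-size helper evaluates
`n = 2σ²·f(α, β)/Δ²` with `f = (z_{1−α/2} + z_{1−β})²`.

## Worked example

```python
import gliamorph as gm
from gliamorph.pipeline import PipelineConfig, preprocess_iba1

# derive the constant segmentation threshold from a cell-free control
ctrl, _ = gm.render_scene(gm.SceneSpec(seed=99, n_cells_per_class={}))
ref = preprocess_iba1(gm.max_project(ctrl)["iba1"], PipelineConfig(threshold_gray=1))
thr = gm.suggest_threshold(ref, 0.999)          # -> 34.9 gray levels

spec = gm.SceneSpec(seed=7, n_cells_per_class={
    "ramified": 6, "hypertrophic": 6, "ameboid": 6})
stack, truth = gm.render_scene(spec)
cells, groups, labels = gm.run_pipeline(stack, PipelineConfig(threshold_gray=thr))
print(groups[["class", "n", "mean", "sd"]])
```

prints (`examples/02_segment_and_classify.py`):

```
       class  n       mean        sd
     ameboid  6  44.777707 14.782530
hypertrophic  6  80.419446 14.970146
    ramified  6 218.253441  3.115812
```

All 18 truth cells are recovered and classified correctly, and ameboid
cells — generated with marker signal near background — show the lowest
mean Tmem119 intensity, the contrast the analysis is designed to detect.
Each script in `examples/` demonstrates one capability (simulation,
segmentation, soma/process split, ROI windows, ddCt, sample size).

A thin CLI mirrors the library:
`gliamorph simulate | run | qpcr | evaluate | samplesize`.

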