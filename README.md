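# aoangio

Motion-contrast angiography for adaptive-optics scanning laser
ophthalmoscopy (AO-SLO), and positive detection of non-perfused
("ghost") retinal capillaries by fusing structural and flow images —
with a synthetic capillary phantom generator providing ground-truthed
inputs, and the study's cohort tables packaged for deterministic
tallies.

## The problem

Early diabetic retinopathy remodels the retinal capillaries — loops,
s-shaped inflections, dilated or saccular segments, microaneurysms —
and eventually shuts individual capillaries down. A non-perfused
capillary is invisible to angiography but still present structurally: a
narrow hyperreflective string on an *en face* reflectance image with no
flow signal in the corresponding motion-contrast map. This package
implements that analysis chain for researchers working with AO-SLO
frame sequences (≈1.5 µm/px, ~12 frames per location):

1. **Registration** (`aoangio.registration`): groupwise B-spline
   registration of all frames to a common space (48 µm control-point
   spacing, normalized-correlation cost, 5-level multiresolution
   pyramid, 128 iterations/level, random sampler).
2. **Angiography** (`aoangio.angiography`): per-pair decorrelation

       D(x,y) = 1 − I₁I₂ / (½I₁² + ½I₂²),

   averaged over the pair set, with the mean image
   I(x,y) = (1/N)ΣIₙ used to zero D below an intensity threshold
   (noise masking).
3. **Fusion** (`aoangio.fusion`): ridge-filter vessel segmentation of
   the structural image, skeleton partition into segments, per-segment
   flow scoring against a null-calibrated threshold, and the composite
   rendering (magenta = perfused, gray = non-perfused).
4. **Phantoms** (`aoangio.phantom`): capillary scenes with known vessel
   ground truth, lesion morphologies, flow modulation, eye motion, and
   sensor noise — every stage is testable without instrument data.
5. **Cohort** (`aoangio.cohort`): the study's participant/lesion tables
   as a validated CSV fixture with deterministic tallies.

## Worked example

```python
from aoangio import (MotionModel, PhantomSpec, generate_phantom,
                     render_frames, render_structural, register_groupwise,
                     perfusion_map, segment_vessels, classify_perfusion,
                     ghost_confusion)

phantom = generate_phantom(PhantomSpec(seed=3))          # 12 segments, 2 ghosts
frames = render_frames(phantom, 12, MotionModel(seed=5),
                       noise_sd=0.02, flow_on=True, seed=7)
result = register_groupwise(frames)
perf = perfusion_map(result.registered)
seg = segment_vessels(render_structural(phantom))
labels = classify_perfusion(seg, perf)
print(ghost_confusion(seg, labels, phantom.perfused_mask,
                      phantom.ghost_mask))
```

prints

```
{'tp': 4, 'fp': 3, 'tn': 111, 'fn': 0, 'unmatched': 0,
 'sensitivity': 1.0, 'specificity': 0.9736842105263158}
```

— of the 118 skeleton segments extracted from the structural image, all
4 overlapping the truly non-perfused capillaries are detected
(sensitivity 1.0) and 111 of 114 perfused segments are correctly
labeled perfused. Over the full 20-seed suite
(`analysis/04_ghost_detection.py`) the aggregate segment-level
sensitivity is 0.93 and specificity 0.99.

The deterministic cohort tallies:

```sh
$ aoangio tally
{
  "patients_with_lesion": {"capillary_loops": 8,
                           "dilated_or_saccular": 4,
                           "microaneurysms": 9},
  "eyes_by_group": {"D": 21, "H": 13},
  "eyes_by_grade": {"none": 1, "very_mild_NPDR": 11,
                    "mild_NPDR": 7, "moderate_NPDR": 2}
}
```

— capillary loops in 8 diabetes patients, microaneurysms in 9; 21
diabetic and 13 healthy study eyes, 11 eyes graded very mild NPDR.

## Command line and analysis drivers

`aoangio` exposes `simulate`, `register`, `angio`, `fuse`, `tally`,
`run` (full pipeline with manifest), and `defaults` (print the YAML
configuration). The numbered scripts under `analysis/` run the study's
computations as narratives and write their tables to `results/`:
phantom census, registration accuracy, perfusion contrast, ghost
detection, cohort tallies.

The cohort CSV schema (one row per study eye):
`participant_id, group (D|H), age, sex, eye (OD|OS, or OU which expands
to both), grade (none|very_mild_NPDR|mild_NPDR|moderate_NPDR), loops,
dilated_saccular, microaneurysms (0/1 flags)`.

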