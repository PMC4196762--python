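# subvoxseg — subvoxel-accurate optimal surface segmentation

`subvoxseg` segments terrain-like surfaces (one per image column, e.g.
retinal layer boundaries in OCT or vessel-wall interfaces after polar
unwrapping) from 3-D volumes by globally optimal graph search, and pushes
the accuracy of that search below the voxel grid with a **non-Euclidean**
variant: the graph nodes are displaced by a cost-derived deformation
field, confined to half a voxel per axis, so that the discrete solution
can land between voxel centers.

## The science

Conventional optimal surface segmentation finds, for each target surface,
one node per image column such that the summed boundary cost is minimal
subject to hard smoothness constraints (neighboring columns may differ by
at most `dx`/`dy`) and, for coupled surfaces, hard separation bounds.
The problem is solved exactly as a minimum-weight closed set via a single
s–t maximum flow, which is what this package implements.

The catch: the solution lives on the integer grid. When the true
boundary sits at `z = k + 0.4`, the conventional result is `k` (or
`k + 1` — a quantization error that averages 0.25 voxel for uniformly
distributed subvoxel phases and can be half a voxel in the worst case.
In thin structures (retinal layers, vessel walls imaged at 0.5–0.7 mm)
this quantization dominates the error budget.

The non-Euclidean variant removes the limitation without refining the
grid:

1. a smooth displacement field is derived from the cost volume (the
   negative gradient of a regularized cost, or optionally a gradient
   vector flow field with a larger capture range),
2. the field is normalized so the **maximum per-axis displacement is
   exactly half the voxel spacing** — nodes stay inside their voxels, so
   column order and graph topology remain valid,
3. the graph is built on the deformed node positions: costs are sampled
   at the displaced locations and smoothness/separation arcs connect
   each node to the bottom-most neighbor node satisfying the constraint
   *in deformed coordinates*,
4. the same max-flow machinery returns surfaces whose heights are the
   deformed (non-integer) z-coordinates.

With zero displacement the construction reduces exactly to the
conventional graph, which the test suite verifies surface-for-surface.

## Worked example

```python
from subvoxseg.benchmark import TWO_LAYER_CONSTRAINTS
from subvoxseg.model import SurfaceSegmentationModel
from subvoxseg.phantom import preset_spec, render_phantom

vol, truth = render_phantom(preset_spec("two_layer", seed=7))
res = SurfaceSegmentationModel(vol, TWO_LAYER_CONSTRAINTS,
                               transitions=("dark_to_bright",) * 2,
                               mode="non_euclidean").fit()
print(res.summary())
```

```
Optimal Surface Segmentation Results
====================================================
mode                        non_euclidean
grid (x, y, z)              (20, 8, 32)
surfaces                    2
smoothness (dx, dy)         (1, 1)
separation bounds           [(3.0, 8.0)]
cost sigma (voxels)         0.3
deformation method          neg_gradient
regularization sigma        0.3
normalization eta           3.21579
max |D|/spacing             0.5
graph nodes                 8960
graph arcs                  50624
max-flow value              113.483
total surface cost          -76.9555
----------------------------------------------------
surface       mean z     min z     max z
0             12.100    10.889    13.226
1             17.600    15.785    19.139
```

```python
rep = res.evaluate(truth)
print(f"mean unsigned error: {rep.mean_unsigned():.4f} voxels")
# mean unsigned error: 0.0625 voxels
```

The conventional mode (`mode="conventional"`) on the same phantom family
averages ≈0.26 voxel unsigned error — the uniform-quantization floor —
while the non-Euclidean mode averages ≈0.07 (see below).

### Command line

```bash
subvoxseg simulate --preset two_layer --seed 11 --out bundle/
subvoxseg segment bundle/input_volume.nii.gz --surfaces 2 \
    --sep-min 3 --sep-max 8 --mode non_euclidean --out seg/
subvoxseg evaluate --bundle bundle/ --out report/
```

`segment` writes `surfaces.tsv`, `thickness.tsv` and `manifest.json`;
`evaluate` scores all three modes against the bundled reference and
writes `error_report.json`. Options can also be given in a YAML file via
`--config` (flags override the file).

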