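# Methods

## Problem and model

Given a 3-D volume on an `(nx, ny, nz)` grid, the task is to find λ
*terrain* surfaces: each surface assigns exactly one z-position to every
`(x, y)` column. Feasibility is hard-constrained:

- **smoothness** — heights of 4-neighbor columns may differ by at most
  `dx` (resp. `dy`) in physical z-units;
- **separation** — for coupled surfaces `i` and `i+1`, the gap in every
  column must lie within `[sep_min, sep_max]`.

Each surface has a per-node boundary cost; the optimum minimizes the
total cost over all feasible surface sets simultaneously. This is
solved exactly, not heuristically.

### Reduction to a minimum closed set

Per column the node weights are the first differences of the column cost
(the bottom node keeps the raw cost), so that the weight of the set of
all nodes at or below height `k` telescopes to the cost at `k`. A
directed arc `u → v` means "if `u` is in the set, `v` must be": intra-
column arcs point downward; smoothness and separation arcs point from
each node to the *bottom-most* node of the neighboring column that
satisfies the constraint. A minimum-weight closed set of this graph is
computed with one s–t maximum flow (source to negative-weight nodes with
capacity `−w`, positive-weight nodes to sink with capacity `w`,
constraint arcs with capacity exceeding the total negative weight). The
surface set is read off as the top of the closed set per column.

To make the coupled problem bounded, each subgraph keeps only the
feasible k-range implied by the separation bounds (plus a margin of
twice the maximum axial displacement when deformed), a base ring
connects the bottom nodes of every column, and one bottom node carries a
shift larger than the total absolute weight so the closed set is never
empty.

### Solver details

- Costs are scaled to integers (default scale `1e6`) for the integer
  max-flow backend; the scale is automatically reduced by decades when
  the scaled weights would overflow 32-bit capacities. Costs that are
  exact multiples of small dyadic fractions are therefore solved
  *exactly*, which the tests exploit for strict equality against
  oracles.
- The returned solution is the **inclusion-minimal** minimum closed set
  (BFS from the source in the residual network), i.e. the lowest optimal
  surface set. The independent dynamic-programming oracle resolves ties
  with the same pointwise-minimum convention, so the two agree not only
  in cost but surface-for-surface; this canonical equality holds because
  the feasible set is a lattice under pointwise min/max and the cost is
  column-separable.
- Two independent oracles back the solver: exhaustive closed-set
  enumeration for small graphs (filters feasibility directly from the
  constraint windows, no shared code with the arc construction) and a 2-D
  dynamic program for single surfaces on B-scans.

## Cost design

The default boundary cost is the negative z-derivative-of-Gaussian
response (signed for dark→bright or bright→dark transitions) with
Gaussian smoothing laterally, computed with reflecting boundaries. The
kernel radius is `max(1, round(4σ))`.

## The non-Euclidean deformation

The displacement field is `D = −∇(G_σ ∗ c)` (negative gradient of the
regularized cost), or optionally a gradient vector flow field, which
diffuses the gradient into flat regions and roughly quadruples the
capture range in the bundled demonstration.

**Normalization.** The field is scaled by `η = 0.5 / max_rel`, where
`max_rel` is the maximum of `|D_axis| / spacing_axis` over all voxels
and axes. After scaling, the extremal components are pinned to exactly
`±0.5 · spacing` (pure scaling can land one ulp off in floating point)
and everything is clipped to that limit. Hence the maximum per-axis
relative displacement equals one half *exactly*, every node stays inside
its voxel, and deformed columns are strictly increasing in z, so graph
topology and column order survive the deformation.

**Deformed graph.** Costs are resampled at the displaced positions by
trilinear interpolation (edge-clamped); smoothness and separation
windows are evaluated on the deformed z-coordinates. The bottom-most
feasible neighbor is found per node; if a separation window is empty
under deformation (possible for windows narrower than two voxels), the
nearest node is used as a fallback and counted in
`SegGraph.fallback_count`. Width-2 or wider windows never trigger the
fallback, because deformed gaps deviate from integer gaps by strictly
less than one voxel on each side.

With `D ≡ 0` the deformed pipeline is bit-identical to the conventional
one; the suite asserts this on every phantom preset.

## Phantom generator

Voxel centers sit at integer coordinates; voxel `k` spans
`[k − 0.5, k + 0.5)`. Boundaries are analytic surfaces (flat offsets,
tilted planes, sinusoids; presets `flat`, `sinusoid`, `two_layer`) and
voxels are rendered by **exact box-averaging** of the piecewise-constant
layer intensities over the voxel extent, so partial-volume values are
exact to machine precision (verified against a supersampling oracle).
Gaussian noise is optional and seeded. A cylindrical phantom plus polar
unwrapping utilities demonstrate the tubular use case.

A high-resolution companion can be rendered at an axial factor `f` and
downsampled by anti-aliased (Gaussian, sd `0.4·f`) block averaging; the
continuous reference maps to the coarse grid as `(z_fine − (f−1)/2) / f`.

### Realism and limits

The generator covers subvoxel phase, tilt, curvature, contrast and
noise, which is what the quantization comparison needs. It does not
model speckle, vessel shadowing, motion, or intensity inhomogeneity, so
absolute error levels on real OCT/MR data will differ; the *relative*
ordering of the modes is the claim under test.

## Benchmarks

- **Quantization benchmark**: 50 seeded two-layer phantoms with
  uniformly random subvoxel phases, segmented by the conventional,
  smoothed-conventional (Gaussian-smoothed integer surfaces) and
  non-Euclidean modes under identical constraints. Uniform phases give
  the conventional mode an analytic 0.25-voxel expected unsigned error,
  anchoring the scale. Scores: mean signed/unsigned surface error,
  thickness error, and the fraction of columns with thickness error
  above 0.5 voxel, with paired t-tests across phantoms.
- **Step recovery**: noise-free flat boundary at `k + φ`,
  `φ ∈ {0.1, …, 0.9}` — pure subvoxel localization with no lateral
  structure.

## Known limitations

- **Global normalization vs anti-aliased inputs.** η is a single global
  factor over all axes. On volumes whose axial gradients have been
  flattened by heavy anti-aliased downsampling while lateral structure
  (tilt, sinusoids) remains sharp, the lateral components dominate
  `max_rel` and the axial displacements become tiny (measured per-axis
  maxima of (0.50, 0.066, 0.006) on such a volume), so the non-Euclidean
  mode degenerates toward the conventional one (0.238 vs 0.241 mean
  unsigned on one such bundle, while the smoothed mode reached 0.097).
  On directly rendered volumes the axial gradient dominates and the
  non-Euclidean mode wins decisively (0.073 vs 0.256). A per-axis or
  locally adaptive normalization would lift this but changes the
  confinement guarantee, so it is left out.
- Empty separation windows narrower than two voxels fall back to the
  nearest node, which relaxes the constraint for those arcs; the count
  is reported so callers can detect it.
- The deformation is derived from the same cost that is optimized; in
  very low-contrast columns the displacement carries little information
  and the result reverts to grid accuracy there.
- Surfaces must be terrain-like in z; tubular objects need the provided
  polar unwrapping first, and the unwrapping requires the axis to lie
  inside the lumen.
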