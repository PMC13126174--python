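# classinet

Classification and spatial mapping of node-link network architectures in
single-molecule localization microscopy (SMLM) images.

Cytoskeletal assemblies such as the actin-spectrin membrane-associated
periodic skeleton (MPS) — an actin-"node" / spectrin-"link" lattice with
~190 nm periodicity — appear in SMLM as sparse, discontinuous localization
clusters. `classinet` reconstructs the underlying network and segments the
image, at 256 nm resolution, into four organizational states: **1D
periodic**, **2D polygonal ordered**, **disordered network**, and
**non-network**. It is aimed at microscopists analyzing STORM/PALM point
clouds of lattice-forming structures, and ships the calibrated simulator
used to validate every module.

Three classifier modules run in sequence over a 1024 nm moving window
(step 256 nm):

1. **Connectivity** — Delaunay-based network reconstruction with a
   biologically constrained link-length window (160–220 nm for
   node-labeled images, keeping the sole out-of-range edge of a triangle
   whose other two edges are in range), scored by the triangle area sum
   Σ_Δ A(Δ) per window and thresholded at the 95th percentile of
   density-matched completely-spatially-random (CSR) nulls — a 5%
   per-window false-positive rate.
2. **1D periodicity** — windowed 2D FFT; the dominant symmetric peak pair
   in the 160–220 nm annulus gives orientation θ and period d, and the
   integrated regularity score S = r_global + r_local − r_global·r_local
   (a probabilistic OR of global and localized grating correlations)
   drives seed region growing with orientation/period consistency
   (Δθ < 15°, Δd ≤ 10 nm).
3. **2D regularity** — per-node similarity of neighbor count, link-length
   and link-angle distributions to the immediate neighbors (inverse
   deviation, Wasserstein-1 for distributions), combined by a linear
   discriminant trained on simulated ordered vs disordered lattices and
   averaged per window.

Residual network pixels are labeled disordered. Utilities cover pixelwise
F1 evaluation, k-nearest-neighbor distances, node inference from
link-midpoint-labeled images (Voronoi-vertex candidates with an
exactly-two-nodes-per-midpoint assembly), actin stress-fiber detection in
conventional fluorescence images, and state-fraction / orientation
statistics relative to the nearest fiber.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Simulate a composite field — an island of 1D periodic lattice (190 nm
line spacing) embedded in a density-matched random background — and run
the full pipeline:

```python
import classinet as cn

island = cn.SimConfig(pattern="1d_periodic", extent=(6144.0, 6144.0), seed=7)
background = cn.SimConfig(pattern="csr", extent=(6144.0, 6144.0), seed=8)
clusters, truth = cn.make_composite(island, background, boundary_seed=3)

result = cn.run_classinet(clusters, cn.PipelineConfig(seed=0))

for code, name in cn.LABEL_NAMES.items():
    print(f"{name:13s} {(result.label_grid == code).mean():.3f}")

pred = result.label_grid == cn.LABEL_1D
f1, precision, recall = cn.f1_metric(pred, truth.island_mask)
print(f"1D-island F1 = {f1:.3f} (precision {precision:.3f}, recall {recall:.3f})")

from classinet.periodic1d import period_histogram
dist = period_histogram(result.oned_mask, result.oned_maps)
print(f"period mode = {dist.mode:.0f} nm, mean = {dist.mean:.1f} nm")
```

Output:

```
outside       0.000
non_network   0.429
oned_periodic 0.569
twod_ordered  0.002
disordered    0.000
1D-island F1 = 0.922 (precision 0.869, recall 0.983)
period mode = 190 nm, mean = 190.4 nm
```

The island (57% of the field here) is recovered as 1D periodic with
pixelwise F1 0.92 against the generator's ground-truth mask, and the
measured period distribution peaks at the simulated 190 nm lattice
spacing. `result` also carries the connectivity heatmaps, the
orientation/period/score maps, the thresholds actually applied and full
provenance.

## Command line

```sh
classinet simulate --pattern 1d_periodic --seed 1 --out sim/
classinet run --clusters sim/clusters.csv --out out/
classinet infer-nodes --in midpoints.csv --out nodes.csv
classinet evaluate --pred out/labels.tif --truth sim/truth_labels.tif --label 2
```

`run` writes the label map (8-bit TIFF; codes 0 outside, 1 non-network,
2 1D periodic, 3 2D ordered, 4 disordered), all score heatmaps (32-bit
TIFF) and a JSON provenance sidecar.

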