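# cabbage3d

Quantification and classification of leafy-plant architecture (plant type)
from single-plant 3D point clouds, built around heading Chinese cabbage
(*Brassica rapa* ssp. *pekinensis*).

Plant type — whether a rosette is full-bodied, tall and lean, tightly headed,
or widely spread — drives yield and management decisions, but is usually
scored by eye.  This package replaces that with a reproducible pipeline:

1. **Preprocessing** — color-gate foliage points, remove statistical
   outliers, rotate the cloud into a PCA-canonical frame that keeps the
   botanical vertical on Z, normalize to a unit Chebyshev box, and
   farthest-point-sample to a fixed point count.
2. **Ten shape traits** per plant, computed on the canonical cloud:
   - height-to-spread ratio `T = H / D` (max Z extent over max horizontal
     diameter),
   - mean leaf inclination `θ̄ = mean arccos|nᵢ·ẑ|` in degrees, from local
     plane-fit normals on the middle vertical third,
   - radial dimension difference `W = max(dᵢⱼ) − min(dᵢⱼ)` over XY hull
     vertices,
   - convex-hull volume `V = Σ |rᵢ·(rⱼ×rₖ)|/6` and surface `S = Σ |…|/2`,
   - projection areas `S1, S2, S3` (XZ, YZ, XY hull areas),
   - head roundness `O = A / A_c` (XY hull area over its minimum enclosing
     circle),
   - symmetry `M = (1/K) Σ σₖ²`, the mean over axial slabs of the variance of
     point-to-main-axis distances.
3. **Plant-type discovery** — z-score the trait matrix, cluster by K-medoids
   (Voronoi iteration, restarts, deterministic tie-breaks), pick k by the
   silhouette coefficient over k = 2..8 (the k-means WCSS elbow is reported
   as a second diagnostic), and name the four clusters by deterministic
   rank-sum rules on their centroid traits (FULL, HIGHLY_LEAN, TIGHT,
   ROUND_SPREAD).
4. **Supervised classification** — a hierarchical set-abstraction point-cloud
   encoder (FPS sampling, radius-ball grouping, shared per-point MLPs,
   symmetric max-pooling; single- or multi-scale) produces a 1024-dim
   embedding that is fused with the 10 z-scored traits into a 1034-dim
   vector classified by a fully connected head.  Implemented in numpy with
   hand-written backprop; it trains in minutes on one CPU at desk scale.
5. **Synthetic rosettes** — a parametric generator for the four
   architectures (arc-bent leaf patches around a vertical axis) plus
   rotation/scale/noise augmentation, so the whole pipeline is testable
   without access to any scan collection.

## Worked example

```python
from cabbage3d import (ARCHETYPES, TypeLabel, generate_cabbage,
                       pca_align, normalize, compute_traits)

pc = generate_cabbage(ARCHETYPES[TypeLabel.TIGHT], n_points=2000, seed=7)
aligned, _ = pca_align(pc)
canonical, _ = normalize(aligned)
tv = compute_traits(canonical)
for name, value in tv.as_dict().items():
    print(f"{name:10} {value:8.4f}")
```

prints

```
T            1.2970
theta_bar   63.0775
W            0.8384
V            0.1730
S            1.8710
S1           0.5556
S2           0.4598
S3           0.3729
O            0.5226
M            0.0024
```

A tight-headed plant reads exactly as expected: taller than wide (`T` ≈ 1.3),
steep leaf surfaces (`θ̄` ≈ 63°), and — because traits are computed on the
unit-normalized cloud — small unit-free hull volume, surface and projection
areas compared with the other architectures.  Feeding a table of such rows to
the clustering stage recovers the four planted types:

```bash
cabbage pipeline --n-per-class 25 --seed 7 -o demo/
# -> traits.csv, typed.csv with cluster ids and type names, JSON sidecars
```

The same stages are available individually as `cabbage simulate / preprocess /
extract / cluster / train / classify / evaluate`.

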