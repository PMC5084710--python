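# apexkit

Quantitative tools for studying **oriented tissue growth in the shoot
apex** — how the upper stem is built by the orientation of cell divisions
in the rib zone below the meristem summit — together with the ChIP-seq
analysis used to find the transcription-factor targets that control it.

The package covers four analyses that in the literature are usually run as
ad-hoc scripts:

1. **New-wall detection and 3D orientation** (`apexkit.walls`,
   `apexkit.geometry`). In tissue stained with a cross-linking cell-wall
   dye (e.g. modified pseudo-Schiff propidium iodide), recently formed
   walls are thinner and fluoresce less. Given a segmented 3D label volume
   and the co-registered stain volume, the package measures the mean stain
   density of every cell–cell facet and calls a facet a *new wall* when it
   is the weakest facet of **both** adjacent cells. Each called wall's
   best-fitting plane is estimated from its voxel-face midpoints (normal =
   eigenvector of the smallest eigenvalue of the centered second-moment
   matrix), and its orientation is summarised by two angles of the plane
   normal **n**, both folded into [0°, 90°]:
   - angle to the stem main axis **a**: `arccos |n · a|` (transversal wall
     → 0°, wall containing the axis → 90°);
   - radial angle: `arccos |n · r̂|`, where **r̂** is the radial direction
     at the wall's centre of mass (wall facing the central axis → 0°, wall
     containing the radial direction → 90°).
2. **Zonation statistics** (`apexkit.zonation`). Walls are assigned to the
   standard regions in depth-below-summit × radius-from-axis windows —
   apical region AR (0–30 μm, 0–40 μm), rib-meristem core RC (30–60 μm,
   0–40 μm), rib-meristem periphery RP (30–60 μm, 40–50 μm) — and angle
   distributions are compared by the two-sided Mann–Whitney U test (exact
   tie-aware enumeration for min(n₁, n₂) ≤ 8, tie-corrected normal
   approximation otherwise).
3. **Clonal sector analysis** (`apexkit.sectors`). Recombination-marked
   clones, landmarked with one point per cell, are rigidly aligned across
   apices (summit → origin, main axis → +z), then each sector's centre of
   mass, principal axis, vertical and radial angles, cell count and
   main-axis length are measured and compared per region.
4. **ChIP-seq consensus peaks and positional enrichment**
   (`apexkit.peaks`). From three treatment and three control narrowPeak
   replicate sets: keep the intervals covered by a peak with q ≤ 10⁻³ in
   every treatment replicate, at least 50 nt long and free of any control
   peak; attribute each consensus region (by its centre) to gene models
   within 3 kb upstream / 1.5 kb downstream of the coding sequence,
   strand-aware, with no intervening coding sequence; test
   promoter+downstream concentration of peak centres against peaks placed
   uniformly at random within the attributed genes' extended spans
   (Monte Carlo, default 10,000 simulations,
   `p = (1 + #{sim ≥ obs}) / (n_sims + 1)`); and export observed ±75 nt
   and 10× random control sequence windows for motif discovery. A
   two-sided Fisher exact test for gene-set overlaps is included.

Because the original imaging and sequencing data are not required,
`apexkit.simulate` provides seeded generators for every input — dome-shaped
tessellated tissue with planted divisions of known plane orientation,
clonal sectors grown along known directions, and toy genomes with
positionally biased replicate peaks — each with a ground-truth table, so
the whole toolkit is testable end to end.

## Worked example

```python
import numpy as np
import apexkit as ak

# a synthetic apex: ~2,000 cells, 100 planted divisions with known planes
vol, stain, frame, truth = ak.generate_meristem(ak.MeristemSimParams(seed=1))

facets = ak.detect_divisions(vol, stain, frame=frame, regions=ak.default_regions())
called = [f for f in facets if f.is_new_wall]
print(len(facets), "facets,", len(called), "called as new walls")
# -> 10980 facets, 100 called as new walls

ev = ak.evaluate_detection(facets, truth)
print(ev["recall"], ev["precision"], np.median(ev["normal_errors_deg"]))
# -> 1.0 1.0 1.92   (all 100 planted walls found, no false calls,
#                    plane normals within ~2 degrees of the planted planes)

sa = ak.zonation.angle_samples(facets, frame, metric="angle_to_axis")
u, p = ak.compare_angles(sa["RC"], sa["RP"])
print(np.median(sa["RC"].values), np.median(sa["RP"].values), p)
# -> 2.6 83.1 7.2e-13
```

The rib-meristem core shows transversal new walls (median angle to the
axis 2.6°), its periphery anticlinal walls (83.1°), and the Mann–Whitney
comparison of the two distributions is overwhelming (p ≈ 7 × 10⁻¹³) — the
quantitative signature of organised rib-zone growth that the toolkit is
built to measure. `ak.summarize_by_region(facets, frame)` returns the
matching boxplot table (n, median, quartiles by the Hazen rule, 1.5×IQR
whiskers, outliers).

The same volume can be analysed from the shell:

```sh
apexkit simulate meristem --seed 1 --out-dir sim/
apexkit detect-walls --labels sim/labels.tif --intensity sim/intensity.tif \
    --spacing-z 1 --spacing-y 1 --spacing-x 1 \
    --frame sim/frame.yaml --out facets.csv
apexkit zonation --facets facets.csv --frame sim/frame.yaml --out summary.csv
```

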