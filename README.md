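# orchard3d

Per-tree 3D phenotyping of orchards from UAV digital surface models (DSMs):
automatic crown delineation, projected canopy area / tree height / crown
volume per tree, and multi-temporal quantification of pruning impact, annual
growth and restoration.

## The problem

Characterizing how pruning reshapes tree architecture normally means
measuring crown dimensions tree by tree with a ruler — slow, and inconsistent
on irregular crowns. UAV photogrammetry offers an alternative: overlapping
aerial images are photo-reconstructed into a DSM, a raster of
terrain-plus-canopy elevations in which every tree is a local elevation high.
`orchard3d` turns such DSMs into a per-tree inventory for an intensively
planted orchard (the reference layout is 27 rows x 24 trees at 8 x 4 m
spacing, 648 trees, three pruning treatments in 9-row blocks) and compares
inventories across acquisition dates (before pruning, after pruning, one year
after pruning).

## The algorithm

Delineation is object-based and purely height-driven:

1. **Chessboard segmentation** — the DSM is partitioned into 1 m² square
   tiles anchored at the raster origin.
2. **Coarse classification** — a tile is *tree* iff the standard deviation of
   its DSM values exceeds 0.10 m (strictly); canopy is rough at the meter
   scale, bare soil is flat.
3. **Border refinement** — tiles on (and, in dense plantations, inside) the
   canopy zone are re-examined pixel by pixel against the surrounding soil
   and tree elevations; refined tree pixels are labeled into 8-connected
   components, one per tree.
4. **Feature loop** — for each tree *i* with crown pixel set `C_i`, pixel
   area `p²` and local bare-soil reference `z_soil` (mean soil DSM in a 1 m
   ring around the crown):

   - projected canopy area `A_i = |C_i| · p²`  (m²)
   - tree height `H_i = max_{x ∈ C_i} DSM(x) − z_soil`  (m)
   - crown volume `V_i = p² · Σ_{x ∈ C_i} max(0, DSM(x) − z_soil)`  (m³)

   plus the plantation-grid identity (row, column) from the crown centroid,
   which keys the tree across dates.

For matched trees on two dates, the signed percent change of a feature is
`% = 100 · (f_later − f_earlier) / f_earlier`; per-treatment tables report
mean ± sample SD of the deltas and the mean per-tree percentage for the three
standard comparisons (impact, annual growth, restoration), and annual volume
growth is stratified by pruning-severity class (<10%, 10–30%, 30–50%, >50% of
crown volume removed).

Because no real imagery ships with the package, a **synthetic orchard
simulator** provides test beds with exact analytic ground truth:
half-ellipsoid crowns on smooth terrain, rendered as an opaque-from-above
canopy DSM, with traditional / adapted / mechanical pruning and
severity-dependent horizontal regrowth (see `docs/methods.md`).

## Worked example

Run the built-in demo (a 6 x 6 synthetic orchard, three dates, two rows per
treatment):

```sh
orchard3d run --demo --seed 1 --out-dir demo_run
```

prints the per-date tree counts

```json
{"Date 1": 36, "Date 2": 36, "Date 3": 36}
```

and writes DSM GeoTIFFs, truth tables, per-tree feature tables
(`trees_date_*.csv`), the analysis tables and a `manifest.json` with every
parameter and seed. The feature table starts like

```
tree_id  row  column      x       y    treatment    date  area_m2  height_m  volume_m3
     32    1       1  -0.17   -0.13  traditional  Date 1     9.33      4.02      26.94
     31    1       2   3.93    0.05  traditional  Date 1     9.15      3.78      24.85
```

— tree (1,1) has a 9.3 m² crown, is 4.02 m tall and holds 26.9 m³ of
DSM-visible crown volume. `impact.csv` (date 2 vs date 1) for this run:

```
  treatment  n_trees  area_pct  height_mean  volume_pct
    adapted       12    -44.30        -0.00      -44.31
 mechanical       12     -0.08        -0.23       -0.82
traditional       12    -37.58        -0.00      -37.57
```

i.e. adapted pruning removed ~44% of crown volume with no height change,
while mechanical topping lowered trees by 0.23 m on average — the signatures
of the two pruning styles. `growth.csv` shows the heavily pruned blocks
regrowing fastest over the following year (≈58% volume growth vs ≈24% for
mechanical).

The same stages are available separately (`orchard3d generate`,
`orchard3d delineate --dsm ...`, `orchard3d features`, `orchard3d compare`)
for use on real DSM GeoTIFFs.

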