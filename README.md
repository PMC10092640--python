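# epilayer

Unbiased classification of the 3D architecture of cultured epithelial cell
layers.

Cultured epithelia (MDCK and similar lines) that look like tidy cobblestone
monolayers from the top down can be flat sheets, domed cobblestones, tall
columnar monolayers, or multilayered disorder when viewed along the
apical-basal axis — and all of these can coexist within one culture well.
`epilayer` classifies each imaged field into one of four architectures —
**Immature**, **Intermediate**, **Mature**, or **Disorganized** — from two
routine stains: segmented nuclear centroids (DAPI/Hoechst) and an F-actin
confocal z-stack (phalloidin). It also quantifies layer height, nuclear
density, in-layer vs. apically attached cells, subregion heterogeneity,
in-plane cell shape, per-cell apical/basal actin polarization, and
monolayer fluidity from live movies. A synthetic-data module generates
class-labeled fields with known ground truth, so the whole pipeline is
testable without microscope data.

## The method

For a field of nuclei with centroid heights `z_i` and an actin stack
`I(z, y, x)`:

1. **Volume filter.** Debris is removed per field: objects with volume
   `v <= mean(v) − k·SD(v)` are excluded (`k = 1.5`; `k = 1` in the
   stricter pyknotic mode). No upper cutoff.
2. **Nuclear z histogram.** Counts in 1 µm half-open bins from `z = 0`.
3. **Actin z profile.** `A(z) = Σ_{x,y} I(z, y, x)`, normalized to peak 1.
4. **Layer bounds.** Bottom = first z where `A` rises above a fraction
   (20–50 % of peak, increasing with nuclear density) of the peak; top =
   last z above a second fraction (60–80 %). Crossings are linearly
   interpolated.
5. **Organized vs. Disorganized.** One- and two-component Gaussian curves
   are fitted to the binned counts (weighted least squares) and compared by
   an extra-sum-of-squares F-test at α = 0.05. A single sharp peak
   (σ ≤ 3 µm) or a monolayer-sharp basal peak with mass above it is
   Organized; a wide peak or broad overlapping components is Disorganized.
6. **Maturity.** Organized layers with the actin peak at/below the nuclear
   peak, or in the basal half of the layer, are Immature. Otherwise the
   smoothed derivative `dA/dz` is examined: two peaks with right/left
   ratio > 1 (a lateral "shoulder" then a brighter apical band) is Mature;
   a single peak or ratio ≤ 1 is Intermediate.
7. **Counts.** Nuclei are partitioned into in-layer and apical by component
   likelihood (two-peak case) or a 3σ rule (single peak).

Fluidity is quantified by the movie autocorrelation
`C(T_k) = (1/(N−k)) Σ_t (1/M²) Σ_{ij} Î_t ∘ Î_{t+k}` over normalized frames
`Î` (scale −1…1), with an exponential-decay fit giving the correlation
half-life `ln 2 / λ`.

## Worked example

```sh
python examples/classify_field.py
```

```
label:              Mature
nuclei (kept/all):  166/180
layer bounds (um):  2.12 .. 8.40
layer height (um):  6.28
density (10^3/mm2): 7.38
in layer / apical:  166 / 0
actin peak (um):    8.00
nuclear peak (um):  4.47
shoulder ratio:     1.50
```

A synthetic 150 × 150 µm field generated at Mature reference conditions
(8 × 10³ cells/mm², 7 µm layer) is classified Mature: 14 debris objects
were filtered out, the actin-derived layer spans 2.1–8.4 µm, and the
derivative of the actin profile is two-peaked with ratio 1.50 > 1 — the
apical actin band above the lateral shoulder. The other scripts in
`examples/` demonstrate subregion tiling, in-plane shape metrics, the
polarization ratio, and the fluidity half-life.

The same operations are available from a thin CLI:

```sh
epilayer synth --scenario mature --seed 7 --field 150 --out demo/
epilayer classify --actin demo/stack.tif --nuclei demo/nuclei.csv \
    --voxel-xy 0.3 --voxel-z 0.23 --out report.json
epilayer subregions --actin demo/stack.tif --nuclei demo/nuclei.csv \
    --voxel-xy 0.3 --voxel-z 0.23 --tile 100 --out tiles.json
```

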