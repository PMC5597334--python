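# lgquant

Quantitative 3D image analysis for *Drosophila* lymph-gland hematopoiesis.

The larval lymph gland is the fly's hematopoietic organ: progenitor cells
(prohemocytes) in the medullary zone differentiate into plasmatocytes,
crystal cells and lamellocytes under the control of a small posterior niche
(the PSC), which is sealed off by a septate-junction permeability barrier.
Experiments on this system produce multi-channel confocal z-stacks (a
DAPI nuclear channel, one or more antibody/reporter marker channels, and in
barrier assays two fluorescent dextran dye channels), and the biology is
read out through a handful of image-derived numbers. `lgquant` implements
that readout as a tested, scriptable pipeline:

- **Nuclei counting** — every z-slice of the nuclear channel is band-pass
  filtered with a difference of Gaussians, `G(σ_small)∗I − G(σ_wide)∗I`
  (the wide kernel removes background, the small one removes sub-nuclear
  speckle), the 3D response is thresholded (Otsu by default) and bright
  spots are extracted as 3D connected components, optionally split by a
  distance-transform watershed. Each nucleus gets a physical centroid and
  an equivalent-sphere radius `r = (3V/4π)^{1/3}`.
- **Marker classification** — for each nucleus, the mean marker intensity
  is taken over a search sphere of radius `1.5 × r̄` (1.5 times the mean
  nuclear radius) around its centroid; cells whose sphere mean reaches the
  marker threshold are called positive.
- **Differentiation index** — the exact ratio
  `DI = N_marker-positive / N_total` over the primary lobe (or any ROI),
  e.g. a plasmatocyte index and a crystal-cell index per specimen. The same
  machinery yields PSC cell counts and circulating hemocyte subset counts.
- **Permeability-barrier assays** — mean dye-influx intensity in an ROI,
  and the dual-dye assay: Pearson correlation r of the 40 kDa and 70 kDa
  dextran channels over PSC vs non-PSC ROI voxels. An intact barrier
  excludes the large dye from the niche, so PSC r collapses; barrier loss
  makes the dyes colocalize (high r).
- **Group statistics** — unpaired Welch t-tests
  (`t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b)` with Welch–Satterthwaite
  degrees of freedom), fold changes, and mean/sd/sem summaries as tidy CSV.
- **Synthetic scenes** — a ground-truthed generator of lymph-gland-like
  stacks (Gaussian-blob nuclei, shell-shaped marker halos, dye channels
  with a configurable exclusion ellipsoid, Poisson + Gaussian noise), so
  every stage can be validated against a known answer.

## Worked example

```python
from lgquant import (NoiseModel, SceneParams, analyze_specimen,
                     render_scene, sample_scene)

params = SceneParams(shape=(32, 128, 128), n_nuclei=80, psc_count=0,
                     marker_fractions={"plasmatocyte": 0.3})
scene = sample_scene(params, seed=42)
volume = render_scene(scene, NoiseModel())          # default confocal noise
result = analyze_specimen(volume, "dapi", ["plasmatocyte"])

print(f"detected nuclei      : {result.n_cells} (truth: {len(scene.nuclei)})")
print(f"mean nuclear radius  : {result.mean_radius_um:.2f} um "
      f"(truth: {scene.mean_radius_um():.2f} um)")
rep = result.report
print(f"plasmatocyte index   : {rep.index['plasmatocyte']:.3f} "
      f"= {rep.positives['plasmatocyte']}/{rep.total_cells} "
      f"(truth: {scene.true_index('plasmatocyte'):.3f})")
```

prints

```
detected nuclei      : 80 (truth: 80)
mean nuclear radius  : 2.46 um (truth: 2.51 um)
plasmatocyte index   : 0.312 = 25/80 (truth: 0.300)
```

All 80 simulated nuclei are found at realistic noise, the mean radius is
recovered within 2%, and the differentiation index lands within 0.012 of
the 0.30 ground truth (25 of 80 detected cells called plasmatocyte-positive).

The same stages are available from the shell:

```sh
lgquant simulate --config scene.yaml --seed 1 --out stack.ome.tif --truth truth.csv
lgquant count    --in stack.ome.tif --nuclear-channel dapi --out nuclei.csv
lgquant classify --in stack.ome.tif --nuclei nuclei.csv --markers plasmatocyte --out cells.csv
lgquant index    --cells cells.csv --nuclei nuclei.csv --out report.csv
lgquant dda      --in stack.ome.tif --roi-psc psc.json --roi-other rest.json --out dda.csv
lgquant compare  --table report.csv --group-col condition --value-col index --out stats.csv
lgquant run      --config experiment.yaml        # whole pipeline + manifest
```

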