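# psdnano

Quantitative analysis of nanoscale protein organisation at the postsynaptic
density (PSD) of glutamatergic synapses.

Superresolution imaging shows that the scaffold proteins SynCAM 1 and MPP2
do not overlap the central PSD marker (PSD-95 / Homer1) but form small
peripheral nanoclusters arranged in a ring — a "bracelet" — around it, and
that MPP2 co-clusters with GABA_A receptor subunits at that periphery.
`psdnano` implements the full quantitative tool-chain behind such claims,
for researchers analysing single-molecule localization microscopy (dSTORM),
3D structured-illumination (SIM) stacks, confocal spine images, and
comparative isotope-label pull-down proteomics:

- **`psdnano.locio`** — localization-table I/O, the 20 nm precision filter,
  constant-width (FWHM 20 nm) Gaussian rendering.
- **`psdnano.cluster`** — DBSCAN nanocluster detection (ε = 20 nm, min 5
  points), longest-axis sizing, 15 nm size histograms, algebraic circle
  fits for bracelet-ring diameters, and a sector-occupancy bracelet score.
- **`psdnano.segment3d`** — 3D segmentation of anisotropic voxel stacks:
  Otsu/Yen threshold segmentation, seeded-watershed blob finding for PSD
  anchors, sphericity (ψ = π^⅓(6V)^⅔/A) and volume filters,
  equivalent-sphere radii, and synapse assembly by a 2–2.5 μm cutoff.
- **`psdnano.spatial`** — 3D radial intensity profiles around PSD centres,
  directional nearest-neighbour (NN) distances between cluster centres or
  surfaces, and two null models: complete spatial randomness (CSR) in/on a
  0.8 μm postsynaptic sphere with 95% envelopes, and a 20 nm toroidal
  shift.
- **`psdnano.spines`** — confocal pipeline: MAP2 skeletonization, puncta
  detection (Otsu/Yen/moments thresholds + maxima), the 2 μm
  dendrite-proximity filter, and per-spine co-occurrence of Homer1, MPP2
  and GABA_A receptor puncta within a 0.5 μm perimeter.
- **`psdnano.proteomics`** — two-bait ¹⁶O/¹⁸O pull-down enrichment:
  intensity-weighted protein ratios, inverted-label orientation, GST
  normalisation, quantification filters (both replicates, ≥ 2 peptides,
  geometric SD < 2), quadrant classification and >7-fold selection.
- **`psdnano.simulate`** — synthetic-data generators for every input above,
  each with an explicit ground-truth record, so that every analysis stage
  is validated by parameter recovery.
- **`psdnano.workflow` / `psdnano.cli`** — YAML-configured staged pipeline
  with a run manifest, TSV/figure reports, and a `psdnano` console script
  (`run`, `simulate`, `storm-cluster`, `nn`, `spines`, `proteomics`, …).

## Worked example

Simulate one bracelet synapse at the measured geometry (PSD disc ~448 nm;
SynCAM 1 ring ~894 nm; MPP2 ring ~791 nm diameter), then run the dSTORM
analysis chain on the SynCAM 1 channel:

```python
from psdnano import simulate, locio, cluster

geometry = simulate.BraceletGeometry(bracelet_probability=1.0)
tables, truth = simulate.simulate_bracelet_synapse(geometry, seed=42)

locs = locio.filter_by_precision(tables["SynCAM1"], max_uncertainty=20.0)
print(f"{len(tables['SynCAM1'])} localizations, {len(locs)} after precision filter")

clusters = cluster.detect_clusters_dbscan(locs, cluster.ClusterParams(epsilon=20.0, min_points=5))
print(f"{len(clusters)} nanoclusters (longest axis "
      f"{clusters.clusters.longest_axis.median():.0f} nm median)")

ring = cluster.estimate_ring_diameter(clusters.centroids)
print(f"ring diameter {ring.diameter:.0f} nm (true {truth.ring_diameter_a:.0f} nm), "
      f"residual {ring.residual:.0f} nm")

score = cluster.classify_bracelet(clusters.centroids[:, :2], truth.centre)
print(f"bracelet score {score.score:.2f} -> {'bracelet' if score.is_bracelet else 'non-bracelet'}")
```

Output:

```
321 localizations, 320 after precision filter
12 nanoclusters (longest axis 40 nm median)
ring diameter 856 nm (true 871 nm), residual 29 nm
bracelet score 0.75 -> bracelet
```

The 12 detected nanoclusters are the satellite clusters of the ring (some
split by DBSCAN at ε = 20 nm); the circle fit through their centroids
recovers this synapse's true ring diameter to within ~2%, and the sector
occupancy score classifies the arrangement as a bracelet.  The same chain
runs from the shell via `psdnano simulate` and `psdnano storm-cluster`.

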