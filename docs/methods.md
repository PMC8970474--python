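# Methods

This note documents the models, parameter choices, and numerical decisions
behind `psdnano`, and states what the synthetic-data validation does and
does not demonstrate.

## The bracelet model

The package's geometric motif is a synapse in which a central
postsynaptic-density (PSD) marker occupies a disc of ~448 nm diameter while
two peripheral scaffold species (SynCAM 1, MPP2) form small nanoclusters on
surrounding rings of ~894 and ~791 nm diameter.  Roughly 65% of synapses
show this bracelet arrangement; the remainder are modelled as unstructured
peripheral label (uniform in a disc of the ring diameter), since no
alternative morphology is established.

### dSTORM generator (`simulate.simulate_bracelet_synapse`)

Per synapse: the central species is uniform in its disc; each peripheral
species places 6 satellite nanoclusters (isotropic Gaussians, σ = 40 nm,
50 localizations each) at jittered equal angles on its ring.  Localization
precision is drawn per detection from N(10, 4²) nm (clipped at 0.5 nm),
added as positional jitter, and recorded in the uncertainty column — so the
20 nm precision filter is meaningful.  Background localizations are Poisson
at 5 μm⁻² over a 2 μm field.  Synapse sizes vary across the population: a
common log-normal synapse-size factor plus per-structure jitter,
mean-corrected, reproduces the reported across-synapse spreads
(SD ≈ 105 / 162 / 209 nm for disc and rings) while keeping ring > disc
structurally.  Setting the SD fields to zero restores a fixed geometry.

Populations derive per-synapse seeds as `seed + index`, so growing a
population never changes earlier synapses.

### Voxel-scene generator (`simulate.simulate_voxel_scene`)

SIM-like anisotropic stacks (40 nm lateral, 125 nm axial voxels).  The
central PSD is deposited as a uniform ball of the disc radius — a filled
structure is what gives the radial profile its half-maximum at the disc
radius; a Gaussian blob would not.  Satellites are Gaussian blobs on a ring
of random 3D orientation; a presynaptic-marker blob sits 200 nm along the
ring normal.  All channels are blurred with an isotropic 80 nm PSF
(anisotropy-corrected per axis) and optionally given Gaussian read noise.
Blob masses are analytically normalised, so channel sums scale linearly
with the configured localization counts.

### Confocal generator (`simulate.simulate_confocal_scene`)

A dendrite polyline rendered as a thick filament (MAP2 channel), Homer1
puncta on spines 0.6–1.5 μm from the shaft, one scaffold (MPP2) punctum per
spine within 250 nm, and — for a Bernoulli fraction of spines — a receptor
punctum within 250 nm.  Receptor-only puncta on the shaft mimic inhibitory
synapses.  Spines are placed in stratified arc-length slots so neighbouring
spines stay separated beyond the 0.5 μm co-occurrence perimeter: the
per-spine scoring procedure presumes resolvable spines, and without the
separation a punctum belonging to one spine can flag its neighbour
(measured +0.09 bias at a truth fraction of 0.5 under uniform placement).

### Peptide-table generator (`simulate.simulate_peptide_table`)

Two replicates with inverted label orientation; peptide ratios are the true
protein ratio times log-normal noise (σ of ln ratio, default 0.1);
log-normal intensities; GST always present.  `study_peptide_config` encodes
the study condition: 188 prey proteins of which the seven GABA_A receptor
subunits are planted 10–30-fold enriched toward the MPP2 bait, a dozen
PSD-95-side interactors, and near-unity background.

## Analysis stages

**Precision filter and rendering.**  Localizations with uncertainty worse
than 20 nm are excluded; the boundary value is kept (the stated rule
excludes values *worse than* the threshold).  Rendering places a unit-mass
isotropic Gaussian per localization; "constant width 20 nm" is interpreted
as FWHM (σ ≈ 8.49 nm), switchable to a σ-interpretation.  Images use the
image convention (y down) with half-open bins.

**Nanoclusters.**  DBSCAN with ε = 20 nm and a minimum of 5 points, the
point itself counted toward its own neighbourhood (the original-algorithm
convention; implementations differ).  Border points are assigned
deterministically given input order; the test suite holds the partition
equal to an exhaustive density-reachability closure.  Cluster size is the
exact maximum pairwise distance (convex-hull pruned for large clusters).
Size histograms use 15 nm half-open bins with a terminal ≥400 nm pool.

**Ring estimation.**  Manual line-tool measurements are replaced by an
algebraic (Kåsa) least-squares circle fit through peripheral cluster
centroids: exact on noiseless circles for any ≥3 non-collinear points;
under-supported or collinear input returns a flagged undefined estimate.
On synthetic bracelets the recovered mean diameter carries a small
(~1–2%) outward bias from centroid jitter — well inside the 5% recovery
band the tests assert.

**Bracelet score.**  score = (fraction of 8 angular sectors occupied by
peripheral cluster centroids) × (1 − fraction of centroids inside a 250 nm
central void), classified bracelet at ≥ 0.5.  This is a heuristic stand-in
for manual assessment, validated purely against generator truth (recovered
prevalence within ±0.07 of truth over 200 synapses).

**3D segmentation.**  Peripheral channels: physical-unit Gaussian
smoothing, percentile background subtraction (a 3D rolling ball is
needlessly slow and the underlying procedure names no algorithm), threshold
at max(Otsu, Yen) — the conservative combination, configurable — and
26-connected labelling.  Anchor channel: smoothing at half the expected
blob diameter (500 nm), robust z-scoring (median/MAD), h-minima filling of
the inverted image at the watershed level (6.7; basins separated by saddles
shallower than the level merge into one seed), seeds thresholded at
z > 4.5, marker-controlled watershed.  The two tool-specific numbers are
kept configurable and nothing downstream depends on their exact values.
Objects are filtered at sphericity > 0.4 and volume > 0.005 μm³ (strict
comparisons; the volume default reflects the plausible reading of an
ambiguously printed threshold, with 0.0005 μm³ selectable).

*Surface area and sphericity.*  Default surface area counts exposed voxel
faces scaled by the two orthogonal voxel dimensions (anisotropy-aware,
exact for boxes: a digitized cube scores ψ = (π/6)^⅓ ≈ 0.806 at any
resolution).  Face counting overestimates smooth surfaces by up to 3/2
(Manhattan staircase), so digitized spheres saturate at ψ ≈ 2/3; a
marching-cubes estimator (`surface_method="mesh"`) is provided for smooth
objects and converges toward 1 with resolution.  Both comfortably separate
spheres from the sheet-like artefacts the 0.4 filter removes.

*Coordinates.*  Arrays are (z, y, x); world coordinate of a voxel is
(index + 0.5) × voxel size; a z-window config restricts analysis to chosen
planes.

**Radial profiles.**  Spherical shells of 50 nm (configurable; the width is
not prescribed anywhere) up to 1 μm, anisotropy-corrected distances, shell
value = mean voxel intensity.  Shells truncated by the stack border are
excluded per anchor.  Aggregation is two-level: 0–1 min-max normalisation
per image, mean per experiment, then mean ± SEM across experiments.  A
constant stack yields an all-zero profile with a warning.

**NN distances.**  Directional: one distance per from-object.  Centre mode
uses a k-d tree; surface mode for the sphere model evaluates
max(0, |Δc| − r₁ − r₂) over all pairs (the nearest centre is not
necessarily the nearest surface); voxelized objects use surface-voxel
coordinates.  Surface NN ≤ centre NN always.

**CSR null.**  Per synapse and simulation round (default 10), species-A
centres are drawn uniform in the volume and species-B centres uniform on
the surface of a 0.8 μm sphere, preserving observed per-synapse counts and
radii; overlap between placed spheres is allowed (no exclusion rule is
stated anywhere).  Round histograms are pooled over synapses; the default
envelope is the exact t-based 95% prediction band
mean ± t₉·SD·√(1 + 1/10).  A mean ± 1.96·SEM band (selectable as
`envelope="sem"`) is a confidence band for the null *mean*: a single
observed histogram drawn from the null itself would leave it in roughly
half the bins, which would make envelope-based comparison meaningless —
calibration tests require the prediction band.  Per-bin min/max are also
exported.

**Toroidal shift.**  One random direction per image (seed-controlled; only
the 20 nm magnitude is prescribed), translation with wrap-around at the
field bounds, then centre-mode NN recomputation.  Shift ≤ 0 is an error;
the identity behaviour is available through the lower-level
`toroidal_shift` with magnitude 0.

**Spine pipeline.**  MAP2: Otsu threshold → Gaussian blur of the binary →
re-binarisation at half maximum → thinning (order as stated, though the
underlying description is ambiguous).  Puncta channels: mean filter
(radius 1.5 px) → auto-threshold (Otsu, Yen, or a moment-preserving
threshold implemented here, as no installed library provides it) →
Gaussian blur (σ = 1.5 px) → local maxima above threshold + prominence
(default 3 × robust background MAD, the analogue of a GUI noise
tolerance) → sub-pixel 3×3 centroid.  Homer puncta farther than 2 μm from
the skeleton (Euclidean distance transform in physical units) are dropped;
a spine is triple-positive when both partner channels have a punctum within
0.5 μm; puncta may serve several spines (no exclusivity is imposed
anywhere).  Physical parameters are in nm and converted via the configured
pixel size (70 nm default; not prescribed).

**Proteomics.**  Protein ratio = Σ(intensityᵢ·ratioᵢ)/Σ(intensityᵢ) per
replicate; replicate B inverted so >1 always means PSD-95-side enrichment;
division by the same-replicate GST ratio (GST's normalised ratio is
exactly 1).  Filters: quantified in both replicates, ≥ 2 peptides each,
geometric SD of the two oriented normalised replicate ratios
(exp of the n−1 SD of ln ratios) strictly < 2, bait/contaminant exclusion.
The geometric SD is taken over replicate-level ratios (the
peptide-level reading is selectable).  Quadrants: both ratios > 1 →
PSD-95-enriched; both < 1 → MPP2-enriched; mixed → unassigned.  Fold
enrichment uses the weaker replicate (min of the inverses on the MPP2
side), and the >7-fold selection is strict, so a protein at exactly 7.0 is
excluded.

## Problem sizes

Test and acceptance runs are sized for a single CPU: 100–200 synapses for
ring recovery, 200–500 for prevalence, 2 voxel scenes of 3 synapses for the
radial profiles, 200–400 spines for the fraction grid, 10⁴ singleton
synapses for the CSR mean-distance cross-check, and 200 random instances
(≤ 300 points) for the clustering-oracle equivalence.  The acceptance
script reports each quantity with the problem size used.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that each analysis stage recovers the parameters
of data generated under its own assumptions: rings that are truly circular
arrangements of Gaussian nanoclusters, discs of uniform label, spines
resolvable at the scoring scale, peptide noise that is log-normal and
label-symmetric.  Real data violate these in known ways the generators do
not emulate: antibody linkage error and repeated blinking (clustered
artefacts in dSTORM), incomplete labelling, SIM reconstruction artefacts,
dendrite crossings and out-of-focus puncta in confocal stacks,
peptide-level interference and missingness in quantitative proteomics.
Recovery on synthetic truth is therefore a correctness check of the
computation, not evidence about biological specimens.  The bracelet score
in particular is validated only against the generator's notion of a
bracelet.

## Known limitations

- The ring fit assumes peripheral clusters lie near a common circle in the
  analysis plane; strongly tilted 3D rings in 2D projections foreshorten
  into ellipses and bias the fitted diameter downward.
- The blob-finder parameter mapping (watershed level, threshold) to robust
  z-units is a reinterpretation of a commercial tool's semantics.
- `read_protein_sheet` maps deposited protein-level spreadsheets via an
  explicit column map; peptide-level re-analysis of deposited data is out
  of scope.
- The CSR null conditions on segmented counts and radii; it does not model
  segmentation error itself.
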