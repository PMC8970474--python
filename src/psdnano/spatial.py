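"""Spatial statistics: radial profiles, nearest-neighbour distances, and
null models.

Three questions about the spatial organisation of synaptic nanoclusters are
answered here.  (1) How is intensity distributed radially around segmented
PSD centres?  3D shells with anisotropy-corrected distances, 0-1
normalised per image and averaged twice (per image, then per experiment).
(2) How far is each cluster of one species from the nearest cluster of
another?  Directional nearest-neighbour (NN) distances between centres or
surfaces.  (3) Would that NN distribution arise by chance?  Two bespoke
null models: complete spatial randomness (CSR) constrained to a 0.8-um
postsynaptic sphere (one species uniform in the volume, the other on the
surface), with per-bin 95% envelopes over repeated simulation rounds; and
a toroidal shift that translates one channel by a fixed magnitude with
wrap-around at the field borders, destroying cross-channel correlation
while preserving within-channel structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# Radial intensity profiles
# ---------------------------------------------------------------------------

@dataclass
class RadialProfileParams:
    bin_width: float = 50.0      # nm
    max_radius: float = 1000.0   # nm

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.max_radius < self.bin_width:
            raise ValueError("max_radius must be >= bin_width")

    @property
    def edges(self) -> np.ndarray:
        n = int(math.ceil(self.max_radius / self.bin_width))
        return np.arange(n + 1) * self.bin_width


def radial_profile_3d(
    stack: np.ndarray,
    centres_nm: np.ndarray,
    voxel_size: tuple[float, float, float],
    params: RadialProfileParams | None = None,
) -> np.ndarray:
    """Mean radial intensity profile of one channel around anchor centres.

    For each anchor, voxels are binned into spherical shells
    ``[k*w, (k+1)*w)`` by anisotropy-corrected Euclidean distance; the
    shell value is the mean voxel intensity.  Shells truncated by the stack
    border are excluded (NaN) for that anchor; the per-image profile is the
    NaN-aware mean over anchors.  Returns one value per bin (NaN where no
    anchor contributed).
    """
    params = params or RadialProfileParams()
    stack = np.asarray(stack, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    edges = params.edges
    n_bins = len(edges) - 1
    extent = np.array(stack.shape) * vs
    profiles = []
    for centre in np.atleast_2d(centres_nm):
        half = np.ceil(params.max_radius / vs).astype(int) + 1
        idx_c = np.floor(centre / vs - 0.5).astype(int)
        lo = idx_c - half
        hi = idx_c + half + 1
        clo = np.maximum(lo, 0)
        chi = np.minimum(hi, stack.shape)
        grids = [(np.arange(clo[d], chi[d]) + 0.5) * vs[d] - centre[d] for d in range(3)]
        gz, gy, gx = np.meshgrid(*grids, indexing="ij")
        dist = np.sqrt(gz ** 2 + gy ** 2 + gx ** 2)
        sub = stack[clo[0]:chi[0], clo[1]:chi[1], clo[2]:chi[2]]
        # largest radius fully contained in the stack around this centre
        r_ok = min(np.min(centre), np.min(extent - centre), params.max_radius)
        which = np.clip(np.digitize(dist.ravel(), edges) - 1, 0, n_bins)
        sums = np.bincount(which, weights=sub.ravel(), minlength=n_bins + 1)[:n_bins]
        counts = np.bincount(which, minlength=n_bins + 1)[:n_bins]
        with np.errstate(invalid="ignore"):
            prof = sums / counts
        prof[edges[1:] > r_ok + 1e-9] = np.nan  # truncated shells excluded
        profiles.append(prof)
    if not profiles:
        return np.full(n_bins, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN shells stay NaN
        return np.nanmean(np.array(profiles), axis=0)


def normalize_profile(profile: np.ndarray) -> np.ndarray:
    """Min-max normalise a profile to [0, 1]; degenerate range yields zeros."""
    prof = np.asarray(profile, dtype=float)
    finite = prof[np.isfinite(prof)]
    if len(finite) == 0 or finite.max() == finite.min():
        import logging
        logging.getLogger(__name__).warning("normalize_profile: degenerate intensity range")
        return np.zeros_like(prof)
    return (prof - finite.min()) / (finite.max() - finite.min())


def aggregate_profiles(
    per_image: list[np.ndarray],
    experiment_ids: list[object],
) -> tuple[np.ndarray, np.ndarray]:
    """0-1 normalise per-image profiles, average per experiment, then across
    experiments.  Returns (mean, SEM); SEM is NaN with one experiment."""
    normed = [normalize_profile(p) for p in per_image]
    return aggregate_histograms(normed, experiment_ids)


# ---------------------------------------------------------------------------
# Nearest-neighbour distances
# ---------------------------------------------------------------------------

def nn_distances(
    from_centres: np.ndarray,
    to_centres: np.ndarray,
    mode: str = "centre",
    from_radii: np.ndarray | None = None,
    to_radii: np.ndarray | None = None,
) -> np.ndarray:
    """Directional nearest-neighbour distances from one object set to another.

    centre mode: Euclidean centroid distances.  surface mode (sphere
    model): ``max(0, |c_i - c_j| - r_i - r_j)`` minimised over j, i.e. the
    gap between sphere surfaces; tangent or overlapping spheres give 0.
    Direction matters: distances are reported per from-object.
    """
    from_c = np.atleast_2d(np.asarray(from_centres, dtype=float))
    to_c = np.atleast_2d(np.asarray(to_centres, dtype=float))
    if len(from_c) == 0:
        return np.empty(0)
    if len(to_c) == 0:
        raise ValueError("to-set must be non-empty")
    if mode == "centre":
        tree = cKDTree(to_c)
        d, _ = tree.query(from_c)
        return np.asarray(d, dtype=float)
    if mode == "surface":
        if from_radii is None or to_radii is None:
            raise ValueError("surface mode requires radii for both sets")
        dmat = cdist(from_c, to_c)
        gaps = dmat - np.asarray(from_radii, dtype=float)[:, None] \
                    - np.asarray(to_radii, dtype=float)[None, :]
        return np.clip(gaps, 0.0, None).min(axis=1)
    raise ValueError(f"unknown mode: {mode!r}")


def surface_nn_voxels(
    from_surfaces: list[np.ndarray],
    to_surfaces: list[np.ndarray],
) -> np.ndarray:
    """Surface NN distances between voxelized objects: for each from-object,
    the minimum distance between any of its surface-voxel world coordinates
    and any to-object surface voxel."""
    if not to_surfaces:
        raise ValueError("to-set must be non-empty")
    tree = cKDTree(np.vstack(to_surfaces))
    out = np.empty(len(from_surfaces))
    for i, surf in enumerate(from_surfaces):
        d, _ = tree.query(surf)
        out[i] = float(np.min(d))
    return out


# ---------------------------------------------------------------------------
# CSR null: random placement in / on a 0.8-um sphere
# ---------------------------------------------------------------------------

@dataclass
class CSRParams:
    """CSR null-model parameters: species A uniform within the sphere
    volume, species B uniform on its surface."""

    sphere_diameter: float = 800.0   # nm
    n_simulations_per_synapse: int = 10
    envelope_level: float = 0.95
    envelope: str = "prediction"     # "prediction": +-z*SD across rounds
                                     # "sem":        +-z*SEM (band for the null mean)

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be > 0")
        if self.n_simulations_per_synapse < 2:
            raise ValueError("need >= 2 simulation rounds for envelopes")
        if self.envelope not in ("prediction", "sem"):
            raise ValueError("envelope must be 'prediction' or 'sem'")


@dataclass
class NNHistogramWithEnvelope:
    """Observed NN histogram with a per-bin null mean and envelope."""

    bin_edges: np.ndarray
    observed: np.ndarray | None
    null_mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    null_min: np.ndarray
    null_max: np.ndarray
    mode: str
    direction: tuple[str, str] = ("A", "B")


def sample_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in the volume of a sphere of given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def sample_on_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform on the surface of a sphere of given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius


def csr_null(
    synapse_counts: list[tuple[int, int]],
    synapse_radii: list[tuple[np.ndarray, np.ndarray]] | None,
    bin_edges: np.ndarray,
    params: CSRParams | None = None,
    mode: str = "centre",
    seed: int = 0,
) -> NNHistogramWithEnvelope:
    """Simulate the CSR null and build per-bin envelopes.

    Per synapse and simulation round, species-A centres are drawn uniform
    within a sphere of ``sphere_diameter`` and species-B centres uniform on
    its surface, preserving the observed per-synapse object counts (and
    radii, for surface mode).  NN distances A->B are histogrammed per round
    (pooled over synapses); the envelope is the t-based prediction band
    mean +- t * SD * sqrt(1 + 1/rounds) covering a single observed
    realisation at ``envelope_level``, or the mean-only band
    +- t * SD / sqrt(rounds) when ``envelope='sem'``.  Per-bin min/max are
    also reported.

    ``synapse_radii`` may be None in centre mode.  A cluster radius larger
    than the sphere radius triggers a warning but placement follows the
    rule regardless.
    """
    params = params or CSRParams()
    rng = np.random.default_rng(seed)
    radius = params.sphere_diameter / 2.0
    if synapse_radii is not None:
        for ra, rb in synapse_radii:
            if np.any(np.asarray(ra) > radius) or np.any(np.asarray(rb) > radius):
                import logging
                logging.getLogger(__name__).warning(
                    "csr_null: object radius exceeds the postsynapse sphere radius")
    rounds = []
    for _ in range(params.n_simulations_per_synapse):
        dists = []
        for s, (na, nb) in enumerate(synapse_counts):
            if na < 1 or nb < 1:
                continue
            a = sample_in_sphere(rng, na, radius)
            b = sample_on_sphere(rng, nb, radius)
            if mode == "surface":
                ra, rb = synapse_radii[s]
                d = nn_distances(a, b, mode="surface",
                                 from_radii=np.asarray(ra, dtype=float),
                                 to_radii=np.asarray(rb, dtype=float))
            else:
                d = nn_distances(a, b, mode="centre")
            dists.append(d)
        pooled = np.concatenate(dists) if dists else np.empty(0)
        rounds.append(np.histogram(pooled, bins=bin_edges)[0].astype(float))
    hists = np.array(rounds)
    n_rounds = len(hists)
    mean = hists.mean(axis=0)
    sd = hists.std(axis=0, ddof=1)
    from scipy.stats import t as t_dist
    tval = float(t_dist.ppf(0.5 + params.envelope_level / 2.0, df=n_rounds - 1))
    if params.envelope == "prediction":
        # prediction band for one future realisation, mean and SD estimated
        half, zval = sd * math.sqrt(1.0 + 1.0 / n_rounds), tval
    else:
        half, zval = sd / math.sqrt(n_rounds), tval
    return NNHistogramWithEnvelope(
        bin_edges=np.asarray(bin_edges, dtype=float),
        observed=None,
        null_mean=mean,
        lower=mean - zval * half,
        upper=mean + zval * half,
        null_min=hists.min(axis=0),
        null_max=hists.max(axis=0),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Toroidal-shift null
# ---------------------------------------------------------------------------

def toroidal_shift(
    points: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    shift: float,
    rng: np.random.Generator | None = None,
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Translate points by ``shift`` in a random (or given) direction, with
    wrap-around at the field bounds (torus topology)."""
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    pts = np.asarray(points, dtype=float)
    if direction is None:
        if rng is None:
            raise ValueError("either rng or direction required")
        direction = rng.normal(size=pts.shape[1])
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    span = hi - lo
    return lo + np.mod(pts - lo + shift * direction, span)


def toroidal_shift_null(
    centres_a: np.ndarray,
    centres_b: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    shift: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Null NN distances after a toroidal shift of channel A.

    One random shift direction per image (seed-controlled); species-A
    cluster centres are translated with wrap-around at the field bounds and
    centre-mode NN distances to channel B recomputed.
    """
    if shift <= 0:
        raise ValueError("shift must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    pts = np.atleast_2d(np.asarray(centres_a, dtype=float))
    if np.any(pts < lo) or np.any(pts > hi):
        raise ValueError("field bounds must enclose all points")
    shifted = toroidal_shift(pts, bounds, shift, rng)
    return nn_distances(shifted, centres_b, mode="centre")


# ---------------------------------------------------------------------------
# Two-level histogram aggregation
# ---------------------------------------------------------------------------

def aggregate_histograms(
    per_image: list[np.ndarray],
    experiment_ids: list[object],
) -> tuple[np.ndarray, np.ndarray]:
    """Two-level mean +- SEM: average per-image values within each
    experiment, then mean and SEM across experiments.

    All inputs must share bin edges (equal length); a single experiment
    yields SEM = NaN (flagged, not an error).
    """
    if len(per_image) != len(experiment_ids):
        raise ValueError("one experiment id per image required")
    lengths = {len(h) for h in per_image}
    if len(lengths) > 1:
        raise ValueError("mismatched histogram bins")
    groups: dict[object, list[np.ndarray]] = {}
    for hist, eid in zip(per_image, experiment_ids):
        groups.setdefault(eid, []).append(np.asarray(hist, dtype=float))
    with np.errstate(invalid="ignore"):
        exp_means = np.array([np.nanmean(np.array(v), axis=0) for v in groups.values()])
        mean = np.nanmean(exp_means, axis=0)
    if len(groups) < 2:
        sem = np.full_like(mean, np.nan)
    else:
        sem = np.nanstd(exp_means, axis=0, ddof=1) / math.sqrt(len(groups))
    return mean, sem
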