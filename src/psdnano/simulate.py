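"""Synthetic-data generators with ground truth for every pipeline stage.

The package analyses four kinds of input: dSTORM localization tables, 3D
multi-channel voxel stacks (SIM-like), multi-channel confocal scenes, and
two-replicate isotope-ratio peptide tables.  Every analysis stage is
validated against synthetic inputs generated here, each with an explicit
ground-truth record, so correctness is established by parameter recovery.

The central geometric motif is the "bracelet": small peripheral nanoclusters
of the scaffold proteins SynCAM 1 and MPP2 arranged on rings (~894 and
~791 nm diameter) that surround the central postsynaptic-density (PSD)
marker, a disc of ~448 nm diameter.  Defaults encode those measured
dimensions and the reported 65% prevalence of the bracelet arrangement.

Seeding: generators take one seed; populations derive per-entity streams as
``seed + index`` so adding entities never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BraceletGeometry",
    "SynapseTruth",
    "VoxelSceneConfig",
    "ConfocalSceneConfig",
    "PeptideTableConfig",
    "simulate_bracelet_synapse",
    "simulate_bracelet_population",
    "simulate_voxel_scene",
    "simulate_confocal_scene",
    "simulate_peptide_table",
    "study_peptide_config",
]

CENTRAL_CHANNEL = "PSD95"
SPECIES_A = "SynCAM1"   # outer ring
SPECIES_B = "MPP2"      # inner ring


# ---------------------------------------------------------------------------
# dSTORM bracelet synapses
# ---------------------------------------------------------------------------

@dataclass
class BraceletGeometry:
    """Geometry of a bracelet synapse: a central disc plus two rings of
    satellite nanoclusters.

    All lengths in nm.  ``satellite_radius`` is the Gaussian sigma of one
    satellite nanocluster.  ``background_density`` is in localizations per
    square micrometre over the field.  With probability
    ``1 - bracelet_probability`` a synapse is generated without ring
    structure (peripheral species uniform in a disc of the ring diameter).
    """

    psd_disc_diameter: float = 448.0
    ring_diameter_species_a: float = 894.0
    ring_diameter_species_b: float = 791.0
    # across-synapse spread of the structure sizes (0 = every synapse identical)
    psd_disc_diameter_sd: float = 105.0
    ring_diameter_sd_a: float = 162.0
    ring_diameter_sd_b: float = 209.0
    n_satellites_per_species: int = 6
    satellite_radius: float = 40.0
    locs_per_satellite: int = 50
    locs_in_disc: int = 200
    precision_mean: float = 10.0
    precision_sd: float = 4.0
    background_density: float = 5.0       # per um^2
    bracelet_probability: float = 0.65
    angular_jitter_sd: float = 0.12       # rad, jitter of satellite angles
    field_size: float = 2000.0            # nm, square field side, centred

    def __post_init__(self) -> None:
        lengths = (
            self.psd_disc_diameter, self.ring_diameter_species_a,
            self.ring_diameter_species_b, self.satellite_radius,
            self.precision_mean, self.field_size,
        )
        if not all(np.isfinite(v) and v > 0 for v in lengths):
            raise ValueError("all geometry lengths must be finite and > 0")
        if not (np.isfinite(self.precision_sd) and self.precision_sd >= 0):
            raise ValueError("precision_sd must be finite and >= 0")
        for sd in (self.psd_disc_diameter_sd, self.ring_diameter_sd_a, self.ring_diameter_sd_b):
            if not (np.isfinite(sd) and sd >= 0):
                raise ValueError("diameter SDs must be finite and >= 0")
        if min(self.ring_diameter_species_a, self.ring_diameter_species_b) <= self.psd_disc_diameter:
            raise ValueError("ring diameters must exceed psd_disc_diameter")
        if not 0.0 <= self.bracelet_probability <= 1.0:
            raise ValueError("bracelet_probability must lie in [0, 1]")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")


@dataclass
class SynapseTruth:
    """Ground truth for one generated bracelet synapse.

    The recorded diameters are the per-synapse draws, not the population
    means; downstream recovery tests compare against these.
    """

    centre: tuple[float, float]
    bracelet: bool
    ring_diameter_a: float
    ring_diameter_b: float
    psd_disc_diameter: float
    satellite_centres_a: np.ndarray   # (n, 2) nm; empty when not a bracelet
    satellite_centres_b: np.ndarray


def _localization_frame(xy: np.ndarray, uncertainty: np.ndarray, channel: str,
                        rng: np.random.Generator) -> pd.DataFrame:
    n = len(xy)
    return pd.DataFrame({
        "x": xy[:, 0],
        "y": xy[:, 1],
        "frame": np.arange(n, dtype=int),
        "intensity": rng.gamma(shape=4.0, scale=250.0, size=n),
        "uncertainty": uncertainty,
        "channel": channel,
    })


def _draw_precision(rng: np.random.Generator, n: int, geometry: BraceletGeometry) -> np.ndarray:
    prec = rng.normal(geometry.precision_mean, geometry.precision_sd, size=n)
    return np.clip(prec, 0.5, None)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float,
                  centre: np.ndarray) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return centre + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _species_cloud(rng: np.random.Generator, geometry: BraceletGeometry,
                   centre: np.ndarray, ring_diameter: float,
                   bracelet: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (localizations, satellite centres) for one peripheral species."""
    n_sat = geometry.n_satellites_per_species
    n_locs = n_sat * geometry.locs_per_satellite
    if bracelet:
        base = rng.uniform(0.0, 2.0 * math.pi)
        angles = base + 2.0 * math.pi * np.arange(n_sat) / n_sat
        angles = angles + rng.normal(0.0, geometry.angular_jitter_sd, n_sat)
        radius = ring_diameter / 2.0
        sat_centres = centre + radius * np.column_stack([np.cos(angles), np.sin(angles)])
        pts = np.repeat(sat_centres, geometry.locs_per_satellite, axis=0)
        pts = pts + rng.normal(0.0, geometry.satellite_radius, size=pts.shape)
        return pts, sat_centres
    pts = _uniform_disc(rng, n_locs, ring_diameter / 2.0, centre)
    return pts, np.empty((0, 2))


def _draw_diameters(rng: np.random.Generator,
                    geometry: BraceletGeometry) -> tuple[float, float, float]:
    """Per-synapse structure sizes: a common log-normal synapse-size factor
    plus per-structure log-normal jitter, mean-corrected so expectations
    equal the nominal diameters and total SDs match the configured spreads.

    The shared factor keeps disc and rings scaling together, so ring > disc
    holds structurally; the rare residual inversion is clipped.  Zero SDs
    give back the nominal geometry exactly.
    """
    nominal = np.array([geometry.psd_disc_diameter,
                        geometry.ring_diameter_species_a,
                        geometry.ring_diameter_species_b])
    sds = np.array([geometry.psd_disc_diameter_sd,
                    geometry.ring_diameter_sd_a,
                    geometry.ring_diameter_sd_b])
    rel = np.where(nominal > 0, sds / nominal, 0.0)
    sigma_common = 0.7 * rel.min()
    sigma_struct = np.sqrt(np.maximum(rel ** 2 - sigma_common ** 2, 0.0))
    log_common = rng.normal(0.0, sigma_common) if sigma_common > 0 else 0.0
    draws = []
    for i in range(3):
        total_var = sigma_common ** 2 + sigma_struct[i] ** 2
        jitter = rng.normal(0.0, sigma_struct[i]) if sigma_struct[i] > 0 else 0.0
        draws.append(float(nominal[i] * math.exp(log_common + jitter - total_var / 2.0)))
    disc, diam_a, diam_b = draws
    diam_a = max(diam_a, disc + 100.0)
    diam_b = max(diam_b, disc + 100.0)
    return disc, diam_a, diam_b


def simulate_bracelet_synapse(
    geometry: BraceletGeometry | None = None,
    seed: int = 0,
    centre: tuple[float, float] = (0.0, 0.0),
) -> tuple[dict[str, pd.DataFrame], SynapseTruth]:
    """Generate one synapse as three localization tables plus ground truth.

    Channels: the central PSD marker (uniform in its disc), and two
    peripheral species whose satellite nanoclusters sit on their respective
    ring circles when the synapse carries the bracelet arrangement.
    Per-localization precision is drawn from the configured distribution,
    added as positional jitter, and recorded in the uncertainty column.
    Background localizations are Poisson over the square field.
    """
    geometry = geometry or BraceletGeometry()
    rng = np.random.default_rng(seed)
    c = np.asarray(centre, dtype=float)
    bracelet = bool(rng.random() < geometry.bracelet_probability)

    disc, diam_a, diam_b = _draw_diameters(rng, geometry)

    clouds: dict[str, np.ndarray] = {}
    clouds[CENTRAL_CHANNEL] = _uniform_disc(rng, geometry.locs_in_disc, disc / 2.0, c)
    pts_a, sats_a = _species_cloud(rng, geometry, c, diam_a, bracelet)
    pts_b, sats_b = _species_cloud(rng, geometry, c, diam_b, bracelet)
    clouds[SPECIES_A] = pts_a
    clouds[SPECIES_B] = pts_b

    half = geometry.field_size / 2.0
    area_um2 = (geometry.field_size / 1000.0) ** 2
    tables: dict[str, pd.DataFrame] = {}
    for name, pts in clouds.items():
        n_bg = rng.poisson(geometry.background_density * area_um2)
        bg = c + rng.uniform(-half, half, size=(n_bg, 2))
        pts_all = np.vstack([pts, bg])
        prec = _draw_precision(rng, len(pts_all), geometry)
        jitter = rng.normal(0.0, 1.0, size=pts_all.shape) * prec[:, None]
        tables[name] = _localization_frame(pts_all + jitter, prec, name, rng)

    truth = SynapseTruth(
        centre=(float(c[0]), float(c[1])),
        bracelet=bracelet,
        ring_diameter_a=diam_a,
        ring_diameter_b=diam_b,
        psd_disc_diameter=disc,
        satellite_centres_a=sats_a,
        satellite_centres_b=sats_b,
    )
    return tables, truth


def simulate_bracelet_population(
    geometry: BraceletGeometry | None = None,
    n_synapses: int = 100,
    seed: int = 0,
) -> list[tuple[dict[str, pd.DataFrame], SynapseTruth]]:
    """Generate ``n_synapses`` independent synapses with derived seeds.

    Entity ``i`` uses stream ``seed + i``, so extending the population never
    changes previously generated synapses.
    """
    geometry = geometry or BraceletGeometry()
    return [simulate_bracelet_synapse(geometry, seed=seed + i) for i in range(n_synapses)]


# ---------------------------------------------------------------------------
# SIM-like voxel scenes
# ---------------------------------------------------------------------------

@dataclass
class VoxelSceneConfig:
    """Configuration of a 3D multi-channel voxel scene.

    Anisotropic voxels (axial step coarser than lateral) mirror 3D SIM
    acquisition.  ``field_size`` is (nz, ny, nx) in voxels.  ``psf_sigma``
    is the isotropic blur sigma (nm) applied to every deposited blob.
    """

    voxel_size_xy: float = 40.0    # nm
    voxel_size_z: float = 125.0    # nm
    field_size: tuple[int, int, int] = (24, 160, 160)
    psf_sigma: float = 80.0        # nm
    channel_names: tuple[str, ...] = (CENTRAL_CHANNEL, SPECIES_B, SPECIES_A, "vGlut1")
    photon_scale: float = 10.0     # intensity units per localization-equivalent
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.voxel_size_xy > 0 and self.voxel_size_z > 0):
            raise ValueError("voxel sizes must be > 0")
        if self.voxel_size_z < self.voxel_size_xy:
            raise ValueError("axial voxel size must be >= lateral (anisotropy convention)")

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        return (self.voxel_size_z, self.voxel_size_xy, self.voxel_size_xy)


@dataclass
class VoxelSceneTruth:
    """Ground truth of a voxel scene: per-synapse centres and blob records."""

    centres_nm: np.ndarray                      # (n, 3) z, y, x
    blobs: dict[str, np.ndarray]                # channel -> (m, 4): z, y, x, mass
    bracelet_flags: np.ndarray
    ring_diameter_a: float
    ring_diameter_b: float


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _deposit_gaussian(stack: np.ndarray, centre_nm: np.ndarray, sigma_nm: float,
                      mass: float, voxel_zyx: tuple[float, float, float]) -> None:
    """Add an analytically normalised 3D Gaussian blob in place.

    The blob is evaluated on a local window of +-4 sigma, using the voxel
    centre convention world = (index + 0.5) * voxel_size, so the deposited
    mass approximates ``mass`` to well under 1%.
    """
    vz, vy, vx = voxel_zyx
    sizes = np.array([vz, vy, vx])
    idx_c = centre_nm / sizes - 0.5
    half = np.ceil(4.0 * sigma_nm / sizes).astype(int)
    lo = np.maximum(np.floor(idx_c).astype(int) - half, 0)
    hi = np.minimum(np.floor(idx_c).astype(int) + half + 1, np.array(stack.shape))
    if np.any(lo >= hi):
        return
    grids = [
        (np.arange(lo[d], hi[d]) + 0.5) * sizes[d] - centre_nm[d]
        for d in range(3)
    ]
    gz, gy, gx = np.meshgrid(*grids, indexing="ij")
    dist2 = gz ** 2 + gy ** 2 + gx ** 2
    norm = (2.0 * math.pi * sigma_nm ** 2) ** -1.5 * vz * vy * vx
    stack[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
        mass * norm * np.exp(-0.5 * dist2 / sigma_nm ** 2)
    )


def _deposit_ball(stack: np.ndarray, centre_nm: np.ndarray, radius_nm: float,
                  mass: float, voxel_zyx: tuple[float, float, float]) -> None:
    """Add a uniform-density ball of total ``mass`` in place (sharp edge;
    the scene-level PSF blur softens it)."""
    sizes = np.array(voxel_zyx)
    half = np.ceil(radius_nm / sizes).astype(int) + 1
    idx_c = centre_nm / sizes - 0.5
    lo = np.maximum(np.floor(idx_c).astype(int) - half, 0)
    hi = np.minimum(np.floor(idx_c).astype(int) + half + 1, np.array(stack.shape))
    if np.any(lo >= hi):
        return
    grids = [(np.arange(lo[d], hi[d]) + 0.5) * sizes[d] - centre_nm[d] for d in range(3)]
    gz, gy, gx = np.meshgrid(*grids, indexing="ij")
    inside = gz ** 2 + gy ** 2 + gx ** 2 <= radius_nm ** 2
    n_inside = inside.sum()
    if n_inside == 0:
        return
    stack[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += mass / n_inside * inside


def simulate_voxel_scene(
    config: VoxelSceneConfig | None = None,
    geometry: BraceletGeometry | None = None,
    n_synapses: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, VoxelSceneTruth]:
    """Render bracelet synapses into a blurred multi-channel voxel stack.

    Each synapse contributes a central blob in the PSD channel, peripheral
    satellite blobs for the two ring species on a ring of random 3D
    orientation, and a presynaptic-marker blob offset along the ring-plane
    normal.  Blob masses scale with the configured localization counts via
    ``photon_scale``; Gaussian read noise is added when ``noise_sd > 0``.

    Synapse centres are placed with >= 1.6 um mutual separation and a border
    margin; an unplaceable request raises with the achieved count.
    """
    config = config or VoxelSceneConfig()
    geometry = geometry or BraceletGeometry()
    rng = np.random.default_rng(seed)
    nz, ny, nx = config.field_size
    vz, vy, vx = config.voxel_size_zyx
    extent = np.array([nz * vz, ny * vy, nx * vx])
    margin = geometry.ring_diameter_species_a / 2.0 + 4.0 * config.psf_sigma
    min_sep = 1600.0  # nm, keeps neighbouring synapses distinct at the 0.8 um scale

    centres: list[np.ndarray] = []
    feasible = bool(np.all(extent - 2 * margin > 0))
    attempts = 0
    while feasible and len(centres) < n_synapses and attempts < 200 * max(1, n_synapses):
        attempts += 1
        cand = rng.uniform(margin, extent - margin)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centres):
            centres.append(cand)
    if len(centres) < n_synapses:
        raise ValueError(
            f"could only place {len(centres)} of {n_synapses} synapses in the field")

    stack = np.zeros((len(config.channel_names), nz, ny, nx), dtype=float)
    chan_idx = {name: i for i, name in enumerate(config.channel_names)}
    blobs: dict[str, list[list[float]]] = {name: [] for name in config.channel_names}
    flags = np.zeros(len(centres), dtype=bool)

    for i, c in enumerate(centres):
        srng = np.random.default_rng(seed + 1000 + i)
        flags[i] = bool(srng.random() < geometry.bracelet_probability)
        rot = _random_rotation(srng)
        # central PSD: uniform ball of the disc radius (PSF blur applied below)
        mass_c = geometry.locs_in_disc * config.photon_scale
        _deposit_ball(stack[chan_idx[CENTRAL_CHANNEL]], c,
                      geometry.psd_disc_diameter / 2.0, mass_c, config.voxel_size_zyx)
        blobs[CENTRAL_CHANNEL].append([*c, mass_c])
        # peripheral rings (planar, rotated into 3D)
        for species, diam in ((SPECIES_A, geometry.ring_diameter_species_a),
                              (SPECIES_B, geometry.ring_diameter_species_b)):
            n_sat = geometry.n_satellites_per_species
            if flags[i]:
                base = srng.uniform(0.0, 2.0 * math.pi)
                ang = base + 2.0 * math.pi * np.arange(n_sat) / n_sat
                planar = np.column_stack([
                    np.zeros(n_sat), diam / 2.0 * np.sin(ang), diam / 2.0 * np.cos(ang)])
            else:
                r = diam / 2.0 * np.sqrt(srng.random(n_sat))
                th = srng.uniform(0, 2 * math.pi, n_sat)
                planar = np.column_stack([np.zeros(n_sat), r * np.sin(th), r * np.cos(th)])
            pos = c + planar @ rot.T
            mass_s = geometry.locs_per_satellite * config.photon_scale
            for p in pos:
                _deposit_gaussian(stack[chan_idx[species]], p, geometry.satellite_radius,
                                  mass_s, config.voxel_size_zyx)
                blobs[species].append([*p, mass_s])
        # presynaptic marker offset along the ring-plane normal
        if "vGlut1" in chan_idx:
            normal = rot @ np.array([1.0, 0.0, 0.0])
            p = c + 200.0 * normal
            mass_v = geometry.locs_in_disc * config.photon_scale / 2.0
            _deposit_gaussian(stack[chan_idx["vGlut1"]], p, 120.0, mass_v,
                              config.voxel_size_zyx)
            blobs["vGlut1"].append([*p, mass_v])

    # optical blur: isotropic physical PSF, anisotropy-corrected per axis
    from scipy import ndimage as _ndi
    sig_vox = [config.psf_sigma / v for v in config.voxel_size_zyx]
    for ch in range(stack.shape[0]):
        stack[ch] = _ndi.gaussian_filter(stack[ch], sigma=sig_vox)
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, size=stack.shape)

    truth = VoxelSceneTruth(
        centres_nm=np.array(centres).reshape(-1, 3),
        blobs={k: np.array(v).reshape(-1, 4) for k, v in blobs.items()},
        bracelet_flags=flags,
        ring_diameter_a=geometry.ring_diameter_species_a,
        ring_diameter_b=geometry.ring_diameter_species_b,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Confocal spine scenes
# ---------------------------------------------------------------------------

@dataclass
class ConfocalSceneConfig:
    """Configuration of a 4-channel confocal scene of a dendrite with spines.

    A fraction ``cooccurrence_fraction`` of Homer1-positive spines carry
    both a second-scaffold punctum and a receptor punctum within 250 nm; the
    rest carry the scaffold only.  Extra receptor-only puncta sit on the
    dendrite shaft, mimicking inhibitory synapses.
    """

    pixel_size: float = 70.0      # nm
    image_shape: tuple[int, int] = (512, 512)
    dendrite_path: np.ndarray | None = None    # (k, 2) pixels (row, col)
    n_homer_spines: int = 40
    cooccurrence_fraction: float = 0.2
    off_dendrite_puncta_density: float = 0.02  # receptor-only puncta per um^2
    spot_sigma: float = 120.0     # nm
    dendrite_width: float = 900.0  # nm
    spine_offset_range: tuple[float, float] = (600.0, 1500.0)  # nm from shaft
    partner_offset: float = 250.0  # nm, partner puncta placed within this radius
    amplitude: float = 100.0
    noise_sd: float = 1.0
    channel_names: tuple[str, ...] = ("MAP2", "Homer1", "MPP2", "GABAAR")

    def __post_init__(self) -> None:
        if not 0.0 <= self.cooccurrence_fraction <= 1.0:
            raise ValueError("cooccurrence_fraction must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class ConfocalSceneTruth:
    """Per-spine ground truth of a confocal scene."""

    spine_positions_nm: np.ndarray   # (n, 2) row, col in nm
    cooccurring: np.ndarray          # bool per spine: both partners present
    shaft_receptor_positions_nm: np.ndarray


def _default_path(shape: tuple[int, int]) -> np.ndarray:
    r0, c0 = shape[0] * 0.2, shape[1] * 0.1
    r1, c1 = shape[0] * 0.8, shape[1] * 0.9
    rm, cm = shape[0] * 0.55, shape[1] * 0.5
    return np.array([[r0, c0], [rm, cm], [r1, c1]])


def _sample_on_polyline(rng: np.random.Generator, path: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample points uniformly by arc length; return points and unit normals."""
    segs = np.diff(path, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    s = rng.uniform(0.0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(segs) - 1)
    t = (s - cum[idx]) / lengths[idx]
    pts = path[idx] + segs[idx] * t[:, None]
    tangents = segs[idx] / lengths[idx][:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return pts, normals


def _stratified_on_polyline(
    rng: np.random.Generator, path: np.ndarray, n: int, jitter_frac: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """One point per equal arc-length slot (small jitter), so consecutive
    spines keep a minimum separation and stay resolvable at the
    co-occurrence scale.  Returns points and unit normals."""
    segs = np.diff(path, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    slot = cum[-1] / n
    s = (np.arange(n) + 0.5) * slot + rng.uniform(-jitter_frac, jitter_frac, n) * slot
    s = np.clip(s, 0.0, cum[-1] - 1e-9)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(segs) - 1)
    t = (s - cum[idx]) / lengths[idx]
    pts = path[idx] + segs[idx] * t[:, None]
    tangents = segs[idx] / lengths[idx][:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return pts, normals


def _render_spot(img: np.ndarray, pos_px: np.ndarray, sigma_px: float, amp: float) -> None:
    half = int(math.ceil(4 * sigma_px))
    r0 = int(round(pos_px[0])); c0 = int(round(pos_px[1]))
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, img.shape[0])
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, img.shape[1])
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    d2 = (rr - pos_px[0]) ** 2 + (cc - pos_px[1]) ** 2
    img[rlo:rhi, clo:chi] += amp * np.exp(-0.5 * d2 / sigma_px ** 2)


def simulate_confocal_scene(
    config: ConfocalSceneConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, ConfocalSceneTruth]:
    """Render a dendrite with Homer1-marked spines and partner puncta.

    Channel 0 renders the dendrite polyline as a thick filament (the
    dendritic-marker channel); Homer1 puncta are placed on spines within
    2 um of the shaft; a Bernoulli draw per spine (p = cooccurrence
    fraction) decides whether both partner channels get a punctum within
    ``partner_offset`` of the Homer punctum, otherwise only the scaffold
    channel does.  Receptor-only puncta are added on the shaft.
    """
    config = config or ConfocalSceneConfig()
    rng = np.random.default_rng(seed)
    shape = config.image_shape
    px = config.pixel_size
    path = config.dendrite_path if config.dendrite_path is not None else _default_path(shape)
    path = np.asarray(path, dtype=float)
    if np.any(path < 0) or np.any(path >= np.array(shape)):
        raise ValueError("dendrite polyline lies outside image bounds")

    imgs = {name: np.zeros(shape) for name in config.channel_names}
    map2, homer, mpp2, gabaar = config.channel_names

    # dendrite filament: stamp discs along a dense resampling of the path
    dense, _ = _sample_on_polyline(np.random.default_rng(0), path, 2000)
    width_px = config.dendrite_width / px
    for p in dense:
        _render_spot(imgs[map2], p, width_px / 2.355, config.amplitude / 20.0)

    n = config.n_homer_spines
    anchors, normals = _stratified_on_polyline(rng, path, n)
    side = rng.choice([-1.0, 1.0], n)
    offset = rng.uniform(*config.spine_offset_range, n) / px
    spine_px = anchors + normals * (side * offset)[:, None]
    spine_px = np.clip(spine_px, 2.0, np.array(shape) - 3.0)
    coocc = rng.random(n) < config.cooccurrence_fraction

    sigma_px = config.spot_sigma / px
    partner_px = config.partner_offset / px
    for i in range(n):
        _render_spot(imgs[homer], spine_px[i], sigma_px, config.amplitude)
        ang = rng.uniform(0, 2 * math.pi)
        r = partner_px * math.sqrt(rng.random()) * 0.9
        _render_spot(imgs[mpp2], spine_px[i] + r * np.array([math.cos(ang), math.sin(ang)]),
                     sigma_px, config.amplitude)
        if coocc[i]:
            ang = rng.uniform(0, 2 * math.pi)
            r = partner_px * math.sqrt(rng.random()) * 0.9
            _render_spot(imgs[gabaar],
                         spine_px[i] + r * np.array([math.cos(ang), math.sin(ang)]),
                         sigma_px, config.amplitude)

    # receptor-only puncta on the shaft (inhibitory-synapse mimic)
    area_um2 = shape[0] * shape[1] * (px / 1000.0) ** 2
    n_shaft = rng.poisson(config.off_dendrite_puncta_density * area_um2)
    shaft_pts, _ = _sample_on_polyline(rng, path, max(n_shaft, 0))
    for p in shaft_pts:
        _render_spot(imgs[gabaar], p, sigma_px, config.amplitude)

    stack = np.stack([imgs[nme] for nme in config.channel_names])
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, stack.shape)

    truth = ConfocalSceneTruth(
        spine_positions_nm=spine_px * px,
        cooccurring=coocc,
        shaft_receptor_positions_nm=shaft_pts.reshape(-1, 2) * px,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Isotope-ratio peptide tables
# ---------------------------------------------------------------------------

@dataclass
class PeptideTableConfig:
    """Configuration of a two-replicate inverted-label peptide ratio table.

    ``true_log2_ratios`` maps protein id to its true log2 enrichment ratio,
    oriented so positive means enrichment toward the first bait (PSD-95
    side).  Replicate A stores ratios in that orientation; replicate B is
    label-switched and stores the reciprocal.  Peptide ratios carry
    multiplicative log-normal noise; intensities are log-normal.
    """

    true_log2_ratios: dict[str, float] = field(default_factory=dict)
    peptides_per_protein: tuple[int, int] = (2, 8)   # inclusive range
    peptide_log_ratio_noise_sd: float = 0.1          # sd of ln(ratio) noise
    intensity_mu: float = 14.0                       # ln-intensity mean
    intensity_sigma: float = 1.5
    gst_true_ratio: float = 1.0
    gst_id: str = "GST"

    def __post_init__(self) -> None:
        if self.peptides_per_protein[0] < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if self.gst_true_ratio <= 0:
            raise ValueError("gst_true_ratio must be > 0")


@dataclass
class PeptideTableTruth:
    """Planted truth: true oriented ratios and the enriched-set membership."""

    true_ratio: dict[str, float]          # oriented, PSD-95-positive
    enriched: dict[str, bool]             # |log2 ratio| > log2(7)


#: GABA_A receptor subunits reported enriched toward the second bait
GABAAR_SUBUNITS = (
    "GABRA1", "GABRA2", "GABRA4", "GABRB1", "GABRB2", "GABRB3", "GABRD",
)


def study_peptide_config(
    n_proteins: int = 188,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> PeptideTableConfig:
    """Peptide-table configuration matching the study conditions.

    Plants the seven receptor subunits at 10-30-fold enrichment toward the
    second bait (MPP2 side), a handful of first-bait (PSD-95 side) enriched
    scaffold interactors, and background proteins with ratios near 1.  The
    total protein count (including GST) is ``n_proteins`` + GST.
    """
    rng = np.random.default_rng(seed)
    ratios: dict[str, float] = {}
    for i, sub in enumerate(GABAAR_SUBUNITS):
        fold = rng.uniform(10.0, 30.0)
        ratios[sub] = -math.log2(fold)              # MPP2-side
    n_psd = 12
    for i in range(n_psd):
        fold = rng.uniform(8.0, 40.0)
        ratios[f"PSD95_INT_{i:02d}"] = math.log2(fold)
    n_bg = n_proteins - len(ratios)
    for i in range(n_bg):
        ratios[f"BG_{i:03d}"] = float(rng.normal(0.0, 0.4))
    return PeptideTableConfig(true_log2_ratios=ratios,
                              peptide_log_ratio_noise_sd=noise_sd)


def simulate_peptide_table(
    config: PeptideTableConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, PeptideTableTruth]:
    """Generate a peptide-level quantification table for both replicates.

    Output columns: protein, peptide, replicate (A/B), ratio (raw, as
    reported: replicate B inverted), intensity.  GST is always present with
    its configured true ratio.
    """
    rng = np.random.default_rng(seed)
    ratios = dict(config.true_log2_ratios)
    ratios.setdefault(config.gst_id, math.log2(config.gst_true_ratio))
    lo, hi = config.peptides_per_protein
    rows = []
    for prot, log2r in sorted(ratios.items()):
        true_ratio = 2.0 ** log2r
        for rep in ("A", "B"):
            n_pep = int(rng.integers(lo, hi + 1))
            for j in range(n_pep):
                noisy = true_ratio * math.exp(rng.normal(0.0, config.peptide_log_ratio_noise_sd))
                raw = noisy if rep == "A" else 1.0 / noisy
                rows.append({
                    "protein": prot,
                    "peptide": f"{prot}_pep{j:02d}",
                    "replicate": rep,
                    "ratio": raw,
                    "intensity": float(np.exp(rng.normal(config.intensity_mu, config.intensity_sigma))),
                })
    table = pd.DataFrame(rows)
    thresh = math.log2(7.0)
    truth = PeptideTableTruth(
        true_ratio={p: 2.0 ** r for p, r in ratios.items()},
        enriched={p: abs(r) > thresh for p, r in ratios.items()},
    )
    return table, truth
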