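"""Confocal spine analysis: dendrite skeletonization, puncta detection, and
per-spine co-occurrence scoring.

The question answered here: what fraction of excitatory synapses (spines
marked by a Homer1 punctum near a dendrite) also carry both a scaffold
(MPP2) punctum and a receptor (GABA_A) punctum within a typical spine-head
radius?  The pipeline follows the classical ImageJ recipe: per-channel mean
filtering, histogram-based auto-thresholding (Otsu / Yen / moment-
preserving), Gaussian blur, local-maximum detection; a MAP2 skeleton
restricts analysis to puncta within 2 um of a dendrite; point selections
are enlarged by 0.5 um and checked for co-occurrence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu, threshold_yen
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)


@dataclass
class SpineParams:
    mean_filter_radius: float = 1.5     # pixels
    gaussian_sigma: float = 1.5         # pixels
    threshold_method: str = "otsu"      # otsu | yen | moments, per channel
    maxima_prominence: float | None = None  # intensity units; None = 3 x background MAD
    dendrite_proximity: float = 2000.0  # nm
    cooccurrence_radius: float = 500.0  # nm
    pixel_size: float = 70.0            # nm

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mean_filter_radius <= 0 or self.gaussian_sigma <= 0:
            raise ValueError("filter radii must be > 0")


def threshold_moments(image: np.ndarray, nbins: int = 256) -> float:
    """Tsai's moment-preserving threshold (the ImageJ "Moments" method).

    Chooses the threshold so that the binarised image preserves the first
    three grey-level moments of the input.  No installed library provides
    this method, so it is implemented here from the histogram.
    """
    img = np.asarray(image, dtype=float).ravel()
    hist, edges = np.histogram(img, bins=nbins)
    p = hist / hist.sum()
    levels = 0.5 * (edges[:-1] + edges[1:])
    # normalised grey-level moments on bin indices
    idx = np.arange(nbins)
    m1 = np.sum(p * idx)
    m2 = np.sum(p * idx ** 2)
    m3 = np.sum(p * idx ** 3)
    cd = m2 - m1 ** 2
    if cd <= 0:
        return float(levels[nbins // 2])
    c0 = (-m2 ** 2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd  # note: coefficients of z^2 + c1 z + c0 = 0
    disc = c1 ** 2 - 4.0 * c0
    if disc < 0:
        return float(levels[nbins // 2])
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        return float(levels[nbins // 2])
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels below threshold
    p0 = min(max(p0, 0.0), 1.0)
    cum = np.cumsum(p)
    t_idx = int(np.searchsorted(cum, p0))
    t_idx = min(t_idx, nbins - 1)
    return float(levels[t_idx])


_THRESHOLDS = {
    "otsu": threshold_otsu,
    "yen": threshold_yen,
    "moments": threshold_moments,
}


def skeletonize_dendrite(map2_image: np.ndarray, blur_sigma: float = 1.5) -> np.ndarray:
    """Reduce a dendrite-marker image to a 1-pixel skeleton mask.

    Otsu threshold, Gaussian blur of the binary mask, re-binarisation at
    half maximum, then morphological thinning.  An empty foreground yields
    an empty skeleton with a warning.
    """
    img = np.asarray(map2_image, dtype=float)
    if np.ptp(img) == 0:
        logger.warning("skeletonize_dendrite: blank image, empty skeleton")
        return np.zeros(img.shape, dtype=bool)
    binary = img > threshold_otsu(img)
    blurred = gaussian(binary.astype(float), sigma=blur_sigma)
    if blurred.max() == 0:
        logger.warning("skeletonize_dendrite: empty foreground")
        return np.zeros(img.shape, dtype=bool)
    rebinary = blurred >= 0.5 * blurred.max()
    return skeletonize(rebinary)


def detect_puncta(
    image: np.ndarray,
    params: SpineParams | None = None,
    threshold_method: str | None = None,
) -> np.ndarray:
    """Detect punctate structures; returns (n, 2) positions in nm (row, col).

    Mean filter, auto-threshold (per-channel method), Gaussian blur, then
    local maxima above the threshold with prominence at least
    ``maxima_prominence`` (default 3x the robust background MAD, the
    analogue of a GUI maxima-tool noise tolerance).  Sub-pixel positions by
    the intensity centroid of the 3x3 neighbourhood.
    """
    params = params or SpineParams()
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return np.empty((0, 2))
    size = max(3, 2 * int(round(params.mean_filter_radius)) + 1)
    filt = ndimage.uniform_filter(img, size=size)
    method = threshold_method or params.threshold_method
    thr = _THRESHOLDS[method](filt)
    blurred = gaussian(filt, sigma=params.gaussian_sigma, preserve_range=True)
    background = blurred[blurred <= thr]
    mad = np.median(np.abs(background - np.median(background))) if background.size else 0.0
    prominence = params.maxima_prominence if params.maxima_prominence is not None \
        else 3.0 * 1.4826 * mad
    peaks = peak_local_max(
        blurred, min_distance=2, threshold_abs=thr + prominence, exclude_border=False)
    positions = []
    for r, c in peaks:
        rlo, rhi = max(r - 1, 0), min(r + 2, img.shape[0])
        clo, chi = max(c - 1, 0), min(c + 2, img.shape[1])
        window = blurred[rlo:rhi, clo:chi]
        rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
        w = window.sum()
        positions.append([(rr * window).sum() / w, (cc * window).sum() / w])
    return np.asarray(positions, dtype=float).reshape(-1, 2) * params.pixel_size


def filter_near_skeleton(
    puncta_nm: np.ndarray,
    skeleton: np.ndarray,
    pixel_size: float,
    max_distance: float = 2000.0,
) -> np.ndarray:
    """Keep puncta within ``max_distance`` nm of the dendrite skeleton."""
    pts = np.atleast_2d(np.asarray(puncta_nm, dtype=float))
    if pts.size == 0:
        return np.empty((0, 2))
    if not skeleton.any():
        logger.warning("filter_near_skeleton: empty skeleton, dropping all puncta")
        return np.empty((0, 2))
    dist = ndimage.distance_transform_edt(~skeleton, sampling=pixel_size)
    idx = np.clip((pts / pixel_size).astype(int), 0, np.array(skeleton.shape) - 1)
    keep = dist[idx[:, 0], idx[:, 1]] <= max_distance
    return pts[keep]


def score_cooccurrence(
    homer_puncta: np.ndarray,
    mpp2_puncta: np.ndarray,
    gabaar_puncta: np.ndarray,
    radius: float = 500.0,
) -> tuple[pd.DataFrame, float]:
    """Per-Homer-spine co-occurrence flags and the triple-positive fraction.

    A spine is positive for a partner channel when at least one punctum of
    that channel lies within ``radius`` nm of the Homer punctum (puncta may
    serve several spines; no exclusivity).  fraction = (# spines with both
    partners) / (# Homer puncta); NaN (flagged) with zero Homer puncta.
    """
    homer = np.atleast_2d(np.asarray(homer_puncta, dtype=float))
    if homer.size == 0:
        logger.warning("score_cooccurrence: no Homer puncta, fraction undefined")
        return pd.DataFrame(columns=["row_nm", "col_nm", "has_mpp2", "has_gabaar"]), float("nan")

    def has_within(targets: np.ndarray) -> np.ndarray:
        t = np.atleast_2d(np.asarray(targets, dtype=float))
        if t.size == 0:
            return np.zeros(len(homer), dtype=bool)
        d, _ = cKDTree(t).query(homer)
        return d <= radius

    has_m = has_within(mpp2_puncta)
    has_g = has_within(gabaar_puncta)
    records = pd.DataFrame({
        "row_nm": homer[:, 0], "col_nm": homer[:, 1],
        "has_mpp2": has_m, "has_gabaar": has_g,
    })
    fraction = float(np.mean(has_m & has_g))
    return records, fraction


def analyze_scene(
    stack: np.ndarray,
    params: SpineParams | None = None,
    channel_methods: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """End-to-end spine scoring of a 4-channel scene.

    Channel order: dendrite marker (MAP2), Homer1, MPP2, receptor.
    Skeletonizes channel 0, detects puncta in channels 1-3, keeps Homer
    puncta within the dendrite-proximity band, and scores co-occurrence.
    """
    params = params or SpineParams()
    methods = channel_methods or {}
    skeleton = skeletonize_dendrite(stack[0])
    puncta = [
        detect_puncta(stack[ch], params, threshold_method=methods.get(ch))
        for ch in (1, 2, 3)
    ]
    homer = filter_near_skeleton(puncta[0], skeleton, params.pixel_size,
                                 params.dendrite_proximity)
    return score_cooccurrence(homer, puncta[1], puncta[2], params.cooccurrence_radius)
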