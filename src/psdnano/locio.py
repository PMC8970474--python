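"""Localization-table I/O, precision filtering, and Gaussian rendering.

Single-molecule localization microscopy (SMLM/dSTORM) data arrive as flat
tables of detections: position (nm), acquisition frame, photon count, and a
per-detection localization precision (Thompson estimate, nm).  This module
reads and writes the CSV dialect used throughout the package, applies the
precision quality filter, and renders point clouds to intensity images by
placing a unit-mass Gaussian kernel at every localization.

Conventions: all coordinates are in nanometres; the image convention is used
(y increases downward); rendering bins are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical column names of a localization table
MANDATORY_COLUMNS = ("x", "y", "uncertainty")
OPTIONAL_COLUMNS = ("z", "frame", "intensity", "channel")

#: header aliases accepted on input (lower-cased, stripped)
DEFAULT_ALIASES: dict[str, str] = {
    "x": "x", "x [nm]": "x", "x_nm": "x", "xnm": "x",
    "y": "y", "y [nm]": "y", "y_nm": "y", "ynm": "y",
    "z": "z", "z [nm]": "z", "z_nm": "z",
    "frame": "frame",
    "intensity": "intensity", "intensity [photon]": "intensity",
    "photons": "intensity",
    "uncertainty": "uncertainty", "uncertainty [nm]": "uncertainty",
    "uncertainty_xy [nm]": "uncertainty", "precision": "uncertainty",
    "precision [nm]": "uncertainty", "sigma [nm]": "uncertainty",
    "channel": "channel",
}

#: header names written on output, keyed by canonical name
OUTPUT_HEADERS = {
    "x": "x [nm]", "y": "y [nm]", "z": "z [nm]", "frame": "frame",
    "intensity": "intensity [photon]", "uncertainty": "uncertainty [nm]",
    "channel": "channel",
}

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class RenderParams:
    """Parameters for Gaussian rendering of localization tables.

    ``render_width`` is interpreted as the kernel FWHM by default (the
    convention of constant-width SMLM renders); set ``width_is_fwhm=False``
    to interpret it as the Gaussian sigma directly.
    """

    render_width: float = 20.0     # nm
    pixel_size: float = 10.0       # nm
    width_is_fwhm: bool = True

    def __post_init__(self) -> None:
        if not (self.render_width > 0 and self.pixel_size > 0):
            raise ValueError("render_width and pixel_size must be > 0")

    @property
    def sigma_nm(self) -> float:
        return self.render_width * FWHM_TO_SIGMA if self.width_is_fwhm else self.render_width


def read_localizations(path: str | Path, aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a localization CSV, mapping header aliases to canonical names.

    Mandatory columns are x, y and uncertainty (all nm).  Rows whose
    coordinates are non-numeric are dropped with a logged count.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k.strip().lower(): v for k, v in aliases.items()})
    raw = pd.read_csv(path)
    renames = {}
    for col in raw.columns:
        key = str(col).strip().lower()
        if key in alias_map:
            renames[col] = alias_map[key]
    table = raw.rename(columns=renames)
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing mandatory column: {col!r} (in {path})")
    keep = [c for c in (*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    table = table[keep]
    numeric_cols = [c for c in keep if c != "channel"]
    coerced = table.copy()
    for col in numeric_cols:
        coerced[col] = pd.to_numeric(table[col], errors="coerce")
    bad = coerced[["x", "y", "uncertainty"]].isna().any(axis=1)
    if bad.any():
        logger.warning("read_localizations: dropped %d rows with non-numeric coordinates", int(bad.sum()))
    return coerced.loc[~bad].reset_index(drop=True)


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table in the package's CSV dialect."""
    cols = [c for c in (*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    out = table[cols].rename(columns=OUTPUT_HEADERS)
    out.to_csv(path, index=False)


def filter_by_precision(table: pd.DataFrame, max_uncertainty: float = 20.0) -> pd.DataFrame:
    """Keep localizations whose precision estimate is ``<= max_uncertainty`` nm.

    Detections whose localization precision is worse than the threshold are
    excluded; the boundary value is kept.  Row order is preserved and the
    removed count is logged.  Idempotent.
    """
    if "uncertainty" not in table.columns:
        raise ValueError("table has no 'uncertainty' column")
    mask = table["uncertainty"].to_numpy() <= max_uncertainty
    removed = int((~mask).sum())
    if removed:
        logger.info("filter_by_precision: removed %d of %d localizations", removed, len(table))
    return table.loc[mask].reset_index(drop=True)


def render_gaussian(
    table: pd.DataFrame,
    params: RenderParams | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render localizations as a 2D image of unit-mass Gaussians.

    Each localization contributes an isotropic Gaussian of constant width
    (FWHM = ``render_width``) and unit integrated mass, so the image sum
    equals the row count up to discretization at the field border.

    Parameters
    ----------
    bounds : (x_lo, x_hi, y_lo, y_hi) in nm, optional
        Field extent.  Inferred from the data (padded by 4 sigma) if absent.

    Returns
    -------
    image : (ny, nx) float array, row index = y (image convention)
    origin : (x_lo, y_lo) of the field in nm
    """
    params = params or RenderParams()
    sigma = params.sigma_nm
    px = params.pixel_size
    if px > params.render_width:
        logger.warning("render_gaussian: pixel_size %.3g nm exceeds render_width %.3g nm (undersampled kernel)", px, params.render_width)
    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    if bounds is None:
        if len(x) == 0:
            bounds = (0.0, px, 0.0, px)
        else:
            pad = 4.0 * sigma + px
            bounds = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    x_lo, x_hi, y_lo, y_hi = bounds
    nx = max(1, int(math.ceil((x_hi - x_lo) / px)))
    ny = max(1, int(math.ceil((y_hi - y_lo) / px)))
    counts, _, _ = np.histogram2d(
        y, x, bins=(ny, nx), range=((y_lo, y_lo + ny * px), (x_lo, x_lo + nx * px))
    )
    image = ndimage.gaussian_filter(counts, sigma=sigma / px, mode="constant", truncate=6.0)
    return image, (x_lo, y_lo)
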