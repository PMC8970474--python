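"""Comparative two-bait pull-down enrichment from isotope-ratio peptide data.

Two GST-tagged bait domains are compared in a single mass-spectrometry run
per replicate via enzymatic 16O/18O labelling: each peptide carries a
heavy/light intensity ratio, and the label orientation is switched between
the two replicates.  This module computes protein-level ratios
(intensity-weighted mean of peptide ratios), re-orients replicate B so that
ratios > 1 always mean enrichment toward the first bait (PSD-95 side),
normalises by the GST carrier ratio, applies the quantification filters
(both replicates present, >= 2 peptides, geometric SD of the replicate
ratios < 2, bait/contaminant exclusion), classifies proteins into scatter
quadrants, and selects proteins enriched more than a fold threshold
(default 7) toward either bait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPLICATES = ("A", "B")
#: label orientation: +1 = raw ratio already PSD-95-positive, -1 = inverted
DEFAULT_ORIENTATION = {"A": +1, "B": -1}

QUAD_PSD95 = "PSD95-enriched"
QUAD_MPP2 = "MPP2-enriched"
QUAD_NONE = "unassigned"


@dataclass
class QuantFilterParams:
    min_peptides: int = 2
    max_geometric_sd: float = 2.0
    require_both_replicates: bool = True
    fold_threshold: float = 7.0
    exclusion: tuple[str, ...] = ()   # bait proteins, contaminants (e.g. keratins)

    def __post_init__(self) -> None:
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


def protein_ratio(peptides: pd.DataFrame) -> tuple[float, int]:
    """Intensity-weighted mean peptide ratio of one protein in one replicate.

    ratio = sum(intensity_i * ratio_i) / sum(intensity_i); returns the
    ratio and the number of quantified peptides.
    """
    if len(peptides) == 0:
        raise ValueError("protein has no peptides")
    w = peptides["intensity"].to_numpy(dtype=float)
    r = peptides["ratio"].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total intensity")
    return float((w * r).sum() / total), int(len(peptides))


def orient_ratio(raw_ratio: float, replicate: str,
                 orientation: dict[str, int] | None = None) -> float:
    """Re-orient one raw ratio so > 1 means first-bait enrichment."""
    orientation = orientation or DEFAULT_ORIENTATION
    if replicate not in orientation:
        raise ValueError(f"unknown replicate label: {replicate!r}")
    return raw_ratio if orientation[replicate] > 0 else 1.0 / raw_ratio


def geometric_sd(ratios: np.ndarray) -> float:
    """Geometric standard deviation: exp of the sample SD (n-1) of log ratios."""
    logs = np.log(np.asarray(ratios, dtype=float))
    if len(logs) < 2:
        return 1.0
    return float(np.exp(np.std(logs, ddof=1)))


def compute_protein_table(
    peptides: pd.DataFrame,
    orientation: dict[str, int] | None = None,
    gst_id: str = "GST",
) -> pd.DataFrame:
    """Protein-level oriented, GST-normalised ratios per replicate.

    Input columns: protein, peptide, replicate, ratio, intensity.  Output:
    one row per protein with ratio_A/ratio_B (oriented, normalised by the
    same-replicate GST ratio), peptide counts, geometric SD of the two
    normalised replicate ratios, quadrant, and fold enrichment per side.
    GST absent from a replicate is an error naming the replicate.
    """
    orientation = orientation or DEFAULT_ORIENTATION
    per_rep: dict[str, dict[str, tuple[float, int]]] = {}
    for (prot, rep), grp in peptides.groupby(["protein", "replicate"], sort=True):
        ratio, n = protein_ratio(grp)
        per_rep.setdefault(rep, {})[prot] = (orient_ratio(ratio, rep, orientation), n)
    gst = {}
    for rep in sorted(per_rep):
        if gst_id not in per_rep[rep]:
            raise ValueError(f"GST carrier {gst_id!r} absent from replicate {rep}")
        gst[rep] = per_rep[rep][gst_id][0]

    proteins = sorted({p for rep in per_rep.values() for p in rep})
    rows = []
    for prot in proteins:
        row: dict[str, object] = {"protein": prot}
        normed = []
        for rep in sorted(per_rep):
            if prot in per_rep[rep]:
                oriented, n = per_rep[rep][prot]
                norm = oriented / gst[rep]
                row[f"ratio_{rep}"] = norm
                row[f"n_peptides_{rep}"] = n
                normed.append(norm)
            else:
                row[f"ratio_{rep}"] = np.nan
                row[f"n_peptides_{rep}"] = 0
        row["geometric_sd"] = geometric_sd(np.array(normed)) if len(normed) >= 2 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    quad, fold_m, fold_p = zip(*(
        classify_quadrant(a, b) for a, b in zip(table["ratio_A"], table["ratio_B"])
    ))
    table["quadrant"] = quad
    table["mpp2_fold_enrichment"] = fold_m
    table["psd95_fold_enrichment"] = fold_p
    return table


def classify_quadrant(ratio_a: float, ratio_b: float) -> tuple[str, float, float]:
    """Scatter-quadrant class and per-side fold enrichment.

    Both ratios > 1: first-bait (PSD-95) enriched; both < 1: second-bait
    (MPP2) enriched; mixed: unassigned.  Fold enrichment uses the weaker
    replicate: MPP2 side min(1/a, 1/b), PSD-95 side min(a, b).
    """
    if np.isnan(ratio_a) or np.isnan(ratio_b):
        return QUAD_NONE, float("nan"), float("nan")
    if ratio_a <= 0 or ratio_b <= 0:
        raise ValueError("ratios must be positive")
    fold_mpp2 = min(1.0 / ratio_a, 1.0 / ratio_b)
    fold_psd95 = min(ratio_a, ratio_b)
    if ratio_a > 1 and ratio_b > 1:
        return QUAD_PSD95, fold_mpp2, fold_psd95
    if ratio_a < 1 and ratio_b < 1:
        return QUAD_MPP2, fold_mpp2, fold_psd95
    return QUAD_NONE, fold_mpp2, fold_psd95


def apply_quant_filters(
    table: pd.DataFrame,
    params: QuantFilterParams | None = None,
) -> pd.DataFrame:
    """Apply the quantification filters to a protein table.

    Retains proteins quantified in both replicates, with at least
    ``min_peptides`` peptides in each, geometric SD of the oriented
    normalised replicate ratios strictly below ``max_geometric_sd``, and
    not on the exclusion list.  Removal counts per criterion are logged.
    """
    params = params or QuantFilterParams()
    t = table
    masks = {}
    masks["excluded"] = ~t["protein"].isin(params.exclusion)
    both = t["ratio_A"].notna() & t["ratio_B"].notna()
    masks["one_replicate"] = both if params.require_both_replicates else pd.Series(True, index=t.index)
    masks["too_few_peptides"] = (
        (t["n_peptides_A"] >= params.min_peptides) & (t["n_peptides_B"] >= params.min_peptides)
        if params.require_both_replicates
        else (t[["n_peptides_A", "n_peptides_B"]].max(axis=1) >= params.min_peptides)
    )
    masks["dispersed"] = t["geometric_sd"] < params.max_geometric_sd
    keep = pd.Series(True, index=t.index)
    for name, mask in masks.items():
        removed = int((keep & ~mask).sum())
        if removed:
            logger.info("apply_quant_filters: %s removed %d proteins", name, removed)
        keep &= mask
    return t.loc[keep].reset_index(drop=True)


def select_enriched(
    table: pd.DataFrame,
    side: str = "MPP2",
    fold_threshold: float = 7.0,
) -> pd.DataFrame:
    """Proteins enriched strictly more than ``fold_threshold`` toward one bait.

    The fold is taken from the weaker replicate, so "enriched in both
    replicates" is required; the boundary value is excluded (strict >).
    """
    if side == "MPP2":
        mask = (table["quadrant"] == QUAD_MPP2) & (table["mpp2_fold_enrichment"] > fold_threshold)
    elif side == "PSD95":
        mask = (table["quadrant"] == QUAD_PSD95) & (table["psd95_fold_enrichment"] > fold_threshold)
    else:
        raise ValueError(f"unknown side: {side!r}")
    return table.loc[mask].reset_index(drop=True)


def analyze_peptide_table(
    peptides: pd.DataFrame,
    params: QuantFilterParams | None = None,
    orientation: dict[str, int] | None = None,
    gst_id: str = "GST",
) -> pd.DataFrame:
    """Full pipeline: protein ratios, orientation, GST normalisation, filters."""
    params = params or QuantFilterParams()
    table = compute_protein_table(peptides, orientation=orientation, gst_id=gst_id)
    # GST is the normaliser, not a prey protein
    exclusion = tuple(set(params.exclusion) | {gst_id})
    params = QuantFilterParams(
        min_peptides=params.min_peptides,
        max_geometric_sd=params.max_geometric_sd,
        require_both_replicates=params.require_both_replicates,
        fold_threshold=params.fold_threshold,
        exclusion=exclusion,
    )
    return apply_quant_filters(table, params)


def read_protein_sheet(
    path: str | Path,
    column_map: dict[str, str],
    sheet: str | int = 0,
) -> pd.DataFrame:
    """Read a deposited protein-level quantification sheet (xlsx or TSV).

    ``column_map`` maps source column names to the canonical names
    protein, ratio_A, ratio_B, n_peptides_A, n_peptides_B (and optionally
    geometric_sd).  Missing geometric SD is recomputed from the two ratios.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path, sep="\t")
    missing = [c for c in column_map if c not in raw.columns]
    if missing:
        raise ValueError(f"columns not found in {path}: {missing}")
    table = raw[list(column_map)].rename(columns=column_map)
    if "geometric_sd" not in table.columns:
        table["geometric_sd"] = [
            geometric_sd(np.array([a, b])) if np.isfinite(a) and np.isfinite(b) else np.nan
            for a, b in zip(table["ratio_A"], table["ratio_B"])
        ]
    for col, default in (("n_peptides_A", 2), ("n_peptides_B", 2)):
        if col not in table.columns:
            table[col] = default
    quad, fold_m, fold_p = zip(*(
        classify_quadrant(a, b) for a, b in zip(table["ratio_A"], table["ratio_B"])
    ))
    table["quadrant"] = quad
    table["mpp2_fold_enrichment"] = fold_m
    table["psd95_fold_enrichment"] = fold_p
    return table
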