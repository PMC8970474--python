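"""Pipeline orchestration: configuration, staged execution, manifest, report.

A run is described by a YAML/dict configuration with a master seed, stage
selection, and per-module parameter blocks.  Stages execute in dependency
order; each writes TSV outputs plus a JSON manifest (config hash, package
version, per-stage row counts and filter-removal counts, warnings) so that
identical configurations reproduce identical outputs.

Stages
------
simulate        generate a bracelet-synapse population (dSTORM branch)
cluster         precision filter + DBSCAN + per-synapse ring fit and
                bracelet classification
nn              observed NN distances + toroidal-shift null histograms
proteomics      synthetic peptide table -> filtered protein table
report          summary TSVs and figures from saved stage outputs
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster as clu, locio, proteomics, simulate, spatial

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "cluster", "nn", "proteomics", "report")
#: direct prerequisites of each stage
STAGE_DEPS = {
    "simulate": (),
    "cluster": ("simulate",),
    "nn": ("cluster",),
    "proteomics": (),
    "report": (),
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGE_ORDER),
    "out_dir": "psdnano_run",
    "simulate": {"n_synapses": 50},
    "geometry": {},
    "cluster": {"epsilon": 20.0, "min_points": 5, "max_uncertainty": 20.0},
    "nn": {"bin_width": 15.0, "max_distance": 600.0, "toroidal_shift": 20.0},
    "proteomics": {"n_proteins": 188, "fold_threshold": 7.0},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default configuration with a YAML file and overrides."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(config.get(key), dict):
            config[key].update(val)
        else:
            config[key] = val
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _resolve_stages(selected: list[str]) -> tuple[list[str], list[str]]:
    """Return (runnable stages in order, skipped-with-reason messages)."""
    chosen = set(selected)
    runnable, skipped = [], []
    for stage in STAGE_ORDER:
        if stage not in chosen:
            continue
        missing = [d for d in STAGE_DEPS[stage] if d not in chosen or d not in runnable]
        if missing:
            skipped.append(f"{stage}: prerequisite stage(s) {missing} not selected")
            continue
        runnable.append(stage)
    return runnable, skipped


def run_pipeline(config: dict) -> dict:
    """Execute the selected stages and return the run manifest.

    Outputs are written under ``config['out_dir']``; the manifest is saved
    as ``manifest.json`` there as well.  A stage failure aborts the run
    with the stage name in the exception.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "config_hash": config_hash(config),
        "version": __version__,
        "seed": seed,
        "stages": {},
        "warnings": [],
    }
    stages, skipped = _resolve_stages(config["stages"])
    for msg in skipped:
        logger.warning("run_pipeline: skipping %s", msg)
        manifest["warnings"].append(msg)

    state: dict = {}
    for stage in stages:
        try:
            counts = _STAGE_FUNCS[stage](config, seed, out_dir, state)
        except Exception as exc:  # pragma: no cover - abort path
            for partial in out_dir.glob(f"{stage}_*.tsv"):
                partial.unlink()
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = counts
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(config: dict, seed: int, out_dir: Path, state: dict) -> dict:
    geometry = simulate.BraceletGeometry(**config.get("geometry", {}))
    n = int(config["simulate"]["n_synapses"])
    population = simulate.simulate_bracelet_population(geometry, n, seed=seed)
    state["population"] = population
    rows = []
    for i, (tables, truth) in enumerate(population):
        for channel, table in tables.items():
            rows.append({"synapse": i, "channel": channel, "n_localizations": len(table)})
    pd.DataFrame(rows).to_csv(out_dir / "simulate_counts.tsv", sep="\t", index=False)
    return {"n_synapses": n,
            "n_bracelets_true": int(sum(t.bracelet for _, t in population))}


def _stage_cluster(config: dict, seed: int, out_dir: Path, state: dict) -> dict:
    cfg = config["cluster"]
    params = clu.ClusterParams(epsilon=cfg["epsilon"], min_points=cfg["min_points"])
    removed = 0
    results = []
    for i, (tables, truth) in enumerate(state["population"]):
        per_channel = {}
        for channel, table in tables.items():
            filtered = locio.filter_by_precision(table, cfg["max_uncertainty"])
            removed += len(table) - len(filtered)
            per_channel[channel] = clu.detect_clusters_dbscan(filtered, params)
        peripheral = clu.combined_peripheral_centroids(
            per_channel[simulate.SPECIES_A], per_channel[simulate.SPECIES_B])
        ring = clu.estimate_ring_diameter(per_channel[simulate.SPECIES_A].centroids)
        score = clu.classify_bracelet(peripheral, truth.centre)
        results.append({
            "synapse": i,
            "n_clusters_a": len(per_channel[simulate.SPECIES_A]),
            "n_clusters_b": len(per_channel[simulate.SPECIES_B]),
            "ring_diameter_a": ring.diameter if ring.defined else np.nan,
            "bracelet_score": score.score,
            "bracelet_call": score.is_bracelet,
            "bracelet_true": truth.bracelet,
        })
        state.setdefault("cluster_sets", []).append(per_channel)
    frame = pd.DataFrame(results)
    frame.to_csv(out_dir / "cluster_synapses.tsv", sep="\t", index=False)
    state["cluster_table"] = frame
    return {
        "n_synapses": len(results),
        "localizations_removed_by_precision_filter": removed,
        "prevalence_called": float(frame["bracelet_call"].mean()),
    }


def _stage_nn(config: dict, seed: int, out_dir: Path, state: dict) -> dict:
    cfg = config["nn"]
    edges = np.arange(0.0, cfg["max_distance"] + cfg["bin_width"], cfg["bin_width"])
    observed, null = [], []
    half = simulate.BraceletGeometry(**config.get("geometry", {})).field_size / 2.0
    for i, per_channel in enumerate(state["cluster_sets"]):
        a = per_channel[simulate.SPECIES_B].centroids  # scaffold channel
        b = per_channel[simulate.SPECIES_A].centroids
        if len(a) == 0 or len(b) == 0:
            continue
        centre = np.asarray(state["population"][i][1].centre)
        bounds = (centre - half, centre + half)
        d_obs = spatial.nn_distances(a, b, mode="centre")
        d_null = spatial.toroidal_shift_null(a, b, bounds, shift=cfg["toroidal_shift"],
                                             seed=seed + 5000 + i)
        observed.append(np.histogram(d_obs, bins=edges)[0])
        null.append(np.histogram(d_null, bins=edges)[0])
    obs_mean, obs_sem = spatial.aggregate_histograms(observed, [0] * len(observed))
    null_mean, _ = spatial.aggregate_histograms(null, [0] * len(null))
    frame = pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "observed_mean": obs_mean, "null_mean": null_mean,
    })
    frame.to_csv(out_dir / "nn_histogram.tsv", sep="\t", index=False)
    return {"n_synapses_used": len(observed)}


def _stage_proteomics(config: dict, seed: int, out_dir: Path, state: dict) -> dict:
    cfg = config["proteomics"]
    pep_config = simulate.study_peptide_config(n_proteins=cfg["n_proteins"], seed=seed)
    peptides, truth = simulate.simulate_peptide_table(pep_config, seed=seed + 1)
    table = proteomics.analyze_peptide_table(peptides)
    enriched = proteomics.select_enriched(table, side="MPP2",
                                          fold_threshold=cfg["fold_threshold"])
    table.to_csv(out_dir / "proteomics_proteins.tsv", sep="\t", index=False)
    enriched.to_csv(out_dir / "proteomics_enriched_mpp2.tsv", sep="\t", index=False)
    state["protein_table"] = table
    return {"n_proteins_quantified": len(table),
            "n_enriched_mpp2": len(enriched)}


def _stage_report(config: dict, seed: int, out_dir: Path, state: dict) -> dict:
    """Summary tables and figures regenerated from the saved stage TSVs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    produced = []
    nn_path = out_dir / "nn_histogram.tsv"
    if nn_path.exists():
        frame = pd.read_csv(nn_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        centres = 0.5 * (frame["bin_lo"] + frame["bin_hi"])
        ax.bar(centres, frame["observed_mean"], width=0.9 * (frame["bin_hi"] - frame["bin_lo"]),
               color="0.6", label="observed")
        ax.plot(centres, frame["null_mean"], "k--", label="toroidal-shift null")
        ax.set_xlabel("NN distance (nm)")
        ax.set_ylabel("mean count per image")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_dir / "nn_histogram.png", dpi=150)
        plt.close(fig)
        produced.append("nn_histogram.png")
    prot_path = out_dir / "proteomics_proteins.tsv"
    if prot_path.exists():
        frame = pd.read_csv(prot_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        colors = frame["quadrant"].map({
            "PSD95-enriched": "tab:blue", "MPP2-enriched": "tab:green",
            "unassigned": "0.7"})
        ax.scatter(frame["ratio_A"], frame["ratio_B"], s=12, c=colors)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.axhline(1, color="0.8", lw=0.8)
        ax.axvline(1, color="0.8", lw=0.8)
        ax.set_xlabel("replicate A ratio (PSD-95 / MPP2, GST-normalised)")
        ax.set_ylabel("replicate B ratio (oriented)")
        fig.tight_layout()
        fig.savefig(out_dir / "enrichment_scatter.png", dpi=150)
        plt.close(fig)
        produced.append("enrichment_scatter.png")
    if not produced:
        logger.warning("report: no stage outputs found, nothing to plot")
    return {"figures": produced}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cluster": _stage_cluster,
    "nn": _stage_nn,
    "proteomics": _stage_proteomics,
    "report": _stage_report,
}
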