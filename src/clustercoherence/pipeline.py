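"""End-to-end orchestration: simulate/ingest -> partition -> screen -> coherence.

A run is described by a structured YAML config (strictly validated — unknown
keys are rejected) and produces deterministic TSV/JSON outputs plus a run
report with sha256 checksums, so that re-running the same config reproduces
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .coherence import (
    coherence_panel,
    deviation_matrix,
    load_timecourse,
    unsigned_deviation,
)
from .genome import (
    clustering_significance,
    detect_clusters,
    load_annotation,
    load_gmt,
    select_clustered_families,
)
from .screen import group_mutants, load_compendium, screen
from .simulate import (
    FamilySpec,
    PlantedDisruption,
    SimulationConfig,
    TimecourseConfig,
    default_config,
    simulate_compendium,
    simulate_genome,
    simulate_timecourses,
    write_bed,
    write_compendium,
    write_gmt,
    write_timecourse,
)

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DataError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (exit code 3 at the CLI)."""


_SCHEMA: dict[str, dict[str, Any]] = {
    "seed": None,
    "inputs": {"bed": None, "gmt": None, "compendium": None, "timecourses": None},
    "simulate": {
        "n_genes": None,
        "n_chromosomes": None,
        "n_mutants": None,
        "families": None,
        "planted_disruptions": None,
        "noise_sd": None,
        "background_disruption_rate": None,
        "background_effect": None,
        "timecourse": {
            "n_timepoints": None,
            "rho_cluster": None,
            "rho_singleton": None,
            "stressors": None,
        },
    },
    "cluster": {
        "max_intervening": None,
        "max_gap_bp": None,
        "n_permutations": None,
        "alpha": None,
    },
    "screen": {"threshold": None, "tail": None, "top_fraction": None, "kmeans_k": None},
    "coherence": {"aggregate": None, "kmeans_k": None},
    "plots": None,
}


def _check_keys(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(schema[key], dict) and isinstance(val, dict):
            if key not in ("families", "planted_disruptions"):
                _check_keys(val, schema[key], f"{path}{key}.")


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, _SCHEMA)
    if "seed" not in cfg:
        raise ConfigError("config must set an explicit seed")
    if "inputs" in cfg and "simulate" in cfg:
        raise ConfigError("give either 'inputs' or 'simulate', not both")
    if "inputs" not in cfg and "simulate" not in cfg:
        raise ConfigError("config needs an 'inputs' or a 'simulate' section")
    if "inputs" in cfg:
        for field in ("bed", "gmt"):
            if field not in cfg["inputs"]:
                raise ConfigError(f"inputs.{field} is required")
    return cfg


def _build_sim_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulate") or {})
    seed = cfg["seed"]
    if not sim:
        return default_config(seed=seed)
    fams = sim.pop("families", None)
    planted = sim.pop("planted_disruptions", None)
    tc = sim.pop("timecourse", None)
    base = default_config(seed=seed)
    kwargs: dict[str, Any] = {"seed": seed}
    kwargs.update(sim)
    kwargs["families"] = (
        tuple(FamilySpec(**{**f, "cluster_sizes": tuple(f.get("cluster_sizes", ()))})
              for f in fams)
        if fams is not None
        else base.families
    )
    kwargs["planted_disruptions"] = (
        tuple(PlantedDisruption(**d) for d in planted)
        if planted is not None
        else base.planted_disruptions
    )
    if tc is not None:
        if "stressors" in tc:
            tc = {**tc, "stressors": tuple(tc["stressors"])}
        kwargs["timecourse"] = TimecourseConfig(**tc)
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate section: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute all stages in dependency order; return the run report.

    Outputs land in ``out_dir``; the report (also written there as
    ``report.json``) lists parameters, per-stage record counts, warnings,
    and a checksum manifest of every file produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    # -- stage 1: obtain inputs --------------------------------------------
    if "simulate" in cfg or "inputs" not in cfg:
        sim_cfg = _build_sim_config(cfg)
        annotation, families, truth = simulate_genome(sim_cfg)
        compendium = simulate_compendium(annotation, truth, sim_cfg)
        emit("genome.bed", lambda p: write_bed(annotation, p))
        emit("families.gmt", lambda p: write_gmt(families, p))
        emit("compendium.tsv", lambda p: write_compendium(compendium, p))
        timecourses = None  # built after partitioning
    else:
        sim_cfg = truth = None
        inputs = cfg["inputs"]
        try:
            annotation = load_annotation(inputs["bed"])
            families = load_gmt(inputs["gmt"])
            compendium = (
                load_compendium(inputs["compendium"])
                if inputs.get("compendium")
                else None
            )
        except (OSError, ValueError) as exc:
            raise DataError(f"stage ingest: {exc}") from exc
        timecourses = []
        if inputs.get("timecourses"):
            with open(inputs["timecourses"]) as fh:
                manifest = yaml.safe_load(fh) or {}
            for stressor, path in manifest.items():
                timecourses.append(load_timecourse(path, stressor))

    # -- stage 2: cluster partitioning -------------------------------------
    ccfg = cfg.get("cluster") or {}
    max_int = ccfg.get("max_intervening", 0)
    max_gap = ccfg.get("max_gap_bp")
    n_perm = ccfg.get("n_permutations", 1000)
    alpha = ccfg.get("alpha", 0.05)
    try:
        partitions = [
            detect_clusters(annotation, fam, max_int, max_gap) for fam in families
        ]
        sigs = [
            clustering_significance(
                annotation, fam, max_int, max_gap, n_perm, seed=cfg["seed"]
            )
            for fam in families
        ]
    except ValueError as exc:
        raise DataError(f"stage partition: {exc}") from exc
    selected = select_clustered_families(sigs, alpha=alpha)
    counts["families"] = len(families)
    counts["families_selected"] = len(selected)
    for part in partitions:
        if part.unplaced:
            warnings.append(
                f"family {part.family.name}: {len(part.unplaced)} unplaced gene(s)"
            )
    import pandas as pd

    part_table = pd.concat([p.to_frame(annotation) for p in partitions])
    emit("partitions.tsv", lambda p: part_table.to_csv(p, sep="\t", index=False))
    sig_table = pd.DataFrame(
        {
            "family": [s.family_name for s in sigs],
            "observed_clustered": [s.observed_clustered_count for s in sigs],
            "p_value": [s.p_value for s in sigs],
            "selected": [s.family_name in selected for s in sigs],
        }
    )
    emit("clustering_significance.tsv",
         lambda p: sig_table.to_csv(p, sep="\t", index=False))

    # -- stage 3: disruption screen ----------------------------------------
    scfg = cfg.get("screen") or {}
    if compendium is not None:
        try:
            matrix = screen(
                compendium,
                partitions,
                threshold=scfg.get("threshold", 1.0),
                tail=scfg.get("tail", "upper"),
                top_fraction=scfg.get("top_fraction"),
            )
            matrix = group_mutants(
                matrix, k=scfg.get("kmeans_k", 3), seed=cfg["seed"]
            )
        except ValueError as exc:
            raise DataError(f"stage screen: {exc}") from exc
        counts["screen_cells"] = len(matrix.cells)
        emit("pvalues.tsv", lambda p: matrix.pvalues.to_csv(p, sep="\t"))
        emit("scores.tsv", lambda p: matrix.scores.to_csv(p, sep="\t"))
        emit("cells.tsv",
             lambda p: matrix.cell_table().to_csv(p, sep="\t", index=False))
        emit("mutant_groups.tsv", lambda p: matrix.mutant_groups.to_csv(p, sep="\t"))
        if cfg.get("plots", False):
            from .plotting import heatmap

            emit("scores_heatmap.png",
                 lambda p: heatmap(matrix.scores, p, "deviation score (1 - P)",
                                   cmap="viridis", vmin=0, vmax=1))

    # -- stage 4: coherence -------------------------------------------------
    if timecourses is None and sim_cfg is not None:
        timecourses = simulate_timecourses(
            partitions, truth, sim_cfg, gene_ids=annotation.gene_ids
        )
        for tc in timecourses:
            emit(f"timecourse_{tc.stressor}.tsv",
                 lambda p, tc=tc: write_timecourse(tc, p))
        emit("truth.json", lambda p: truth.to_json(p))
    if timecourses:
        cocfg = cfg.get("coherence") or {}
        agg = cocfg.get("aggregate", "mean")
        clustered, singleton, family_m = coherence_panel(
            timecourses, partitions, aggregate=agg
        )
        if cocfg.get("kmeans_k"):
            # heatmap-style display order: group stressors and families
            from .coherence import kmeans_order

            k = cocfg["kmeans_k"]
            rows = kmeans_order(clustered, k, seed=cfg["seed"], axis=0)
            cols = kmeans_order(clustered, k, seed=cfg["seed"], axis=1)
            clustered = clustered.loc[rows, cols]
            singleton = singleton.loc[rows, cols]
            family_m = family_m.loc[rows, cols]
        dev = deviation_matrix(clustered, singleton)
        counts["stressors"] = len(timecourses)
        emit("coherence_clustered.tsv", lambda p: clustered.to_csv(p, sep="\t"))
        emit("coherence_singleton.tsv", lambda p: singleton.to_csv(p, sep="\t"))
        emit("coherence_family.tsv", lambda p: family_m.to_csv(p, sep="\t"))
        emit("deviation.tsv", lambda p: dev.to_csv(p, sep="\t"))
        emit("deviation_unsigned.tsv",
             lambda p: unsigned_deviation(clustered, singleton).to_csv(p, sep="\t"))
        if cfg.get("plots", False):
            from .plotting import heatmap

            emit("deviation_heatmap.png",
                 lambda p: heatmap(dev, p, "clustered PCC - singleton PCC"))

    # -- report --------------------------------------------------------------
    report = {
        "version": __version__,
        "parameters": cfg,
        "counts": counts,
        "warnings": warnings,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str) + "\n")
    return report
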