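"""Full phyloclimatic analysis pipeline.

Stages, mirroring the analysis workflow end to end: occurrence cleaning;
per-variable mean-AUC and correlation-based variable selection; tip
envelope fitting; Brownian-motion ancestral envelope reconstruction;
projection of well-supported nodes into their age-matched paleoclimate
scenario and into present-day climate; pairwise niche overlap (D, I) and
the age-range correlation test.  Every artifact is a pure function of
(inputs, config, seed); a manifest records the configuration hash and
per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import EnvelopeReconstruction, reconstruct_envelopes
from .bioclim import (
    EnvelopeModel,
    SuitabilitySurface,
    classify_surface,
    fit_envelope,
    project_envelope,
    write_envelope_table,
)
from .evaluation import MeanAucTable, mean_auc_per_variable
from .geodata import (
    ClimateLayer,
    ClimateScenario,
    OccurrenceSet,
    clean_occurrences,
    read_occurrences,
    read_scenario,
    sample_values,
    write_ascii_grid,
)
from .niche_stats import ARCResult, OverlapMatrix, age_range_correlation, overlap_matrix
from .phylo import DatedTree, assign_scenario, read_tree, supported_nodes
from .varselect import SelectionConfig, correlation_matrix, select_variables

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "project_nodes"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    scenario_manifests: list[str]
    occurrences: str
    tree: str
    output_dir: str
    seed: int
    # variable selection; if `variables` is given, selection is skipped
    variables: list[str] | None = None
    selection_threshold: float = 0.8
    min_unique: int = 10
    n_background: int | None = None
    # node filtering / projection
    min_pp: float = 0.95
    # overlap / ARC
    arc_statistic: str = "D"
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    scenarios: list[ClimateScenario]
    present: ClimateScenario
    tree: DatedTree
    cleaned: dict[str, OccurrenceSet]
    mean_auc: MeanAucTable | None
    retained_variables: list[str]
    tip_envelopes: dict[str, EnvelopeModel]
    reconstruction: EnvelopeReconstruction
    node_surfaces: dict[int, dict[str, SuitabilitySurface]]
    tip_surfaces: dict[str, SuitabilitySurface]
    overlap: OverlapMatrix | None
    arc: ARCResult | None
    manifest: dict


def _load_inputs(config: PipelineConfig):
    scenarios = [read_scenario(p) for p in config.scenario_manifests]
    present = min(scenarios, key=lambda s: s.age_ma)
    tree = read_tree(config.tree)
    occurrences = read_occurrences(config.occurrences)
    return scenarios, present, tree, occurrences


def _select_stage(
    config: PipelineConfig,
    cleaned: Mapping[str, OccurrenceSet],
    present: ClimateScenario,
) -> tuple[MeanAucTable | None, list[str], list]:
    if config.variables is not None:
        logger.info("variable selection skipped: pre-specified variable list %s",
                    config.variables)
        return None, list(config.variables), []
    mean_auc = mean_auc_per_variable(
        cleaned, present,
        min_unique=config.min_unique,
        seed=config.seed,
        n_background=config.n_background,
    )
    pooled = pd.concat(
        [sample_values(present, occ.points) for occ in cleaned.values()],
        ignore_index=True,
    )
    corr = correlation_matrix(pooled)
    sel = select_variables(
        corr, mean_auc, SelectionConfig(threshold=config.selection_threshold)
    )
    return mean_auc, sel.retained, sel.log


def project_nodes(
    supported: list[int],
    reconstruction: EnvelopeReconstruction,
    tree: DatedTree,
    scenarios: list[ClimateScenario],
    present: ClimateScenario,
) -> dict[int, dict[str, SuitabilitySurface]]:
    """Project each supported node into its age-matched scenario and present.

    Returns node_id -> {"assigned": surface, "present": surface}; the
    assigned scenario is the one closest in age to the node (ties go
    younger).
    """
    out: dict[int, dict[str, SuitabilitySurface]] = {}
    for node_id in supported:
        env = reconstruction.node_envelopes.get(node_id)
        if env is None:
            raise KeyError(f"no reconstructed envelope for node {node_id}")
        node = tree.node_by_id(node_id)
        assigned = assign_scenario(node.age_ma, scenarios)
        out[node_id] = {
            "assigned": project_envelope(env, assigned),
            "present": project_envelope(env, present),
        }
    return out


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write per-stage artifacts."""
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    scenarios, present, tree, occurrences = _load_inputs(config)

    # stage: cleaning
    cleaned: dict[str, OccurrenceSet] = {}
    reports = []
    for name, occ in occurrences.items():
        occ_clean, report = clean_occurrences(occ, present)
        if len(occ_clean):
            cleaned[name] = occ_clean
        reports.append(report)
    logger.info("cleaned %d species (%d dropped entirely)",
                len(cleaned), len(occurrences) - len(cleaned))

    # stage: variable selection
    mean_auc, retained, exclusion_log = _select_stage(config, cleaned, present)
    logger.info("retained variables: %s", retained)

    # stage: tip envelopes
    tip_envelopes: dict[str, EnvelopeModel] = {}
    n_below_min = 0
    for name, occ in cleaned.items():
        table = sample_values(present, occ.points, variables=retained)
        model = fit_envelope(table, taxon=name)
        if model.n_points < config.min_unique:
            n_below_min += 1
        tip_envelopes[name] = model
    logger.info("fitted %d tip envelopes (%d below %d points)",
                len(tip_envelopes), n_below_min, config.min_unique)

    # stage: ancestral reconstruction (only tips present in the data)
    tree_tips = set(tree.tip_labels)
    missing = tree_tips - set(tip_envelopes)
    if missing:
        raise ValueError(f"tree tips without envelopes: {sorted(missing)}")
    reconstruction = reconstruct_envelopes(tree, tip_envelopes)

    # stage: node projections
    nodes = supported_nodes(tree, min_pp=config.min_pp)
    logger.info("%d nodes above pp %.2f", len(nodes), config.min_pp)
    node_surfaces = project_nodes(nodes, reconstruction, tree, scenarios, present)

    # stage: tip projections + overlap + ARC
    tip_surfaces = {
        name: project_envelope(env, present) for name, env in tip_envelopes.items()
    }
    overlap = arc = None
    if len(tip_surfaces) >= 2:
        overlap = overlap_matrix(tip_surfaces)
        n = len(overlap.taxa)
        if n * (n - 1) // 2 >= 3:
            arc = age_range_correlation(
                overlap, tree,
                statistic=config.arc_statistic,  # type: ignore[arg-type]
                n_permutations=config.n_permutations,
                seed=config.seed,
            )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_species_input": len(occurrences),
        "n_species_modeled": len(tip_envelopes),
        "n_species_below_min_points": n_below_min,
        "retained_variables": retained,
        "n_supported_nodes": len(nodes),
        "n_bound_repairs": len(reconstruction.repairs),
    }

    result = PipelineResult(
        config=config,
        scenarios=scenarios,
        present=present,
        tree=tree,
        cleaned=cleaned,
        mean_auc=mean_auc,
        retained_variables=retained,
        tip_envelopes=tip_envelopes,
        reconstruction=reconstruction,
        node_surfaces=node_surfaces,
        tip_surfaces=tip_surfaces,
        overlap=overlap,
        arc=arc,
        manifest=manifest,
    )
    if write:
        _write_artifacts(result, exclusion_log, reports, outdir)
    return result


def _write_artifacts(result: PipelineResult, exclusion_log, reports, outdir: Path):
    config = result.config
    pd.DataFrame([asdict(r) for r in reports]).to_csv(
        outdir / "cleaning_report.csv", index=False
    )
    if result.mean_auc is not None:
        result.mean_auc.to_csv(outdir / "mean_auc.csv")
    with open(outdir / "retained_variables.txt", "w") as fh:
        fh.write("\n".join(result.retained_variables) + "\n")
    with open(outdir / "exclusion_log.txt", "w") as fh:
        for rec in exclusion_log:
            fh.write(
                f"dropped {rec.dropped}: pair ({rec.pair[0]}, {rec.pair[1]}) "
                f"r={rec.r:+.3f} — {rec.reason}\n"
            )
    write_envelope_table(result.tip_envelopes, outdir / "tip_envelopes.csv")
    result.reconstruction.bounds_table(result.tree).to_csv(
        outdir / "ancestral_envelopes.csv", index=False
    )
    result.reconstruction.rates_table().to_csv(outdir / "bm_rates.csv", index=False)
    result.tree.node_table().to_csv(outdir / "node_table.csv", index=False)

    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for node_id, pair in result.node_surfaces.items():
        for kind, surface in pair.items():
            base = f"node{node_id}_{kind}"
            _write_surface(surface, result.present, maps_dir / f"{base}.asc")
            classes = classify_surface(surface)
            layer = ClimateLayer(
                variable_name=base + "_class",
                grid=classes.astype(float),
                origin=result.present.origin,
                cell_size=result.present.cell_size,
            )
            write_ascii_grid(layer, maps_dir / f"{base}_class.asc")

    if result.overlap is not None:
        result.overlap.to_dataframe("D").to_csv(outdir / "overlap_D.csv")
        result.overlap.to_dataframe("I").to_csv(outdir / "overlap_I.csv")
        summary = {
            "mean_D": result.overlap.mean_offdiagonal("D"),
            "mean_I": result.overlap.mean_offdiagonal("I"),
        }
        sisters = [
            p for p in result.tree.sister_pairs()
            if p[0] in result.overlap.taxa and p[1] in result.overlap.taxa
        ]
        if sisters:
            summary["mean_D_sister_pairs"] = result.overlap.mean_over_pairs("D", sisters)
            summary["mean_I_sister_pairs"] = result.overlap.mean_over_pairs("I", sisters)
        with open(outdir / "overlap_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    if result.arc is not None:
        with open(outdir / "arc.json", "w") as fh:
            json.dump(
                {k: v for k, v in asdict(result.arc).items()}, fh, indent=2
            )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def _write_surface(surface: SuitabilitySurface, scenario: ClimateScenario, path: Path):
    grid = surface.grid.astype(float).copy()
    grid[surface.nodata_mask] = -9999.0
    layer = ClimateLayer(
        variable_name=path.stem,
        grid=grid,
        origin=scenario.origin,
        cell_size=scenario.cell_size,
        nodata_value=-9999.0,
    )
    write_ascii_grid(layer, path)
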