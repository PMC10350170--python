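"""Readers/writers, pipeline configuration, and the end-to-end orchestrator.

Interchange format: comma-separated UTF-8 text with a one-line schema header
(``# alloatlas-table v1 kind=cell_table state=raw``) so readers can reject
tables written by an incompatible version. Coordinates are real-valued µm in
an ROI-local frame, origin top-left, y increasing downward (image
convention, matching segmentation-mask provenance).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import GROUPS, ConfigurationError, DataError, derived_int_seed, get_state, marker_columns, set_state
from .gating import GatingRuleSet, default_ruleset
from .phenotype import assign_phenotypes, compute_proportions, preprocess, proportion_matrix
from .predict import bootstrap_feature_frequency, evaluate_model
from .spatial import (
    build_graphs,
    cluster_neighborhoods,
    cn_proportions,
    compute_neighborhood_profiles,
    distance_to_reference,
    interaction_network,
    median_distances,
    test_interactions_by_group,
)
from .stats import test_features
from .synth import default_cohort_config, generate_cohort
from .trajectory import TrajectoryModel, pseudotime_density_by_group

logger = logging.getLogger("alloatlas")

SCHEMA_VERSION = "v1"
REQUIRED_COLUMNS = ("cell_id", "roi", "patient", "group", "x", "y")


def _header(kind: str, state: str | None = None) -> str:
    extra = f" state={state}" if state else ""
    return f"# alloatlas-table {SCHEMA_VERSION} kind={kind}{extra}\n"


def write_table(df: pd.DataFrame, path: str | Path, kind: str, state: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header(kind, state))
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_header(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        line = fh.readline().strip()
    parts = line.split()
    if len(parts) < 4 or parts[0] != "#" or parts[1] != "alloatlas-table":
        raise DataError(f"{path}: missing schema header")
    meta = {"version": parts[2]}
    for token in parts[3:]:
        key, _, val = token.partition("=")
        meta[key] = val
    if meta["version"] != SCHEMA_VERSION:
        raise DataError(f"{path}: schema version {meta['version']} not supported (expected {SCHEMA_VERSION})")
    return meta


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    meta = _read_header(path)
    if meta.get("kind") != kind:
        raise DataError(f"{path}: table kind {meta.get('kind')!r}, expected {kind!r}")
    return pd.read_csv(path, skiprows=1)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    write_table(table, path, "cell_table", state=get_state(table))


def read_cell_table(path: str | Path, groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """Validated cell table; row order preserved; processing state restored
    from the schema header (defaults to raw)."""
    meta = _read_header(path)
    if meta.get("kind") != "cell_table":
        raise DataError(f"{path}: table kind {meta.get('kind')!r}, expected 'cell_table'")
    table = pd.read_csv(path, skiprows=1)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    bad_groups = set(table["group"].unique()) - set(groups)
    if bad_groups:
        raise DataError(f"{path}: unknown group label(s) {sorted(bad_groups)}")
    state = meta.get("state", "raw")
    markers = marker_columns(table)
    if state == "raw":
        vals = table[markers].to_numpy(dtype=float)
        if (vals < 0).any():
            row = int(np.argwhere(vals < 0)[0][0])
            raise DataError(f"{path}: negative raw intensity at row {row}")
    per_patient_groups = table.groupby("patient")["group"].nunique()
    if (per_patient_groups > 1).any():
        bad = per_patient_groups[per_patient_groups > 1].index[0]
        raise DataError(f"{path}: patient {bad!r} maps to multiple clinical groups")
    dup = table.duplicated(subset=["roi", "cell_id"])
    if dup.any():
        raise DataError(f"{path}: duplicate (roi, cell_id) at row {int(np.flatnonzero(dup)[0])}")
    return set_state(table, state)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study settings."""

    output_dir: str = "alloatlas_run"
    cell_table: str | None = None  # path; None -> synthesize
    gating_rules: str | None = None  # path; None -> default ruleset
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["synth", "phenotype", "stats", "spatial", "trajectory", "predict"])
    # synth
    n_patients_per_group: dict[str, int] = field(default_factory=lambda: {"NR": 24, "TCMR": 41, "CR": 14})
    rois_per_patient: int = 1
    cells_per_roi: float = 4800.0
    # phenotype
    cofactor: float = 5.0
    # spatial
    k: int = 10
    n_perm: int = 1000
    alpha: float = 0.01
    n_cn: int = 9
    reference_label: str = "Endothelial cells"
    # trajectory
    trajectory_metaclusters: list[str] = field(default_factory=lambda: ["CD4 T-cells", "CD8 T-cells"])
    coarse_k: dict[str, int] = field(default_factory=lambda: {"default": 2, "CD8 T-cells": 5})
    # predict
    predict_contrast: list[str] = field(default_factory=lambda: ["NR", "TCMR"])
    n_boot: int = 5000
    selection_threshold: float = 0.5
    n_iter: int = 1000
    train_frac: float = 0.75
    n_lambdas: int = 100

    def validate(self) -> None:
        if self.cofactor <= 0 or self.k < 1 or self.n_perm < 1 or self.n_cn < 1:
            raise ConfigurationError("cofactor, k, n_perm, n_cn must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.train_frac < 1) or not (0 <= self.selection_threshold <= 1):
            raise ConfigurationError("alpha, train_frac in (0,1); selection_threshold in [0,1]")
        if self.n_boot < 1 or self.n_iter < 1 or self.n_lambdas < 2:
            raise ConfigurationError("n_boot, n_iter >= 1 and n_lambdas >= 2")
        unknown = set(self.stages) - {"synth", "phenotype", "stats", "spatial", "trajectory", "predict"}
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {sorted(unknown)}")
        if len(self.predict_contrast) != 2:
            raise ConfigurationError("predict_contrast must name exactly 2 groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# orchestrator


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order and write per-stage tables, a log
    and a machine-readable manifest; reruns with the same config and seed are
    bit-stable for all outputs (the log carries no timestamps either)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, kind: str, state: str | None = None) -> None:
        path = out / name
        write_table(df.reset_index(drop=True) if df.index.name is None and isinstance(df.index, pd.RangeIndex) else df.reset_index(), path, kind, state)
        written.append(path)
        logger.info("wrote %s (%d rows)", name, len(df))

    stage = "setup"
    try:
        logger.info("parameters: %s", json.dumps(config.to_dict(), sort_keys=True))
        enabled = set(config.stages)
        rules = GatingRuleSet.from_file(config.gating_rules) if config.gating_rules else default_ruleset()
        need_phenotype = bool(enabled & {"phenotype", "stats", "spatial", "trajectory", "predict"})

        # --- synth / input
        stage = "synth"
        truth = None
        if "synth" in enabled:
            cohort_cfg = default_cohort_config(
                n_patients_per_group=dict(config.n_patients_per_group),
                rois_per_patient=config.rois_per_patient,
                cells_per_roi=config.cells_per_roi,
                seed=derived_int_seed(config.seed, 1),
            )
            table, truth = generate_cohort(cohort_cfg)
            save(table, "cells.csv", "cell_table", state="raw")
            save(truth.cells, "truth.csv", "ground_truth")
        elif config.cell_table:
            table = read_cell_table(config.cell_table)
        elif need_phenotype:
            raise ConfigurationError("no cell table: enable the synth stage or set cell_table")
        else:
            table = None

        # --- phenotype
        assignment = None
        std = None
        if need_phenotype and table is not None:
            stage = "phenotype"
            std = preprocess(table, cofactor=config.cofactor)
            assignment = assign_phenotypes(std, rules)
            props_meta = compute_proportions(assignment, table, "all_cells", level="metacluster")
            props_final = compute_proportions(assignment, table, "all_cells", level="final")
            if "phenotype" in enabled:
                save(assignment, "assignments.csv", "assignment")
                save(props_meta, "proportions_metacluster.csv", "proportions")
                save(props_final, "proportions_final.csv", "proportions")

        # --- stats
        if "stats" in enabled:
            stage = "stats"
            save(test_features(props_meta), "stats_metacluster.csv", "group_tests")
            stats_final = test_features(props_final)
            save(stats_final, "stats_final.csv", "group_tests")
        else:
            stats_final = None

        # --- spatial
        if "spatial" in enabled:
            stage = "spatial"
            graphs = build_graphs(table, k=config.k)
            labels = assignment["final"]
            interactions = test_interactions_by_group(
                graphs, labels, table, n_perm=config.n_perm, alpha=config.alpha, seed=derived_int_seed(config.seed, 2)
            )
            save(interactions, "interactions.csv", "interactions")
            save(interaction_network(interactions), "network_edges.csv", "network")
            profiles = compute_neighborhood_profiles(graphs, labels)
            cn = cluster_neighborhoods(profiles, n_cn=config.n_cn, seed=derived_int_seed(config.seed, 3))
            save(cn.assignment.to_frame(), "cn_assignments.csv", "cn_assignment")
            save(cn.centroids, "cn_centroids.csv", "cn_centroids")
            cn_props = cn_proportions(cn, table)
            save(cn_props, "cn_proportions.csv", "proportions")
            save(test_features(cn_props), "cn_stats.csv", "group_tests")
            if config.reference_label in set(labels.unique()):
                dist = distance_to_reference(table, labels, config.reference_label)
                save(median_distances(dist), "distances_median.csv", "distances")
            else:
                logger.warning("reference label %r absent; distance profile skipped", config.reference_label)

        # --- trajectory
        if "trajectory" in enabled:
            stage = "trajectory"
            for meta in config.trajectory_metaclusters:
                cells = std.loc[assignment.index[assignment["metacluster"] == meta]]
                groups_m = cells["group"]
                coarse_k = config.coarse_k.get(meta, config.coarse_k.get("default", 2))
                if len(cells) < max(10, coarse_k) or not (groups_m == "NR").any():
                    logger.warning("trajectory for %r skipped (too few cells or no NR cells)", meta)
                    continue
                model = TrajectoryModel(coarse_k=coarse_k, seed=derived_int_seed(config.seed, 4)).fit(cells, groups_m)
                tag = meta.replace(" ", "_").replace("/", "-")
                save(model.result_.frame(), f"trajectory_{tag}.csv", "trajectory")
                save(pseudotime_density_by_group(model.result_, groups_m), f"pseudotime_density_{tag}.csv", "density")

        # --- predict
        if "predict" in enabled:
            stage = "predict"
            ga, gb = config.predict_contrast
            if stats_final is None:
                stats_final = test_features(compute_proportions(assignment, table, "all_cells", level="final"))
            mask = stats_final["comparison"].isin([f"{ga} vs {gb}", f"{gb} vs {ga}"])
            sig = stats_final.loc[mask & stats_final["significant"], "feature"].tolist()
            if not sig:
                fallback = stats_final.loc[mask].nsmallest(5, "p_raw")["feature"].tolist()
                logger.warning("no significant features for %s vs %s; falling back to top %d by raw p", ga, gb, len(fallback))
                sig = fallback
            props_final = compute_proportions(assignment, table, "all_cells", level="final")
            wide = proportion_matrix(props_final).fillna(0.0)
            outcome_map = table.drop_duplicates("patient").set_index("patient")["group"]
            keep = outcome_map[outcome_map.isin([ga, gb])].index
            X = wide.loc[keep, sig]
            y = (outcome_map.loc[keep] == gb).astype(int)
            selection = bootstrap_feature_frequency(
                X, y, n_boot=config.n_boot, threshold=config.selection_threshold,
                seed=derived_int_seed(config.seed, 5), n_lambdas=config.n_lambdas,
            )
            final_features = selection.selected or sig
            if not selection.selected:
                logger.warning("bootstrap selected no features at threshold %.2f; using all candidates", config.selection_threshold)
            report = evaluate_model(
                X, y, features=final_features, n_iter=config.n_iter, train_frac=config.train_frac,
                seed=derived_int_seed(config.seed, 6), n_lambdas=config.n_lambdas,
            )
            payload = {
                "contrast": [ga, gb],
                "positive_class": gb,
                "candidate_features": sig,
                "selection_frequencies": {k: float(v) for k, v in selection.frequencies.items()},
                "selected_features": final_features,
                "metric_summary": {m: {"mean": float(r["mean"]), "sd": float(r["sd"])} for m, r in report.metric_summary.iterrows()},
                "coefficients": {k: float(v) for k, v in report.coefficients.items()},
                "median_predictions": {k: (None if v != v else float(v)) for k, v in report.median_predictions.items()},
                "auc_median_prediction": float(report.auc_median_pred),
                "spearman_rho": None if report.spearman_rho != report.spearman_rho else float(report.spearman_rho),
                "spearman_p": float(report.spearman_p),
            }
            path = out / "model_report.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
            written.append(path)
            logger.info("wrote model_report.json")
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage
        logger.removeHandler(handler)
        handler.close()
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "schema": SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return out
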