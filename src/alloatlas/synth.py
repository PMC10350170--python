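"""Synthetic liver-allograft cohorts with the compositional, expressional and
spatial structure the analysis stages assume.

The generator starts at the segmented-cell level (no pixels): each ROI is a
rectangle of real-valued centroids with per-marker raw intensities. Design:

* cell types are drawn per clinical group from a configurable composition
  vector; the default emulates the study cohort (hepatocyte-dominated tissue,
  ~10% macrophages, rare B/plasma/monocyte populations, and group-dependent
  shifts such as enriched PD1+ T-cell and HLADR+ M2 fractions in TCMR);
* marker expression is log-normal per (type, marker) — right-skewed raw
  intensities, negatives impossible by construction, which is exactly what
  motivates the arcsinh transform downstream;
* spatial structure: background types follow a homogeneous Poisson scatter;
  types named in an attraction pair are co-placed as Neyman-Scott offspring
  (Gaussian children around shared uniform parents), the simplest point
  process with tunable cross-type aggregation; motif blocks carve the ROI
  into vertical bands with their own composition, planting higher-order
  neighborhood structure;
* a single master seed drives everything; per-ROI streams are derived from
  (group, patient, roi) spawn keys, so output is bit-identical across reruns
  and insensitive to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ConfigurationError, derived_rng, set_state
from .gating import GatingRuleSet, MarkerPanel, default_panel, default_ruleset

# log-normal (meanlog, sdlog) levels for negative / intermediate / high
# expression of a marker. Raw medians ~0.8 / 8 / 40 counts: after
# asinh(x/5) and channel z-scoring, "high" sits far above the z>=0.5
# positivity cut and "neg" far below it for every minority marker.
NEG = (math.log(0.8), 0.20)
MOD = (math.log(8.0), 0.20)
HIGH = (math.log(40.0), 0.20)


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort."""

    n_patients_per_group: dict[str, int]
    rois_per_patient: int = 1
    roi_size: tuple[float, float] = (1000.0, 1000.0)  # µm, matches ~1 mm² ROIs
    cells_per_roi: float = 4800.0  # mean count; realized counts are Poisson
    composition: dict[str, dict[str, float]] = field(default_factory=dict)  # group -> type -> prob
    expression_templates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    attraction_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    motif_blocks: list[tuple[float, dict[str, float]]] = field(default_factory=list)
    noise_sd: float = 0.0  # extra multiplicative log-scale noise
    patient_effect_sd: float = 0.0  # per-patient multiplicative intensity factor (off by default)
    seed: int = 0

    def validate(self) -> None:
        if self.rois_per_patient <= 0 or self.cells_per_roi <= 0:
            raise ConfigurationError("rois_per_patient and cells_per_roi must be positive")
        if self.roi_size[0] <= 0 or self.roi_size[1] <= 0:
            raise ConfigurationError("roi_size must be positive")
        if not self.n_patients_per_group or any(n <= 0 for n in self.n_patients_per_group.values()):
            raise ConfigurationError("n_patients_per_group must be positive per group")
        comps = [(f"group {g!r}", c) for g, c in self.composition.items()]
        comps += [(f"motif block {i}", c) for i, (_, c) in enumerate(self.motif_blocks)]
        for name, comp in comps:
            vals = np.array(list(comp.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"composition of {name} must be nonnegative and sum to 1")
            for t in comp:
                if t not in self.expression_templates:
                    raise ConfigurationError(f"cell type {t!r} in {name} has no expression template")
        known = set(self.expression_templates)
        for a, b, strength in self.attraction_pairs:
            if a not in known or b not in known:
                raise ConfigurationError(f"attraction pair ({a!r}, {b!r}) names an unknown cell type")
            if strength <= 0:
                raise ConfigurationError("attraction strength must be positive")
        frac = sum(f for f, _ in self.motif_blocks)
        if frac >= 1.0 or any(f <= 0 for f, _ in self.motif_blocks):
            raise ConfigurationError("motif block fractions must be positive and sum to < 1")
        for g in self.n_patients_per_group:
            if g not in self.composition:
                raise ConfigurationError(f"no composition for group {g!r}")


@dataclass
class GroundTruth:
    """Per-cell truth labels and planted structure, aligned with the table index."""

    cells: pd.DataFrame  # columns: true_label, motif_block
    attraction_pairs: list[tuple[str, str, float]]
    patient_outcomes: pd.Series  # patient -> clinical group


def templates_from_ruleset(
    ruleset: GatingRuleSet | None = None,
    panel: MarkerPanel | None = None,
    overrides: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Derive one expression template per final label from the gating rules:
    markers required ">=" go high, markers required "<" (and everything
    unmentioned) stay negative, nuclear intercalators are high everywhere.
    Explicit overrides handle multi-level markers (CD3 within CD4 T-cells).
    """
    ruleset = ruleset or default_ruleset()
    panel = panel or default_panel()
    sub_rule = {r.target: r for r in ruleset.subcluster_rules()}
    meta_rule = {r.target: r for r in ruleset.metacluster_rules()}
    parent_of = ruleset.parent_of_final()
    templates: dict[str, dict[str, tuple[float, float]]] = {}
    for label in ruleset.final_labels():
        tpl = {m: NEG for m in panel.names}
        for m, role in panel.roles.items():
            if role == "nuclear":
                tpl[m] = HIGH
        parent = parent_of[label]
        for source in (meta_rule.get(parent), sub_rule.get(label)):
            if source is None:
                continue
            for p in source.predicates:
                tpl[p.marker] = HIGH if p.comparator == ">=" else NEG
        templates[label] = tpl
    # CD3 carries three levels inside the T-cell compartments: resident-memory
    # CD4 cells are CD3-intermediate, the generic CD4/CD8 pools are CD3-high.
    if "Resident memory CD4 T-cells" in templates:
        templates["Resident memory CD4 T-cells"]["CD3"] = MOD
    for label, tpl in (overrides or {}).items():
        templates.setdefault(label, {m: NEG for m in panel.names}).update(tpl)
    return templates


def _study_composition() -> dict[str, dict[str, float]]:
    """Group-wise composition over the 41 final labels (fractions of cells).

    NR is the hepatocyte-dominated baseline; TCMR enriches exhausted T-cell
    phenotypes (PD1+ CD4/CD8, HLADR+ Treg), proliferating CD8 T-cells,
    HLADR+ M2 macrophages and proliferating hepatocytes while depleting
    resident-memory CD4 T-cells and CD16+ M2 macrophages; CR shifts toward
    activated CD4 pools and HLADR+ parenchymal variants without the PD1+
    expansion.
    """
    nr = {
        "Hepatocytes": 0.586, "Ki67+ hepatocytes": 0.020, "HLADR+ hepatocytes": 0.040,
        "Endothelial cells": 0.050, "Ki67+ endothelial cells": 0.004, "HLADR+ endothelial cells": 0.006,
        "Cholangiocytes": 0.014, "Ki67+ cholangiocytes": 0.002, "HLADR+ cholangiocytes": 0.002,
        "M1 macrophages": 0.025, "CD11b+ M1 macrophages": 0.010, "CD16+ M1 macrophages": 0.012,
        "Proliferating M1 macrophages": 0.006, "M2 macrophages": 0.020, "CD11b+ M2 macrophages": 0.008,
        "CD16+ M2 macrophages": 0.012, "Proliferating M2 macrophages": 0.004, "HLADR+ M2 macrophages": 0.003,
        "CD3+CD4+ T-cells": 0.015, "Resident memory CD4 T-cells": 0.020, "Naive CD4 T-cells": 0.008,
        "Activated CD4 T-cells": 0.007, "Treg": 0.004, "HLADR+ Treg": 0.002,
        "PD1+ CD4 T-cells": 0.003, "Proliferating CD4 T-cells": 0.004, "CD16+ CD4 T-cells": 0.002,
        "CD3+CD8+ T-cells": 0.030, "Proliferating CD8 T-cells": 0.008, "Cytotoxic T-cells": 0.006,
        "PD1+ CD8 T-cells": 0.007, "PD1+CD28+ CD8 T-cells": 0.004,
        "Classical monocytes": 0.006, "Non-classical monocytes": 0.004,
        "Intermediate monocytes": 0.003, "Activated monocytes": 0.001,
        "Neutrophils": 0.020,
        "B cells": 0.006, "Proliferating B cells": 0.002, "Activated B cells": 0.002,
        "Plasma cells": 0.012,
    }
    tweaks = {
        "TCMR": {
            "PD1+ CD4 T-cells": 3.0, "PD1+ CD8 T-cells": 2.5, "PD1+CD28+ CD8 T-cells": 2.0,
            "HLADR+ Treg": 2.5, "Proliferating CD8 T-cells": 2.5, "CD3+CD8+ T-cells": 1.6,
            "CD3+CD4+ T-cells": 1.8, "HLADR+ M2 macrophages": 3.0, "Proliferating M1 macrophages": 2.0,
            "Ki67+ hepatocytes": 2.0, "HLADR+ hepatocytes": 1.8, "HLADR+ cholangiocytes": 2.0,
            "Resident memory CD4 T-cells": 0.4, "CD16+ M2 macrophages": 0.5,
            "Intermediate monocytes": 0.5, "Non-classical monocytes": 0.6,
            "Classical monocytes": 1.5, "Plasma cells": 1.5, "B cells": 1.4,
        },
        "CR": {
            "CD3+CD4+ T-cells": 2.2, "Activated CD4 T-cells": 1.8, "CD3+CD8+ T-cells": 1.5,
            "HLADR+ hepatocytes": 1.8, "HLADR+ cholangiocytes": 2.0, "HLADR+ M2 macrophages": 2.5,
            "Resident memory CD4 T-cells": 0.3, "CD16+ M1 macrophages": 0.5, "CD16+ M2 macrophages": 0.6,
            "Intermediate monocytes": 0.5, "Plasma cells": 0.6,
        },
    }
    out = {"NR": _normalize(nr)}
    for g, mult in tweaks.items():
        comp = {k: v * mult.get(k, 1.0) for k, v in nr.items()}
        out[g] = _normalize(comp)
    return out


def _normalize(comp: dict[str, float]) -> dict[str, float]:
    total = sum(comp.values())
    out = {k: v / total for k, v in comp.items()}
    # push rounding residue into the largest entry so sums are exactly 1
    key = max(out, key=out.get)
    out[key] += 1.0 - sum(out.values())
    return out


def default_cohort_config(
    n_patients_per_group: dict[str, int] | None = None,
    rois_per_patient: int = 1,
    cells_per_roi: float = 4800.0,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Cohort emulating the study design: three clinical groups, ~4,800 cells
    per 1 mm² ROI, 41 cell types with group-dependent composition, planted
    T-cell/antigen-presenting-cell co-aggregation and two structural motif
    bands (a vascular region and a portal-infiltrate-like region)."""
    cfg = CohortConfig(
        n_patients_per_group=n_patients_per_group or {"NR": 24, "TCMR": 41, "CR": 14},
        rois_per_patient=rois_per_patient,
        cells_per_roi=cells_per_roi,
        composition=_study_composition(),
        expression_templates=templates_from_ruleset(),
        attraction_pairs=[
            ("CD3+CD8+ T-cells", "Classical monocytes", 2.0),
            ("HLADR+ M2 macrophages", "HLADR+ hepatocytes", 2.0),
        ],
        motif_blocks=[
            (0.10, _normalize({"Endothelial cells": 0.55, "HLADR+ endothelial cells": 0.05,
                               "Hepatocytes": 0.25, "Classical monocytes": 0.08,
                               "CD3+CD8+ T-cells": 0.07})),
            (0.15, _normalize({"CD3+CD8+ T-cells": 0.16, "CD3+CD4+ T-cells": 0.14,
                               "Proliferating CD8 T-cells": 0.05, "PD1+ CD8 T-cells": 0.04,
                               "M1 macrophages": 0.12, "B cells": 0.06, "Plasma cells": 0.05,
                               "Cholangiocytes": 0.08, "Hepatocytes": 0.30})),
        ],
        seed=seed,
        **kwargs,
    )
    cfg.validate()
    return cfg


def _place_cells(rng, types, band_rect, attraction_pairs):
    """Coordinates for one band: Neyman-Scott clusters for attraction-pair
    members, homogeneous uniform scatter for everything else."""
    x0, x1, y0, y1 = band_rect
    n = len(types)
    xy = np.empty((n, 2))
    placed = np.zeros(n, dtype=bool)
    for a, b, strength in attraction_pairs:
        idx = np.flatnonzero(~placed & ((types == a) | (types == b)))
        if idx.size == 0:
            continue
        n_parents = max(1, int(round(idx.size / 15.0)))
        parents = np.column_stack([rng.uniform(x0, x1, n_parents), rng.uniform(y0, y1, n_parents)])
        assign = rng.integers(0, n_parents, idx.size)
        sd = 50.0 / strength  # µm; larger strength = tighter co-clusters
        xy[idx] = parents[assign] + rng.normal(0.0, sd, (idx.size, 2))
        placed[idx] = True
    rest = ~placed
    xy[rest, 0] = rng.uniform(x0, x1, int(rest.sum()))
    xy[rest, 1] = rng.uniform(y0, y1, int(rest.sum()))
    np.clip(xy[:, 0], x0, x1, out=xy[:, 0])
    np.clip(xy[:, 1], y0, y1, out=xy[:, 1])
    return xy


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one cohort; returns (cell table in state "raw", ground truth).

    One row per cell with roi/patient/group ids, coordinates inside the ROI
    rectangle and nonnegative raw intensities; bit-identical under a fixed
    config seed.
    """
    config.validate()
    W, H = config.roi_size
    markers = list(next(iter(config.expression_templates.values())))
    rows, truth_rows = [], []
    groups = sorted(config.n_patients_per_group)
    for gi, group in enumerate(groups):
        comp_bg = config.composition[group]
        for pi in range(config.n_patients_per_group[group]):
            patient = f"{group}_P{pi:03d}"
            p_rng = derived_rng(config.seed, gi, pi)
            patient_factor = (
                float(np.exp(p_rng.normal(0.0, config.patient_effect_sd)))
                if config.patient_effect_sd > 0
                else 1.0
            )
            for ri in range(config.rois_per_patient):
                rng = derived_rng(config.seed, gi, pi, ri + 1)
                roi = f"{patient}_R{ri}"
                n_cells = max(2, int(rng.poisson(config.cells_per_roi)))
                # vertical bands: background first, then each motif block
                fracs = [1.0 - sum(f for f, _ in config.motif_blocks)] + [f for f, _ in config.motif_blocks]
                comps = [comp_bg] + [c for _, c in config.motif_blocks]
                band_n = rng.multinomial(n_cells, fracs)
                edges = np.concatenate([[0.0], np.cumsum(fracs)]) * W
                for bi, (nb, comp) in enumerate(zip(band_n, comps)):
                    if nb == 0:
                        continue
                    tnames = list(comp)
                    counts = rng.multinomial(nb, [comp[t] for t in tnames])
                    types = np.repeat(np.array(tnames, dtype=object), counts)
                    rng.shuffle(types)
                    xy = _place_cells(rng, types, (edges[bi], edges[bi + 1], 0.0, H), config.attraction_pairs)
                    X = np.empty((nb, len(markers)))
                    for t in np.unique(types):
                        sel = types == t
                        tpl = config.expression_templates[t]
                        mu = np.array([tpl[m][0] for m in markers])
                        sd = np.sqrt(np.array([tpl[m][1] for m in markers]) ** 2 + config.noise_sd**2)
                        X[sel] = np.exp(mu + sd * rng.standard_normal((int(sel.sum()), len(markers))))
                    X *= patient_factor
                    for j in range(nb):
                        rows.append((roi, patient, group, xy[j, 0], xy[j, 1], *X[j]))
                        truth_rows.append((types[j], bi))
    table = pd.DataFrame(rows, columns=["roi", "patient", "group", "x", "y", *markers])
    table.insert(0, "cell_id", table.groupby("roi").cumcount().map(lambda i: f"c{i:05d}"))
    set_state(table, "raw")
    truth = pd.DataFrame(truth_rows, columns=["true_label", "motif_block"], index=table.index)
    outcomes = table.drop_duplicates("patient").set_index("patient")["group"]
    return table, GroundTruth(cells=truth, attraction_pairs=list(config.attraction_pairs), patient_outcomes=outcomes)


def generate_feature_cohort(
    n_patients: int,
    n_features: int,
    informative: list[int] | tuple[int, ...] = (),
    effect_size: float = 0.0,
    seed: int = 0,
    class_balance: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Patient-level feature matrix with a binary outcome: informative
    features differ between classes by `effect_size` standardized units,
    all others are exchangeable standard-normal noise."""
    informative = tuple(informative)
    if any(j < 0 or j >= n_features for j in informative):
        raise ConfigurationError("informative indices must lie in [0, n_features)")
    n_pos = int(round(n_patients * class_balance))
    if n_pos <= 0 or n_pos >= n_patients:
        raise ConfigurationError("both outcome classes must be present")
    rng = derived_rng(seed, 97)
    y = np.zeros(n_patients, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n_patients, n_features))
    for j in informative:
        X[y == 1, j] += effect_size
    idx = [f"P{i:03d}" for i in range(n_patients)]
    cols = [f"feature_{j:02d}" for j in range(n_features)]
    return pd.DataFrame(X, index=idx, columns=cols), pd.Series(y, index=idx, name="outcome")


def generate_gradient_cells(
    n_cells: int = 2000,
    n_markers: int = 10,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Cells along a 1-D latent differentiation gradient t in [0, 1]:
    expression = monotone (linear) functions of t plus Gaussian noise, with
    NR cells concentrated at low t (TCMR mid, CR high) so that the
    orientation rule has a well-defined root. Returns (expression, groups, t).
    """
    rng = derived_rng(seed, 131)
    t = rng.uniform(0.0, 1.0, n_cells)
    signs = np.where(np.arange(n_markers) % 2 == 0, 1.0, -1.0)
    weights = signs * rng.uniform(1.0, 2.0, n_markers)
    X = t[:, None] * weights[None, :] + rng.normal(0.0, noise_sd, (n_cells, n_markers))
    u = t + rng.normal(0.0, 0.12, n_cells)
    qs = np.quantile(u, [1 / 3, 2 / 3])
    groups = np.where(u < qs[0], "NR", np.where(u < qs[1], "TCMR", "CR"))
    df = pd.DataFrame(X, columns=[f"m{j:02d}" for j in range(n_markers)])
    set_state(df, "standardized")
    return df, pd.Series(groups, name="group"), t
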