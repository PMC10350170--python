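"""Intensity transformation, channel standardization, hierarchical gating and
per-patient composition features.

Raw IMC mean intensities are right-skewed; they are variance-stabilized with
the cytometry-standard inverse hyperbolic sine, x -> asinh(x / cofactor) with
cofactor 5, then z-scored per channel (sample SD, ddof=1) so that a single
positivity threshold is meaningful across markers. Gating then assigns each
cell one metacluster and, within subclustered metaclusters, one subcluster;
the final label is the subcluster when present, else the metacluster.

The fit/transform pieces are sklearn-style transformers; the gating engine is
an sklearn-style classifier whose "fit" validates the rule set. Module-level
functions wrap them for pipeline use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import (
    ConfigurationError,
    DataError,
    marker_columns,
    require_state,
    set_state,
)
from .gating import GatingRuleSet, MarkerPanel


class ArcsinhTransformer(TransformerMixin, BaseEstimator):
    """x -> asinh(x / cofactor); strictly monotone, maps 0 to 0."""

    def __init__(self, cofactor: float = 5.0):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if self.cofactor <= 0:
            raise ConfigurationError("cofactor must be positive")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise DataError("negative raw intensity")
        return np.arcsinh(X / self.cofactor)


class ChannelStandardizer(TransformerMixin, BaseEstimator):
    """Per-channel z-scoring with the *sample* standard deviation (ddof=1).

    Constant channels map to all-zeros with a warning rather than erroring,
    so dropped markers and degenerate synthetic channels do not abort a run.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise DataError("cannot standardize an empty table")
        self.mean_ = X.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # ddof=1 on n=1
            sd = X.std(axis=0, ddof=1)
        constant = ~(sd > 0)
        if constant.any():
            warnings.warn(f"{int(constant.sum())} constant channel(s) standardized to zeros")
        self.scale_ = np.where(constant, 1.0, sd)
        self.constant_ = constant
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.constant_] = 0.0
        return Z


def transform_intensities(table: pd.DataFrame, cofactor: float = 5.0) -> pd.DataFrame:
    """Arcsinh-transform every marker channel of a raw cell table."""
    require_state(table, "raw", "transform_intensities")
    markers = marker_columns(table)
    out = table.copy()
    out[markers] = ArcsinhTransformer(cofactor).fit_transform(table[markers].to_numpy())
    return set_state(out, "transformed")


def standardize_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every marker channel across all cells of the cohort."""
    require_state(table, "transformed", "standardize_channels")
    markers = marker_columns(table)
    out = table.copy()
    out[markers] = ChannelStandardizer().fit_transform(table[markers].to_numpy())
    return set_state(out, "standardized")


def preprocess(table: pd.DataFrame, cofactor: float = 5.0) -> pd.DataFrame:
    """Raw -> transformed -> standardized in one step."""
    return standardize_channels(transform_intensities(table, cofactor))


class GatingClassifier(BaseEstimator):
    """Ordered-rule hierarchical gater over standardized expression.

    ``fit`` validates the rule set against the observed channels; ``predict``
    returns the assignment frame (metacluster / subcluster / final label per
    cell). Purely deterministic: identical inputs and rules give identical
    labels.
    """

    def __init__(self, rules: GatingRuleSet, panel: MarkerPanel | None = None):
        self.rules = rules
        self.panel = panel

    def fit(self, X: pd.DataFrame, y=None):
        self.rules.validate(self.panel)
        markers = set(marker_columns(X))
        for rule in self.rules.rules:
            for p in rule.predicates:
                if p.marker not in markers:
                    raise ConfigurationError(
                        f"rule {rule.target!r} references marker {p.marker!r} absent from the table"
                    )
        self.marker_names_ = sorted(markers)
        return self

    @staticmethod
    def _match(table: pd.DataFrame, predicates) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        for p in predicates:
            col = table[p.marker].to_numpy()
            mask &= (col >= p.threshold) if p.comparator == ">=" else (col < p.threshold)
        return mask

    def predict_metaclusters(self, X: pd.DataFrame) -> pd.Series:
        labels = pd.Series(self.rules.fallback, index=X.index, dtype=object, name="metacluster")
        unassigned = np.ones(len(X), dtype=bool)
        for rule in self.rules.metacluster_rules():
            hit = unassigned & self._match(X, rule.predicates)
            labels.iloc[hit] = rule.target
            unassigned &= ~hit
        return labels

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        meta = self.predict_metaclusters(X)
        sub = pd.Series(None, index=X.index, dtype=object, name="subcluster")
        for parent in self.rules.subclustered_parents():
            in_parent = (meta == parent).to_numpy()
            if not in_parent.any():
                continue
            cells = X.loc[in_parent]
            open_ = np.ones(len(cells), dtype=bool)
            assigned = pd.Series(None, index=cells.index, dtype=object)
            for rule in self.rules.subcluster_rules(parent):
                hit = open_ & self._match(cells, rule.predicates)
                assigned.iloc[hit] = rule.target
                open_ &= ~hit
            sub.loc[assigned.index] = assigned
        final = sub.where(sub.notna(), meta)
        final.name = "final"
        return pd.DataFrame({"metacluster": meta, "subcluster": sub, "final": final})


def assign_metaclusters(table: pd.DataFrame, rules: GatingRuleSet) -> pd.DataFrame:
    """First matching metacluster rule wins; unmatched cells get the fallback."""
    require_state(table, "standardized", "assign_metaclusters")
    gater = GatingClassifier(rules).fit(table)
    meta = gater.predict_metaclusters(table)
    return pd.DataFrame({"metacluster": meta, "subcluster": pd.Series(None, index=table.index, dtype=object), "final": meta.rename("final")})


def assign_subclusters(table: pd.DataFrame, assignment: pd.DataFrame, rules: GatingRuleSet) -> pd.DataFrame:
    """Refine an existing metacluster assignment with the subcluster rules.

    Rules are evaluated only on cells of their parent metacluster, first match
    wins; a parent's empty-predicate rule is its generic label; cells of
    parents with no rules keep the metacluster as final label.
    """
    require_state(table, "standardized", "assign_subclusters")
    gater = GatingClassifier(rules).fit(table)
    out = gater.predict(table)
    if not out["metacluster"].equals(assignment["metacluster"]):
        raise DataError("assignment does not match the given rule set's metacluster gating")
    return out


def assign_phenotypes(table: pd.DataFrame, rules: GatingRuleSet) -> pd.DataFrame:
    """Metacluster + subcluster gating in one pass."""
    require_state(table, "standardized", "assign_phenotypes")
    return GatingClassifier(rules).fit(table).predict(table)


def compute_proportions(
    assignment: pd.DataFrame,
    table: pd.DataFrame,
    denominator: str = "all_cells",
    level: str = "metacluster",
) -> pd.DataFrame:
    """Per-patient label proportions, cells pooled across a patient's ROIs.

    denominator "all_cells": count of the label over the patient's total cell
    count. denominator "parent_metacluster": a final label's count over its
    parent metacluster's count for that patient; patients with zero parent
    cells yield missing (not zero) values.

    Returns a tidy frame: patient, group, label, proportion, denominator.
    """
    if denominator not in ("all_cells", "parent_metacluster"):
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    if level not in ("metacluster", "final"):
        raise ConfigurationError(f"unknown level {level!r}")
    labels = assignment[level]
    df = pd.DataFrame(
        {
            "patient": table["patient"].to_numpy(),
            "group": table["group"].to_numpy(),
            "label": labels.to_numpy(),
        }
    )
    patients = df[["patient", "group"]].drop_duplicates().set_index("patient")["group"]
    all_labels = sorted(df["label"].unique())
    counts = (
        df.groupby(["patient", "label"], sort=True).size().unstack(fill_value=0).reindex(columns=all_labels, fill_value=0)
    )
    if denominator == "all_cells":
        denom = counts.sum(axis=1)
        props = counts.div(denom, axis=0)
    else:
        meta = pd.DataFrame(
            {"patient": table["patient"].to_numpy(), "label": assignment["metacluster"].to_numpy()}
        )
        meta_counts = meta.groupby(["patient", "label"]).size().unstack(fill_value=0)
        if level == "metacluster":
            parent_of = {m: m for m in all_labels}
        else:
            parent_of = None  # resolved per label below via the assignment itself
            pairs = assignment[["final", "metacluster"]].drop_duplicates()
            parent_of = dict(zip(pairs["final"], pairs["metacluster"]))
        denom_mat = pd.DataFrame(
            {lab: meta_counts.reindex(counts.index).get(parent_of[lab], pd.Series(0, index=counts.index)) for lab in all_labels}
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            props = counts / denom_mat.replace(0, np.nan)
    tidy = props.reset_index().melt(id_vars="patient", var_name="label", value_name="proportion")
    tidy["group"] = tidy["patient"].map(patients)
    tidy["denominator"] = denominator
    return tidy[["patient", "group", "label", "proportion", "denominator"]].sort_values(
        ["patient", "label"], kind="stable", ignore_index=True
    )


def proportion_matrix(proportions: pd.DataFrame) -> pd.DataFrame:
    """Wide patients x labels matrix from a tidy proportion table."""
    return proportions.pivot(index="patient", columns="label", values="proportion")
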