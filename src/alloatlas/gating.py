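"""Declarative hierarchical gating: marker panel, rule sets, and the default
liver-allograft ruleset (10 metaclusters, 30 immune subclusters, 41 final labels).

A rule set is an *ordered* list of conjunctive threshold rules evaluated on
standardized marker expression, first match wins — mirroring manual
hierarchical gating. Metacluster rules partition all cells (with a declared
fallback label, hepatocytes in the liver panel, for cells matching nothing:
parenchymal cells are classified by exclusion of every other lineage).
Subcluster rules refine a parent metacluster; a rule with an empty predicate
is the parent's generic catch-all and must come last within its parent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from ._utils import ConfigurationError

#: default positivity cut on the standardized expression scale: a marker is
#: called "+"/"high" at z >= 0.5 and "-"/"low" below. Individual rules may
#: carry their own thresholds (e.g. the CD3-high/low split within CD4 T-cells).
DEFAULT_THRESHOLD = 0.5

_COMPARATORS = (">=", "<")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered antibody panel; roles follow the usual IMC split between
    structural, lineage and functional markers."""

    names: tuple[str, ...]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != len(set(self.names)) or not self.names:
            raise ConfigurationError("marker names must be unique and nonempty")

    def __len__(self) -> int:
        return len(self.names)


def default_panel() -> MarkerPanel:
    """The 22-marker liver-allograft panel: two nuclear intercalators,
    structural markers (collagen, CD31 vasculature, CK7 bile ducts), immune
    lineage markers and functional/phenotypic markers."""
    roles = {}
    for m in ("DNA1", "DNA2"):
        roles[m] = "nuclear"
    for m in ("Collagen1", "CD31", "CK7"):
        roles[m] = "structural"
    for m in ("CD45", "CD3", "CD4", "CD8", "CD20", "CD68", "CD11b", "CD138", "CD15"):
        roles[m] = "lineage"
    for m in ("CD163", "HLADR", "CD16", "PD1", "FoxP3", "Ki67", "GranzymeB", "CD28"):
        roles[m] = "functional"
    return MarkerPanel(names=tuple(roles), roles=roles)


@dataclass(frozen=True)
class Predicate:
    marker: str
    comparator: str  # ">=" or "<"
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ConfigurationError(f"comparator must be one of {_COMPARATORS}")
        if not (self.threshold == self.threshold and abs(self.threshold) < float("inf")):
            raise ConfigurationError("threshold must be finite")

    def __str__(self) -> str:
        return f"{self.marker}{self.comparator}{self.threshold:g}"


@dataclass(frozen=True)
class GatingRule:
    level: str  # "metacluster" or "subcluster"
    parent: str | None  # None for metacluster rules
    target: str
    predicates: tuple[Predicate, ...]  # conjunction; empty = generic catch-all
    immune: bool = True  # metacluster rules only; subclusters inherit

    def __post_init__(self):
        if self.level not in ("metacluster", "subcluster"):
            raise ConfigurationError(f"unknown rule level {self.level!r}")
        if self.level == "subcluster" and not self.parent:
            raise ConfigurationError("subcluster rules need a parent")
        if self.level == "metacluster" and not self.predicates:
            raise ConfigurationError("metacluster rules need a nonempty predicate (use the fallback for catch-all)")


@dataclass
class GatingRuleSet:
    """Ordered rules plus the metacluster fallback label."""

    rules: list[GatingRule]
    fallback: str = "Hepatocytes"
    fallback_immune: bool = False

    # -- structure ---------------------------------------------------------
    def metacluster_rules(self) -> list[GatingRule]:
        return [r for r in self.rules if r.level == "metacluster"]

    def subcluster_rules(self, parent: str | None = None) -> list[GatingRule]:
        rules = [r for r in self.rules if r.level == "subcluster"]
        if parent is not None:
            rules = [r for r in rules if r.parent == parent]
        return rules

    def metacluster_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.metacluster_rules():
            seen.setdefault(r.target, None)
        seen.setdefault(self.fallback, None)
        return list(seen)

    def is_immune(self, metacluster: str) -> bool:
        for r in self.metacluster_rules():
            if r.target == metacluster:
                return r.immune
        if metacluster == self.fallback:
            return self.fallback_immune
        raise ConfigurationError(f"unknown metacluster {metacluster!r}")

    def subclustered_parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.subcluster_rules():
            seen.setdefault(r.parent, None)
        return list(seen)

    def final_labels(self) -> list[str]:
        """Distinct final labels: subcluster targets plus, for every parent
        without a generic catch-all rule, the parent metacluster label itself."""
        labels: dict[str, None] = {}
        subclustered = set(self.subclustered_parents())
        for m in self.metacluster_labels():
            subs = self.subcluster_rules(m)
            if not subs:
                labels.setdefault(m, None)
                continue
            for r in subs:
                labels.setdefault(r.target, None)
            if not any(not r.predicates for r in subs):
                labels.setdefault(m, None)  # unmatched cells keep the parent label
        for m in self.metacluster_labels():
            if m not in subclustered and m not in labels:
                labels.setdefault(m, None)
        return list(labels)

    def summary(self) -> dict[str, int]:
        """Label accounting: subcluster count covers final labels under the
        *immune* subclustered metaclusters (the non-immune base/Ki67+/HLADR+
        variants count only toward the final labels, matching the study's
        '30 subclusters -> 32 immune + 9 non-immune clusters' bookkeeping)."""
        metas = self.metacluster_labels()
        finals = self.final_labels()
        immune_sub_parents = [m for m in self.subclustered_parents() if self.is_immune(m)]
        n_sub = 0
        for parent in immune_sub_parents:
            subs = self.subcluster_rules(parent)
            targets = {r.target for r in subs}
            if not any(not r.predicates for r in subs):
                targets.add(parent)
            n_sub += len(targets)
        parent_of = self.parent_of_final()
        n_immune = sum(self.is_immune(parent_of[f]) for f in finals)
        return {
            "n_metaclusters": len(metas),
            "n_subclusters": n_sub,
            "n_final_labels": len(finals),
            "n_immune_final": n_immune,
            "n_non_immune_final": len(finals) - n_immune,
        }

    def parent_of_final(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for m in self.metacluster_labels():
            subs = self.subcluster_rules(m)
            out.setdefault(m, m)
            for r in subs:
                out.setdefault(r.target, m)
        return out

    # -- validation --------------------------------------------------------
    def validate(self, panel: MarkerPanel | None = None) -> None:
        metas = set(self.metacluster_labels())
        meta_targets = [r.target for r in self.metacluster_rules()]
        if len(meta_targets) != len(set(meta_targets)):
            raise ConfigurationError("duplicate metacluster target labels")
        for r in self.subcluster_rules():
            if r.parent not in metas:
                raise ConfigurationError(f"subcluster rule {r.target!r} names unknown parent {r.parent!r}")
        for parent in self.subclustered_parents():
            subs = self.subcluster_rules(parent)
            generic = [i for i, r in enumerate(subs) if not r.predicates]
            if generic and generic[0] != len(subs) - 1:
                raise ConfigurationError(f"generic catch-all for {parent!r} must be the last rule of its parent")
        if panel is not None:
            known = set(panel.names)
            for r in self.rules:
                for p in r.predicates:
                    if p.marker not in known:
                        raise ConfigurationError(f"rule {r.target!r} references unknown marker {p.marker!r}")

    # -- round-trippable file format --------------------------------------
    # one rule per line: level,parent,target,predicate(;-joined "MARKER>=0.5"),immune
    # the fallback is declared once with level "fallback".
    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["level", "parent", "target", "predicate", "immune"])
            w.writerow(["fallback", "", self.fallback, "", int(self.fallback_immune)])
            for r in self.rules:
                w.writerow([
                    r.level,
                    r.parent or "",
                    r.target,
                    ";".join(str(p) for p in r.predicates),
                    int(r.immune),
                ])

    @classmethod
    def from_file(cls, path: str | Path) -> "GatingRuleSet":
        rules: list[GatingRule] = []
        fallback, fallback_immune = None, False
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                level = row["level"].strip()
                if level == "fallback":
                    fallback = row["target"].strip()
                    fallback_immune = bool(int(row.get("immune") or 0))
                    continue
                preds = tuple(_parse_predicate(t) for t in row["predicate"].split(";") if t.strip())
                rules.append(
                    GatingRule(
                        level=level,
                        parent=row["parent"].strip() or None,
                        target=row["target"].strip(),
                        predicates=preds,
                        immune=bool(int(row.get("immune") or 1)),
                    )
                )
        if fallback is None:
            raise ConfigurationError("rules file declares no fallback metacluster")
        rs = cls(rules=rules, fallback=fallback, fallback_immune=fallback_immune)
        rs.validate()
        return rs


def _parse_predicate(term: str) -> Predicate:
    term = term.strip()
    for comp in _COMPARATORS:
        if comp in term:
            marker, thr = term.split(comp, 1)
            return Predicate(marker.strip(), comp, float(thr))
    raise ConfigurationError(f"cannot parse predicate term {term!r}")


def _p(marker: str, comparator: str = ">=", threshold: float = DEFAULT_THRESHOLD) -> Predicate:
    return Predicate(marker, comparator, threshold)


def default_ruleset() -> GatingRuleSet:
    """The study ruleset: 10 metaclusters; subclustering of the five most
    relevant immune metaclusters (CD4 T-cells, CD8 T-cells, B cells,
    macrophages, monocytes) into 30 subclusters; Ki67+/HLADR+ variants of the
    three non-immune metaclusters; 41 final labels in total.

    Macrophages split M1/M2 on CD163 first (every macrophage rule carries the
    CD163 branch conjunct, with explicit CD163-low catch-alls), then refine
    within each branch. Resident-memory CD4 T-cells are the CD3-low fraction
    of the CD4 compartment (second CD3 threshold at z = 1.5).
    """
    R: list[GatingRule] = []
    M = lambda target, preds, immune=True: R.append(
        GatingRule("metacluster", None, target, tuple(preds), immune)
    )
    S = lambda parent, target, preds: R.append(GatingRule("subcluster", parent, target, tuple(preds)))

    # --- metaclusters (ordered; hepatocytes are the fallback, by exclusion)
    M("Endothelial cells", [_p("CD31")], immune=False)
    M("Cholangiocytes", [_p("CK7")], immune=False)
    M("Neutrophils", [_p("CD45"), _p("CD15")])
    M("B cells", [_p("CD45"), _p("CD20")])
    M("Plasma cells", [_p("CD45"), _p("CD138")])
    M("CD8 T-cells", [_p("CD45"), _p("CD3"), _p("CD8")])
    M("CD4 T-cells", [_p("CD45"), _p("CD3"), _p("CD4")])
    M("Macrophages", [_p("CD45"), _p("CD68")])
    M("Monocytes", [_p("CD45"), _p("CD11b")])

    # --- CD4 T-cell compartment (9)
    S("CD4 T-cells", "HLADR+ Treg", [_p("FoxP3"), _p("HLADR")])
    S("CD4 T-cells", "Treg", [_p("FoxP3")])
    S("CD4 T-cells", "PD1+ CD4 T-cells", [_p("PD1")])
    S("CD4 T-cells", "Proliferating CD4 T-cells", [_p("Ki67")])
    S("CD4 T-cells", "CD16+ CD4 T-cells", [_p("CD16")])
    S("CD4 T-cells", "Activated CD4 T-cells", [_p("HLADR")])
    S("CD4 T-cells", "Naive CD4 T-cells", [_p("CD28")])
    S("CD4 T-cells", "Resident memory CD4 T-cells", [_p("CD3", "<", 1.5)])
    S("CD4 T-cells", "CD3+CD4+ T-cells", [])  # CD3-high generic

    # --- CD8 T-cell compartment (5)
    S("CD8 T-cells", "PD1+CD28+ CD8 T-cells", [_p("PD1"), _p("CD28")])
    S("CD8 T-cells", "PD1+ CD8 T-cells", [_p("PD1")])
    S("CD8 T-cells", "Proliferating CD8 T-cells", [_p("Ki67")])
    S("CD8 T-cells", "Cytotoxic T-cells", [_p("GranzymeB")])
    S("CD8 T-cells", "CD3+CD8+ T-cells", [])

    # --- macrophage compartment (9): CD163 branch first, then refine
    S("Macrophages", "HLADR+ M2 macrophages", [_p("CD163"), _p("HLADR")])
    S("Macrophages", "CD16+ M2 macrophages", [_p("CD163"), _p("CD16")])
    S("Macrophages", "Proliferating M2 macrophages", [_p("CD163"), _p("Ki67")])
    S("Macrophages", "CD11b+ M2 macrophages", [_p("CD163"), _p("CD11b")])
    S("Macrophages", "M2 macrophages", [_p("CD163")])
    S("Macrophages", "CD16+ M1 macrophages", [_p("CD163", "<"), _p("CD16")])
    S("Macrophages", "Proliferating M1 macrophages", [_p("CD163", "<"), _p("Ki67")])
    S("Macrophages", "CD11b+ M1 macrophages", [_p("CD163", "<"), _p("CD11b")])
    S("Macrophages", "M1 macrophages", [])

    # --- monocyte compartment (4)
    S("Monocytes", "Intermediate monocytes", [_p("CD16"), _p("HLADR")])
    S("Monocytes", "Activated monocytes", [_p("HLADR")])
    S("Monocytes", "Classical monocytes", [_p("CD16")])
    S("Monocytes", "Non-classical monocytes", [])

    # --- B-cell compartment (3)
    S("B cells", "Proliferating B cells", [_p("Ki67")])
    S("B cells", "Activated B cells", [_p("HLADR")])
    S("B cells", "B cells", [])

    # --- non-immune Ki67+/HLADR+ variants (count toward final labels only)
    for meta, stem in (
        ("Hepatocytes", "hepatocytes"),
        ("Cholangiocytes", "cholangiocytes"),
        ("Endothelial cells", "endothelial cells"),
    ):
        S(meta, f"Ki67+ {stem}", [_p("Ki67")])
        S(meta, f"HLADR+ {stem}", [_p("HLADR")])
        S(meta, f"{stem.capitalize()}" if meta != "Endothelial cells" else "Endothelial cells", [])

    rs = GatingRuleSet(rules=R, fallback="Hepatocytes", fallback_immune=False)
    rs.validate(default_panel())
    return rs
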