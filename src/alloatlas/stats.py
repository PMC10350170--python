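"""Group-difference testing with normality-gated test selection.

Per feature (a cell-type proportion, CN proportion or distance summary), the
test family is chosen by Shapiro-Wilk on every group: parametric (one-way
ANOVA overall, two-sample t pairwise) only when no group rejects normality at
0.05; otherwise nonparametric (Kruskal-Wallis overall, Wilcoxon rank-sum
pairwise). Groups too small for the normality test (< 3 values) default the
feature to nonparametric. Pairwise p-values are Holm-adjusted within the
feature's family of comparisons (3 pairs for 3 groups), and significance is
read at the 0.05 cut-off.

Small-sample rank tests use exact enumeration when there are no ties
(scipy's exact method), mid-ranks with the normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._utils import ConfigurationError, DataError

ALPHA = 0.05


def select_test_family(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> str:
    """"parametric" iff Shapiro-Wilk p > alpha in every group; any group with
    fewer than 3 values defaults the feature to "nonparametric"."""
    if not groups:
        raise DataError("no groups given")
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise DataError(f"group {name!r} is empty")
        if values.size < 3:
            return "nonparametric"
        if np.ptp(values) == 0:  # Shapiro is undefined on constant samples
            return "nonparametric"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(values).pvalue <= alpha:
                return "nonparametric"
    return "parametric"


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (sort ascending, multiply the i-th by
    m-i+1, enforce the running maximum, cap at 1, restore input order).
    Missing entries pass through as missing."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def _overall_test(samples: list[np.ndarray], family: str) -> tuple[str, float]:
    if np.ptp(np.concatenate(samples)) == 0:
        # no separation at all: every rank/mean is tied
        return ("one-way ANOVA" if family == "parametric" else "Kruskal-Wallis"), 1.0
    if family == "parametric":
        if len(samples) == 2:
            return "two-sample t", float(sps.ttest_ind(*samples).pvalue)
        return "one-way ANOVA", float(sps.f_oneway(*samples).pvalue)
    if len(samples) == 2:
        return "Wilcoxon rank-sum", _ranksum_p(samples[0], samples[1])
    return "Kruskal-Wallis", float(sps.kruskal(*samples).pvalue)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


@dataclass
class GroupTestResult:
    feature: str
    family: str
    overall_test: str
    overall_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    # pairwise columns: group_a, group_b, test, p_raw, p_holm, significant


def compare_groups(
    groups: dict[str, np.ndarray],
    family: str | None = None,
    feature: str = "feature",
    alpha: float = ALPHA,
) -> GroupTestResult:
    """Overall test across all groups plus all pairwise tests with Holm
    adjustment over the feature's pairwise family.

    Group pairs where either side has < 2 values yield missing p-values
    (excluded from the Holm family)."""
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    clean = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        clean[name] = v[~np.isnan(v)]
    if family is None:
        family = select_test_family(clean, alpha=alpha)
    if family not in ("parametric", "nonparametric"):
        raise ConfigurationError(f"unknown family {family!r}")
    names = list(clean)
    usable = [clean[n] for n in names if clean[n].size >= 2]
    if len(usable) >= 2:
        overall_test, overall_p = _overall_test(usable, family)
    else:
        overall_test, overall_p = ("one-way ANOVA" if family == "parametric" else "Kruskal-Wallis"), np.nan

    pair_test = "two-sample t" if family == "parametric" else "Wilcoxon rank-sum"
    rows = []
    for a, b in itertools.combinations(names, 2):
        va, vb = clean[a], clean[b]
        if va.size < 2 or vb.size < 2:
            rows.append((a, b, pair_test, np.nan))
            continue
        if np.ptp(np.concatenate([va, vb])) == 0:
            p = 1.0
        elif family == "parametric":
            p = float(sps.ttest_ind(va, vb).pvalue)
        else:
            p = _ranksum_p(va, vb)
        rows.append((a, b, pair_test, p))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "test", "p_raw"])
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    pairwise["significant"] = pairwise["p_holm"] < alpha
    return GroupTestResult(feature=feature, family=family, overall_test=overall_test, overall_p=overall_p, pairwise=pairwise)


def test_features(
    proportions: pd.DataFrame,
    family: str | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run compare_groups on every label of a tidy per-patient proportion
    table (columns patient, group, label, proportion). Returns a tidy result:
    feature, family, overall_test, overall_p, comparison, test, p_raw,
    p_holm, significant."""
    rows = []
    for label, sub in proportions.groupby("label", sort=True):
        groups = {g: s["proportion"].to_numpy() for g, s in sub.groupby("group")}
        groups = {g: v[~np.isnan(v)] for g, v in groups.items()}
        groups = {g: v for g, v in groups.items() if v.size > 0}
        if len(groups) < 2:
            continue
        res = compare_groups(groups, family=family, feature=str(label), alpha=alpha)
        for _, pr in res.pairwise.iterrows():
            rows.append(
                (
                    res.feature,
                    res.family,
                    res.overall_test,
                    res.overall_p,
                    f"{pr['group_a']} vs {pr['group_b']}",
                    pr["test"],
                    pr["p_raw"],
                    pr["p_holm"],
                    bool(pr["significant"]) if pr["p_holm"] == pr["p_holm"] else False,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["feature", "family", "overall_test", "overall_p", "comparison", "test", "p_raw", "p_holm", "significant"],
    )
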