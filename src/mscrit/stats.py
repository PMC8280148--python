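"""Group comparison of MsCr fingerprints.

Feature-wise parametric (t-test / one-way ANOVA) or nonparametric
(Mann-Whitney / Kruskal-Wallis) tests, Benjamini-Hochberg FDR correction
across the 33-feature family, and control-referenced z-score deviance
fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fingerprint import FEATURE_NAMES

__all__ = [
    "GroupedFingerprints",
    "per_feature_tests",
    "fdr_correct",
    "deviance_fingerprint",
]


@dataclass(frozen=True)
class GroupedFingerprints:
    """A fingerprint table with group labels and a designated control group.

    ``table`` holds one row per recording with the 33 canonical feature
    columns; ``labels`` the group of each row.
    """

    table: pd.DataFrame
    labels: pd.Series
    control_label: str = "control"

    def __post_init__(self) -> None:
        missing = [f for f in FEATURE_NAMES if f not in self.table.columns]
        if missing:
            raise ValueError(f"fingerprint table lacks features: {missing}")
        labels = pd.Series(np.asarray(self.labels), index=self.table.index)
        if labels.nunique() < 2:
            raise ValueError("need at least 2 groups")
        object.__setattr__(self, "labels", labels)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.labels.unique())

    def feature_by_group(self, feature: str) -> dict[str, np.ndarray]:
        out = {}
        for g in self.group_names:
            v = self.table.loc[self.labels == g, feature].to_numpy(dtype=float)
            out[g] = v[np.isfinite(v)]
        return out


def per_feature_tests(
    g: GroupedFingerprints, family: str = "parametric"
) -> pd.DataFrame:
    """Per-feature group-difference tests.

    Two groups: two-sided t-test (parametric) or Mann-Whitney U
    (nonparametric); more than two: one-way ANOVA or Kruskal-Wallis.
    Missing feature values are dropped per feature; a feature leaving any
    group with fewer than two usable values gets a NaN p-value.
    Returns a table with columns feature, test, statistic, p.
    """
    if family not in ("parametric", "nonparametric"):
        raise ValueError("family must be 'parametric' or 'nonparametric'")
    two = len(g.group_names) == 2
    if family == "parametric":
        test_name = "t-test" if two else "anova"
    else:
        test_name = "mann-whitney" if two else "kruskal-wallis"
    rows = []
    for feature in FEATURE_NAMES:
        groups = list(g.feature_by_group(feature).values())
        if any(len(v) < 2 for v in groups):
            stat, p = float("nan"), float("nan")
        elif test_name == "t-test":
            stat, p = sps.ttest_ind(*groups)
        elif test_name == "mann-whitney":
            stat, p = sps.mannwhitneyu(*groups, alternative="two-sided")
        elif test_name == "anova":
            stat, p = sps.f_oneway(*groups)
        else:
            stat, p = sps.kruskal(*groups)
        rows.append(
            {"feature": feature, "test": test_name, "statistic": float(stat),
             "p": float(p)}
        )
    return pd.DataFrame(rows)


def fdr_correct(pvalues: pd.Series, q: float = 0.01) -> pd.DataFrame:
    """Benjamini-Hochberg step-up correction over the feature family.

    Missing p-values are excluded from the family size m and reported as
    non-significant with NaN adjusted values. Returns a table indexed like
    the input with columns p, p_adjusted, significant; the result does not
    depend on the input order.
    """
    pvalues = pd.Series(pvalues, dtype=float)
    if ((pvalues < 0) | (pvalues > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.DataFrame(
        {"p": pvalues, "p_adjusted": np.nan, "significant": False},
        index=pvalues.index,
    )
    mask = pvalues.notna()
    if mask.any():
        reject, p_adj, _, _ = multipletests(
            pvalues[mask].to_numpy(), alpha=q, method="fdr_bh"
        )
        out.loc[mask, "p_adjusted"] = p_adj
        out.loc[mask, "significant"] = reject
    return out


def deviance_fingerprint(
    g: GroupedFingerprints, target_group: str
) -> pd.Series:
    """Control-referenced z-score fingerprint of one group.

    Per feature, (mean_target - mean_control) / std_control, with the
    control standard deviation computed with one delta degree of freedom.
    A zero-variance control feature yields NaN (flagged, not zero).
    """
    for name in (target_group, g.control_label):
        if name not in g.group_names:
            raise ValueError(f"unknown group label {name!r}")
    z = {}
    for feature in FEATURE_NAMES:
        by_group = g.feature_by_group(feature)
        target, control = by_group[target_group], by_group[g.control_label]
        if len(control) == 0 or len(target) == 0:
            z[feature] = float("nan")
            continue
        sd = control.std(ddof=1) if len(control) > 1 else 0.0
        z[feature] = (
            (target.mean() - control.mean()) / sd if sd > 0 else float("nan")
        )
    s = pd.Series(z, name=target_group)
    s.index.name = "feature"
    return s
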