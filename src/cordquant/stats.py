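"""Group-comparison statistics mirroring the study's figure conventions.

Outcomes are compared across experimental groups with a one-way ANOVA when
its assumptions hold, otherwise a Kruskal-Wallis test.  Assumptions are
checked on the data themselves: Shapiro-Wilk on the within-group residuals
and Levene's test for variance homogeneity (both at alpha 0.05 by default).
When the omnibus test is significant a post-hoc family is applied:
Tukey-Kramer all-pairs (histology-style outcomes) or Dunnett many-to-one
against a control group (breathing-style outcomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Omnibus + post-hoc result for one outcome."""

    outcome: str
    omnibus_test: str  # "anova" or "kruskal"
    omnibus_p: float
    normality_p: float  # Shapiro-Wilk on residuals
    variance_p: float  # Levene across groups
    posthoc_family: str  # "tukey", "dunnett" or "none"
    pairwise: pd.DataFrame | None  # group1, group2, p_adj (None if no post-hoc)
    group_means: dict[str, float]
    n_per_group: dict[str, int]


def group_compare(
    tidy: pd.DataFrame,
    *,
    outcome: str = "value",
    value_col: str = "value",
    group_col: str = "group",
    posthoc: str = "tukey",
    control: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    normality_alpha: float = DEFAULT_ALPHA,
    variance_alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Compare one outcome across groups with assumption-guided test choice.

    Groups with fewer than 2 observations are excluded (logged).  The
    omnibus test is a one-way ANOVA unless Shapiro-Wilk on the residuals or
    Levene's test rejects at their alphas, in which case Kruskal-Wallis is
    used.  Post-hoc tests run only when the omnibus p is below ``alpha``:
    ``posthoc="tukey"`` for all pairwise comparisons, ``"dunnett"`` for
    many-to-one against ``control``.
    """
    if posthoc not in ("tukey", "dunnett", "none"):
        raise ValueError(f"unknown posthoc family {posthoc!r}")
    if posthoc == "dunnett" and control is None:
        raise ValueError("dunnett post-hoc requires a control group")
    df = tidy[[group_col, value_col]].dropna()
    sizes = df.groupby(group_col)[value_col].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding groups with < 2 observations: %s", small)
        df = df[~df[group_col].isin(small)]
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    samples = [df.loc[df[group_col] == g, value_col].to_numpy(dtype=float) for g in groups]

    residuals = np.concatenate([s - s.mean() for s in samples])
    if np.ptp(residuals) == 0:
        normality_p = 1.0  # degenerate: identical values within groups
    else:
        with np.errstate(all="ignore"):
            normality_p = float(sps.shapiro(residuals[:5000]).pvalue)
        if not np.isfinite(normality_p):
            normality_p = 1.0
    with np.errstate(all="ignore"):
        variance_p = float(sps.levene(*samples).pvalue)
    if not np.isfinite(variance_p):
        variance_p = 1.0  # zero spread in every group

    if normality_p < normality_alpha or variance_p < variance_alpha:
        test = "kruskal"
        omnibus_p = float(sps.kruskal(*samples).pvalue)
    else:
        test = "anova"
        omnibus_p = float(sps.f_oneway(*samples).pvalue)
        if np.isnan(omnibus_p):  # zero between- and within-variance
            omnibus_p = 1.0

    pairwise = None
    family = "none"
    if omnibus_p < alpha and posthoc != "none":
        family = posthoc
        if posthoc == "tukey":
            res = pairwise_tukeyhsd(
                df[value_col].to_numpy(dtype=float),
                df[group_col].to_numpy(),
                alpha=alpha,
            )
            tbl = pd.DataFrame(
                res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
            )
            pairwise = pd.DataFrame(
                {
                    "group1": tbl["group1"],
                    "group2": tbl["group2"],
                    "p_adj": tbl["p-adj"].astype(float),
                }
            )
        else:
            if control not in groups:
                raise ValueError(f"control group {control!r} not present in data")
            others = [g for g in groups if g != control]
            ctrl = df.loc[df[group_col] == control, value_col].to_numpy(dtype=float)
            rest = [df.loc[df[group_col] == g, value_col].to_numpy(dtype=float) for g in others]
            res = sps.dunnett(*rest, control=ctrl)
            pairwise = pd.DataFrame(
                {
                    "group1": others,
                    "group2": control,
                    "p_adj": np.asarray(res.pvalue, dtype=float),
                }
            )

    return GroupComparison(
        outcome=outcome,
        omnibus_test=test,
        omnibus_p=omnibus_p,
        normality_p=normality_p,
        variance_p=variance_p,
        posthoc_family=family,
        pairwise=pairwise,
        group_means={g: float(s.mean()) for g, s in zip(groups, samples)},
        n_per_group={g: int(s.size) for g, s in zip(groups, samples)},
    )


def comparison_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tidy one-row-per-outcome summary of a list of comparisons."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "outcome": c.outcome,
                "omnibus_test": c.omnibus_test,
                "omnibus_p": c.omnibus_p,
                "normality_p": c.normality_p,
                "variance_p": c.variance_p,
                "posthoc_family": c.posthoc_family,
                "n_groups": len(c.group_means),
            }
        )
    return pd.DataFrame(rows)
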