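"""Within-group variation: CIELAB moments, centroid colour difference, ANOVA.

Per group we report the mean and SD of L*, a*, b* and chroma C*, plus a
perceptually meaningful dispersion measure: the mean (and SD) of the
ΔE*ab between each measurement and the group's mean colour.  A two-way
fixed-effects ANOVA (ethnicity × gender, with interaction) quantifies
how much of each attribute's variance the group labels actually carry;
effect sizes are partial eta-squared.  Measurements are treated as
independent observations (the per-measurement analysis convention),
with an optional per-subject aggregation for sensitivity checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as smf_api
import statsmodels.formula.api as smf

from .colorimetry import chroma, delta_e_ab
from .dataset import SkinDataset

__all__ = ["summarize_groups", "anova_two_way"]

_ATTRS = {"L": "L", "a": "a", "b": "b"}


def summarize_groups(dataset: SkinDataset) -> pd.DataFrame:
    """Per-group moments of L*, a*, b*, C* and the centroid ΔE*ab.

    Returns one row per group (canonical order) with columns
    ``n, L_mean, L_sd, a_mean, a_sd, b_mean, b_sd, C_mean, C_sd,
    dE_mean, dE_sd``.  SDs are sample standard deviations (ddof=1).
    Raises if any group has fewer than two measurements.
    """
    rows = []
    for g in dataset.groups:
        lab = dataset.lab(g)
        n = len(lab)
        if n < 2:
            raise ValueError(f"group {g!r} has {n} measurement(s); need at least 2")
        centroid = lab.mean(axis=0)
        c_star = chroma(lab)
        de = delta_e_ab(lab, centroid)
        rows.append(
            {
                "group": g,
                "n": n,
                "L_mean": lab[:, 0].mean(), "L_sd": lab[:, 0].std(ddof=1),
                "a_mean": lab[:, 1].mean(), "a_sd": lab[:, 1].std(ddof=1),
                "b_mean": lab[:, 2].mean(), "b_sd": lab[:, 2].std(ddof=1),
                "C_mean": c_star.mean(), "C_sd": c_star.std(ddof=1),
                "dE_mean": de.mean(), "dE_sd": de.std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def anova_two_way(
    dataset: SkinDataset,
    attribute: str = "L",
    ss_type: int = 2,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Ethnicity × gender fixed-effects ANOVA for one CIELAB attribute.

    ss_type
        2 (default; main effects unbiased by the interaction under the
        unbalanced archive design) or 3 (sum-to-zero contrasts).
    per_subject
        Aggregate measurements to subject means first (off by default).

    Returns a table indexed by effect (``ethnicity``, ``gender``,
    ``ethnicity:gender``, ``residual``) with columns ``df, sum_sq, F,
    p, partial_eta_sq``.
    """
    if attribute not in _ATTRS:
        raise ValueError(f"attribute must be one of {sorted(_ATTRS)}")
    df = dataset.frame[["subject_id", "group", "gender", attribute]].copy()
    if per_subject:
        df = df.groupby(["subject_id", "group", "gender"], as_index=False)[attribute].mean()
    cells = df.groupby(["group", "gender"]).size().unstack(fill_value=0)
    if cells.shape[1] < 2 or (cells == 0).any().any():
        empty = [
            (g, sex)
            for g in cells.index
            for sex in ("female", "male")
            if sex not in cells.columns or cells.loc[g].get(sex, 0) == 0
        ]
        raise ValueError(f"every group needs both genders; empty cells: {empty}")
    if df["group"].nunique() < 2:
        raise ValueError("ANOVA needs at least two groups")

    df = df.rename(columns={attribute: "y"})
    if ss_type == 3:
        formula = "y ~ C(group, Sum) * C(gender, Sum)"
    else:
        formula = "y ~ C(group) * C(gender)"
    fit = smf.ols(formula, data=df).fit()
    table = smf_api.stats.anova_lm(fit, typ=ss_type)

    rename = {}
    for idx in table.index:
        if "group" in idx and "gender" in idx:
            rename[idx] = "ethnicity:gender"
        elif "group" in idx:
            rename[idx] = "ethnicity"
        elif "gender" in idx:
            rename[idx] = "gender"
        elif idx == "Residual":
            rename[idx] = "residual"
    table = table.rename(index=rename)
    ss_resid = table.loc["residual", "sum_sq"]
    out = pd.DataFrame(
        {
            "df": table["df"],
            "sum_sq": table["sum_sq"],
            "F": table["F"],
            "p": table["PR(>F)"],
            "partial_eta_sq": table["sum_sq"] / (table["sum_sq"] + ss_resid),
        }
    )
    out.loc["residual", ["F", "p", "partial_eta_sq"]] = np.nan
    out.index.name = "effect"
    return out.loc[["ethnicity", "gender", "ethnicity:gender", "residual"]]
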