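"""Stage/organ statistics on per-character homoplasy indices.

Implements the three analyses run on per-character retention values:
a Kruskal-Wallis test across groups (developmental stages or adult organs),
a Wilcoxon rank-sum test between two pooled groups (terminalia vs somatic
organs), and linear vs quadratic least-squares regression of the index on the
numeric stage code D (egg = 1 ... adult = 6) compared by AIC.  A quadratic
fit with an interior minimum is the signature of a developmental-hourglass
pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ADULT_ORGANS, STAGES

#: Numeric stage codes used as the regression covariate D.
STAGE_CODE = {s: i + 1 for i, s in enumerate(STAGES)}
TERMINALIA = ("male_terminalia", "female_terminalia")
SOMATIC = ("head", "thorax", "abdomen")


def kruskal_wallis(groups: dict[str, np.ndarray]) -> dict:
    """Rank-based Kruskal-Wallis test with tie correction; df = groups - 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"group '{name}' is empty")
        arrays.append(vals)
    if sum(a.size for a in arrays) < 2:
        raise ValueError("need at least two observations in total")
    h, p = stats.kruskal(*arrays)
    return {"chi2": float(h), "df": len(arrays) - 1, "p": float(p)}


def wilcoxon_rank_sum(group_a, group_b) -> dict:
    """Two-sided rank-sum test; W is the Mann-Whitney statistic of the first
    group (R's ``wilcox.test`` convention), normal approximation with tie
    correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    w, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {"W": float(w), "p": float(p), "n_a": int(a.size), "n_b": int(b.size)}


def hourglass_regression(stage_codes, values) -> dict:
    """Linear and quadratic OLS fits of an index on the stage code D.

    Returns both fits' coefficients, the quadratic term's p-value, Gaussian
    AICs (full log-likelihood, statsmodels convention) and their difference
    ``delta_aic = AIC(linear) - AIC(quadratic)`` (positive favours the
    quadratic), plus the vertex D* = -b/(2c).
    """
    d = np.asarray(stage_codes, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(d) & np.isfinite(y)
    d, y = d[keep], y[keep]
    if np.unique(d).size < 3:
        raise ValueError("need at least three distinct stage codes")
    x_lin = sm.add_constant(d)
    x_quad = sm.add_constant(np.column_stack([d, d * d]))
    fit_lin = sm.OLS(y, x_lin).fit()
    fit_quad = sm.OLS(y, x_quad).fit()
    a, b, c = (float(v) for v in fit_quad.params)
    return {
        "quadratic": {"intercept": a, "linear": b, "quadratic": c},
        "linear": {
            "intercept": float(fit_lin.params[0]),
            "slope": float(fit_lin.params[1]),
        },
        "p_quadratic_term": float(fit_quad.pvalues[2]),
        "aic_linear": float(fit_lin.aic),
        "aic_quadratic": float(fit_quad.aic),
        "delta_aic": float(fit_lin.aic - fit_quad.aic),
        "vertex": -b / (2 * c) if c != 0 else float("nan"),
        "r2_quadratic": float(fit_quad.rsquared),
        "r2_linear": float(fit_lin.rsquared),
        "n": int(y.size),
    }


# ---------------------------------------------------------------------------
# convenience drivers on per-character stats tables
# ---------------------------------------------------------------------------

def _index_values(stats_df: pd.DataFrame, meta: pd.DataFrame, index: str, autapomorphies: str):
    """Attach metadata and select the analysis value per character.

    ``autapomorphies='include'`` uses r_ic (autapomorphy-only characters set
    to 1); ``'exclude'`` uses plain ri, which drops them as undefined.
    """
    df = stats_df.merge(meta.rename(columns={"id": "char_id"}), on="char_id")
    if index not in ("r_ic", "ri"):
        raise ValueError("index must be 'r_ic' or 'ri'")
    if autapomorphies == "exclude":
        col = df["ri"]
    elif autapomorphies == "include":
        col = df[index]
    else:
        raise ValueError("autapomorphies must be 'include' or 'exclude'")
    df = df.assign(value=col)
    return df[np.isfinite(df["value"])]

def stage_test(stats_df: pd.DataFrame, meta: pd.DataFrame, index: str = "r_ic",
               autapomorphies: str = "include") -> dict:
    """Kruskal-Wallis of the retention index across the six developmental stages."""
    df = _index_values(stats_df, meta, index, autapomorphies)
    groups = {s: df.loc[df["stage"] == s, "value"].to_numpy() for s in STAGES
              if (df["stage"] == s).any()}
    return kruskal_wallis(groups)


def organ_test(stats_df: pd.DataFrame, meta: pd.DataFrame, index: str = "r_ic",
               autapomorphies: str = "include") -> dict:
    """Kruskal-Wallis across the five adult organs."""
    df = _index_values(stats_df, meta, index, autapomorphies)
    adult = df[df["stage"] == "adult"]
    groups = {o: adult.loc[adult["organ"] == o, "value"].to_numpy() for o in ADULT_ORGANS
              if (adult["organ"] == o).any()}
    return kruskal_wallis(groups)


def terminalia_test(stats_df: pd.DataFrame, meta: pd.DataFrame, index: str = "r_ic",
                    autapomorphies: str = "include") -> dict:
    """Rank-sum test of terminalia (first group) vs somatic adult characters."""
    df = _index_values(stats_df, meta, index, autapomorphies)
    adult = df[df["stage"] == "adult"]
    term = adult.loc[adult["organ"].isin(TERMINALIA), "value"].to_numpy()
    soma = adult.loc[adult["organ"].isin(SOMATIC), "value"].to_numpy()
    return wilcoxon_rank_sum(term, soma)


def stage_regression(stats_df: pd.DataFrame, meta: pd.DataFrame, index: str = "r_ic",
                     autapomorphies: str = "include", offset: int = 0) -> dict:
    """Hourglass regression of the index on stage code D (egg = 1 + offset)."""
    df = _index_values(stats_df, meta, index, autapomorphies)
    d = df["stage"].map(STAGE_CODE).to_numpy(float) + offset
    return hourglass_regression(d, df["value"].to_numpy())


def stage_summary(stats_df: pd.DataFrame, meta: pd.DataFrame, index: str = "r_ic",
                  autapomorphies: str = "include") -> pd.DataFrame:
    """Per-stage n, mean and median of the chosen index."""
    df = _index_values(stats_df, meta, index, autapomorphies)
    rows = []
    for s in STAGES:
        vals = df.loc[df["stage"] == s, "value"]
        if len(vals):
            rows.append({"stage": s, "D": STAGE_CODE[s], "n": int(len(vals)),
                         "mean": float(vals.mean()), "median": float(vals.median())})
    return pd.DataFrame(rows, columns=["stage", "D", "n", "mean", "median"])
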