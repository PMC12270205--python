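"""Brain-age-gap bias correction and group statistics.

Brain-age models systematically overestimate young and underestimate old
subjects (regression dilution). The correction fits BA = a*CA + b by
ordinary least squares on held-out unimpaired validation data and defines
the corrected gap as (BA - b)/a - CA; the same (a, b) are then applied to
every other dataset. On the fitting set itself the corrected gap has mean
zero and zero OLS slope against CA (an exact property of OLS residuals).

Group comparisons residualize the corrected gap on chronological age (the
nuisance covariate) before a one-way ANOVA with Holm-Sidak step-down
pairwise tests; an ANCOVA formulation is available as an alternative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class BiasModel:
    a: float                     # slope, dimensionless
    b: float                     # intercept, years
    fit_n: int
    fit_source: str = "cu-validation"


@dataclass
class MetricsReport:
    mae: float
    spearman_r: float
    r2: float
    mean_bag: float
    se_bag: float


def fit_bias(ca, ba, fit_source: str = "cu-validation") -> BiasModel:
    """OLS of predicted brain age on chronological age: BA = a*CA + b."""
    ca = np.asarray(ca, dtype=float)
    ba = np.asarray(ba, dtype=float)
    if len(ca) < 3:
        raise ValueError("need at least 3 points to fit the bias model")
    if np.ptp(ca) == 0:
        raise ValueError("degenerate fit: chronological ages are all equal")
    a, b = np.polyfit(ca, ba, 1)
    if abs(a) < 1e-8:
        raise ValueError("fitted slope a is (numerically) zero; correction undefined")
    return BiasModel(a=float(a), b=float(b), fit_n=len(ca), fit_source=fit_source)


def correct_bag(model: BiasModel, records: pd.DataFrame,
                ca_col: str = "CA", ba_col: str = "BA") -> pd.DataFrame:
    """Attach raw and corrected brain-age gaps to a predictions table."""
    out = records.copy()
    out["raw_bag"] = out[ba_col] - out[ca_col]
    out["corrected_bag"] = (out[ba_col] - model.b) / model.a - out[ca_col]
    return out


def compute_metrics(records: pd.DataFrame, model: BiasModel | None = None,
                    ca_col: str = "CA", ba_col: str = "BA") -> MetricsReport:
    """MAE (on bias-corrected BA when a model is given), Spearman r, R^2.

    R^2 is the variance in BA explained by CA in a simple linear model
    (squared Pearson correlation).
    """
    ca = records[ca_col].to_numpy(dtype=float)
    ba = records[ba_col].to_numpy(dtype=float)
    if len(ca) < 3:
        raise ValueError("need at least 3 records")
    ba_corr = (ba - model.b) / model.a if model is not None else ba
    mae = float(np.mean(np.abs(ba_corr - ca)))
    if np.ptp(ca) == 0 or np.ptp(ba) == 0:
        rho, r2 = np.nan, np.nan
    else:
        rho = float(stats.spearmanr(ba, ca).statistic)
        r2 = float(np.corrcoef(ba, ca)[0, 1] ** 2)
    bag = ba_corr - ca
    return MetricsReport(mae=mae, spearman_r=rho, r2=r2,
                         mean_bag=float(bag.mean()),
                         se_bag=float(bag.std(ddof=1) / np.sqrt(len(bag)))
                         if len(bag) > 1 else np.nan)


# ---------------------------------------------------------------------------
# Covariate adjustment and group statistics
# ---------------------------------------------------------------------------

def residualize(values, covariate) -> np.ndarray:
    """OLS residuals of values on a single covariate (plus intercept)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def group_stats(records: pd.DataFrame, group_col: str = "group",
                value_col: str = "corrected_bag", covariate_col: str = "CA",
                method: str = "residualize", alpha: float = 0.05) -> dict:
    """ANOVA across groups with Holm-Sidak pairwise tests, CA-adjusted.

    ``method='residualize'`` (default) removes the covariate by OLS
    residualization before a one-way ANOVA; ``method='ancova'`` models the
    covariate as a regression term and F-tests the group factor. Groups
    with n < 2 are dropped with a warning.
    """
    df = records[[group_col, value_col, covariate_col]].dropna().copy()
    sizes = df.groupby(group_col).size()
    keep = sizes[sizes >= 2].index
    dropped = sorted(set(sizes.index) - set(keep))
    if dropped:
        log.warning("dropping groups with n<2: %s", dropped)
    df = df[df[group_col].isin(keep)]
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")

    if method == "residualize":
        df["_adj"] = residualize(df[value_col], df[covariate_col])
        samples = [df.loc[df[group_col] == g, "_adj"].to_numpy() for g in groups]
        f_stat, p_val = stats.f_oneway(*samples)
    elif method == "ancova":
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        d = df.rename(columns={group_col: "g", value_col: "y", covariate_col: "x"})
        fit = smf.ols("y ~ C(g) + x", data=d).fit()
        tab = anova_lm(fit, typ=2)
        f_stat, p_val = float(tab.loc["C(g)", "F"]), float(tab.loc["C(g)", "PR(>F)"])
        df["_adj"] = residualize(df[value_col], df[covariate_col])
    else:
        raise ValueError(f"unknown method {method!r}")

    pairs, raw_p, diffs, t_stats = [], [], [], []
    for ga, gb in itertools.combinations(groups, 2):
        a = df.loc[df[group_col] == ga, "_adj"].to_numpy()
        b = df.loc[df[group_col] == gb, "_adj"].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        pairs.append((ga, gb))
        raw_p.append(float(p))
        t_stats.append(float(t))
        diffs.append(float(a.mean() - b.mean()))
    adj_p = holm_sidak(raw_p)
    pairwise = pd.DataFrame({
        "group_a": [p[0] for p in pairs], "group_b": [p[1] for p in pairs],
        "mean_diff": diffs, "t": t_stats, "p_raw": raw_p, "p_adj": adj_p,
        "significant": adj_p < alpha,
    })
    means = df.groupby(group_col)[value_col].agg(["mean", "sem", "count"])
    return {"F": float(f_stat), "p": float(p_val), "pairwise": pairwise,
            "group_means": means, "method": method}


def sexwise_stats(records: pd.DataFrame, group_col: str = "group",
                  value_col: str = "corrected_bag", covariate_col: str = "CA",
                  sex_col: str = "sex", alpha: float = 0.05) -> dict:
    """Sex contrasts of the corrected gap.

    Within each subgroup, a male-vs-female two-sample t-test on
    CA-residualized values, Holm-Sidak corrected across subgroups;
    separately, per-sex one-way ANOVAs across subgroups. Empty or
    singleton sex cells skip that subgroup's test.
    """
    df = records[[group_col, value_col, covariate_col, sex_col]].dropna().copy()
    df["_adj"] = residualize(df[value_col], df[covariate_col])
    rows, raw_p = [], []
    for g, sub in df.groupby(group_col, sort=True):
        f = sub.loc[sub[sex_col] == "F", "_adj"].to_numpy()
        m = sub.loc[sub[sex_col] == "M", "_adj"].to_numpy()
        if len(f) < 2 or len(m) < 2:
            log.warning("group %s: a sex cell has n<2; test skipped", g)
            rows.append({"group": g, "mean_F": f.mean() if len(f) else np.nan,
                         "mean_M": m.mean() if len(m) else np.nan,
                         "t": np.nan, "p_raw": np.nan, "skipped": True})
            continue
        t, p = stats.ttest_ind(f, m, equal_var=False)
        rows.append({"group": g, "mean_F": float(f.mean()), "mean_M": float(m.mean()),
                     "t": float(t), "p_raw": float(p), "skipped": False})
        raw_p.append(float(p))
    within = pd.DataFrame(rows)
    tested = ~within["skipped"]
    within["p_adj"] = np.nan
    if tested.any():
        within.loc[tested, "p_adj"] = holm_sidak(within.loc[tested, "p_raw"])
    within["significant"] = within["p_adj"] < alpha

    per_sex = {}
    for sex, sub in df.groupby(sex_col):
        samples = [s["_adj"].to_numpy() for _, s in sub.groupby(group_col)
                   if len(s) >= 2]
        if len(samples) >= 2:
            f_stat, p = stats.f_oneway(*samples)
            per_sex[sex] = {"F": float(f_stat), "p": float(p)}
    return {"within_group": within, "per_sex_anova": per_sex}
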