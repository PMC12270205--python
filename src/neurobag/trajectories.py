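"""Baseline GLM contrasts and longitudinal linear mixed models.

Outcomes (corrected BAG, ICV-normalized regional composites, cognitive
scores) are modeled with per-subject random intercepts and slopes:

    y_ij = b0 + group + time + group x time [+ time^2 + group x time^2]
           + baseline age + sex + cognitive state + education
           + u0_i + u1_i * t_ij + e_ij

fitted by maximum likelihood (not REML) so BIC is comparable across
fixed-effect structures; the quadratic model nests the linear one. Model
order is chosen by the lower BIC with ties going to the linear model.
AD-LB- is the reference level; pairwise group contrasts on baseline,
slope, and (when quadratic) acceleration are Benjamini-Hochberg adjusted
within each term family.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

REFERENCE_GROUP = "AD-LB-"


@dataclass
class CompositeDef:
    name: str
    regions: tuple


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


#: bilateral regional composites used throughout the analyses
DEFAULT_COMPOSITES = (
    CompositeDef("mtl", ("hippocampus", "entorhinal", "amygdala", "parahippocampal")),
    CompositeDef("basal_ganglia", ("caudate", "putamen", "accumbens", "pallidum")),
    CompositeDef("occipital", ("lateral_occipital", "cuneus", "pericalcarine", "lingual")),
    CompositeDef("middle_temporal", ("middle_temporal",)),
)


def normalize_and_aggregate(volumetrics: pd.DataFrame, icv_col: str = "icv",
                            composites=DEFAULT_COMPOSITES,
                            aggregate: str = "sum") -> pd.DataFrame:
    """ICV-normalize region volumes and build composite outcomes.

    ``volumetrics`` has one row per scan with raw region volumes (cm^3)
    and an ICV column (cm^3, > 0). Every region column is divided by ICV;
    each composite is the sum (or mean, behind the flag) of its
    constituents' normalized values. A missing constituent marks the
    composite missing for that scan.
    """
    if (volumetrics[icv_col] <= 0).any():
        raise ValueError("ICV must be positive for every scan")
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    meta_cols = [c for c in volumetrics.columns
                 if c == icv_col or volumetrics[c].dtype == object]
    out = volumetrics[meta_cols].copy()
    region_cols = [c for c in volumetrics.columns if c not in meta_cols]
    for c in region_cols:
        out[f"{c}_norm"] = volumetrics[c] / volumetrics[icv_col]
    for comp in composites:
        missing = [r for r in comp.regions if r not in region_cols]
        if missing:
            out[comp.name] = np.nan
            log.warning("composite %s missing constituents %s", comp.name, missing)
            continue
        vals = sum(out[f"{r}_norm"] for r in comp.regions)
        out[comp.name] = vals / len(comp.regions) if aggregate == "mean" else vals
    return out


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, order: str, reference: str = REFERENCE_GROUP,
            with_time: bool = True):
    """Fixed-effect design matrix with treatment-coded groups.

    Covariate columns (baseline_age, sex, cognitive_state, education) are
    included when present and non-constant; continuous covariates are
    centered so the intercept stays interpretable.
    """
    groups = sorted(df["group"].unique())
    if reference in groups:
        groups = [reference] + [g for g in groups if g != reference]
    cols = {"Intercept": np.ones(len(df))}
    for g in groups[1:]:
        cols[f"group[{g}]"] = (df["group"] == g).astype(float).to_numpy()
    if with_time:
        t = df["time"].to_numpy(dtype=float)
        cols["time"] = t
        for g in groups[1:]:
            cols[f"group[{g}]:time"] = cols[f"group[{g}]"] * t
        if order == "quadratic":
            cols["time2"] = t ** 2
            for g in groups[1:]:
                cols[f"group[{g}]:time2"] = cols[f"group[{g}]"] * t ** 2
    for cov in ("baseline_age", "education"):
        if cov in df.columns and df[cov].nunique() > 1:
            cols[cov] = df[cov].to_numpy(dtype=float) - df[cov].mean()
    if "sex" in df.columns and df["sex"].nunique() > 1:
        cols["sex[M]"] = (df["sex"] == "M").astype(float).to_numpy()
    if "cognitive_state" in df.columns and df["cognitive_state"].nunique() > 1:
        for lvl in sorted(df["cognitive_state"].unique())[1:]:
            cols[f"cognitive_state[{lvl}]"] = \
                (df["cognitive_state"] == lvl).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns for the caller
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased columns: {bad}")
    return X, groups


# ---------------------------------------------------------------------------
# Baseline GLM
# ---------------------------------------------------------------------------

def fit_baseline_glm(df: pd.DataFrame, value_col: str = "value",
                     reference: str = REFERENCE_GROUP, alpha: float = 0.05) -> dict:
    """Cross-sectional group contrasts at baseline, covariate-adjusted.

    Expects one row per subject (time 0). Group coefficients are adjusted
    baseline differences vs the reference; all pairwise contrasts are
    FDR (Benjamini-Hochberg) adjusted.
    """
    d = df.dropna(subset=[value_col]).copy()
    X, groups = _design(d, order="linear", reference=reference, with_time=False)
    fit = sm.OLS(d[value_col].to_numpy(dtype=float), X).fit()
    coef = {g: f"group[{g}]" for g in groups[1:]}
    rows, raw = [], []
    for ga, gb in itertools.combinations(groups, 2):
        L = np.zeros(X.shape[1])
        if ga != reference:
            L[X.columns.get_loc(coef[ga])] += 1
        if gb != reference:
            L[X.columns.get_loc(coef[gb])] -= 1
        tt = fit.t_test(L)
        rows.append({"group_a": ga, "group_b": gb,
                     "beta": float(np.squeeze(tt.effect)),
                     "se": float(np.squeeze(tt.sd)),
                     "p_raw": float(np.squeeze(tt.pvalue))})
        raw.append(rows[-1]["p_raw"])
    adj = benjamini_hochberg(raw) if raw else []
    contrasts = pd.DataFrame(rows)
    contrasts["p_adj"] = adj
    contrasts["significant"] = contrasts["p_adj"] < alpha
    betas = pd.DataFrame({
        "beta": fit.params, "se": fit.bse, "p": fit.pvalues})
    return {"coefficients": betas, "contrasts": contrasts, "result": fit,
            "groups": groups}


# ---------------------------------------------------------------------------
# Linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalFit:
    order: str
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    cov_re: pd.DataFrame
    resid_var: float
    bic: float
    llf: float
    nobs: int
    groups: list
    converged: bool = True
    diagonal_fallback: bool = False
    contrast_table: pd.DataFrame | None = None


def fit_lmm(df: pd.DataFrame, order: str = "linear", value_col: str = "value",
            reference: str = REFERENCE_GROUP) -> LongitudinalFit:
    """Fit the longitudinal mixed model by maximum likelihood.

    Random intercept and slope per subject with unstructured covariance;
    on non-convergence the model is refit with a diagonal random-effect
    covariance and flagged. BIC uses k = fixed effects + random-effect
    (co)variances + residual variance, with n = number of observations.
    """
    if order not in ("linear", "quadratic"):
        raise ValueError("order must be 'linear' or 'quadratic'")
    d = df.dropna(subset=[value_col]).copy()
    X, groups = _design(d, order=order, reference=reference, with_time=True)
    y = d[value_col].to_numpy(dtype=float)
    exog_re = np.column_stack([np.ones(len(d)), d["time"].to_numpy(dtype=float)])
    model = sm.MixedLM(y, X, groups=d["subject_id"].to_numpy(), exog_re=exog_re)

    def _fit(free=None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=False, free=free, method="lbfgs", maxiter=500)

    fallback = False
    try:
        res = _fit()
        ok = res.converged and np.all(np.isfinite(res.bse_fe))
    except (np.linalg.LinAlgError, ValueError):
        ok = False
    if not ok:
        from statsmodels.regression.mixed_linear_model import MixedLMParams
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(2))
        res = _fit(free=free)
        fallback = True
        log.warning("unstructured random effects did not converge; "
                    "diagonal covariance fallback used")

    k_fe = X.shape[1]
    k_re = 2 if fallback else 3  # diag: two variances; else 2x2 symmetric
    k = k_fe + k_re + 1          # + residual variance
    nobs = len(d)
    bic = -2.0 * res.llf + k * np.log(nobs)
    fe = res.fe_params
    fe.index = X.columns
    se = pd.Series(np.asarray(res.bse_fe), index=X.columns)
    pv = pd.Series(np.asarray(res.pvalues)[:k_fe], index=X.columns)
    covp = pd.DataFrame(np.asarray(res.cov_params())[:k_fe, :k_fe],
                        index=X.columns, columns=X.columns)
    cov_re = pd.DataFrame(np.asarray(res.cov_re) * res.scale,
                          index=["intercept", "slope"], columns=["intercept", "slope"])
    fit = LongitudinalFit(order=order, params=fe, se=se, pvalues=pv,
                          cov_params=covp, cov_re=cov_re,
                          resid_var=float(res.scale), bic=float(bic),
                          llf=float(res.llf), nobs=nobs, groups=groups,
                          converged=bool(res.converged), diagonal_fallback=fallback)
    fit.contrast_table = pairwise_contrasts(fit)
    return fit


def select_model_bic(fit_linear: LongitudinalFit | None,
                     fit_quadratic: LongitudinalFit | None) -> LongitudinalFit:
    """Return the lower-BIC fit; ties (and a failed rival) go to linear."""
    if fit_linear is None and fit_quadratic is None:
        raise ValueError("both fits failed")
    if fit_linear is None:
        warnings.warn("linear fit unavailable; returning quadratic")
        return fit_quadratic
    if fit_quadratic is None:
        warnings.warn("quadratic fit unavailable; returning linear")
        return fit_linear
    return fit_quadratic if fit_quadratic.bic < fit_linear.bic else fit_linear


def pairwise_contrasts(fit: LongitudinalFit, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group contrasts per term family, BH-adjusted.

    Families are 'baseline' (group main effects), 'slope' (group x time)
    and, for quadratic fits, 'accel' (group x time^2). Contrasts that are
    inestimable (coefficient absent) are marked rather than dropped.
    """
    families = {"baseline": "group[{g}]", "slope": "group[{g}]:time"}
    if fit.order == "quadratic":
        families["accel"] = "group[{g}]:time2"
    names = list(fit.params.index)
    rows = []
    for fam, pattern in families.items():
        fam_rows = []
        for ga, gb in itertools.combinations(fit.groups, 2):
            def cname(g):
                return None if g == fit.groups[0] else pattern.format(g=g)
            ca, cb = cname(ga), cname(gb)
            estimable = all(c is None or c in names for c in (ca, cb))
            if not estimable:
                fam_rows.append({"family": fam, "group_a": ga, "group_b": gb,
                                 "beta": np.nan, "se": np.nan, "p_raw": np.nan,
                                 "estimable": False})
                continue
            L = np.zeros(len(names))
            if ca is not None:
                L[names.index(ca)] += 1
            if cb is not None:
                L[names.index(cb)] -= 1
            beta = float(L @ fit.params.to_numpy())
            var = float(L @ fit.cov_params.to_numpy() @ L)
            se = np.sqrt(var)
            from scipy import stats as _st
            z = beta / se if se > 0 else np.nan
            p = 2 * _st.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            fam_rows.append({"family": fam, "group_a": ga, "group_b": gb,
                             "beta": beta, "se": se, "p_raw": p, "estimable": True})
        pvals = [r["p_raw"] for r in fam_rows if r["estimable"]]
        if pvals:
            adj = benjamini_hochberg(pvals)
            it = iter(adj)
            for r in fam_rows:
                r["p_adj"] = float(next(it)) if r["estimable"] else np.nan
        rows.extend(fam_rows)
    table = pd.DataFrame(rows)
    if len(table):
        table["significant"] = table["p_adj"] < alpha
    return table


def plot_trajectories(df: pd.DataFrame, fit: LongitudinalFit,
                      value_col: str = "value", ax=None, out_path=None):
    """Spaghetti plot with group-level fitted trajectories and 95% bands.

    Thin lines are individual subjects; thick lines are the fitted mean
    trajectory per group at the covariate means, with pointwise 95%
    confidence bands from the fixed-effect covariance.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    colors = dict(zip(fit.groups, plt.rcParams["axes.prop_cycle"].by_key()["color"]))
    for (g, sid), sub in df.groupby(["group", "subject_id"]):
        sub = sub.sort_values("time")
        ax.plot(sub["time"], sub[value_col], color=colors.get(g, "gray"),
                alpha=0.15, lw=0.6)
    tgrid = np.linspace(df["time"].min(), df["time"].max(), 50)
    names = list(fit.params.index)
    for g in fit.groups:
        L = np.zeros((len(tgrid), len(names)))
        L[:, names.index("Intercept")] = 1.0
        L[:, names.index("time")] = tgrid
        if "time2" in names:
            L[:, names.index("time2")] = tgrid ** 2
        if g != fit.groups[0]:
            L[:, names.index(f"group[{g}]")] = 1.0
            L[:, names.index(f"group[{g}]:time")] = tgrid
            if f"group[{g}]:time2" in names:
                L[:, names.index(f"group[{g}]:time2")] = tgrid ** 2
        mean = L @ fit.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.cov_params.to_numpy(), L))
        ax.plot(tgrid, mean, color=colors.get(g, "gray"), lw=2.2, label=g)
        ax.fill_between(tgrid, mean - 1.96 * se, mean + 1.96 * se,
                        color=colors.get(g, "gray"), alpha=0.2)
    ax.set_xlabel("years since baseline")
    ax.set_ylabel(value_col)
    ax.legend(frameon=False, fontsize=8)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=120, bbox_inches="tight")
    return ax


def fit_trajectory(df: pd.DataFrame, order: str = "auto",
                   value_col: str = "value") -> LongitudinalFit:
    """Fit linear and/or quadratic models and select by BIC when 'auto'."""
    if order in ("linear", "quadratic"):
        return fit_lmm(df, order=order, value_col=value_col)
    lin = quad = None
    try:
        lin = fit_lmm(df, order="linear", value_col=value_col)
    except Exception as e:          # noqa: BLE001 - surfaced via select
        log.warning("linear fit failed: %s", e)
    try:
        quad = fit_lmm(df, order="quadratic", value_col=value_col)
    except Exception as e:          # noqa: BLE001
        log.warning("quadratic fit failed: %s", e)
    return select_model_bic(lin, quad)
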