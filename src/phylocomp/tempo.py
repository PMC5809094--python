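"""Evolutionary tempo indices and cross-trait-class comparisons.

Three rate indices are supported: the analytic BM sigma^2 MLE on z-scored
traits, "felsens" (squared divergence between extant sister species scaled
by twice their divergence time), and BM sigma^2 estimated jointly with
per-species measurement error.  Class comparisons use one-way ANOVA with
Tukey HSD, repeated per tree, and the support regressions relate relative
support for competition models to measurement error, trait class, rate and
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tree import TimeTree, phylo_vcv

__all__ = [
    "TempoRecord",
    "bm_rate",
    "felsens",
    "bm_rate_with_me",
    "class_anova",
    "support_regressions",
]

TRAIT_CLASSES = ("resource-use", "male plumage", "female plumage", "song")


@dataclass
class TempoRecord:
    trait: str
    trait_class: str
    index: str  # sigma2_z | felsen | sigma2_me | mdi
    value: float
    tree_id: str = "mcc"


def _gls_mean_and_rate(x, C):
    cho = cho_factor(C, lower=True)
    ones = np.ones(x.size)
    z0 = (ones @ cho_solve(cho, x)) / (ones @ cho_solve(cho, ones))
    res = x - z0
    return z0, float(res @ cho_solve(cho, res) / x.size)


def bm_rate(tree: TimeTree, x) -> float:
    """Analytic ML estimate of the BM rate sigma^2 (GLS mean, divide by n)."""
    x, keep = _aligned_complete(tree, x)
    if keep.size < 2:
        raise ValueError("need at least 2 tips with data")
    C = phylo_vcv(tree)[np.ix_(keep, keep)]
    _, rate = _gls_mean_and_rate(x, C)
    return rate


def _aligned_complete(tree, x):
    if isinstance(x, dict):
        arr = np.array([x.get(lab, np.nan) for lab in tree.labels], float)
    elif isinstance(x, pd.Series):
        arr = np.array([x.get(lab, np.nan) for lab in tree.labels], float)
    else:
        arr = np.asarray(x, float)
    keep = np.nonzero(np.isfinite(arr))[0]
    return arr[keep], keep


def felsens(tree: TimeTree, x) -> float:
    """Mean over extant sister pairs (cherries) of (x_i - x_j)^2 / (2 t).

    ``t`` is the pair's divergence time; under BM each term estimates
    sigma^2.  Only cherries where both tips have data contribute.
    """
    if isinstance(x, (dict, pd.Series)):
        arr = np.array([x.get(lab, np.nan) if isinstance(x, dict) else x.get(lab, np.nan)
                        for lab in tree.labels], float)
    else:
        arr = np.asarray(x, float)
    vals = []
    for v in range(tree.n_tips, 2 * tree.n_tips - 1):
        a, b = tree.children[v]
        if a < tree.n_tips and b < tree.n_tips:
            if np.isfinite(arr[a]) and np.isfinite(arr[b]):
                vals.append((arr[a] - arr[b]) ** 2 / (2.0 * tree.age[v]))
    if not vals:
        raise ValueError("tree has no cherries with complete data")
    return float(np.mean(vals))


def bm_rate_with_me(tree: TimeTree, x, se) -> dict:
    """BM sigma^2 MLE with measurement error in the tip variances.

    Covariance is ``sigma^2 C + diag(SE^2)``; missing standard errors are
    replaced by one shared free parameter estimated with the rate.  Returns
    a dict with ``sigma2``, ``loglik``, ``z0``, ``se_unknown`` (NaN when all
    SEs are given) and a ``converged`` flag.
    """
    x, keep = _aligned_complete(tree, x)
    if isinstance(se, (dict, pd.Series)):
        se_arr = np.array([se.get(lab, np.nan) for lab in tree.labels], float)[keep]
    else:
        se_arr = np.asarray(se, float)[keep]
    if np.any(se_arr[np.isfinite(se_arr)] < 0):
        raise ValueError("standard errors must be >= 0")
    C = phylo_vcv(tree)[np.ix_(keep, keep)]
    n = x.size
    known = np.isfinite(se_arr)
    diag_known = np.where(known, se_arr, 0.0) ** 2
    any_unknown = bool((~known).any())

    def nll(theta):
        s2 = np.exp(theta[0])
        extra = np.exp(theta[1]) if any_unknown else 0.0
        V = s2 * C + np.diag(diag_known + np.where(known, 0.0, extra))
        try:
            cho = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e10
        ones = np.ones(n)
        z0 = (ones @ cho_solve(cho, x)) / (ones @ cho_solve(cho, ones))
        res = x - z0
        quad = res @ cho_solve(cho, res)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return 0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)

    _, rate0 = _gls_mean_and_rate(x, C)
    x0 = [np.log(max(rate0, 1e-12))] + ([np.log(max(rate0 * tree.root_age * 0.1, 1e-12))]
                                        if any_unknown else [])
    best = None
    for shift in (0.0, -2.0, 2.0):
        res = minimize(nll, np.asarray(x0) + shift, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    s2 = float(np.exp(best.x[0]))
    extra = float(np.exp(best.x[1])) if any_unknown else np.nan
    V = s2 * C + np.diag(diag_known + (0.0 if not any_unknown else
                                       np.where(known, 0.0, extra)))
    cho = cho_factor(V, lower=True)
    ones = np.ones(n)
    z0 = float((ones @ cho_solve(cho, x)) / (ones @ cho_solve(cho, ones)))
    return {
        "sigma2": s2,
        "se_unknown": float(np.sqrt(extra)) if any_unknown else np.nan,
        "z0": z0,
        "loglik": -float(best.fun),
        "converged": bool(best.success),
    }


def class_anova(records: pd.DataFrame, value_col: str = "value",
                class_col: str = "trait_class") -> dict:
    """One-way fixed-effects ANOVA of a tempo index across trait classes,
    with Tukey HSD pairwise comparisons.

    ``records`` holds one row per trait (a single index type, a single
    tree).  Returns F, dfs, p and the Tukey table.
    """
    df = records.dropna(subset=[value_col, class_col])
    groups = [g[value_col].to_numpy() for _, g in df.groupby(class_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 classes with >=2 values each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(df[value_col]) == 0:
        raise ValueError("all values identical: ANOVA undefined")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    tk = pairwise_tukeyhsd(df[value_col], df[class_col])
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return {"F": float(F), "df_between": k - 1, "df_within": n - k,
            "p": float(p), "tukey": tukey}


def support_regressions(table: pd.DataFrame) -> dict:
    """The three support regressions on the per-analysis summary table.

    Expects columns ``rs`` (relative support), ``n`` (sample size),
    ``trait_class``, ``median_me``, ``ln_sigma2``.  Fits:

    a. OLS  rs ~ n                              (sample-size check)
    b. OLS  rs ~ trait_class + median_me        (resource-use reference)
    c. Logit  I(rs > 0.5) ~ ln_sigma2  [and  + trait_class]

    Returns coefficient tables (term, coef, se, stat, p).  A separable
    logistic design falls back to an L2-penalized fit, flagged.
    """
    out = {}
    t = table.copy()
    if "trait_class" in t:
        t["trait_class"] = pd.Categorical(
            t["trait_class"],
            categories=[c for c in TRAIT_CLASSES if c in set(t["trait_class"])]
            + sorted(set(t["trait_class"]) - set(TRAIT_CLASSES)),
        )
    if "n" in t:
        fit = smf.ols("rs ~ n", data=t).fit()
        out["rs_vs_n"] = _coef_table(fit)
    if {"trait_class", "median_me"} <= set(t.columns):
        fit = smf.ols("rs ~ trait_class + median_me", data=t).fit()
        out["rs_vs_class_me"] = _coef_table(fit)
    if "ln_sigma2" in t:
        t["comp_best"] = (t["rs"] > 0.5).astype(int)
        for name, formula in (
            ("logit_rate", "comp_best ~ ln_sigma2"),
            ("logit_rate_class", "comp_best ~ ln_sigma2 + trait_class"),
        ):
            if "trait_class" in formula and "trait_class" not in t:
                continue
            model = smf.logit(formula, data=t)
            try:
                with np.errstate(all="ignore"):
                    fit = model.fit(disp=0, maxiter=200)
                if not fit.mle_retvals.get("converged", True) or \
                        np.any(~np.isfinite(fit.bse)):
                    raise ValueError("separation")
                out[name] = _coef_table(fit)
            except Exception:
                fit = model.fit_regularized(alpha=1.0, disp=0, maxiter=500)
                tab = _coef_table_penalized(fit)
                tab.attrs["penalized"] = True
                out[name] = tab
    return out


def _coef_table(fit):
    return pd.DataFrame({
        "term": fit.params.index,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "stat": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })


def _coef_table_penalized(fit):
    return pd.DataFrame({
        "term": fit.params.index,
        "coef": fit.params.to_numpy(),
        "se": np.nan,
        "stat": np.nan,
        "p": np.nan,
    })
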