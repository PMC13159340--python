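"""Cohort screening, outcome comparisons, logistic models and GAM curves.

Outcome is the 6-month Glasgow Outcome Scale (GOS, 1-5), dichotomised as
favourable vs unfavourable (GOS 4-5 vs 1-3) and survival vs mortality
(GOS 2-5 vs 1).  Group comparisons use the two-sided Mann-Whitney U test;
multivariable outcome models are maximum-likelihood logistic regressions
(model A: age + GCS + PSI; model B: A + median ICP, CPP, PRx), reported as
odds ratios with Wald 95 % confidence intervals.  Exploratory dose-response
curves of PSI against single physiological variables use penalised
cubic-spline GAMs pooled over patients (within-patient correlation ignored;
population-level exploration only).  No multiple-comparison adjustment is
applied; the number of tests performed is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "cohort_filter",
    "compare_groups",
    "fit_outcome_logistic",
    "gam_curves",
    "GAM_X_RANGES",
]

GAM_X_RANGES = {
    "abp": (40.0, 120.0),
    "icp": (0.0, 40.0),
    "amp_icp": (0.0, 15.0),
    "rap": (0.0, 1.0),
}


def cohort_filter(meta: pd.DataFrame, min_hours: float = 12.0):
    """Sequential cohort exclusion cascade with fixed precedence.

    Steps, each applied to the survivors of the previous one:

    1. missing 6-month outcome (``gos`` null),
    2. decompressive craniectomy performed, or DC status unknown,
    3. less than ``min_hours`` hours of joint ICP/PSI monitoring
       (``monitored_hours``).

    Returns ``(included, tally)`` where ``tally`` counts the input, each
    exclusion step, and the included set; a patient failing several steps is
    counted only under the first.
    """
    df = meta.copy()
    tally = {"input": len(df)}
    missing = df["gos"].isna()
    tally["missing_outcome"] = int(missing.sum())
    df = df[~missing]
    dc = df["dc_status"].isin(["performed", "unknown"])
    tally["dc_or_unknown"] = int(dc.sum())
    df = df[~dc]
    short = df["monitored_hours"] < min_hours
    tally["short_monitoring"] = int(short.sum())
    df = df[~short]
    tally["included"] = len(df)
    return df.reset_index(drop=True), tally


def _dichotomise(gos: pd.Series, outcome: str) -> pd.Series:
    gos = gos.astype(float)
    if outcome == "mortality":
        return (gos == 1).astype(int)
    if outcome == "favourable":
        return gos.isin([4, 5]).astype(int)
    raise ValueError("outcome must be 'mortality' or 'favourable'")


def compare_groups(
    summaries: pd.DataFrame,
    outcome: str = "mortality",
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparisons of summary variables by outcome.

    ``summaries`` needs ``gos`` plus the value columns (default: the PSI
    median and the six %GMT bin columns present in the frame).  Returns one
    row per variable with group medians/IQRs, U, and the two-sided p-value;
    groups of size < 2 flag the row as undefined.
    """
    if value_cols is None:
        value_cols = [c for c in summaries.columns if c == "psi_median" or c.startswith("psi_pct_")]
    grp = _dichotomise(summaries["gos"], outcome).to_numpy().astype(bool)
    rows = []
    for col in value_cols:
        v = summaries[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        a = v[ok & grp]  # event group (died / favourable)
        b = v[ok & ~grp]
        row = {"variable": col, "outcome": outcome, "n_event": len(a), "n_other": len(b)}
        for tag, g in (("event", a), ("other", b)):
            if len(g):
                row[f"median_{tag}"] = float(np.median(g))
                row[f"iqr_lo_{tag}"] = float(np.percentile(g, 25))
                row[f"iqr_hi_{tag}"] = float(np.percentile(g, 75))
            else:
                row[f"median_{tag}"] = np.nan
                row[f"iqr_lo_{tag}"] = np.nan
                row[f"iqr_hi_{tag}"] = np.nan
        if len(a) < 2 or len(b) < 2:
            row["u"] = np.nan
            row["pvalue"] = np.nan
            row["defined"] = False
        else:
            u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            row["u"] = float(u)
            row["pvalue"] = float(p)
            row["defined"] = True
        rows.append(row)
    return pd.DataFrame(rows)


_MODEL_COVARIATES = {
    "A": ["age", "gcs", "psi_median"],
    "B": ["age", "gcs", "psi_median", "icp_median", "cpp_median", "prx_median"],
}


def fit_outcome_logistic(
    records: pd.DataFrame,
    model: str = "A",
    outcome: str = "mortality",
) -> pd.DataFrame:
    """Multivariable logistic regression of a dichotomised GOS outcome.

    Model A adjusts for demographics (age) and injury severity (GCS) beside
    the patient's median PSI; model B additionally adjusts for neurocritical
    care targets (median ICP, CPP and PRx).  Returns one row per covariate
    with OR = exp(beta) and Wald 95 % CI; non-convergence, (quasi-)complete
    separation or a degenerate outcome flag the fit instead of estimating.
    """
    if model not in _MODEL_COVARIATES:
        raise ValueError("model must be 'A' or 'B'")
    covs = _MODEL_COVARIATES[model]
    df = records.dropna(subset=["gos"] + covs).copy()
    y = _dichotomise(df["gos"], outcome)
    flag_row = lambda reason: pd.DataFrame(
        [{"model": model, "outcome": outcome, "covariate": "(none)", "flagged": True, "reason": reason}]
    )
    if y.nunique() < 2:
        return flag_row("degenerate outcome: all patients in one class")
    X = sm.add_constant(df[covs].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # includes PerfectSeparationError
        return flag_row(f"fit failed: {exc}")
    separated = bool(np.any(np.abs(res.params.to_numpy()[1:]) > 15))
    ci = res.conf_int()
    rows = []
    for cov in covs:
        rows.append(
            {
                "model": model,
                "outcome": outcome,
                "covariate": cov,
                "or": float(np.exp(res.params[cov])),
                "ci_lo": float(np.exp(ci.loc[cov, 0])),
                "ci_hi": float(np.exp(ci.loc[cov, 1])),
                "pvalue": float(res.pvalues[cov]),
                "flagged": separated or not res.mle_retvals.get("converged", True),
                "reason": "possible separation or non-convergence" if separated else "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GamCurve:
    """Fitted smooth of PSI against one physiological variable."""

    x_name: str
    grid: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_points: int


def gam_curves(
    minutes: pd.DataFrame,
    x: str,
    y: str = "psi",
    exclude_icp_above: float | None = None,
    df_spline: int = 10,
    n_grid: int = 100,
    min_points: int = 100,
) -> GamCurve:
    """Penalised cubic-spline GAM of PSI against one variable, with 95 % band.

    Minute rows are pooled across patients and restricted to the variable's
    stated exploration range (``GAM_X_RANGES``; PSI to [1, 4]).  The
    sensitivity variant ``exclude_icp_above=40`` additionally drops minutes
    where ICP simultaneously exceeds that threshold (pulse amplitude can fall
    artifactually at extreme ICP).  Age stratification is done by the caller
    subsetting ``minutes``.  Fewer than ``min_points`` rows in range is
    refused.  The smoothing penalty is selected by the backend's
    cross-validation criterion.
    """
    if x not in GAM_X_RANGES:
        raise ValueError(f"x must be one of {sorted(GAM_X_RANGES)}")
    lo, hi = GAM_X_RANGES[x]
    d = minutes.dropna(subset=[x, y])
    d = d[(d[x] >= lo) & (d[x] <= hi) & (d[y] >= 1.0) & (d[y] <= 4.0)]
    if exclude_icp_above is not None and "icp" in d.columns:
        d = d[~(d["icp"] > exclude_icp_above)]
    if len(d) < min_points:
        raise ValueError(
            f"only {len(d)} points in range for {x}; at least {min_points} required"
        )
    xv = d[x].to_numpy(dtype=float)[:, None]
    yv = d[y].to_numpy(dtype=float)
    bs = BSplines(xv, df=[df_spline], degree=[3])
    exog = np.ones((len(yv), 1))
    grid = np.linspace(xv.min(), xv.max(), n_grid)
    basis = bs.transform(grid[:, None])
    design = np.column_stack([np.ones(n_grid), basis])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = GLMGam(yv, exog=exog, smoother=bs, alpha=[1.0])
            try:
                alpha = model.select_penweight()[0]
            except Exception:
                alpha = [1.0]
            model = GLMGam(yv, exog=exog, smoother=bs, alpha=alpha)
            res = model.fit()
            params = res.params
            cov = res.cov_params()
            se = np.sqrt(np.einsum("ij,jk,ik->i", design, cov, design))
        except Exception:
            # degenerate (e.g. exactly noiseless) response: unpenalised
            # least squares on the same basis; the band collapses onto the fit
            full = np.column_stack([np.ones(len(yv)), bs.transform(xv)])
            params, *_ = np.linalg.lstsq(full, yv, rcond=None)
            resid = yv - full @ params
            s2 = float(resid @ resid) / max(len(yv) - full.shape[1], 1)
            cov = s2 * np.linalg.pinv(full.T @ full)
            se = np.sqrt(np.einsum("ij,jk,ik->i", design, cov, design))
    fit = design @ params
    return GamCurve(
        x_name=x,
        grid=grid,
        fit=fit,
        lo=fit - 1.96 * se,
        hi=fit + 1.96 * se,
        n_points=len(d),
    )
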