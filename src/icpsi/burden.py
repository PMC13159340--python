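"""Hourly ICP-burden metrics and lagged linear mixed-effects prediction.

Hourly predictor metrics are summaries of PSI (mean, median, SD, IQR, %GMT
above 2 and 3); hourly outcome metrics are summaries of ICP burden: mean and
median ICP, ICP dose (area under the curve above 20 and 22 mmHg, in
mmHg*min), %GMT above those thresholds, the number of insult episodes (any
duration, and lasting >= 5 consecutive minutes), and ICP variability.

The mixed models regress an ICP metric at hour t on a PSI metric and mean
ICP at hour t - lag (lag in {1, 2, 3} h), with a random intercept per
patient (optionally a random slope), fitted by REML.  Marginal R^2 is the
Nakagawa-Schielzeth fixed-effects variance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "hourly_metrics",
    "lagged_design",
    "fit_lmm",
    "fit_lag_grid",
    "LmmResult",
    "PSI_METRICS",
    "ICP_METRICS",
]

PSI_METRICS = ["psi_mean", "psi_median", "psi_gmt_gt2", "psi_gmt_gt3", "psi_sd", "psi_iqr"]
ICP_METRICS = [
    "icp_mean",
    "icp_median",
    "icp_dose_20",
    "icp_dose_22",
    "icp_gmt_gt20",
    "icp_gmt_gt22",
    "n_insults_any",
    "n_insults_ge5min",
    "icp_sd",
    "icp_iqr",
]


def _runs_above(icp: np.ndarray, valid: np.ndarray, thr: float) -> list[int]:
    """Lengths of maximal runs of consecutive *valid* minutes strictly above thr.

    Invalid minutes terminate an episode.
    """
    above = valid & (icp > thr)
    runs, cur = [], 0
    for flag in above:
        if flag:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def _iqr(v: np.ndarray) -> float:
    return float(np.percentile(v, 75) - np.percentile(v, 25))


def hourly_metrics(
    minutes: pd.DataFrame,
    patient: str | None = None,
    thresholds: tuple[float, float] = (20.0, 22.0),
    min_valid_minutes: int = 30,
) -> pd.DataFrame:
    """Per-clock-hour PSI predictor metrics and ICP burden metrics.

    ``minutes`` is a minute series (columns ``minute``, ``icp``, ``psi``; a
    ``patient`` column is used when present).  Hours are left-closed bins of
    60 minutes from the recording start.  An hour needs at least
    ``min_valid_minutes`` valid ICP minutes to produce a row; PSI fields are
    NaN when the hour has fewer valid PSI minutes than that quorum.

    Dose is Riemann area: sum of max(icp - thr, 0) over valid minutes, in
    mmHg*min.  Insults are maximal runs of consecutive valid minutes strictly
    above threshold; invalid minutes end an episode.
    """
    df = minutes
    if patient is None and "patient" in df.columns:
        parts = [hourly_metrics(g, p, thresholds, min_valid_minutes) for p, g in df.groupby("patient")]
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    hours = df["minute"].to_numpy() // 60
    rows = []
    thr_lo, thr_hi = thresholds
    for h in np.unique(hours):
        sub = df[hours == h]
        icp = sub["icp"].to_numpy(dtype=float)
        v_icp = np.isfinite(icp)
        if v_icp.sum() < min_valid_minutes:
            continue
        icp_v = icp[v_icp]
        row: dict = {"patient": patient if patient is not None else "", "hour": int(h)}
        row["icp_mean"] = icp_v.mean()
        row["icp_median"] = float(np.median(icp_v))
        row["icp_sd"] = float(icp_v.std(ddof=1)) if len(icp_v) > 1 else 0.0
        row["icp_iqr"] = _iqr(icp_v)
        for thr, tag in ((thr_lo, "20"), (thr_hi, "22")):
            row[f"icp_dose_{tag}"] = float(np.maximum(icp_v - thr, 0.0).sum())
            row[f"icp_gmt_gt{tag}"] = float((icp_v > thr).mean() * 100.0)
        runs = _runs_above(icp, v_icp, thr_lo)
        row["n_insults_any"] = len(runs)
        row["n_insults_ge5min"] = sum(1 for r in runs if r >= 5)
        psi = sub["psi"].to_numpy(dtype=float) if "psi" in sub.columns else np.array([])
        v_psi = np.isfinite(psi)
        if v_psi.sum() >= min_valid_minutes:
            p = psi[v_psi]
            row["psi_mean"] = p.mean()
            row["psi_median"] = float(np.median(p))
            row["psi_sd"] = float(p.std(ddof=1)) if len(p) > 1 else 0.0
            row["psi_iqr"] = _iqr(p)
            row["psi_gmt_gt2"] = float((p > 2.0).mean() * 100.0)
            row["psi_gmt_gt3"] = float((p > 3.0).mean() * 100.0)
        else:
            for k in PSI_METRICS:
                row[k] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def lagged_design(
    hourly: pd.DataFrame,
    lag: int,
    outcome: str,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Pair hour-t outcomes with hour-(t - lag) predictors, within patient.

    ``predictors`` default to the PSI metrics plus ``icp_mean``; lagged
    columns get an ``_lag`` suffix.  Rows missing the outcome or any lagged
    predictor are dropped.  Pairs never cross patients.
    """
    if lag not in (1, 2, 3):
        raise ValueError("lag must be 1, 2 or 3 hours")
    predictors = predictors or (PSI_METRICS + ["icp_mean"])
    out_rows = []
    for pid, g in hourly.groupby("patient"):
        g = g.set_index("hour")
        for h in g.index:
            if (h - lag) not in g.index:
                continue
            row = {"patient": pid, "hour": int(h), outcome: g.at[h, outcome]}
            for p in predictors:
                row[f"{p}_lag"] = g.at[h - lag, p]
            out_rows.append(row)
    design = pd.DataFrame(out_rows)
    if len(design):
        design = design.dropna(subset=[outcome] + [f"{p}_lag" for p in predictors])
    return design.reset_index(drop=True)


@dataclass
class LmmResult:
    """One fitted lagged mixed model."""

    outcome: str
    predictor: str
    lag: int
    beta: float
    se: float
    pvalue: float
    marginal_r2: float
    re_structure: str
    converged: bool
    singular: bool

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "lag": self.lag,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "marginal_r2": self.marginal_r2,
            "re_structure": self.re_structure,
            "converged": self.converged,
            "singular": self.singular,
        }


def fit_lmm(
    design: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariate: str | None = "icp_mean_lag",
    lag: int = 1,
    random: str = "intercept",
    ar1: bool = False,
) -> LmmResult:
    """REML linear mixed model of ``outcome`` on lagged predictor + covariate.

    Fixed effects: intercept, ``predictor`` and (optionally) ``covariate``.
    Random effects: a per-patient intercept (``random='intercept'``), plus a
    random slope on the predictor (``random='slope_predictor'``) or on hour
    (``random='slope_time'``).  Marginal R^2 is Nakagawa-Schielzeth:
    var(fixed-effect predictions) / (fixed + random + residual variance),
    with the random-effects contribution averaged over each row's
    random-effects design.  Singular fits (a variance component estimated at
    ~0) are flagged, not dropped.
    """
    if ar1:
        raise NotImplementedError(
            "AR(1) residual correlation is not available in the mixed-model "
            "backend used here; fit with independent residuals instead"
        )
    terms = [predictor] + ([covariate] if covariate else [])
    formula = f"{outcome} ~ " + " + ".join(terms)
    if random == "intercept":
        re_formula = "1"
    elif random == "slope_predictor":
        re_formula = f"1 + {predictor}"
    elif random == "slope_time":
        re_formula = "1 + hour"
    else:
        raise ValueError(f"unknown random-effects structure: {random!r}")
    model = smf.mixedlm(formula, design, groups=design["patient"], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    fe_names = [n for n in res.fe_params.index]
    X = pd.DataFrame({"Intercept": np.ones(len(design))})
    for n in fe_names:
        if n != "Intercept":
            X[n] = design[n].to_numpy()
    fixed_pred = X[fe_names].to_numpy() @ res.fe_params.to_numpy()
    var_f = float(np.var(fixed_pred))
    cov_re = np.atleast_2d(res.cov_re.to_numpy())
    # average z' Sigma z over rows (z = random-effects design row)
    if re_formula == "1":
        var_re = float(cov_re[0, 0])
    else:
        zcol = re_formula.split("+")[1].strip()
        z = np.column_stack([np.ones(len(design)), design[zcol].to_numpy()])
        var_re = float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    var_e = float(res.scale)
    total = var_f + var_re + var_e
    marginal_r2 = var_f / total
    singular = bool(np.any(np.diag(cov_re) < 1e-8 * total))
    return LmmResult(
        outcome=outcome,
        predictor=predictor,
        lag=lag,
        beta=float(res.fe_params[predictor]),
        se=float(res.bse_fe[predictor]),
        pvalue=float(res.pvalues[predictor]),
        marginal_r2=marginal_r2,
        re_structure=random,
        converged=bool(res.converged),
        singular=singular,
    )


def fit_lag_grid(
    hourly: pd.DataFrame,
    outcomes: list[str] | None = None,
    predictors: list[str] | None = None,
    lags: tuple[int, ...] = (1, 2, 3),
    random: str = "intercept",
) -> pd.DataFrame:
    """Tidy table of LMM fits over the outcome x predictor x lag grid."""
    outcomes = outcomes or ICP_METRICS
    predictors = predictors or PSI_METRICS
    rows = []
    for lag in lags:
        for outc in outcomes:
            design = lagged_design(hourly, lag, outc)
            if len(design) < 10:
                continue
            for pred in predictors:
                try:
                    res = fit_lmm(design, outc, f"{pred}_lag", lag=lag, random=random)
                except Exception:
                    continue
                rows.append(res.as_row())
    return pd.DataFrame(rows)
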