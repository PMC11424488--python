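"""Association and survival statistics for participant-level metrics.

Implements the metric transformations and cohort splits, the univariate
proportional-hazards screen (P < 0.1), the multivariate Cox model with the
clinical covariate set and 5th-95th percentile rescaling (so a continuous
hazard ratio reads as the hazard increase between a metric's 5th and 95th
percentiles), Kaplan-Meier/log-rank group comparisons, and per-chromosome-arm
mixed-effects association scans with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.formula.api import mixedlm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CovariateSpec",
    "rescale_5_95",
    "transform_metric",
    "split_binary",
    "prepare_covariates",
    "univariate_screen",
    "multivariate_cph",
    "km_logrank",
    "mixed_association",
    "arm_association_scan",
]

# transformations used for each genomic metric before modelling
DEFAULT_TRANSFORMS = {
    "mPGA": "log",
    "max_PGA": "log",
    "lossness": "log",
    "total_events": "log",
    "subclonal_events": "log",
    "subclonality": "exp",
}
# Spearman divergence splits at the upper tertile; everything else at the median
DEFAULT_SPLITS = {"spearman": "upper-tertile"}


@dataclass
class CovariateSpec:
    """How one covariate enters the survival models."""

    name: str
    kind: str = "continuous"  # continuous | binary | categorical
    transform: str = "identity"  # identity | log | exp
    split: str = "median"  # median | upper-tertile | none
    reference: Optional[str] = None  # categorical reference level


def rescale_5_95(values: np.ndarray) -> np.ndarray:
    """Affine rescaling sending the 5th and 95th percentiles to 0 and 1.

    Percentiles use linear interpolation; values outside the band map
    outside [0, 1]. Degenerate spread (p5 == p95) is an error.
    """
    values = np.asarray(values, dtype=float)
    p5, p95 = np.percentile(values[~np.isnan(values)], [5, 95])
    if p5 == p95:
        raise ValueError("degenerate spread: 5th and 95th percentiles coincide")
    return (values - p5) / (p95 - p5)


def transform_metric(values: np.ndarray, transform: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if transform == "identity":
        return values
    if transform == "log":
        with np.errstate(divide="ignore"):
            return np.log(values)
    if transform == "exp":
        return np.exp(values)
    raise ValueError(f"unknown transform {transform!r}")


def split_binary(values: np.ndarray, split: str) -> np.ndarray:
    """Binary split of a metric over the analysis cohort.

    Median split: ties go to the lower group (strictly greater than the
    median scores 1). Upper-tertile split: the boundary value goes to the
    upper group (at or above the 2/3 quantile scores 1). Quantiles use
    linear interpolation.
    """
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if split == "median":
        return (values > np.median(finite)).astype(float)
    if split == "upper-tertile":
        return (values >= np.quantile(finite, 2.0 / 3.0)).astype(float)
    raise ValueError(f"unknown split {split!r}")


def prepare_covariates(metrics: pd.DataFrame, specs: Sequence[CovariateSpec],
                       rescale: bool = True) -> pd.DataFrame:
    """Model matrix from a ParticipantMetrics table.

    Continuous covariates are transformed then (optionally) rescaled to the
    5th-95th band; binary covariates are transformed then split; categorical
    covariates are dummy-coded against their stated reference level.
    """
    cols = {}
    for spec in specs:
        v = metrics[spec.name]
        if spec.kind == "categorical":
            cats = pd.Categorical(v)
            for level in cats.categories:
                if str(level) == str(spec.reference):
                    continue
                cols[f"{spec.name}_{level}"] = (v == level).astype(float)
            continue
        x = transform_metric(v.to_numpy(dtype=float), spec.transform)
        if spec.kind == "binary":
            cols[spec.name] = split_binary(x, spec.split)
        else:
            cols[spec.name] = rescale_5_95(x) if rescale else x
    return pd.DataFrame(cols, index=metrics.index)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def univariate_screen(
    metrics: pd.DataFrame,
    candidates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    transforms: Optional[dict] = None,
    splits: Optional[dict] = None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Univariate Cox screen of candidate metrics, continuous and binary.

    Each metric is fitted twice — transformed continuous and cohort-split
    binary. Metrics with Wald P < ``alpha`` in either form qualify for the
    multivariate model; when both forms qualify only the continuous form is
    carried forward. Returns one row per (metric, form) with the qualifying
    flag and the selected form.
    """
    transforms = {**DEFAULT_TRANSFORMS, **(transforms or {})}
    splits = {**DEFAULT_SPLITS, **(splits or {})}
    rows = []
    for name in candidates:
        sub = metrics[[name, duration_col, event_col]].dropna()
        x = transform_metric(sub[name].to_numpy(dtype=float), transforms.get(name, "identity"))
        for form in ("continuous", "binary"):
            xx = x if form == "continuous" else split_binary(x, splits.get(name, "median"))
            df = pd.DataFrame({name: xx, duration_col: sub[duration_col],
                               event_col: sub[event_col]})
            try:
                cph = _fit_cox(df, duration_col, event_col)
                p = float(cph.summary.loc[name, "p"])
                hr = float(cph.summary.loc[name, "exp(coef)"])
            except Exception as exc:  # noqa: BLE001 - surfaced per metric
                warnings.warn(f"univariate fit failed for {name} ({form}): {exc}")
                p, hr = np.nan, np.nan
            rows.append(dict(metric=name, form=form, hr=hr, p=p,
                             qualifies=bool(p < alpha) if np.isfinite(p) else False))
    out = pd.DataFrame(rows)
    selected = []
    for name, grp in out.groupby("metric", sort=False):
        forms = set(grp.loc[grp["qualifies"], "form"])
        if "continuous" in forms:
            selected.append((name, "continuous"))
        elif "binary" in forms:
            selected.append((name, "binary"))
    out["selected"] = out.apply(
        lambda r: (r["metric"], r["form"]) in selected, axis=1
    )
    return out


def multivariate_cph(
    model_matrix: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron ties).

    ``model_matrix`` holds the prepared covariates plus duration and event
    columns. Returns the per-covariate hazard ratios with 95% CIs and Wald
    P values; for a 5th-95th rescaled covariate the HR is the hazard
    increase between those percentiles. Convergence and collinearity
    problems raise with diagnostics rather than being silently dropped.
    """
    cph = _fit_cox(model_matrix, duration_col, event_col)
    s = cph.summary
    return pd.DataFrame({
        "covariate": s.index,
        "hr": s["exp(coef)"].to_numpy(),
        "hr_lo": s["exp(coef) lower 95%"].to_numpy(),
        "hr_hi": s["exp(coef) upper 95%"].to_numpy(),
        "coef": s["coef"].to_numpy(),
        "se": s["se(coef)"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)


def km_logrank(
    metrics: pd.DataFrame,
    group_col: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Kaplan-Meier curves per group with a two-sided log-rank test.

    Returns the chi-square statistic, degrees of freedom, P value, fitted
    KM curves and per-group median survival times (inf = not reached).
    """
    res = multivariate_logrank_test(
        metrics[duration_col], metrics[group_col], metrics[event_col]
    )
    curves = {}
    medians = {}
    for g, grp in metrics.groupby(group_col):
        km = KaplanMeierFitter()
        km.fit(grp[duration_col], grp[event_col], label=str(g))
        curves[g] = km
        medians[g] = float(km.median_survival_time_)
    return {
        "chi2": float(res.test_statistic),
        "df": int(res.degrees_of_freedom),
        "p": float(res.p_value),
        "curves": curves,
        "median_survival": medians,
    }


def mixed_association(
    samples: pd.DataFrame,
    dependent: str,
    predictor: str,
    group: str = "participant",
) -> dict:
    """Linear mixed model with a random intercept per participant.

    Tests the fixed-effect gradient of ``predictor`` on ``dependent`` with a
    two-sided Wald z test, absorbing between-participant baseline shifts in
    the random intercept. A constant predictor is a singular design and is
    refused.
    """
    sub = samples[[dependent, predictor, group]].dropna()
    if sub[predictor].nunique() <= 1:
        raise ValueError(f"singular design: predictor {predictor!r} is constant")
    model = mixedlm(f"{dependent} ~ {predictor}", sub, groups=sub[group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    return {
        "estimate": float(fit.params[predictor]),
        "se": float(fit.bse[predictor]),
        "t": float(fit.tvalues[predictor]),
        "p": float(fit.pvalues[predictor]),
        "n_observations": int(len(sub)),
    }


def arm_association_scan(
    samples: pd.DataFrame,
    dependent: str,
    group: str = "participant",
    arm_col: str = "arm",
    status_col: str = "status",
    min_observations: int = 10,
) -> pd.DataFrame:
    """Per-arm gain/loss association with a morphology dependent variable.

    For each chromosome arm and each direction (gain, loss) a mixed model of
    ``dependent`` on an indicator (direction vs neutral baseline) is fitted,
    but only when the direction has more than ``min_observations``
    observations. P values are Benjamini-Hochberg adjusted across the
    emitted models (one dependent variable per call, matching the
    per-dependent adjustment rule).
    """
    rows = []
    for arm, grp in samples.groupby(arm_col):
        for direction in ("gain", "loss"):
            sel = grp[grp[status_col].isin([direction, "neutral"])].copy()
            n_dir = int((sel[status_col] == direction).sum())
            if n_dir <= min_observations:
                continue
            sel["indicator"] = (sel[status_col] == direction).astype(float)
            try:
                res = mixed_association(sel, dependent, "indicator", group=group)
            except ValueError:
                continue
            rows.append(dict(arm=arm, direction=direction, dependent=dependent,
                             estimate=res["estimate"], se=res["se"], p=res["p"],
                             n_observations=n_dir))
    out = pd.DataFrame(rows, columns=["arm", "direction", "dependent", "estimate",
                                      "se", "p", "n_observations"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out
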