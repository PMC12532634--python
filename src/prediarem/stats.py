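"""Longitudinal and progression statistics.

Group x time linear mixed models (random intercept per subject, REML) with
Benjamini-Hochberg multiplicity correction across the model family and
Holm-corrected within-group post hoc changes; 2x2 risk ratios with
log-method confidence intervals and Fisher's exact test; in-package
Kaplan-Meier and log-rank; Wilson intervals for stratified remission
proportions; and chained-equation multiple imputation for the fat-depot
variables with Rubin pooling.

Model fitting is delegated to statsmodels (MixedLM); inference on the
interaction contrast uses the large-sample normal approximation of the Wald
statistic, which is recorded in every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.imputation.mice import MICEData
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ModelResult",
    "RiskRatioResult",
    "fit_group_time_model",
    "bh_adjust",
    "holm_adjust",
    "relative_risk",
    "km_estimate",
    "log_rank",
    "stratified_remission_rates",
    "impute_missing",
    "pool_rubin",
]


@dataclass
class ModelResult:
    """Interaction inference plus within-group post hoc changes."""

    outcome: str
    estimate: float  # group x time interaction, units of the outcome
    ci_low: float
    ci_high: float
    p_interaction: float
    p_adjusted: float | None  # filled by BH across the model family
    within_group: dict  # group -> {"estimate", "p", "p_holm"}
    converged: bool
    n_subjects: int
    inference: str = "wald-normal"

    def as_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_interaction": self.p_interaction,
            "p_adjusted": self.p_adjusted,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "inference": self.inference,
        }
        for g, res in self.within_group.items():
            d[f"change_{g}"] = res["estimate"]
            d[f"p_change_{g}"] = res["p_holm"]
        return d


def _design(
    table: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    groups = sorted(table["group"].unique())
    times = sorted(table["time"].unique())
    if len(groups) != 2 or len(times) != 2:
        raise ValueError("expected exactly two groups and two time points")
    ref_g, alt_g = groups[0], groups[1]
    g = (table["group"] == alt_g).astype(float).to_numpy()
    t = (table["time"] == times[1]).astype(float).to_numpy()
    cols = [np.ones(len(table)), g, t, g * t]
    names = ["intercept", f"group[{alt_g}]", f"time[{times[1]}]", "group_x_time"]
    for cov in covariates:
        col = table[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    return X, table["value"].to_numpy(dtype=float), np.asarray(table["subject_id"]), names


def fit_group_time_model(
    table: pd.DataFrame,
    outcome: str = "value",
    covariates: list[str] | None = None,
    adjust_for_sensitivity: bool = False,
) -> ModelResult:
    """Random-intercept mixed model of ``value ~ group * time (+ covariates)``.

    ``table`` is long-format with columns ``subject_id``, ``group``,
    ``time``, ``value`` and any covariate columns (time-invariant; baseline
    BMI should be supplied, not time-varying BMI).  With
    ``adjust_for_sensitivity=True`` the column ``insulin_sensitivity`` is
    added as a fixed effect, as done for the secretion models.  Returns the
    group x time interaction contrast with a 95% CI and Wald p-value, plus
    Holm-corrected within-group baseline -> follow-up changes.  Rows with a
    missing outcome are dropped (complete-case within the model).
    """
    covariates = list(covariates or [])
    if adjust_for_sensitivity:
        covariates.append("insulin_sensitivity")
    tab = table.dropna(subset=["value"] + covariates).copy()
    n_per = tab.groupby("group")["subject_id"].nunique()
    if (n_per < 2).any() or len(n_per) < 2:
        raise ValueError("need at least 2 subjects per group")
    X, y, subj, names = _design(tab, covariates)
    model = sm.MixedLM(y, X, groups=subj)
    converged = True
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # boundary variance fits are reported, not raised
        try:
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=True, method="powell")
            converged = bool(fit.converged)
    k = names.index("group_x_time")
    est = float(fit.fe_params[k])
    se = float(fit.bse_fe[k])
    z = sps.norm.ppf(0.975)
    p_int = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else float("nan")

    # within-group changes: reference group = time coefficient; the other
    # group = time + interaction, with variance from the fitted covariance
    kt = names.index([n for n in names if n.startswith("time[")][0])
    cov_fe = np.asarray(fit.cov_params())[: len(names), : len(names)]
    groups = sorted(tab["group"].unique())
    within = {}
    c_ref = np.zeros(len(names))
    c_ref[kt] = 1.0
    c_alt = c_ref.copy()
    c_alt[k] = 1.0
    raw = {}
    for gname, cvec in ((groups[0], c_ref), (groups[1], c_alt)):
        e = float(cvec @ fit.fe_params[: len(names)])
        s = float(np.sqrt(cvec @ cov_fe @ cvec))
        raw[gname] = (e, 2.0 * sps.norm.sf(abs(e / s)) if s > 0 else float("nan"))
    holm = holm_adjust([raw[g][1] for g in groups])
    for gname, ph in zip(groups, holm):
        within[gname] = {"estimate": raw[gname][0], "p": raw[gname][1], "p_holm": ph}

    return ModelResult(
        outcome=outcome,
        estimate=est,
        ci_low=est - z * se,
        ci_high=est + z * se,
        p_interaction=float(p_int),
        p_adjusted=None,
        within_group=within,
        converged=converged,
        n_subjects=int(tab["subject_id"].nunique()),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (used for post hoc families)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


@dataclass
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    p_fisher: float
    table: tuple  # (events1, nonevents1, events2, nonevents2)


def relative_risk(
    events1: int, nonevents1: int, events2: int, nonevents2: int
) -> RiskRatioResult:
    """Risk ratio of group 1 vs group 2 with the log-method 95% CI.

    CI = exp(ln RR +/- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))); the
    two-sided Fisher exact p-value is computed alongside.  Zero events in
    the reference group leave RR/CI undefined (inf/NaN flagged).
    """
    a, b, c, d = events1, nonevents1, events2, nonevents2
    if min(a, b, c, d) < 0 or (a + b) == 0 or (c + d) == 0:
        raise ValueError("both group sizes must be positive")
    _, p = sps.fisher_exact([[a, b], [c, d]])
    risk1 = a / (a + b)
    risk2 = c / (c + d)
    if risk2 == 0:
        return RiskRatioResult(float("inf"), float("nan"), float("nan"), p, (a, b, c, d))
    rr = risk1 / risk2
    if a == 0:
        return RiskRatioResult(rr, float("nan"), float("nan"), p, (a, b, c, d))
    z = sps.norm.ppf(0.975)
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    return RiskRatioResult(
        rr=rr,
        ci_low=rr * math.exp(-z * se),
        ci_high=rr * math.exp(z * se),
        p_fisher=float(p),
        table=(a, b, c, d),
    )


def km_estimate(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimator.

    Returns ``(timeline, survival)`` where the timeline is the sorted unique
    set of observed times and survival is the right-continuous estimate at
    each of them.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no survival records")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    timeline = np.unique(t)
    surv = np.empty_like(timeline)
    s = 1.0
    for i, ti in enumerate(timeline):
        at_risk = np.sum(t >= ti)
        deaths = np.sum((t == ti) & e)
        if at_risk > 0 and deaths > 0:
            s *= 1.0 - deaths / at_risk
        surv[i] = s
    return timeline, surv


def log_rank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Standard observed-vs-expected form with the hypergeometric variance at
    each distinct event time; the statistic is chi-square with 1 df.  No
    events at all leaves the test undefined (NaN, NaN).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank implemented for exactly two groups")
    if not e.any():
        return float("nan"), float("nan")
    is1 = g == labels[0]
    obs1 = 0.0
    exp1 = 0.0
    var = 0.0
    for ti in np.unique(t[e]):
        at_risk = np.sum(t >= ti)
        n1 = np.sum((t >= ti) & is1)
        d = np.sum((t == ti) & e)
        d1 = np.sum((t == ti) & e & is1)
        obs1 += d1
        exp1 += d * n1 / at_risk
        if at_risk > 1:
            var += d * (n1 / at_risk) * (1 - n1 / at_risk) * (at_risk - d) / (at_risk - 1)
    if var == 0:
        return float("nan"), float("nan")
    chi2 = (obs1 - exp1) ** 2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def stratified_remission_rates(
    values, is_responder, bins
) -> pd.DataFrame:
    """Remission proportion per stratum of a continuous variable.

    Bins follow the half-open ``[lo, hi)`` convention; each row carries the
    stratum n, the responder proportion and its 95% Wilson score interval.
    Empty bins are reported with n = 0.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(is_responder, dtype=bool)
    edges = np.asarray(sorted(bins), dtype=float)
    if v.size and (v.min() < edges[0] or v.max() >= edges[-1]):
        raise ValueError("bins must cover the observed range")
    rows = []
    idx = np.digitize(v, edges, right=False) - 1
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        k = int(r[mask].sum())
        if n > 0:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            prop = k / n
        else:
            prop, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": n,
                "n_responders": k,
                "proportion": prop,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def impute_missing(
    table: pd.DataFrame,
    variables: list[str],
    m: int = 5,
    seed: int = 0,
    n_burn: int = 5,
) -> list[pd.DataFrame]:
    """Chained-equation multiple imputation of the given variables.

    Uses all numeric columns of ``table`` as predictors (MICE with
    predictive mean matching as implemented in statsmodels); returns ``m``
    completed copies of the full table.  Deterministic for a given seed.  A
    table with no missing values is returned unchanged (m identical copies).
    """
    missing_frac = table[variables].isna().mean()
    if (missing_frac >= 0.5).any():
        bad = missing_frac[missing_frac >= 0.5].index.tolist()
        raise ValueError(f"more than 50% missing for {bad}")
    numeric = table.select_dtypes(include=[np.number]).copy()
    for v in variables:
        if v not in numeric.columns:
            raise ValueError(f"variable {v} not numeric or absent")
    if not numeric[variables].isna().any().any():
        return [table.copy() for _ in range(m)]
    rng_state = np.random.get_state()
    np.random.seed(seed % (2**31))
    try:
        mdata = MICEData(numeric)
        completed = []
        mdata.update_all(n_burn)
        for _ in range(m):
            mdata.update_all(1)
            filled = table.copy()
            for v in variables:
                filled[v] = mdata.data[v].to_numpy()
            completed.append(filled)
    finally:
        np.random.set_state(rng_state)
    return completed


def pool_rubin(estimates, variances) -> dict:
    """Rubin's rules for combining per-imputation estimates."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    se = math.sqrt(total)
    z = sps.norm.ppf(0.975)
    return {
        "estimate": float(qbar),
        "se": se,
        "ci_low": float(qbar - z * se),
        "ci_high": float(qbar + z * se),
        "m": int(m),
    }
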