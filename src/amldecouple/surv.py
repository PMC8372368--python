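"""Survival analysis: Kaplan-Meier estimation, log-rank testing, and Cox
proportional-hazards modelling with the univariate-screen -> multivariable
workflow.

Times are in weeks throughout.  Cox models use lifelines' partial-likelihood
fitter (Efron tie handling); cluster indicators are coded against cluster 1
as the reference.  The median survival is the smallest time at which the
survival function drops to 0.5 or below, and is reported as undefined (NaN)
when the curve never reaches it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

log = logging.getLogger(__name__)

__all__ = [
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "cluster_outcome_model",
    "KaplanMeierCurve",
    "CoxFit",
]


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: step table plus the median survival time."""

    table: pd.DataFrame  # time, survival, at_risk, events
    median: float  # NaN when S never reaches 0.5


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator for one group of observations."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size == 0:
        raise ValueError("need >= 1 observation")
    if (time < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_.iloc[:, 0]
    table = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(),
            "at_risk": kmf.event_table["at_risk"].to_numpy(),
            "events": kmf.event_table["observed"].to_numpy(),
        }
    )
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return KaplanMeierCurve(table, median)


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """Unweighted K-group log-rank test; returns (chi-square, df, p)."""
    groups = pd.Series(groups)
    levels = groups.dropna().unique()
    if len(levels) < 2:
        raise ValueError("need >= 2 groups for the log-rank test")
    res = multivariate_logrank_test(np.asarray(time, dtype=float), groups,
                                    np.asarray(event, dtype=float))
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary.

    ``summary`` has one row per covariate: coefficient (log hazard ratio),
    hr, se, p (Wald).  Ties handled with the Efron approximation.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"


def _fit_cox(frame: pd.DataFrame) -> CoxFit:
    n_events = int(frame["event"].sum())
    n_covariates = frame.shape[1] - 2
    if n_events < n_covariates:
        warnings.warn(
            f"{n_events} events for {n_covariates} covariates; estimates may "
            "be unstable"
        )
    constant = [c for c in frame.columns
                if c not in ("time", "event") and frame[c].nunique() == 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox fit failed (possible separation or collinearity): {err}")
    summary = pd.DataFrame(
        {
            "coefficient": cph.params_,
            "hr": np.exp(cph.params_),
            "se": cph.standard_errors_,
            "p": cph.summary["p"],
        }
    )
    return CoxFit(summary, float(cph.log_likelihood_), int(frame.shape[0]), n_events)


def cox_fit(time, event, covariates: pd.DataFrame) -> CoxFit:
    """Cox model of (time, event) on a numeric covariate frame.

    Categorical columns are dummy-coded against their first level.  Rows
    with missing values are excluded listwise.
    """
    covariates = pd.get_dummies(covariates, drop_first=True, dtype=float)
    frame = covariates.copy()
    frame["time"] = np.asarray(time, dtype=float)
    frame["event"] = np.asarray(event, dtype=float)
    frame = frame.dropna()
    return _fit_cox(frame)


def univariate_screen(
    clinical: pd.DataFrame,
    time_col: str,
    event_col: str,
    variables: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox screen: fit each variable alone against the endpoint
    and keep those with Wald p < alpha (minimum over dummy levels for
    categoricals).  Variables whose fit fails are skipped with a warning."""
    rows = []
    for var in variables:
        sub = clinical[[time_col, event_col, var]].dropna()
        try:
            fit = cox_fit(sub[time_col], sub[event_col], sub[[var]])
        except ValueError as err:
            warnings.warn(f"univariate Cox failed for {var!r}: {err}")
            continue
        p = float(fit.summary["p"].min())
        rows.append({"variable": var, "p": p, "selected": p < alpha})
    report = pd.DataFrame(rows)
    if len(report):
        log.info("univariate screen selected: %s",
                 report.loc[report["selected"], "variable"].tolist())
    return report


def cluster_outcome_model(
    labels: pd.Series,
    clinical: pd.DataFrame,
    time_col: str,
    event_col: str,
    adjust_for: list[str] | None = None,
) -> CoxFit:
    """Multivariable Cox model of the endpoint on cluster membership
    (indicator covariates ``cluster_k`` against cluster 1 as reference)
    plus any screened adjustment variables."""
    labels = labels[labels > 0]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    shared = [s for s in labels.index if s in clinical.index]
    frame = clinical.loc[shared, [time_col, event_col] + list(adjust_for or [])].copy()
    for k in clusters[1:]:
        frame[f"cluster_{k}"] = (labels.loc[shared] == k).astype(float)
    frame = frame.dropna()
    return cox_fit(frame[time_col], frame[event_col],
                   frame.drop(columns=[time_col, event_col]))
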