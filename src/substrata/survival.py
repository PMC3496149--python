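"""Kaplan-Meier / log-rank and Cox proportional-hazards stages.

Outcome analyses use distant metastasis-free survival (DMFS) with an
optional follow-up horizon: events after the horizon are censored at the
horizon before fitting (the five-year analyses use ``horizon=5``).  Cox
models use Efron tie handling and encode categorical covariates against
fixed reference levels (T2 vs T1, N+ vs N0, NHG 3 vs 1-2, marker negative
vs positive), so a hazard ratio > 1 for ``nat1`` reads "negative tumors
do worse".  Records with NA in any requested covariate are dropped
per-analysis (complete-case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ClinicalTable

logger = logging.getLogger("substrata")

__all__ = ["KMFit", "CoxFit", "km_logrank", "cox_fit", "COVARIATE_CODINGS"]


#: covariate -> (indicator name, coding function); indicator is 1 for the
#: "risk" level printed in multivariate tables
COVARIATE_CODINGS = {
    "tumor_size": ("tumor_size_T2", lambda s: (s == "T2").astype(float)),
    "node_status": ("node_status_Npos", lambda s: (s == "N+").astype(float)),
    "nhg": ("nhg_3", lambda s: (s == "3").astype(float)),
    "er": ("er_neg", lambda s: (s == "neg").astype(float)),
    "pr": ("pr_neg", lambda s: (s == "neg").astype(float)),
    "her2": ("her2_neg", lambda s: (s == "neg").astype(float)),
    "nat1": ("nat1_neg", lambda s: (s == "neg").astype(float)),
    "hla": ("hla_neg", lambda s: (s != "pos").astype(float)),
}


@dataclass
class KMFit:
    """Per-group product-limit estimates plus the log-rank comparison."""

    tables: dict[str, pd.DataFrame]  # group -> (time, at_risk, events, survival)
    logrank_statistic: float
    logrank_p: float
    horizon: float | None

    def at_risk_at(self, times) -> pd.DataFrame:
        """Number at risk per group at each requested time point."""
        out = {}
        for g, tab in self.tables.items():
            risk = []
            for t in times:
                rows = tab[tab["time"] <= t]
                if rows.empty:
                    risk.append(int(tab["at_risk"].iloc[0]) if len(tab) else 0)
                else:
                    last = rows.iloc[-1]
                    risk.append(int(last["at_risk"] - last["events"] - last["censored"]))
            out[g] = risk
        return pd.DataFrame(out, index=list(times)).T

    def survival_at(self, group: str, t: float) -> float:
        tab = self.tables[group]
        rows = tab[(tab["time"] <= t) & (tab["events"] > 0)]
        return float(rows["survival"].iloc[-1]) if len(rows) else 1.0


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: coef, hr, ci_lower, ci_upper, p
    ties_method: str
    horizon: float | None
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _apply_horizon(time: pd.Series, event: pd.Series, horizon: float | None):
    if horizon is None:
        return time, event
    capped = time.clip(upper=horizon)
    ev = event.where(time <= horizon, 0)
    return capped, ev


def km_logrank(clinical: ClinicalTable, groups, horizon: float | None = None) -> KMFit:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    ``groups`` is a per-sample label series (aligned on sample id); NA
    labels and records without follow-up data are dropped.
    """
    groups = pd.Series(groups)
    df = clinical.data[["dmfs_time", "dmfs_event"]].join(groups.rename("group"), how="inner")
    df = df.dropna()
    if df["group"].nunique() < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    time, event = _apply_horizon(df["dmfs_time"], df["dmfs_event"].astype(int), horizon)
    for g, sub in df.groupby("group"):
        if (time[sub.index] <= 0).all():
            raise ValueError(f"group {g!r} has no positive follow-up time")

    tables = {}
    for g, sub in df.groupby("group", sort=True):
        t, e = time[sub.index], event[sub.index]
        kmf = KaplanMeierFitter().fit(t, e, label=str(g))
        ev = kmf.event_table
        surv = kmf.survival_function_[str(g)]
        tables[str(g)] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(float),
                "at_risk": ev["at_risk"].to_numpy(int),
                "events": ev["observed"].to_numpy(int),
                "censored": ev["censored"].to_numpy(int),
                "survival": surv.reindex(ev.index).to_numpy(float),
            }
        ).reset_index(drop=True)

    lr = multivariate_logrank_test(time, df["group"], event)
    return KMFit(tables, float(lr.test_statistic), float(lr.p_value), horizon)


def cox_fit(
    clinical: ClinicalTable,
    covariates: list[str],
    horizon: float | None = 5.0,
    extra: pd.DataFrame | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit on DMFS with Efron tie handling.

    ``covariates`` may name clinical columns (coded per
    :data:`COVARIATE_CODINGS`, numeric columns used as-is) or columns of
    ``extra`` (e.g. subgroup indicators).  Complete-case per analysis.
    """
    base = clinical.data
    frames = {"dmfs_time": base["dmfs_time"], "dmfs_event": base["dmfs_event"]}
    for cov in covariates:
        source = None
        if cov in base.columns:
            source = base[cov]
        elif extra is not None and cov in extra.columns:
            source = extra[cov].reindex(base.index)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
        if cov in COVARIATE_CODINGS and not pd.api.types.is_numeric_dtype(source):
            name, coder = COVARIATE_CODINGS[cov]
            coded = coder(source.astype("string"))
            coded[source.isna()] = np.nan
            frames[name] = coded
        else:
            frames[cov] = pd.to_numeric(source, errors="coerce")
    df = pd.DataFrame(frames).dropna()
    n_cov = len(covariates)
    if len(df) < 10 * n_cov:
        logger.warning("only %d complete cases for %d covariate(s)", len(df), n_cov)
    time, event = _apply_horizon(df["dmfs_time"], df["dmfs_event"].astype(int), horizon)
    fit_df = df.drop(columns=["dmfs_time", "dmfs_event"]).assign(T=time, E=event)

    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="T", event_col="E")  # lifelines uses Efron ties
    except Exception as exc:  # convergence / separation problems surface clearly
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(summary, "efron", horizon, n=len(fit_df), n_events=int(fit_df["E"].sum()))
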