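"""Marker-based patient subgrouping and the survival battery.

Patients are split two ways from margin-0 expression calls: two groups by the
marker gene alone (low vs high), or three groups by the marker x VIM call
combination — marker-low/VIM-high, marker-high/VIM-high, marker-high/VIM-low
— with the rare marker-low/VIM-low patients collected as OTHER (that quadrant
is sparse by the implication that selected the marker).

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards fits
(Efron tie handling) are delegated to lifelines behind this module's surface.
5-year rates are read at 60 months. The marker x chemotherapy 2x2 factorial
analysis reports both a multiplicative interaction (Wald p on the Cox product
term) and an additive one (RERI = HR11 - HR10 - HR01 + 1 with a delta-method
95% CI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .stepminer import HIGH, LOW

logger = logging.getLogger("boolmark")

TWO_GROUP = ("marker_low", "marker_high")
THREE_GROUP = ("marker_low_vim_high", "marker_high_vim_high", "marker_high_vim_low", "OTHER")

FIVE_YEARS_MONTHS = 60.0


@dataclass
class SurvivalCurve:
    """Product-limit estimate: event-time grid, S(t), at-risk counts and
    censoring times."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


@dataclass
class InteractionResult:
    multiplicative_coef: float
    multiplicative_p: float
    hr10: float
    hr01: float
    hr11: float
    reri: float
    reri_ci: tuple[float, float]


def assign_marker_groups(
    calls_marker: pd.Series, calls_vim: pd.Series | None = None, mode: str = "two"
) -> pd.Series:
    """Label each patient from margin-0 marker (and VIM) calls.

    ``mode='two'`` uses the marker call alone; ``mode='three'`` crosses it
    with VIM, labelling marker-low/VIM-low patients OTHER. Patients with a
    missing or intermediate call are excluded (logged).
    """
    if mode not in ("two", "three"):
        raise ValueError("mode must be 'two' or 'three'")
    marker = calls_marker.astype(int)
    usable = marker.isin([LOW, HIGH])
    if mode == "two":
        labels = pd.Series(
            np.where(marker == LOW, TWO_GROUP[0], TWO_GROUP[1]), index=marker.index, dtype=object
        )
    else:
        if calls_vim is None:
            raise ValueError("three-group mode requires VIM calls")
        vim = calls_vim.astype(int).reindex(marker.index)
        usable &= vim.isin([LOW, HIGH])
        labels = pd.Series("OTHER", index=marker.index, dtype=object)
        labels[(marker == LOW) & (vim == HIGH)] = THREE_GROUP[0]
        labels[(marker == HIGH) & (vim == HIGH)] = THREE_GROUP[1]
        labels[(marker == HIGH) & (vim == LOW)] = THREE_GROUP[2]
        n_other = int(((marker == LOW) & (vim == LOW) & usable).sum())
        if n_other:
            logger.info("assign_marker_groups: %d marker-low/VIM-low patient(s) -> OTHER", n_other)
    excluded = int((~usable).sum())
    if excluded:
        logger.info("assign_marker_groups: %d patient(s) excluded (missing/intermediate call)",
                    excluded)
    return labels.where(usable)


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("times must be strictly positive")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    return SurvivalCurve(
        timeline=timeline,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(t[e == 0]),
    )


def survival_at(curve: SurvivalCurve, t_months: float) -> float:
    """S(t) of the step-function estimate (right-continuous): the value at the
    largest curve time <= t."""
    idx = np.searchsorted(curve.timeline, t_months, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def five_year_rate(times: np.ndarray, events: np.ndarray) -> float:
    return survival_at(km_estimate(times, events), FIVE_YEARS_MONTHS)


def logrank_test(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Log-rank chi-square ((G-1) df) and two-sided p across >= 2 groups."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    uniq, counts = np.unique(g, return_counts=True)
    if uniq.size < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    if (counts == 0).any():
        raise ValueError("every group must contain at least one subject")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
) -> tuple[pd.DataFrame, float]:
    """Multivariate Cox PH fit with Wald CIs and p-values per covariate.

    ``covariates`` are numeric columns in ``data`` (indicators / ordinal
    codes); rows with a missing covariate, duration or event are dropped
    (complete-case, logged). Returns (per-covariate table with hazard ratios
    and 95% CI, model log-likelihood).
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    cols = [duration_col, event_col] + list(covariates)
    df = data[cols].apply(pd.to_numeric, errors="coerce")
    complete = df.dropna()
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("cox_fit: dropped %d row(s) with missing values (complete-case)", dropped)
    if complete[event_col].sum() < 1:
        raise ValueError("no events in the data")
    cph = CoxPHFitter()
    cph.fit(complete, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    out = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "coef": summary["coef"],
            "se": summary["se(coef)"],
            "p_value": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out, float(cph.log_likelihood_)


def encode_clinical_covariates(clinical: pd.DataFrame, marker_low: pd.Series) -> pd.DataFrame:
    """Standard covariate encodings for the Cox models.

    marker_low: 1 = marker-low group; age60: 1 = age >= 60; sex_male: 1 = M;
    stage_ordinal: I/II/III -> 1/2/3 ("per increase in stage");
    chemo_yes: 1 = yes, 0 = no, NaN = missing (complete-case excluded);
    grade_poor: 1 = poorly differentiated vs others;
    location_colon: 1 = colon vs rectum.
    """
    df = pd.DataFrame(index=clinical.index)
    df["marker_low"] = marker_low.reindex(clinical.index).astype(float)
    df["age60"] = (pd.to_numeric(clinical["age"], errors="coerce") >= 60).astype(float)
    df["sex_male"] = clinical["sex"].map({"M": 1.0, "F": 0.0})
    df["stage_ordinal"] = clinical["stage"].map({"I": 1.0, "II": 2.0, "III": 3.0})
    df["chemo_yes"] = clinical["chemo"].map({"yes": 1.0, "no": 0.0})
    if "grade" in clinical.columns:
        df["grade_poor"] = clinical["grade"].map(
            {"poor": 1.0, "moderate": 0.0, "well": 0.0}
        )
    if "location" in clinical.columns:
        df["location_colon"] = clinical["location"].map({"colon": 1.0, "rectum": 0.0})
    return df


def chemo_interaction(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    marker_col: str,
    chemo_col: str,
) -> InteractionResult:
    """Marker x chemotherapy 2x2 factorial interaction on the hazard scale.

    Multiplicative: Cox with both main effects and their product; the Wald p
    of the product term tests departure from hazard multiplicativity.
    Additive: Cox on joint-cell indicators (reference marker-0/chemo-0);
    RERI = HR11 - HR10 - HR01 + 1 with a delta-method 95% CI. Rows with a
    missing chemo value are excluded beforehand by the caller; all four
    marker x chemo cells must be non-empty.
    """
    df = data[[duration_col, event_col, marker_col, chemo_col]].dropna().copy()
    m = df[marker_col].astype(int)
    c = df[chemo_col].astype(int)
    for mv in (0, 1):
        for cv in (0, 1):
            if ((m == mv) & (c == cv)).sum() == 0:
                raise ValueError(f"empty marker={mv}, chemo={cv} cell in the 2x2 factorial")

    # multiplicative scale
    mult = pd.DataFrame(
        {
            duration_col: df[duration_col].astype(float),
            event_col: df[event_col].astype(int),
            "marker": m,
            "chemo": c,
            "product": m * c,
        }
    )
    cph = CoxPHFitter()
    cph.fit(mult, duration_col=duration_col, event_col=event_col)
    mult_coef = float(cph.summary.loc["product", "coef"])
    mult_p = float(cph.summary.loc["product", "p"])

    # additive scale via joint indicators
    joint = pd.DataFrame(
        {
            duration_col: df[duration_col].astype(float),
            event_col: df[event_col].astype(int),
            "i10": ((m == 1) & (c == 0)).astype(int),
            "i01": ((m == 0) & (c == 1)).astype(int),
            "i11": ((m == 1) & (c == 1)).astype(int),
        }
    )
    cph2 = CoxPHFitter()
    cph2.fit(joint, duration_col=duration_col, event_col=event_col)
    beta = cph2.params_[["i10", "i01", "i11"]].to_numpy()
    cov = cph2.variance_matrix_.loc[["i10", "i01", "i11"], ["i10", "i01", "i11"]].to_numpy()
    hr10, hr01, hr11 = np.exp(beta)
    reri = hr11 - hr10 - hr01 + 1.0
    grad = np.array([-hr10, -hr01, hr11])
    se = float(np.sqrt(grad @ cov @ grad))
    ci = (reri - 1.959963984540054 * se, reri + 1.959963984540054 * se)
    return InteractionResult(
        multiplicative_coef=mult_coef,
        multiplicative_p=mult_p,
        hr10=float(hr10),
        hr01=float(hr01),
        hr11=float(hr11),
        reri=float(reri),
        reri_ci=ci,
    )


def stage_subset_analysis(
    clinical: pd.DataFrame,
    groups: pd.Series,
    stages: set[str],
    duration_col: str = "dfs_months",
    event_col: str = "dfs_event",
) -> dict:
    """Restrict to the chosen stages and rerun KM + log-rank.

    Returns per-group 5-year rates and the log-rank (chi2, p) on the subset.
    """
    if not stages:
        raise ValueError("stage subset must be non-empty")
    bad = stages - {"I", "II", "III"}
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    sel = clinical["stage"].isin(stages) & groups.reindex(clinical.index).notna()
    sub = clinical.loc[sel]
    if sub.empty:
        raise ValueError("no patients in the requested stage subset")
    g = groups.reindex(sub.index)
    times = pd.to_numeric(sub[duration_col]).to_numpy(dtype=float)
    events = pd.to_numeric(sub[event_col]).to_numpy(dtype=int)
    chi2, p = logrank_test(times, events, g.to_numpy())
    rates = {
        label: five_year_rate(times[g.to_numpy() == label], events[g.to_numpy() == label])
        for label in pd.unique(g)
    }
    return {"stages": sorted(stages), "n": int(len(sub)), "five_year_rates": rates,
            "logrank_chi2": chi2, "logrank_p": p}
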