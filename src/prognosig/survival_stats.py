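"""Survival evaluation: Kaplan-Meier + log-rank, group Cox models,
backward-Wald multivariate elimination, and the two-group association tests
(Welch / paired t, Yates-corrected chi-square).

Model fitting is delegated to lifelines (Efron tie handling, the same
convention as the per-gene screen); this module adds the group plumbing,
the stepwise-elimination loop and report structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .errors import ConfigError, DegenerateError, EmptyCohortError
from .types import GroupAssignment, SurvivalTable

DEFAULT_REMOVAL_ALPHA = 0.10
DEFAULT_PRESCREEN_ALPHA = 0.05


@dataclass
class KMCurve:
    """Product-limit estimates per group: step-function tables plus at-risk counts."""

    curves: dict[str, pd.DataFrame]  # per group: columns time, survival, at_risk
    group_sizes: dict[str, int]

    @property
    def group_labels(self) -> list[str]:
        return list(self.curves)

    def median_survival(self, group: str) -> float:
        df = self.curves[group]
        below = df[df["survival"] <= 0.5]
        return float(below["time"].iloc[0]) if len(below) else float("inf")


@dataclass
class CoxModelReport:
    """Cox fit summary (per covariate: HR, 95% CI, Wald p) plus step history."""

    summary: pd.DataFrame
    n: int
    n_events: int
    steps: list[list[str]] = field(default_factory=list)
    step_summaries: list[pd.DataFrame] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


class TestResult(NamedTuple):
    statistic: float
    p: float
    degenerate: bool = False


def _aligned_groups(groups: GroupAssignment, survival: SurvivalTable
                    ) -> tuple[pd.Series, SurvivalTable]:
    common = [s for s in groups.sample_ids if s in set(survival.sample_ids)]
    if not common:
        raise EmptyCohortError("no overlap between group assignment and survival table")
    return groups.groups.loc[common], survival.subset(common)


def _fit_cph(df: pd.DataFrame) -> tuple[CoxPHFitter, list[str]]:
    cph = CoxPHFitter()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
    for w in rec:
        caught.append(str(w.message))
    return cph, caught


def _cph_summary(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


def km_logrank(
    groups: GroupAssignment, survival: SurvivalTable
) -> tuple[KMCurve, float, float]:
    """Kaplan-Meier estimates per group and the two-sided log-rank test."""
    labels, surv = _aligned_groups(groups, survival)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise DegenerateError(f"need >= 2 non-empty groups, got {uniq}")
    if surv.n_events < 1:
        raise DegenerateError("no events observed in any group")

    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for label in uniq:
        ids = labels.index[labels == label]
        sub = surv.subset(list(ids))
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, sub.event, label=str(label))
        tab = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
        tab["at_risk"] = [
            int((sub.time >= t).sum()) for t in tab["time"]
        ]
        curves[str(label)] = tab
        sizes[str(label)] = sub.n_samples

    if len(uniq) == 2:
        a = labels == uniq[0]
        res = logrank_test(
            surv.time[a.to_numpy()], surv.time[~a.to_numpy()],
            event_observed_A=surv.event[a.to_numpy()],
            event_observed_B=surv.event[~a.to_numpy()],
        )
    else:
        res = multivariate_logrank_test(surv.time, labels.to_numpy(), surv.event)
    return KMCurve(curves=curves, group_sizes=sizes), float(res.test_statistic), float(res.p_value)


def cox_univariate_group(
    groups: GroupAssignment, survival: SurvivalTable
) -> CoxModelReport:
    """Cox fit of survival on the binary high-vs-low indicator (low = reference)."""
    labels, surv = _aligned_groups(groups, survival)
    indicator = (labels == "high").astype(int)
    if indicator.nunique() < 2:
        raise DegenerateError("both groups must be non-empty")
    df = pd.DataFrame(
        {"time": surv.time, "event": surv.event, "high": indicator.to_numpy()},
        index=surv.sample_ids,
    )
    events_per_group = df.groupby("high")["event"].sum()
    notes: list[str] = []
    if (events_per_group == 0).any():
        notes.append("monotone likelihood: a group has zero events; CI unreliable")
    cph, caught = _fit_cph(df)
    report = CoxModelReport(
        summary=_cph_summary(cph),
        n=surv.n_samples,
        n_events=surv.n_events,
        steps=[["high"]],
        warnings=notes + caught,
    )
    return report


def cox_backward_wald(
    covariates: pd.DataFrame,
    survival: SurvivalTable,
    removal_alpha: float = DEFAULT_REMOVAL_ALPHA,
) -> CoxModelReport:
    """Backward stepwise Cox: repeatedly drop the covariate with the largest
    Wald p >= ``removal_alpha`` and refit, recording every step.

    Categorical covariates must arrive pre-encoded as numeric columns.
    """
    if covariates.shape[1] < 1:
        raise ConfigError("need at least one covariate")
    common = [s for s in covariates.index if s in set(survival.sample_ids)]
    if not common:
        raise EmptyCohortError("no overlap between covariates and survival table")
    surv = survival.subset(common)
    X = covariates.loc[common].astype(float)

    remaining = list(X.columns)
    steps: list[list[str]] = []
    step_summaries: list[pd.DataFrame] = []
    notes: list[str] = []
    summary = None
    while remaining:
        df = pd.DataFrame({"time": surv.time, "event": surv.event}, index=common)
        df[remaining] = X[remaining]
        try:
            cph, caught = _fit_cph(df)
        except Exception as exc:  # report truncated with context
            notes.append(f"fit failed with covariates {remaining}: {exc}")
            break
        notes.extend(caught)
        summary = _cph_summary(cph)
        steps.append(list(remaining))
        step_summaries.append(summary)
        worst = summary["p"].idxmax()
        if summary.loc[worst, "p"] >= removal_alpha and len(remaining) > 1:
            remaining.remove(worst)
        elif summary.loc[worst, "p"] >= removal_alpha:
            # last covariate also non-significant: drop it and stop with an empty model
            notes.append(f"final covariate {worst!r} removed (p >= {removal_alpha})")
            remaining.remove(worst)
            break
        else:
            break
    if summary is None:
        raise DegenerateError("backward elimination could not fit any model; " + "; ".join(notes))
    return CoxModelReport(
        summary=step_summaries[-1] if remaining else summary,
        n=surv.n_samples,
        n_events=surv.n_events,
        steps=steps,
        step_summaries=step_summaries,
        warnings=notes,
    )


def univariate_prescreen(
    covariates: pd.DataFrame,
    survival: SurvivalTable,
    alpha: float = DEFAULT_PRESCREEN_ALPHA,
) -> list[str]:
    """Covariates univariately associated with survival at p < alpha
    (the conventional gate before a multivariate backward elimination)."""
    keep = []
    for col in covariates.columns:
        report = cox_backward_wald(covariates[[col]], survival, removal_alpha=1.1)
        if report.p(col) < alpha:
            keep.append(col)
    return keep


def two_group_tests(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> TestResult:
    """Welch two-sided t-test (unpaired) or paired t-test."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigError("each group needs at least 2 observations")
    if paired:
        if len(x) != len(y):
            raise ConfigError("paired test requires equal-length groups")
        if np.std(x - y) == 0:
            return TestResult(float("nan"), float("nan"), degenerate=True)
        t, p = stats.ttest_rel(x, y)
    else:
        if np.std(x) == 0 and np.std(y) == 0:
            if np.mean(x) == np.mean(y):
                return TestResult(0.0, 1.0, degenerate=True)
            return TestResult(float("inf"), 0.0, degenerate=True)
        t, p = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p))


def chisq_yates(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square on a 2x2 count table (df = 1)."""
    from scipy import stats

    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ConfigError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ConfigError("table must hold non-negative integer counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateError("chi-square undefined: a row or column margin is zero")
    res = stats.chi2_contingency(arr, correction=True)
    return float(res.statistic), float(res.pvalue)


def write_km_curves(km: KMCurve, path, delimiter: str = "\t") -> None:
    frames = []
    for label, tab in km.curves.items():
        t = tab.copy()
        t.insert(0, "group", label)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False)
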