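"""Group comparisons: fold changes, ratio uncertainty, ANOVA, survival.

The ratio-with-uncertainty operation implements the first-order delta
method for a ratio of two independent means:

    r = a / b,   sd(r) = r * sqrt((sd_a/a)^2 + (sd_b/b)^2)

which is how tumor-to-kidney cumulated-activity ratios with +/- bands
are derived from cohort-level mean +/- SD (per-animal AUCs do not exist
in cross-sectional biodistribution designs).

Kaplan-Meier estimation and the Mantel-Cox log-rank test are delegated
to ``lifelines``; Dunnett many-to-one comparisons use the multivariate-t
distribution via ``scipy.stats.dunnett``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .io import SurvivalRecord


# ---------------------------------------------------------------- ratios


def fold_change(a: float, b: float) -> dict:
    """Fold difference between two positive values, larger over smaller.

    Returns the raw ratio, the direction (``"increase"`` if a > b), and
    a rounded headline value: nearest integer for folds >= 2, one
    decimal below (so 23.25 -> 23, 1.599 -> 1.6).
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"fold change requires positive inputs, got {a}, {b}")
    raw = max(a, b) / min(a, b)
    headline = float(round(raw)) if raw >= 2 else round(raw, 1)
    return dict(
        raw=raw,
        fold=headline,
        direction="increase" if a > b else ("decrease" if b > a else "equal"),
    )


@dataclass
class RatioResult:
    """Ratio of two means with delta-method SD."""

    ratio: float
    sd: float
    numerator: str = ""
    denominator: str = ""


def ratio_with_uncertainty(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    numerator: str = "",
    denominator: str = "",
) -> RatioResult:
    """Delta-method ratio of independent means (see module docstring)."""
    if not (mean_a > 0 and mean_b > 0):
        raise ValueError("both means must be positive")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be >= 0")
    r = mean_a / mean_b
    sd = r * np.sqrt((sd_a / mean_a) ** 2 + (sd_b / mean_b) ** 2)
    return RatioResult(ratio=r, sd=float(sd), numerator=numerator, denominator=denominator)


# ----------------------------------------------------------------- ANOVA


@dataclass
class AnovaResult:
    """One-way ANOVA with multiplicity-adjusted comparisons.

    ``comparisons`` has columns ``group, vs, estimate, p_adj``;
    ``exact_separation`` flags the degenerate zero-within-variance case
    where p-values are not meaningful.
    """

    f_statistic: float
    p_overall: float
    comparisons: pd.DataFrame
    adjust: str
    exact_separation: bool = False


def anova_multi(
    groups: Mapping[str, Sequence[float]],
    adjust: Literal["dunnett", "sidak"],
    control: str | None = None,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Dunnett or Sidak adjustment.

    Dunnett compares every group against ``control`` using the
    many-to-one multivariate-t distribution; Sidak adjusts all pairwise
    pooled-variance t-tests as p_adj = 1 - (1 - p)^m.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")

    n = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_error = int(n.sum() - len(arrays))
    mse = ss_within / df_error

    if mse == 0:
        # Degenerate: no within-group variance.  Identical means are a
        # trivially null result; distinct means are exact separation.
        equal = np.allclose(means, means[0])
        rows = _degenerate_comparisons(labels, means, adjust, control, equal)
        return AnovaResult(
            f_statistic=0.0 if equal else np.inf,
            p_overall=1.0 if equal else 0.0,
            comparisons=pd.DataFrame(rows),
            adjust=adjust,
            exact_separation=not equal,
        )

    f_stat, p_overall = sps.f_oneway(*arrays)

    if adjust == "dunnett":
        if control is None:
            raise ValueError("Dunnett adjustment requires a control group label")
        if control not in labels:
            raise KeyError(f"control group {control!r} not among {labels}")
        ci = labels.index(control)
        treat_labels = [k for k in labels if k != control]
        treat_arrays = [arrays[labels.index(k)] for k in treat_labels]
        res = sps.dunnett(*treat_arrays, control=arrays[ci])
        rows = [
            dict(
                group=k,
                vs=control,
                estimate=float(np.mean(groups[k]) - means[ci]),
                p_adj=float(p),
            )
            for k, p in zip(treat_labels, res.pvalue)
        ]
    elif adjust == "sidak":
        pairs = [
            (i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))
        ]
        m = len(pairs)
        rows = []
        for i, j in pairs:
            se = np.sqrt(mse * (1.0 / n[i] + 1.0 / n[j]))
            tval = (means[i] - means[j]) / se
            p = 2.0 * sps.t.sf(abs(tval), df_error)
            rows.append(
                dict(
                    group=labels[i],
                    vs=labels[j],
                    estimate=float(means[i] - means[j]),
                    p_adj=float(min(1.0, 1.0 - (1.0 - p) ** m)),
                )
            )
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return AnovaResult(
        f_statistic=float(f_stat),
        p_overall=float(p_overall),
        comparisons=pd.DataFrame(rows),
        adjust=adjust,
    )


def _degenerate_comparisons(labels, means, adjust, control, equal):
    if adjust == "dunnett":
        if control is None or control not in labels:
            raise ValueError("Dunnett adjustment requires a valid control label")
        ci = labels.index(control)
        pairs = [(labels.index(k), ci) for k in labels if k != control]
    else:
        pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    return [
        dict(
            group=labels[i],
            vs=labels[j],
            estimate=float(means[i] - means[j]),
            p_adj=1.0 if (equal or means[i] == means[j]) else 0.0,
        )
        for i, j in pairs
    ]


def two_way_anova(df: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA table with interaction.

    Thin wrapper over ``statsmodels`` OLS; returns the classic
    sum-of-squares table (type II).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols(
        f"{response} ~ C({factor_a}) * C({factor_b})", data=df
    ).fit()
    return sm.stats.anova_lm(model, typ=2)


# -------------------------------------------------------------- survival


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group.

    ``median_d`` is the smallest time with S(t) <= 0.5, NaN when the
    curve never drops to 0.5 (e.g. heavy censoring).
    """

    group: str
    times_d: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_d: float

    def probability_at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        idx = np.searchsorted(self.times_d, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(records: Sequence[SurvivalRecord], group: str | None = None) -> KMCurve:
    """Kaplan-Meier product-limit fit for one group of records."""
    if group is not None:
        records = [r for r in records if r.group == group]
    if not records:
        raise ValueError("no records to fit")
    label = group if group is not None else records[0].group
    t = np.array([r.time_d for r in records])
    e = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e, label=label)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_[label].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
    median = kmf.median_survival_time_
    return KMCurve(
        group=label,
        times_d=times,
        survival=surv,
        at_risk=at_risk,
        median_d=float(median) if np.isfinite(median) else np.nan,
    )


def logrank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> dict:
    """Mantel-Cox log-rank test between two groups.

    Returns the 1-df chi-square statistic and p-value.  Raises if
    either group is empty or no event was observed at all (the test is
    undefined without events).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta = np.array([r.time_d for r in group_a])
    ea = np.array([r.event for r in group_a])
    tb = np.array([r.time_d for r in group_b])
    eb = np.array([r.event for r in group_b])
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined with zero observed events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return dict(chi2=float(res.test_statistic), p=float(res.p_value))
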