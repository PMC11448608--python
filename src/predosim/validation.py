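"""Validation studies: worked examples, calibration checks, power/type-I.

These routines recompute, from scratch, the quantities the package is
expected to reproduce: the published worked-example chain (therapeutic
indices, fold changes and ratio uncertainties from reference dosimetry
numbers), the local-deposition dose reconstruction, the simulator's
lag-time behavior under the default calibration, one-step parameter
recovery, and the type-I error of the log-rank test under the null.
They are shared by the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .dose import local_deposition_dose, therapeutic_index
from .io import SurvivalRecord
from .nuclides import LU177
from .pipeline import REFERENCE_CUMULATED, REFERENCE_MADS
from .pksim import (
    DEFAULT_PRETARGET_PARAMS,
    NoiseModel,
    fit_params,
    simulate_conventional,
    sweep,
)
from .stats import fold_change, logrank, ratio_with_uncertainty
from .tac import CumulatedActivity


def _mad(arm: str, organ: str) -> float:
    for row in REFERENCE_MADS:
        if row["arm"] == arm and row["organ"] == organ:
            return row["mad_cGy_per_MBq"]
    raise KeyError((arm, organ))


def _cum(study: str, arm: str, organ: str) -> tuple[float, float]:
    for row in REFERENCE_CUMULATED:
        if (row["study"], row["arm"], row["organ"]) == (study, arm, organ):
            return row["mean"], row["sd"]
    raise KeyError((study, arm, organ))


def _dose(organ, mad, arm=""):
    from .dose import AbsorbedDose

    return AbsorbedDose(organ=organ, mad_cGy_per_MBq=mad, method="local", cohort=arm)


def worked_examples() -> dict[str, float]:
    """The published-number chain, recomputed through the package.

    Therapeutic indices from reference organ MADs, headline fold
    changes and delta-method tumor-to-kidney ratios from reference
    cumulated activities, and the local-deposition reconstruction of
    the kidney/tumor MADs.
    """
    out: dict[str, float] = {}

    pre = therapeutic_index(
        [
            _dose("blood", _mad("pretargeting", "blood")),
            _dose("kidney", _mad("pretargeting", "kidney")),
            _dose("tumor", _mad("pretargeting", "tumor")),
        ],
        "tumor",
        arm="pretargeting",
    ).table.set_index("organ")
    conv = therapeutic_index(
        [
            _dose("kidney", _mad("conventional", "kidney")),
            _dose("tumor", _mad("conventional", "tumor")),
        ],
        "tumor",
        arm="conventional",
    ).table.set_index("organ")
    out["kidney_ti_pretargeting"] = float(pre.loc["kidney", "ti_rounded"])
    out["kidney_ti_conventional"] = float(conv.loc["kidney", "ti_rounded"])
    out["blood_ti_pretargeting"] = float(pre.loc["blood", "ti_rounded"])

    out["tumor_mad_fold_decrease"] = fold_change(
        _mad("conventional", "tumor"), _mad("pretargeting", "tumor")
    )["fold"]
    out["pdx_tumor_mad_fold_decrease"] = fold_change(
        _mad("conventional", "tumor"), _mad("conventional_pdx", "tumor")
    )["fold"]

    out["kidney_cumact_fold_healthy"] = fold_change(
        _cum("healthy", "conventional", "kidney")[0],
        _cum("healthy", "pretargeting_8h", "kidney")[0],
    )["fold"]
    out["kidney_cumact_fold_u87mg"] = fold_change(
        _cum("u87mg", "conventional", "kidney")[0],
        _cum("u87mg", "pretargeting_8h", "kidney")[0],
    )["fold"]

    tm, ts = _cum("u87mg", "pretargeting_8h", "tumor")
    km, ks = _cum("u87mg", "pretargeting_8h", "kidney")
    r_pre = ratio_with_uncertainty(tm, ts, km, ks, "tumor", "kidney")
    tm, ts = _cum("u87mg", "conventional", "tumor")
    km, ks = _cum("u87mg", "conventional", "kidney")
    r_conv = ratio_with_uncertainty(tm, ts, km, ks, "tumor", "kidney")
    out["tumor_to_kidney_ratio_pretargeting"] = round(r_pre.ratio, 2)
    out["tumor_to_kidney_ratio_pretargeting_sd"] = round(r_pre.sd, 2)
    out["tumor_to_kidney_ratio_conventional"] = round(r_conv.ratio, 2)
    out["kidney_ti_fold_increase"] = fold_change(r_pre.ratio, r_conv.ratio)["fold"]

    # local-deposition reconstruction of the printed MADs (phi = 1)
    for key, (study, arm, organ) in {
        "kidney_mad_local_conventional": ("u87mg", "conventional", "kidney"),
        "tumor_mad_local_pretargeting": ("u87mg", "pretargeting_8h", "tumor"),
    }.items():
        mean, sd = _cum(study, arm, organ)
        cum = CumulatedActivity(
            organ=organ, value=mean, sd=sd, method="published", window=(0.0, np.inf)
        )
        out[key] = round(local_deposition_dose(cum, LU177).mad_cGy_per_MBq, 2)
    return out


def lag_sweep_summary(
    seed: int = 0,
    lags_h=(0.5, 2.0, 8.0, 24.0),
    cv: float = 0.15,
    n_per_time: int = 5,
    reps: int = 1,
) -> dict:
    """Lag sweep under the default calibration.

    Returns the tidy sweep table plus the lag maximizing the
    tumor-to-kidney ratio, whether kidney cumulated activity decreases
    strictly over the first three lags, and the kidney fold drop from
    the shortest to the 8-h lag.
    """
    table = sweep(lags_h=lags_h, reps=reps, seed=seed, cv=cv, n_per_time=n_per_time)
    by_lag = table.set_index("lag_h")
    kidney = by_lag["kidney_auc"]
    optimal = float(by_lag["tumor_to_kidney"].idxmax())
    first_three = [kidney[l] for l in lags_h[:3]]
    return dict(
        table=table,
        optimal_lag_h=optimal,
        kidney_strictly_decreasing=bool(np.all(np.diff(first_three) < 0)),
        kidney_fold_lag05_to_8=float(kidney[lags_h[0]] / kidney[8.0]),
    )


def recovery_study(
    n_replicates: int = 100,
    cv: float = 0.15,
    n_per_time: int = 5,
    times_h=(1.0, 4.0, 24.0),
    rel_tol: float = 0.25,
    seed: int = 0,
) -> dict:
    """One-step parameter recovery under realistic noise.

    Simulates ``n_replicates`` cross-sectional cohorts from the default
    one-step parameters and refits ``k_ren`` (with ``f_kid`` free) from
    mis-specified starting values; reports the fraction of replicates
    recovering ``k_ren`` within ``rel_tol`` of the truth.
    """
    truth = DEFAULT_PRETARGET_PARAMS
    ss = np.random.SeedSequence(seed)
    estimates = []
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        study = simulate_conventional(
            truth,
            times_h=times_h,
            n_per_time=n_per_time,
            noise=NoiseModel(cv=cv, seed=rep_seed),
        )
        fit = fit_params(
            study,
            free=("k_ren", "f_kid"),
            start=replace(truth, k_ren=2.0, f_kid=0.2),
            seed=rep_seed,
        )
        estimates.append(fit.estimates["k_ren"])
    estimates = np.asarray(estimates)
    within = np.abs(estimates - truth.k_ren) / truth.k_ren <= rel_tol
    return dict(
        estimates=estimates,
        truth=truth.k_ren,
        rate_within_tol=float(within.mean()),
        rel_tol=rel_tol,
    )


def logrank_type1(
    n_replicates: int = 2000,
    n_per_arm: int = 10,
    scale_d: float = 30.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the log-rank test under identical exponentials."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        ta = rng.exponential(scale_d, n_per_arm)
        tb = rng.exponential(scale_d, n_per_arm)
        a = [SurvivalRecord("a", float(t), 1) for t in ta]
        b = [SurvivalRecord("b", float(t), 1) for t in tb]
        if logrank(a, b)["p"] < alpha:
            rejections += 1
    return dict(rate=rejections / n_replicates, alpha=alpha, n_replicates=n_replicates)
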