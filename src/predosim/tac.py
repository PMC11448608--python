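"""Time-activity curves and time-integrated (cumulated) activity.

The cumulated activity a-tilde of an organ is the time integral of its
activity concentration (here in %IA/g * h), proportional to the total
number of decays per gram of tissue and hence to absorbed dose.  The
integral is always taken on the *physical* activity scale: if the input
biodistribution is decay-corrected, apply :func:`apply_physical_decay`
first (``integrate_tac`` refuses decay-corrected curves).

The integral is split into three parts:

* a leading segment from t = 0 to the first sample, under a configurable
  convention (linear rise from zero, or a plateau at the first sample);
* the trapezoid rule between the first and last sample;
* a tail beyond the last sample: a terminal mono-exponential fitted on
  the last k >= 2 points (rate constrained >= lambda_phys so the
  integral is finite), physical decay only, or no tail.

Uncertainty is propagated by the delta method over the trapezoid
weights, treating per-time means as independent -- valid for
cross-sectional designs where each time point is a different group of
animals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import BiodistStudy, normalize_organ
from .nuclides import Radionuclide

logger = logging.getLogger("predosim")

T0Convention = Literal["rise", "plateau", "none"]
TailModel = Literal["monoexp", "physical", "none"]


@dataclass
class TimeActivityCurve:
    """Per-organ mean +/- SD activity concentration versus time.

    ``sd_pct_ia_per_g`` entries are NaN where only one animal was
    measured.  ``decay_corrected`` records whether values are corrected
    back to injection time (True) or physical (False).
    """

    organ: str
    times_h: np.ndarray
    mean_pct_ia_per_g: np.ndarray
    sd_pct_ia_per_g: np.ndarray
    n_per_time: np.ndarray
    decay_corrected: bool
    cohort: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_pct_ia_per_g = np.asarray(self.mean_pct_ia_per_g, dtype=float)
        self.sd_pct_ia_per_g = np.asarray(self.sd_pct_ia_per_g, dtype=float)
        self.n_per_time = np.asarray(self.n_per_time, dtype=int)
        k = len(self.times_h)
        if not all(
            len(a) == k
            for a in (self.mean_pct_ia_per_g, self.sd_pct_ia_per_g, self.n_per_time)
        ):
            raise ValueError("all TAC arrays must have equal length")
        if k and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")


@dataclass
class CumulatedActivity:
    """Time-integrated activity of one organ, %IA/g * h, with SD.

    ``method`` records the integration scheme (t0 convention, tail
    model, number of terminal points); ``window`` is the integration
    interval, ``inf`` end for extrapolated tails.
    """

    organ: str
    value: float
    sd: float
    method: str
    window: tuple[float, float]
    cohort: str = ""
    physical: bool = True  # integrated on the physical-activity scale


def build_tac(study: BiodistStudy, cohort: str, organ: str) -> TimeActivityCurve:
    """Aggregate per-animal measurements into a mean +/- SD curve.

    SD is the sample (ddof=1) standard deviation over animals at each
    time point, NaN where n = 1.  Order of input rows is irrelevant.
    """
    organ = normalize_organ(organ)
    df = study.measurements
    if cohort not in set(df["cohort"]):
        raise KeyError(f"unknown cohort {cohort!r}; have {study.cohorts}")
    sub = df[(df["cohort"] == cohort) & (df["organ"] == organ)]
    if sub.empty:
        raise KeyError(f"no measurements for organ {organ!r} in cohort {cohort!r}")
    g = sub.groupby("time_h")["pct_ia_per_g"]
    agg = g.agg(["mean", "std", "count"]).sort_index()
    return TimeActivityCurve(
        organ=organ,
        times_h=agg.index.to_numpy(),
        mean_pct_ia_per_g=agg["mean"].to_numpy(),
        sd_pct_ia_per_g=agg["std"].to_numpy(),
        n_per_time=agg["count"].to_numpy(),
        decay_corrected=study.decay_corrected,
        cohort=cohort,
    )


def apply_physical_decay(
    tac: TimeActivityCurve, nuclide: Radionuclide
) -> TimeActivityCurve:
    """Convert a decay-corrected curve to physical activity.

    Multiplies mean and SD by exp(-lambda_phys * t).  Applying it to an
    already-physical curve is a warned no-op, so the operation is
    idempotent.
    """
    if not tac.decay_corrected:
        logger.warning("TAC for %r is already physical; no decay applied", tac.organ)
        return tac
    f = np.exp(-nuclide.lambda_phys * tac.times_h)
    return replace(
        tac,
        mean_pct_ia_per_g=tac.mean_pct_ia_per_g * f,
        sd_pct_ia_per_g=tac.sd_pct_ia_per_g * f,
        decay_corrected=False,
    )


def _tail_rate_monoexp(
    times: np.ndarray, values: np.ndarray, k_points: int, lambda_phys: float
) -> tuple[float, bool]:
    """Terminal rate from a log-linear fit on the last ``k_points`` samples.

    Returns (rate, fell_back); falls back to physical decay when the
    fitted rate is below lambda_phys (integral would diverge relative to
    pure decay) or when terminal values are non-positive.
    """
    t = times[-k_points:]
    v = values[-k_points:]
    if np.any(v <= 0):
        return lambda_phys, True
    slope = np.polyfit(t, np.log(v), 1)[0]
    rate = -slope
    if rate < lambda_phys:
        logger.warning(
            "fitted terminal rate %.4g/h < lambda_phys %.4g/h; "
            "falling back to physical-decay tail",
            rate,
            lambda_phys,
        )
        return lambda_phys, True
    return rate, False


def integrate_tac(
    tac: TimeActivityCurve,
    nuclide: Radionuclide,
    tail: TailModel = "monoexp",
    t0_convention: T0Convention = "rise",
    k_terminal: int = 2,
) -> CumulatedActivity:
    """Time-integrate a physical-activity curve to cumulated activity.

    Parameters
    ----------
    tail
        ``"monoexp"``: terminal mono-exponential fitted on the last
        ``k_terminal`` points, rate constrained >= lambda_phys (falls
        back to ``"physical"`` with a warning otherwise);
        ``"physical"``: tail decays at lambda_phys only, contributing
        A_last / lambda_phys; ``"none"``: truncate at the last sample.
    t0_convention
        ``"rise"``: linear from 0 at t = 0 up to the first sample
        (uptake starts at injection; default for one-step studies);
        ``"plateau"``: first sample extends back to t = 0;
        ``"none"``: start the window at the first sample.

    Raises
    ------
    ValueError
        If the curve is still decay-corrected or has < 2 points.
    """
    if tac.decay_corrected:
        raise ValueError(
            "integrate_tac requires a physical-activity curve; "
            "run apply_physical_decay first"
        )
    t = tac.times_h
    a = tac.mean_pct_ia_per_g
    sd = np.nan_to_num(tac.sd_pct_ia_per_g, nan=0.0)
    if len(t) < 2:
        raise ValueError("need at least 2 time points to integrate")
    if k_terminal < 2:
        raise ValueError("k_terminal must be >= 2")

    # Trapezoid weights: d(value)/d(a_i); variance follows by delta method.
    w = np.zeros_like(a)
    dt = np.diff(t)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0

    t_start = t[0]
    if t0_convention == "rise":
        w[0] += t[0] / 2.0
        t_start = 0.0
    elif t0_convention == "plateau":
        w[0] += t[0]
        t_start = 0.0
    elif t0_convention != "none":
        raise ValueError(f"unknown t0 convention {t0_convention!r}")

    method_bits = [f"trapezoid+t0={t0_convention}"]
    t_end: float = float(t[-1])
    if tail == "monoexp":
        k = min(k_terminal, len(t))
        rate, fell_back = _tail_rate_monoexp(t, a, k, nuclide.lambda_phys)
        w[-1] += 1.0 / rate
        t_end = np.inf
        method_bits.append(
            f"tail=physical(fallback from monoexp k={k})"
            if fell_back
            else f"tail=monoexp(k={k}, rate={rate:.4g}/h)"
        )
    elif tail == "physical":
        w[-1] += 1.0 / nuclide.lambda_phys
        t_end = np.inf
        method_bits.append("tail=physical")
    elif tail == "none":
        method_bits.append("tail=none")
    else:
        raise ValueError(f"unknown tail model {tail!r}")

    value = float(w @ a)
    var = float(w**2 @ sd**2)
    return CumulatedActivity(
        organ=tac.organ,
        value=value,
        sd=float(np.sqrt(var)),
        method="; ".join(method_bits),
        window=(float(t_start), float(t_end)),
        cohort=tac.cohort,
    )


def auc_table(
    study: BiodistStudy,
    organs: Sequence[str] | None = None,
    cohorts: Sequence[str] | None = None,
    tail: TailModel = "monoexp",
    t0_convention: T0Convention = "rise",
    k_terminal: int = 2,
) -> pd.DataFrame:
    """Cumulated activity for every cohort x organ under one configuration.

    Returns a tidy DataFrame with columns ``cohort, organ, value, sd,
    method, t_start, t_end``.  The biodistribution is converted to
    physical activity before integration when the study is flagged
    decay-corrected.
    """
    organs = [normalize_organ(o) for o in (organs or study.organs)]
    cohorts = list(cohorts or study.cohorts)
    rows = []
    for cohort in cohorts:
        for organ in organs:
            tac = build_tac(study, cohort, organ)
            if tac.decay_corrected:
                tac = apply_physical_decay(tac, study.radionuclide)
            cum = integrate_tac(
                tac,
                study.radionuclide,
                tail=tail,
                t0_convention=t0_convention,
                k_terminal=k_terminal,
            )
            rows.append(
                dict(
                    cohort=cohort,
                    organ=organ,
                    value=cum.value,
                    sd=cum.sd,
                    method=cum.method,
                    t_start=cum.window[0],
                    t_end=cum.window[1],
                )
            )
    return pd.DataFrame(rows)
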