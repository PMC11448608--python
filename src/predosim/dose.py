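"""Organ mean absorbed dose (MAD) and therapeutic index.

Two dose methods are supported:

* **local deposition** -- every decay deposits its mean energy Delta in
  the source organ itself (scaled by an absorbed fraction phi).  For
  electron-dominated emitters such as Lu-177 at mouse-organ scale this
  is the standard first-order model; photon cross-dose is neglected.
* **S-values** -- the MIRD formalism D(target) = sum_source
  A-tilde(source) * S(target <- source), with a user-supplied S matrix
  in Gy/(MBq*s) and per-organ masses to convert per-gram cumulated
  activity into whole-organ decays.

Doses are reported in cGy per MBq injected.  The therapeutic index (TI)
of an organ at risk is tumor MAD divided by that organ's MAD; kidney TI
is the usual optimization objective for renally cleared vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nuclides import Radionuclide
from .tac import CumulatedActivity

#: decays per gram per MBq injected, for 1 %IA/g*h of cumulated activity:
#: (1/100) MBq*h/g  *  3600 s/h  *  1e6 decays/(MBq*s)
_DECAYS_PER_G_PER_PCTIAGH = 3.6e7
_J_PER_G_TO_CGY = 1e5  # J/g -> J/kg (x1000) -> Gy -> cGy (x100)


@dataclass
class AbsorbedDose:
    """Mean absorbed dose of one organ, cGy per MBq injected."""

    organ: str
    mad_cGy_per_MBq: float
    method: str  # "local" | "svalue"
    sd: float = 0.0
    cohort: str = ""
    inputs: CumulatedActivity | None = None

    def __post_init__(self) -> None:
        if self.mad_cGy_per_MBq < 0:
            raise ValueError("absorbed dose must be >= 0")


@dataclass
class SValueTable:
    """MIRD S-value matrix with organ masses.

    ``s_Gy_per_MBq_s[i, j]`` is the dose to ``target_organs[i]`` per
    unit cumulated activity in ``source_organs[j]``; ``organ_masses_g``
    converts %IA/g cumulated activity into whole-organ decays.
    """

    source_organs: list[str]
    target_organs: list[str]
    s_Gy_per_MBq_s: np.ndarray
    organ_masses_g: dict[str, float]

    def __post_init__(self) -> None:
        self.s_Gy_per_MBq_s = np.asarray(self.s_Gy_per_MBq_s, dtype=float)
        if self.s_Gy_per_MBq_s.shape != (len(self.target_organs), len(self.source_organs)):
            raise ValueError(
                "S matrix shape must be (n_targets, n_sources) = "
                f"({len(self.target_organs)}, {len(self.source_organs)})"
            )
        if np.any(self.s_Gy_per_MBq_s < 0):
            raise ValueError("S-values must be >= 0")


def local_deposition_dose(
    cum: CumulatedActivity,
    nuclide: Radionuclide,
    absorbed_fraction: float = 1.0,
) -> AbsorbedDose:
    """MAD under the local energy deposition model.

    MAD [cGy/MBq] = a-tilde [%IA/g*h] * 3.6e7 decays/(g*MBq)
    * Delta [J/decay] * phi * 1e5 (J/g -> cGy).  At Delta = 147.9 keV
    and phi = 1 the coefficient is ~0.0853 cGy/MBq per %IA/g*h.
    """
    if not 0 < absorbed_fraction <= 1:
        raise ValueError("absorbed_fraction must be in (0, 1]")
    if not cum.physical:
        raise ValueError(
            "cumulated activity was integrated on a decay-corrected curve; "
            "run apply_physical_decay before integrate_tac"
        )
    if cum.value < 0:
        raise ValueError("cumulated activity must be >= 0")
    coeff = (
        _DECAYS_PER_G_PER_PCTIAGH
        * nuclide.mean_energy_per_decay_J
        * _J_PER_G_TO_CGY
        * absorbed_fraction
    )
    return AbsorbedDose(
        organ=cum.organ,
        mad_cGy_per_MBq=coeff * cum.value,
        sd=coeff * cum.sd,
        method="local",
        cohort=cum.cohort,
        inputs=cum,
    )


def svalue_dose(
    cums: Sequence[CumulatedActivity], table: SValueTable
) -> list[AbsorbedDose]:
    """MADs from an S-value matrix.

    Each source organ's per-gram cumulated activity is converted to
    whole-organ decays via its mass, then D(target) = sum_source
    A-tilde(source) * S(target <- source), reported in cGy/MBq.
    """
    cum_by_organ = {c.organ: c for c in cums}
    missing = [o for o in cum_by_organ if o not in table.source_organs]
    if missing:
        raise KeyError(
            f"organ(s) {missing} not among S-table source organs "
            f"{table.source_organs}"
        )
    # whole-organ cumulated activity in MBq*s per MBq injected
    a_tilde = np.zeros(len(table.source_organs))
    for j, organ in enumerate(table.source_organs):
        if organ not in cum_by_organ:
            continue
        try:
            mass = table.organ_masses_g[organ]
        except KeyError:
            raise KeyError(f"no mass for organ {organ!r} in S-table") from None
        # %IA/g*h -> fraction IA * h per g -> whole organ, MBq*h -> MBq*s
        a_tilde[j] = cum_by_organ[organ].value / 100.0 * mass * 3600.0
    d_Gy = table.s_Gy_per_MBq_s @ a_tilde
    cohort = cums[0].cohort if cums else ""
    return [
        AbsorbedDose(
            organ=organ,
            mad_cGy_per_MBq=float(d * 100.0),
            method="svalue",
            cohort=cohort,
            inputs=cum_by_organ.get(organ),
        )
        for organ, d in zip(table.target_organs, d_Gy)
    ]


def round_ti(ti: float) -> float:
    """Reporting convention for TI: 2 decimals below 10, integer above."""
    return round(ti, 2) if ti < 10 else float(round(ti))


@dataclass
class TIReport:
    """Therapeutic indices of one treatment arm.

    ``table`` has columns ``organ, mad_cGy_per_MBq, ti, ti_rounded``;
    the tumor row carries NaN TI (the self-ratio is excluded).  Raw
    unrounded TIs are always retained alongside the reported rounding.
    """

    arm: str
    tumor_mad_cGy_per_MBq: float
    table: pd.DataFrame


def therapeutic_index(
    doses: Sequence[AbsorbedDose], tumor_label: str = "tumor", arm: str = ""
) -> TIReport:
    """TI per organ: tumor MAD / organ MAD.

    Organs with zero dose get NaN TI and are flagged in the table
    (``ti_defined`` False) rather than raising.
    """
    by_organ = {d.organ: d for d in doses}
    if tumor_label not in by_organ:
        raise KeyError(f"tumor organ {tumor_label!r} not among doses")
    tumor_mad = by_organ[tumor_label].mad_cGy_per_MBq
    if not tumor_mad > 0:
        raise ValueError("tumor MAD must be > 0 to define therapeutic indices")
    rows = []
    for d in doses:
        if d.organ == tumor_label:
            ti = np.nan
            defined = False
        elif d.mad_cGy_per_MBq > 0:
            ti = tumor_mad / d.mad_cGy_per_MBq
            defined = True
        else:
            ti = np.nan
            defined = False
        rows.append(
            dict(
                organ=d.organ,
                mad_cGy_per_MBq=d.mad_cGy_per_MBq,
                ti=ti,
                ti_rounded=round_ti(ti) if defined else np.nan,
                ti_defined=defined,
            )
        )
    return TIReport(arm=arm, tumor_mad_cGy_per_MBq=tumor_mad, table=pd.DataFrame(rows))
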