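"""Radionuclide physical data.

The dose chain only needs two nuclear quantities: the physical half-life
(hence the decay constant ``lambda_phys``) and the mean energy emitted per
decay that is absorbed locally in a small organ.  For beta-dominated
emitters at mouse-organ scale the locally absorbed energy is essentially
the mean electron energy per decay; photons largely escape and are
ignored under the local-deposition method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Conversion factor keV -> joule.
KEV_TO_J = 1.602176634e-16

#: Mean locally deposited (electron) energy per Lu-177 decay, keV.
#: ICRP-107-style mean beta + conversion/Auger electron energy; photons
#: are excluded because they mostly escape mouse-sized organs.
LU177_MEAN_ENERGY_KEV = 147.9

#: Lu-177 physical half-life, hours (6.647 d).
LU177_HALF_LIFE_H = 6.647 * 24.0


@dataclass(frozen=True)
class Radionuclide:
    """Physical data for a radionuclide.

    Parameters
    ----------
    name
        Nuclide label, e.g. ``"Lu-177"``.
    half_life_h
        Physical half-life in hours (> 0).
    mean_energy_per_decay_keV
        Mean locally absorbed energy per decay in keV (> 0).  The
        absorbed-fraction handling lives in the dosimetry layer; this is
        the emitted-and-locally-deposited energy Delta.
    """

    name: str
    half_life_h: float
    mean_energy_per_decay_keV: float

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError(f"half_life_h must be > 0, got {self.half_life_h}")
        if not self.mean_energy_per_decay_keV > 0:
            raise ValueError(
                f"mean_energy_per_decay_keV must be > 0, got "
                f"{self.mean_energy_per_decay_keV}"
            )

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant, 1/h."""
        return math.log(2.0) / self.half_life_h

    @property
    def mean_energy_per_decay_J(self) -> float:
        """Mean locally absorbed energy per decay, joule."""
        return self.mean_energy_per_decay_keV * KEV_TO_J


#: Default Lu-177 entry used throughout the pipeline.
LU177 = Radionuclide(
    name="Lu-177",
    half_life_h=LU177_HALF_LIFE_H,
    mean_energy_per_decay_keV=LU177_MEAN_ENERGY_KEV,
)

_REGISTRY = {"lu-177": LU177, "177lu": LU177, "lu177": LU177}


def get_nuclide(name: str) -> Radionuclide:
    """Look up a registered radionuclide by (case-insensitive) name."""
    key = name.strip().lower().replace("^", "")
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown radionuclide {name!r}; registered: "
            + ", ".join(sorted({n.name for n in _REGISTRY.values()}))
        ) from None
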