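"""Data model and I/O for biodistribution and survival tables.

Canonical biodistribution format is long (tidy): one row per animal x
organ x time point, with columns ``cohort``, ``organ``, ``time_h``,
``animal_id``, ``pct_ia_per_g``.  A secondary reader accepts the wide
mean +/- SD layout common in published supplements and expands it to
pseudo-animals (flagged in provenance) when per-animal data are absent.

Times are hours post *radioligand* injection; for pretargeting studies
the clock starts at tetrazine injection, not at vector injection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nuclides import Radionuclide, get_nuclide

logger = logging.getLogger("predosim")

BIODIST_COLUMNS = ["cohort", "organ", "time_h", "animal_id", "pct_ia_per_g"]
SURVIVAL_COLUMNS = ["group", "time_d", "event"]

#: Editable organ synonym map; keys are case-folded inputs.  Unknown
#: organs pass through with a logged warning rather than an error.
ORGAN_SYNONYMS: dict[str, str] = {
    "kidneys": "kidney",
    "kidney": "kidney",
    "tumour": "tumor",
    "tumor": "tumor",
    "blood": "blood",
    "liver": "liver",
    "spleen": "spleen",
    "muscle": "muscle",
    "bone": "bone",
    "lungs": "lung",
    "lung": "lung",
    "heart": "heart",
    "stomach": "stomach",
    "small intestine": "small_intestine",
    "large intestine": "large_intestine",
}


class SchemaError(ValueError):
    """A required column is missing or a table is malformed."""


class ValidationError(ValueError):
    """Row-level values violate a type invariant."""


def normalize_organ(label: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize an organ label (case-fold, strip, map synonyms).

    Idempotent: ``normalize_organ(normalize_organ(x)) == normalize_organ(x)``.
    Unknown labels pass through lower-cased with a warning.
    """
    syn = ORGAN_SYNONYMS if synonyms is None else synonyms
    key = str(label).strip().lower()
    if key in syn:
        return syn[key]
    canonical = key.replace(" ", "_")
    if canonical not in set(syn.values()):
        logger.warning("unknown organ label %r passed through as %r", label, canonical)
    return canonical


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal in a survival study.

    ``time_d`` is days since tumor inoculation; ``event`` is 1 if the
    endpoint (death or euthanasia criterion) was reached, 0 if censored.
    """

    group: str
    time_d: float
    event: int

    def __post_init__(self) -> None:
        if not self.time_d > 0:
            raise ValidationError(f"time_d must be > 0, got {self.time_d}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")


@dataclass
class BiodistStudy:
    """A cross-sectional biodistribution study.

    ``measurements`` is a long-format DataFrame with columns
    ``cohort, organ, time_h, animal_id, pct_ia_per_g``.  Animals are
    sacrificed per time point, so rows at different times are distinct
    animals and statistically independent.
    """

    measurements: pd.DataFrame
    radionuclide: Radionuclide
    injected_activity_MBq: float = 1.0
    injected_mass_ug: float | None = None
    lag_time_h: float | None = None
    decay_corrected: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        self.measurements = _validate_measurements(self.measurements)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.measurements["cohort"].unique())

    @property
    def organs(self) -> list[str]:
        return sorted(self.measurements["organ"].unique())

    def subset(self, cohort: str) -> "BiodistStudy":
        """Return a copy restricted to one cohort."""
        if cohort not in self.cohorts:
            raise KeyError(f"unknown cohort {cohort!r}; have {self.cohorts}")
        out = replace(self)
        out.measurements = self.measurements[
            self.measurements["cohort"] == cohort
        ].reset_index(drop=True)
        return out

    def equals(self, other: "BiodistStudy") -> bool:
        """Field-by-field equality (measurements compared as sorted tables)."""
        key = ["cohort", "organ", "time_h", "animal_id"]
        a = self.measurements.sort_values(key).reset_index(drop=True)
        b = other.measurements.sort_values(key).reset_index(drop=True)
        meta_equal = (
            self.radionuclide == other.radionuclide
            and np.isclose(self.injected_activity_MBq, other.injected_activity_MBq)
            and _opt_close(self.injected_mass_ug, other.injected_mass_ug)
            and _opt_close(self.lag_time_h, other.lag_time_h)
            and self.decay_corrected == other.decay_corrected
        )
        if not meta_equal or len(a) != len(b):
            return False
        return bool(
            (a[key] == b[key]).all().all()
            and np.allclose(a["pct_ia_per_g"], b["pct_ia_per_g"])
        )


def _opt_close(a: float | None, b: float | None) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return bool(np.isclose(a, b))


def _validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BIODIST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[BIODIST_COLUMNS].copy()
    df["cohort"] = df["cohort"].astype(str)
    df["animal_id"] = df["animal_id"].astype(str)
    df["organ"] = df["organ"].map(normalize_organ)
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["pct_ia_per_g"] = pd.to_numeric(df["pct_ia_per_g"])

    bad = df.index[~np.isfinite(df["pct_ia_per_g"]) | (df["pct_ia_per_g"] < 0)]
    if len(bad):
        raise ValidationError(
            f"pct_ia_per_g must be finite and >= 0; offending rows: {list(bad)}"
        )
    bad = df.index[~np.isfinite(df["time_h"]) | (df["time_h"] < 0)]
    if len(bad):
        raise ValidationError(
            f"time_h must be finite and >= 0; offending rows: {list(bad)}"
        )
    key = ["cohort", "organ", "time_h", "animal_id"]
    dup = df.index[df.duplicated(key)]
    if len(dup):
        raise ValidationError(
            f"duplicate (cohort, organ, time_h, animal_id) keys at rows: {list(dup)}"
        )
    return df.reset_index(drop=True)


def _study_metadata(metadata: Mapping) -> dict:
    nuclide = metadata.get("radionuclide", "Lu-177")
    if isinstance(nuclide, str):
        nuclide = get_nuclide(nuclide)
    return dict(
        radionuclide=nuclide,
        injected_activity_MBq=float(metadata.get("injected_activity_MBq", 1.0)),
        injected_mass_ug=_opt_float(metadata.get("injected_mass_ug")),
        lag_time_h=_opt_float(metadata.get("lag_time_h")),
        decay_corrected=bool(metadata.get("decay_corrected", True)),
        provenance=str(metadata.get("provenance", "")),
    )


def _opt_float(x) -> float | None:
    return None if x is None else float(x)


def read_biodist(path: str | Path, metadata: Mapping | None = None) -> BiodistStudy:
    """Read a long-format biodistribution CSV/TSV into a validated study.

    Parameters
    ----------
    path
        Delimited text with columns ``cohort, organ, time_h, animal_id,
        pct_ia_per_g`` (UTF-8; decimal point, never comma).
    metadata
        Mapping supplying ``radionuclide`` (name or object),
        ``injected_activity_MBq``, ``injected_mass_ug``, ``lag_time_h``,
        ``decay_corrected`` and ``provenance``.  Defaults to Lu-177,
        1 MBq, decay-corrected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return BiodistStudy(measurements=df, **_study_metadata(metadata or {}))


def write_biodist(study: BiodistStudy, path: str | Path) -> Path:
    """Write a study's measurements as CSV readable by :func:`read_biodist`.

    Column order is fixed: ``cohort, organ, time_h, animal_id,
    pct_ia_per_g``.  Metadata is not embedded; carry it in the config.
    """
    path = Path(path)
    study.measurements[BIODIST_COLUMNS].to_csv(path, index=False)
    return path


def read_biodist_wide(
    path: str | Path, metadata: Mapping | None = None, n_pseudo: int = 3
) -> BiodistStudy:
    """Read a wide mean +/- SD table and expand it to pseudo-animals.

    Expected columns: ``cohort, organ, time_h, mean, sd`` (``sd`` may be
    empty).  Each row becomes ``n_pseudo`` pseudo-animals whose sample
    mean and sample SD exactly match the printed values (two at
    mean -/+ sd*sqrt((n-1)/n)... a symmetric three-point design is used:
    {mean - sd*c, mean, mean + sd*c} with c = sqrt((n-1)/2) for n = 3).
    The expansion is flagged in provenance.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("cohort", "organ", "time_h", "mean") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if n_pseudo < 2 or n_pseudo % 2 == 0:
        raise ValueError("n_pseudo must be an odd integer >= 3")
    rows = []
    c = np.sqrt((n_pseudo - 1) / 2.0)  # symmetric 3-point: sample SD == sd
    offsets = np.concatenate([[-c, 0.0, c], np.zeros(n_pseudo - 3)])
    for _, r in df.iterrows():
        sd = float(r.get("sd", 0.0) or 0.0)
        for j, off in enumerate(offsets):
            rows.append(
                dict(
                    cohort=r["cohort"],
                    organ=r["organ"],
                    time_h=r["time_h"],
                    animal_id=f"pseudo{j + 1}",
                    pct_ia_per_g=max(float(r["mean"]) + off * sd, 0.0),
                )
            )
    meta = _study_metadata(metadata or {})
    meta["provenance"] = (meta["provenance"] + " | " if meta["provenance"] else "") + (
        f"expanded from wide mean+/-SD table {path.name} to {n_pseudo} pseudo-animals"
    )
    return BiodistStudy(measurements=pd.DataFrame(rows), **meta)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival CSV with columns ``group, time_d, event``."""
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for idx, r in df.iterrows():
        ev = r["event"]
        if ev not in (0, 1):
            raise ValidationError(f"row {idx}: event must be 0 or 1, got {ev}")
        records.append(
            SurvivalRecord(group=str(r["group"]), time_d=float(r["time_d"]), event=int(ev))
        )
    return records


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [dict(group=r.group, time_d=r.time_d, event=r.event) for r in records]
    ).to_csv(path, index=False)
    return path


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a tidy DataFrame."""
    return pd.DataFrame(
        [dict(group=r.group, time_d=r.time_d, event=r.event) for r in records]
    )


def configure_logging(verbose: bool = False) -> None:
    """Send package logs to stderr; DEBUG if verbose, else INFO."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
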