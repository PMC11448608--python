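import numpy as np
import pandas as pd
import pytest

from predosim.io import BiodistStudy, SurvivalRecord
from predosim.nuclides import LU177


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    """2 organs x 3 times x 3 animals, deterministic values."""
    rows = []
    for organ, base in (("kidney", 50.0), ("tumor", 10.0)):
        for t in (1.0, 4.0, 24.0):
            for j, off in enumerate((-2.0, 0.0, 2.0)):
                rows.append(
                    dict(
                        cohort="arm_a",
                        organ=organ,
                        time_h=t,
                        animal_id=f"m{j + 1}",
                        pct_ia_per_g=base / (1 + 0.1 * t) + off,
                    )
                )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_study(toy_frame) -> BiodistStudy:
    return BiodistStudy(
        measurements=toy_frame,
        radionuclide=LU177,
        injected_activity_MBq=1.85,
        injected_mass_ug=200.0,
        lag_time_h=8.0,
        decay_corrected=True,
        provenance="toy",
    )


@pytest.fixture
def survival_toy() -> list[SurvivalRecord]:
    """Mixed events and censoring for hand-checkable KM tables."""
    spec = [(1.0, 1), (2.0, 0), (3.0, 1), (4.0, 0), (5.0, 1)]
    return [SurvivalRecord("g", t, e) for t, e in spec]
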