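# predosim

Preclinical radiopharmaceutical dosimetry for renally cleared targeting
vectors, with a compartmental simulator of click-chemistry pretargeting.

Single-domain antibodies (sdAbs) are attractive vectors for targeted
radionuclide therapy but are cleared through the kidney, where retained
activity makes the kidney the dose-limiting organ.  Pretargeting splits
the dosing in two: an unlabelled TCO-functionalized sdAb is injected
first, and after a lag time a small ¹⁷⁷Lu-labelled tetrazine radioligand
is injected and captured in vivo by bio-orthogonal click reaction.  This
package implements the quantitative chain used to evaluate such schemes
in mice, and a mechanistic simulator to generate synthetic
biodistribution cohorts with realistic between-animal noise.

## The pipeline

Per-animal biodistribution measurements (%IA/g: percent injected
activity per gram of tissue) are aggregated into per-organ
time–activity curves, converted to the physical-activity scale
(A(t) = A_corr(t)·e^(−λt), λ = ln2/T½, T½ = 6.647 d for ¹⁷⁷Lu), and
time-integrated to the cumulated activity

    ã = ∫₀^∞ A(t) dt   [%IA/g·h]

using the trapezoid rule plus a terminal mono-exponential tail whose
rate is constrained to be ≥ λ.  Under local energy deposition the organ
mean absorbed dose per unit injected activity is

    MAD [cGy/MBq] = ã · 3.6×10⁷ decays g⁻¹ MBq⁻¹ · Δ · φ · 10⁵

with Δ the mean locally absorbed energy per decay (147.9 keV for ¹⁷⁷Lu
electrons) and φ the absorbed fraction (default 1); an S-value matrix
path (MIRD formalism, D_target = Σ_source ã·S) is also provided.  The
therapeutic index of an organ at risk is TI = MAD_tumor / MAD_organ.
The comparison layer provides headline fold changes, delta-method
ratios of means (sd(a/b) = (a/b)·√(CV_a² + CV_b²)), one-way ANOVA with
Dunnett or Šídák adjustment, Kaplan–Meier estimation and the Mantel–Cox
log-rank test.

The simulator (`predosim.pksim`) models the one-step scheme (labelled
vector: blood → tumor binding with capacity B_max, renal clearance with
kidney retention fraction) and the two-step scheme (vector phase over
the lag, then radioligand clicking onto reactive TCO in blood and on
tumor, with TCO deactivation and receptor-mediated internalization
competing against capture).  Amounts are tracked in nmol with exact
mass balance; activity follows ligand-bearing species with physical
decay; noise is multiplicative lognormal per animal × organ × time.

## Worked example

```python
from predosim import (fold_change, local_deposition_dose, ratio_with_uncertainty,
                      therapeutic_index, CumulatedActivity, LU177)
from predosim.dose import AbsorbedDose

# tumor-to-kidney ratio from cumulated activities (mean ± SD, %IA/g·h)
r = ratio_with_uncertainty(404.0, 41.0, 197.0, 31.0)
print(round(r.ratio, 2), round(r.sd, 2))          # 2.05 0.38

# kidney therapeutic indices from organ mean absorbed doses (cGy/MBq)
rep = therapeutic_index(
    [AbsorbedDose("tumor", 37.54, "svalue"), AbsorbedDose("kidney", 15.64, "svalue")],
    "tumor")
print(rep.table.set_index("organ").loc["kidney", "ti_rounded"])   # 2.4

# headline fold change in kidney cumulated activity
print(fold_change(260.4, 11.2)["fold"])           # 23.0

# local-deposition dose from a cumulated activity
cum = CumulatedActivity("kidney", 1615.0, 185.0, "published", (0.0, float("inf")))
print(round(local_deposition_dose(cum, LU177).mad_cGy_per_MBq, 1))  # 137.8
```

The printed values mean: a pretargeted tumor-to-kidney cumulated
activity ratio of 2.05 ± 0.38 (delta method), a kidney therapeutic
index of 2.4 for the pretargeted arm, a 23-fold reduction in kidney
cumulated activity versus the directly labelled vector in healthy mice,
and a ~138 cGy/MBq kidney dose reconstructed by local deposition from
the one-step arm's cumulated activity.

## Analyses

The `analysis/` scripts run the full study on synthetic data and write
tidy tables under `results/`:

1. `01_simulate_cohorts.py` — one-step cohort plus pretargeting cohorts
   at lag 0.5/2/8/24 h (5 animals per time point, CV 15%).
2. `02_integrate_cumulated_activity.py` — per-cohort cumulated activity
   and kidney fold changes.
3. `03_dosimetry_therapeutic_index.py` — MADs and TIs for the simulated
   cohorts and from the reference dosimetry fixtures.
4. `04_lag_mass_sweep.py` — lag × injected-mass sweep; the
   tumor-to-kidney optimum falls at the 8-h lag.
5. `05_group_comparisons.py` — ANOVA/Dunnett and Šídák comparisons and
   the recomputed worked examples.
6. `06_survival_analysis.py` — Kaplan–Meier and pairwise log-rank on a
   synthetic five-arm therapy study.

A `predosim` command-line interface mirrors the pipeline
(`predosim simulate|sweep|integrate|compare|survival|pipeline`).

## Layout

- `src/predosim/` — library: `io`, `tac`, `dose`, `stats`, `pksim`,
  `pipeline`, `validation`, `cli`.
- `analysis/` — numbered study drivers (above).
- `tests/` — pytest suite (unit, property and acceptance tests).
- `docs/methods.md` — model, assumptions, numerical choices and
  limitations.
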