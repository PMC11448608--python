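# Methods

## Scope and data model

The package operates on cross-sectional biodistribution studies: at
each time point a separate group of animals is sacrificed and organ
activity concentrations are measured in %IA/g.  Rows at different
times are therefore independent samples, which drives two choices
below (SD propagation without between-time covariance, and
cohort-level rather than per-animal AUC uncertainty).  Times are hours
post radioligand injection; for two-step studies the clock starts at
tetrazine injection, with the vector phase folded into the lag
parameter.  Whether published %IA/g values are decay-corrected to
injection time is often unstated, so every study carries an explicit
`decay_corrected` flag and integration always happens on the physical
scale.

## Cumulated activity

For each organ the time–activity curve of per-time means is integrated
as: a leading segment from t = 0 to the first sample, the trapezoid
rule across the samples, and an extrapolated tail.

- **Leading edge.**  The treatment of the interval before the first
  sample is rarely reported, so it is configurable: `rise` (linear from
  zero; default, appropriate when uptake starts at injection),
  `plateau` (first sample extended back to t = 0), or `none`.
- **Tail.**  Default is a terminal mono-exponential fitted log-linearly
  on the last k = 2 points with its rate constrained to ≥ λ_phys, which
  guarantees a finite integral and reduces gracefully to pure physical
  decay; a fitted rate below λ_phys triggers an automatic fallback to
  the physical-decay tail (A_last/λ) with a warning.  A truncated
  (no-tail) option reports the finite window.  The integration window
  is recorded on every value.
- **Uncertainty.**  The integral is a linear functional w·A of the
  per-time means, so Var(ã) = Σ w_i² SD_i² (delta method over the
  trapezoid/tail weights).  Between-time covariance is zero by design
  in cross-sectional studies; the tail-rate uncertainty is not
  propagated (the tail weight is treated as fixed), a deliberate
  simplification documented here.

## Absorbed dose

The default dose model is local energy deposition: every decay deposits
its mean locally absorbed energy Δ in the source organ.  For ¹⁷⁷Lu we
use Δ = 147.9 keV (mean beta plus conversion/Auger electron energy per
decay); photons mostly escape mouse-sized organs and are neglected
unless an S-value table is supplied.  The conversion is exactly linear:
1 %IA/g·h ↦ 3.6×10⁷ decays/g per MBq injected, giving
≈ 0.0853 cGy/MBq per %IA/g·h at Δ = 147.9 keV, φ = 1.  Published
mouse dosimetry is usually produced with Monte-Carlo S-value tables
that include cross-dose and organ-specific absorbed fractions; the
local model reproduces such kidney/tumor values to within about 10%,
which is the accuracy claimed for it here.  A user-supplied S matrix
(Gy/MBq·s with per-organ masses) is supported and reduces exactly to
the local model for a diagonal matrix with S = Δ_J·10⁶/m_kg.

Therapeutic indices are tumor MAD over organ MAD.  Reported TIs follow
the mixed convention common in published tables (two decimals below 10,
integers above); raw values are always retained.  Note that rounding
MADs before the division can shift the last digit (e.g. 60.03/0.54
rounds to 111 while a table may print 110); the package always divides
unrounded MADs.

## Comparison layer

Fold changes are larger/smaller with direction recorded; the headline
value is rounded to the nearest integer at ≥ 2-fold and to one decimal
below.  Ratios of means carry a first-order delta-method SD assuming
independence, applied at cohort level because per-animal AUCs do not
exist in cross-sectional designs.  One-way ANOVA uses the pooled-MSE
F test; Dunnett many-to-one p-values come from the multivariate-t
distribution (numerical integration via scipy, agreeing with a 10⁵-draw
max-|t| permutation null to < 0.01 in tests), and Šídák adjustment is
p_adj = 1−(1−p)^m over pooled-variance pairwise t tests.  A degenerate
dataset with zero within-group variance is returned as a flagged
exact-separation result rather than NaNs.  Kaplan–Meier estimation and
the Mantel–Cox log-rank test are delegated to lifelines; the median is
the smallest time with S(t) ≤ 0.5 and is undefined when the curve never
reaches 0.5.  At n = 10 per arm the chi-square approximation of the
log-rank test is mildly anticonservative (empirical type-I error
≈ 0.06 at nominal 0.05 in the calibration study), a known small-sample
property.

## The pharmacokinetic simulator

The simulator is a mechanistic construction of this package — published
pretargeting optimizations are empirical, so no rate constants are
imputed to any experiment; the defaults are an explicit calibration.

**One-step.**  Labelled vector in blood clears renally at k_ren, with a
fraction f_kid retained in kidney (tubular reabsorption) and released
at k_kid_rel; tumor binding is second order against remaining capacity
(B_max − bound) with release k_off.  With binding switched off the
blood and kidney compartments form a linear two-compartment chain whose
closed-form solution is used as an oracle in tests.

**Two-step.**  Phase 1 integrates the unlabelled vector over the lag:
binding, internalization of surface-bound vector at k_int (which makes
its TCO unreachable), and the same renal pathway.  The reactive
fraction of unclicked vector decays as ρ(t) = e^(−k_deact·t) from
vector injection (TCO isomerization/metabolism).  Phase 2 adds the
radioligand: free ligand clears renally at k_Lren with a small retained
fraction f_Lkid, and clicks at rate k_click·ρ onto vector in blood and
on tumor surfaces.  Clicked blood vector is modelled with full vector
kinetics — renal clearance with kidney retention *and* tumor binding —
and clicked tumor-bound ligand releases back to the clicked blood pool
at k_off.  This symmetry is required for the model's own consistency:
in the limit lag → 0, k_deact → 0, k_int → 0, k_click → ∞ the labelled
pool must follow one-step kinetics, and the test suite verifies that
the tumor fraction-of-injected curves then coincide.  All species are
tracked in nmol with exact mass balance for both the vector and the
ligand (verified to 10⁻⁶ relative); activity follows ligand-bearing
species with physical decay applied at output.

**Noise.**  Between-animal variability is multiplicative lognormal
(mean-1 factors) per animal × organ × time with CV 0.15 by default,
matching the mean-proportional ±SD scatter of real biodistribution
data.  What the generator does not emulate: within-animal correlation
across organs, cage/batch effects, assay detection limits, dynamic
target expression between cohorts, and additional organs beyond blood,
kidney and tumor — so passing tests demonstrate correctness of the
pipeline under the stated statistical model, not robustness to every
feature of real data.

**Default calibration.**  k_ren = 1.0/h (sdAb blood half-life ≈ 40 min),
f_kid = 0.45, k_kid_rel = 0.075/h, k_on = 5/(nmol·h), B_max = 0.5 nmol,
k_off = 0.02/h, k_int = 0.08/h, k_deact = 0.05/h,
k_click = 0.5/(nmol·h), k_Lren = 2.5/h, f_Lkid = 0.012, lag 8 h,
vector 16 nmol (200 µg at ~12.5 kDa), ligand 2 nmol; organ masses
blood 1.5 g, kidney 0.3 g, tumor 0.15 g for a 20–25 g mouse (assumed,
not measured).  The calibration was chosen so the simulator reproduces
the qualitative physiology of sdAb pretargeting: kidney cumulated
activity drops steeply and monotonically as the lag grows from 0.5 to
8 h (the vector has cleared the blood before the radioligand arrives),
the pretargeted tumor cumulated activity is ~0.6× the one-step arm
(internalization and TCO loss cost capture), and the tumor-to-kidney
ratio peaks at the 8-h lag — shorter lags pay a kidney penalty from
blood-pool clicking, longer lags lose tumor capture to deactivation.
These are behavioral targets of the design, not fitted quantities.

**Fitting.**  `fit_params` does bounded least squares on log-scale
activities (multiplicative noise becomes additive) with ≥ 5 starts from
a seeded Latin hypercube over log-scale bounds, plus the nominal start
when inside bounds.  Only {k_ren, f_kid, k_kid_rel, k_on, k_off} are
identifiable from a single one-step study; requesting click-layer
parameters raises an error naming the needed design (two-step data at
≥ 2 lag times).  A log-residual RMS above 0.8 flags the fit as poor
(e.g. mislabelled organs) instead of returning silently.  Standard
errors come from the linearized covariance at the optimum.

## Numerical choices

ODEs are solved with LSODA at rtol 10⁻⁸ / atol 10⁻¹² on the study time
grid, giving cross-platform reproducibility well below the noise scale;
equality-style tests compare at solver precision (10⁻⁹) rather than
exactly.  All parsing is locale-independent (decimal point).  Organ
labels are case-folded through an editable synonym map; unknown labels
pass through with a logged warning.  Seeds are threaded through
`numpy.random.SeedSequence` spawning so replicate studies are
independent but fully determined by one integer.

## Problem sizes

The validation studies use 5 animals per time point at 4–5 time points
per cohort (typical for mouse biodistribution), 100 replicates for the
parameter-recovery study and 2000 null replicates for the log-rank
calibration — sizes chosen as the smallest that make the Monte-Carlo
error small relative to the tolerances being checked.

## Known limitations

The dose model ignores photon cross-dose unless S-values are supplied;
the simulator is a minimal mechanistic sketch (no whole-body PBPK, no
immunogenicity, no coupling of dose to tumor growth); the tail model
assumes terminal mono-exponential kinetics; TI uncertainty is not
propagated from dose SDs; and the two-step model does not deplete
reactive sites on capture (ligand ≪ sites in the calibrated regime).
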