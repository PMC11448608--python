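import numpy as np
import pytest
from dataclasses import replace

from predosim.nuclides import LU177
from predosim.pksim import (
    DEFAULT_PRETARGET_PARAMS,
    NoiseModel,
    PretargetParams,
    fit_params,
    simulate_conventional,
    simulate_pretargeting,
    solve_conventional,
    solve_pretargeting,
    sweep,
)

TIMES = np.array([1.0, 4.0, 24.0, 48.0, 72.0])


class TestConventional:
    def test_no_binding_means_no_tumor_signal(self):
        p = replace(DEFAULT_PRETARGET_PARAMS, k_on=0.0)
        study = simulate_conventional(p, times_h=TIMES, n_per_time=2,
                                      noise=NoiseModel(cv=0.1, seed=3))
        tumor = study.measurements.query("organ == 'tumor'")["pct_ia_per_g"]
        assert np.all(tumor == 0.0)

    def test_zero_cv_identical_animals(self):
        study = simulate_conventional(times_h=TIMES, n_per_time=3,
                                      noise=NoiseModel(cv=0.0, seed=0))
        spread = study.measurements.groupby(["organ", "time_h"])["pct_ia_per_g"].std()
        assert np.allclose(spread, 0.0)

    def test_linear_submodel_matches_closed_form(self):
        # k_on = 0: blood is a single exponential and the kidney is the
        # classic two-compartment chain with analytic solution
        p = replace(DEFAULT_PRETARGET_PARAMS, k_on=0.0)
        sol = solve_conventional(p, TIMES)
        a, b, f, V = p.k_ren, p.k_kid_rel, p.f_kid, p.vector_nmol
        blood = V * np.exp(-a * TIMES)
        kidney = f * a * V * (np.exp(-a * TIMES) - np.exp(-b * TIMES)) / (b - a)
        assert np.allclose(sol["C_b"], blood, rtol=1e-3)
        assert np.allclose(sol["K"], kidney, rtol=1e-3)

    def test_mass_balance(self):
        sol = solve_conventional(DEFAULT_PRETARGET_PARAMS, TIMES)
        total = sol[["C_b", "T", "K", "X"]].sum(axis=1)
        assert np.allclose(total, DEFAULT_PRETARGET_PARAMS.vector_nmol, rtol=1e-6)

    def test_tumor_bound_monotone_in_vector_and_saturates(self):
        # k_off = 0: bound amount increases with injected amount and
        # cannot exceed the binding capacity B_max
        p0 = replace(DEFAULT_PRETARGET_PARAMS, k_off=0.0)
        peaks = []
        for vn in (0.1, 0.5, 2.0, 8.0, 32.0):
            sol = solve_conventional(replace(p0, vector_nmol=vn), TIMES)
            peaks.append(sol["T"].max())
        assert np.all(np.diff(peaks) >= -1e-9)
        assert peaks[-1] <= p0.B_max * (1 + 1e-6)


class TestPretargeting:
    def test_vector_and_ligand_mass_balance(self):
        sol = solve_pretargeting(DEFAULT_PRETARGET_PARAMS, TIMES)
        p = DEFAULT_PRETARGET_PARAMS
        vec = sol[["C_b", "S", "I", "Kv", "Xv", "Bc", "P", "Kc", "Xc"]].sum(axis=1)
        lig = sol[["L", "Bc", "P", "Kc", "Xc", "Kf", "Xf"]].sum(axis=1)
        # phase-1 vector losses live in Kv/Xv carried into phase 2
        assert np.allclose(vec, p.vector_nmol, rtol=1e-6)
        assert np.allclose(lig, p.ligand_nmol, rtol=1e-6)

    def test_radioactivity_balance_physical_scale(self):
        # physical activity x exp(+lambda t) equals the conserved
        # (decay-corrected) ligand total across all compartments
        p = DEFAULT_PRETARGET_PARAMS
        sol = solve_pretargeting(p, TIMES)
        lam = LU177.lambda_phys
        physical = sol[["L", "Bc", "P", "Kc", "Xc", "Kf", "Xf"]].sum(axis=1).to_numpy() \
            * np.exp(-lam * TIMES)
        assert np.allclose(physical * np.exp(lam * TIMES), p.ligand_nmol, rtol=1e-6)

    def test_no_click_equals_ligand_alone_exactly(self):
        p = replace(DEFAULT_PRETARGET_PARAMS, k_click=0.0)
        with_vector = solve_pretargeting(p, TIMES)
        no_vector = solve_pretargeting(replace(p, vector_nmol=0.0), TIMES)
        # identical up to ODE solver tolerance
        for col in ("blood_act", "tumor_act", "kidney_act"):
            assert np.allclose(with_vector[col], no_vector[col], atol=1e-9)

    def test_long_lag_converges_to_ligand_alone(self):
        p = replace(DEFAULT_PRETARGET_PARAMS, lag_h=500.0)
        long_lag = solve_pretargeting(p, TIMES)
        control = solve_pretargeting(replace(p, vector_nmol=0.0), TIMES)
        for col in ("blood_act", "tumor_act", "kidney_act"):
            assert np.allclose(long_lag[col], control[col], atol=1e-6)

    def test_instant_click_limit_approaches_one_step_tumor(self):
        # lag = 0, no TCO loss, no internalization, k_click large:
        # essentially all radioligand clicks onto blood vector at once,
        # so the labelled pool follows one-step vector kinetics and the
        # tumor fraction-of-injected curves coincide
        p = replace(
            DEFAULT_PRETARGET_PARAMS,
            lag_h=0.0, k_deact=0.0, k_int=0.0, k_click=500.0,
        )
        pre = solve_pretargeting(p, TIMES)
        conv = solve_conventional(replace(p), TIMES)
        frac_pre = pre["tumor_act"].to_numpy() / p.ligand_nmol
        frac_conv = conv["T"].to_numpy() / p.vector_nmol
        assert np.allclose(frac_pre, frac_conv, rtol=0.02)

    def test_study_flags_and_clock(self):
        study = simulate_pretargeting(times_h=TIMES, n_per_time=2,
                                      noise=NoiseModel(cv=0.1, seed=5))
        assert not study.decay_corrected  # physical %IA/g
        assert study.lag_time_h == DEFAULT_PRETARGET_PARAMS.lag_h
        assert set(study.organs) == {"blood", "kidney", "tumor"}


class TestSweep:
    def test_single_cell_equals_direct_simulation(self):
        from predosim.tac import auc_table

        seed = 9
        table = sweep(lags_h=[8.0], vector_nmol=[16.0], reps=1, seed=seed,
                      times_h=TIMES, n_per_time=3, cv=0.1)
        child = int(
            np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31)
        )
        study = simulate_pretargeting(
            replace(DEFAULT_PRETARGET_PARAMS, lag_h=8.0, vector_nmol=16.0),
            times_h=TIMES, n_per_time=3, noise=NoiseModel(cv=0.1, seed=child),
        )
        auc = auc_table(study, organs=["kidney", "tumor"]).set_index("organ")
        assert table["kidney_auc"].iloc[0] == pytest.approx(auc.loc["kidney", "value"])
        assert table["tumor_auc"].iloc[0] == pytest.approx(auc.loc["tumor", "value"])

    def test_fixed_seed_bit_identical(self):
        a = sweep(lags_h=[2.0, 8.0], reps=2, seed=4, times_h=TIMES, n_per_time=2)
        b = sweep(lags_h=[2.0, 8.0], reps=2, seed=4, times_h=TIMES, n_per_time=2)
        assert a.equals(b)


class TestFitParams:
    def test_noiseless_self_consistency(self):
        truth = replace(DEFAULT_PRETARGET_PARAMS, k_ren=1.4, k_off=0.05)
        study = simulate_conventional(
            truth, times_h=[1.0, 4.0, 24.0, 72.0], n_per_time=1,
            noise=NoiseModel(cv=0.0, seed=0),
        )
        # start away from the truth so recovery is not trivial
        start = replace(truth, k_ren=0.3, k_off=0.4)
        fit = fit_params(study, free=("k_ren", "k_off"), start=start, seed=1)
        assert fit.estimates["k_ren"] == pytest.approx(1.4, rel=0.01)
        assert fit.estimates["k_off"] == pytest.approx(0.05, rel=0.01)
        assert not fit.poor_fit

    def test_click_parameters_rejected_for_one_step(self):
        study = simulate_conventional(times_h=[1.0, 4.0, 24.0], n_per_time=1,
                                      noise=NoiseModel(cv=0.0, seed=0))
        with pytest.raises(ValueError, match="lag"):
            fit_params(study, free=("k_ren", "k_click"))

    def test_swapped_organ_labels_flagged(self):
        study = simulate_conventional(times_h=[1.0, 4.0, 24.0, 72.0], n_per_time=2,
                                      noise=NoiseModel(cv=0.05, seed=2))
        m = study.measurements.copy()
        m["organ"] = m["organ"].map(
            {"blood": "kidney", "kidney": "blood", "tumor": "tumor"}
        )
        swapped = replace_measurements(study, m)
        fit = fit_params(swapped, free=("k_ren", "f_kid"), seed=3)
        assert fit.poor_fit


def replace_measurements(study, measurements):
    from dataclasses import replace as dc_replace

    out = dc_replace(study)
    out.measurements = measurements.reset_index(drop=True)
    return out
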