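import numpy as np
import pytest

from polypk.pk_core import (
    DoseEvent,
    DosingRegimen,
    PKParameters,
    auc,
    auc_ss_analytic,
    concentration,
    cumulative_auc,
    first_day_window,
    steady_state_window,
)

from .oracles import ode_auc, ode_concentration

TABLE_PARAMS = PKParameters(V=11.24, V2=39.70, CL=2.86, Q=7.36)


def _single_dose(amount=100.0, rate=100.0):
    return DosingRegimen(events=(DoseEvent(0.0, amount, rate),))


def test_no_dose_gives_zero_everywhere():
    reg = DosingRegimen(events=())
    assert concentration(TABLE_PARAMS, reg, 5.0) == 0.0
    assert auc(TABLE_PARAMS, reg, 0.0, 100.0) == 0.0


def test_near_bolus_one_compartment_limit():
    # Q -> 0 decouples the peripheral compartment; a 0.01 h infusion of
    # 100 mg then gives C ~ Dose/V at the end of the infusion
    p = PKParameters(V=11.24, V2=39.70, CL=2.86, Q=1e-9)
    reg = _single_dose(100.0, 100.0 / 0.01)
    c = concentration(p, reg, 0.01)
    assert c == pytest.approx(100.0 / 11.24, rel=2e-3)


def test_concentration_matches_ode_oracle_on_table_parameters():
    reg = _single_dose(100.0, 100.0)  # 100 mg over 1 h
    times = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 8.0, 24.0])
    closed = np.asarray(concentration(TABLE_PARAMS, reg, times))
    numeric = ode_concentration(TABLE_PARAMS, reg, times)
    np.testing.assert_allclose(closed, numeric, rtol=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_random_params_regimens_match_ode_oracle(seed):
    """Closed form vs stiff integrator on random draws (conc and AUC)."""
    rng = np.random.default_rng(seed)
    p = PKParameters(
        V=rng.uniform(5, 50),
        V2=rng.uniform(5, 200),
        CL=rng.uniform(0.5, 10),
        Q=rng.uniform(0.5, 20),
    )
    reg = DosingRegimen.loading_plus_q12h(
        loading_mg=rng.uniform(50, 300),
        maintenance_mg=rng.uniform(25, 150),
        infusion_rate=50.0,
        horizon=48.0,
    )
    times = np.sort(rng.uniform(0.1, 48.0, size=8))
    np.testing.assert_allclose(
        np.asarray(concentration(p, reg, times)),
        ode_concentration(p, reg, times),
        rtol=1e-6, atol=1e-12,
    )
    t0, t1 = np.sort(rng.uniform(0.0, 48.0, size=2))
    if t1 - t0 > 0.5:
        assert auc(p, reg, t0, t1) == pytest.approx(ode_auc(p, reg, t0, t1), rel=1e-5)


def test_auc_to_infinity_equals_dose_over_clearance():
    assert auc(TABLE_PARAMS, _single_dose(), 0.0, 1e5) == pytest.approx(100.0 / 2.86, rel=1e-6)


def test_steady_state_daily_auc_approaches_dose_over_cl():
    reg = DosingRegimen.loading_plus_q12h(100.0, 100.0, infusion_rate=100.0, horizon=2000.0)
    a = auc(TABLE_PARAMS, reg, 1900.0, 1924.0)
    assert a == pytest.approx(200.0 / 2.86, rel=1e-4)


def test_auc_additivity():
    reg = DosingRegimen.loading_plus_q12h(200.0, 100.0, horizon=96.0)
    total = auc(TABLE_PARAMS, reg, 0.0, 96.0)
    split = auc(TABLE_PARAMS, reg, 0.0, 37.3) + auc(TABLE_PARAMS, reg, 37.3, 96.0)
    assert split == pytest.approx(total, rel=1e-10)


def test_linearity_in_dose():
    reg = DosingRegimen.loading_plus_q12h(200.0, 100.0, horizon=96.0)
    double = reg.scaled(2.0)
    t = np.array([1.0, 13.0, 75.0])
    np.testing.assert_allclose(
        np.asarray(concentration(TABLE_PARAMS, double, t)),
        2.0 * np.asarray(concentration(TABLE_PARAMS, reg, t)),
        rtol=1e-12,
    )
    assert auc(TABLE_PARAMS, double, 72, 96) == pytest.approx(
        2 * auc(TABLE_PARAMS, reg, 72, 96), rel=1e-12
    )


def test_mass_balance_in_bolus_limit():
    # immediately after a very short infusion all drug is in the central
    # compartment: V·C(0+) = dose
    p = TABLE_PARAMS
    reg = _single_dose(100.0, 100.0 / 1e-5)
    c = concentration(p, reg, 1e-5)
    assert 11.24 * c == pytest.approx(100.0, rel=1e-3)


def test_terminal_slope_equals_minus_beta():
    p = TABLE_PARAMS
    _, beta = p.hybrid_constants()
    beta = float(beta)
    reg = _single_dose(100.0, 100.0)
    t = np.linspace(1.0 + 3.0 / beta, 1.0 + 5.0 / beta, 50)
    logc = np.log(np.asarray(concentration(p, reg, t)))
    slope = np.polyfit(t, logc, 1)[0]
    assert slope == pytest.approx(-beta, rel=1e-3)


def test_degenerate_equal_roots_stay_finite():
    # parameters contrived so alpha ~ beta; the nudged formulation must not
    # produce NaN/inf and should stay close to the ODE oracle
    p = PKParameters(V=10.0, V2=10.0, CL=1.0, Q=0.1)
    k10, _, k21 = p.micro_constants()
    reg = _single_dose(100.0, 100.0)
    t = np.array([0.5, 1.0, 5.0, 20.0])
    c = np.asarray(concentration(p, reg, t))
    assert np.all(np.isfinite(c)) and np.all(c >= 0)
    np.testing.assert_allclose(c, ode_concentration(p, reg, t), rtol=1e-5)


def test_continuity_across_infusion_end():
    reg = _single_dose(100.0, 100.0)
    eps = 1e-9
    before = concentration(TABLE_PARAMS, reg, 1.0 - eps)
    after = concentration(TABLE_PARAMS, reg, 1.0 + eps)
    assert after == pytest.approx(before, rel=1e-6)


def test_windows():
    assert steady_state_window() == (72.0, 96.0)
    assert steady_state_window(sampling_day=1) == (0.0, 24.0)
    assert first_day_window() == (0.0, 24.0)
    t0, t1 = steady_state_window(sampling_day=4)
    assert t1 - t0 == 24.0


def test_analytic_ss_shortcut():
    assert auc_ss_analytic(TABLE_PARAMS, 200.0) == pytest.approx(69.93, abs=0.01)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        PKParameters(V=0.0, V2=1.0, CL=1.0, Q=1.0)
    with pytest.raises(ValueError):
        DoseEvent(0.0, -5.0, 50.0)
    with pytest.raises(ValueError):
        auc(TABLE_PARAMS, _single_dose(), 5.0, 5.0)


def test_vectorized_parameters_broadcast():
    n = 7
    p = PKParameters(
        V=np.full(n, 11.24), V2=np.linspace(10, 100, n),
        CL=np.linspace(1, 5, n), Q=np.full(n, 7.36),
    )
    reg = DosingRegimen.loading_plus_q12h(200.0, 100.0, horizon=96.0)
    a = np.asarray(auc(p, reg, 72.0, 96.0))
    assert a.shape == (n,)
    # each element equals the scalar computation
    p0 = PKParameters(V=11.24, V2=10.0, CL=1.0, Q=7.36)
    assert a[0] == pytest.approx(auc(p0, reg, 72.0, 96.0), rel=1e-12)
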