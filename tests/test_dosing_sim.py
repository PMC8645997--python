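import numpy as np
import pandas as pd
import pytest

from polypk.dosing_sim import (
    MIC_GRID,
    RegimenSpec,
    analytic_target_probability,
    exposure_probabilities,
    fixed_regimen_set,
    pta,
    simulate_exposures,
    table3_report,
    weight_based_regimen_set,
)


def test_fixed_regimen_sets():
    methods = fixed_regimen_set("methods")
    assert [(r.loading_mg, r.maintenance_mg) for r in methods] == [
        (100, 50), (150, 75), (200, 100), (250, 125), (300, 150)
    ]
    labels = fixed_regimen_set("table_labels")
    assert [(r.loading_mg, r.maintenance_mg) for r in labels][3:] == [(200, 125), (200, 150)]
    with pytest.raises(ValueError):
        fixed_regimen_set("bogus")


def test_weight_based_set_composition():
    regs = weight_based_regimen_set()
    assert len(regs) == 18
    tbw120 = [r for r in regs if r.weight_basis == "TBW" and r.weight_kg == 120]
    assert sorted(r.maintenance_mg for r in tbw120) == [150.0, 180.0]
    assert all(r.loading_mg == 300.0 for r in tbw120)  # 2.5 mg/kg x 120


def test_regimen_build_uses_50mgh_infusions():
    spec = RegimenSpec.fixed(300.0, 150.0)
    reg = spec.build(horizon=96.0)
    assert reg.events[0].duration == pytest.approx(6.0)  # 300 mg at 50 mg/h
    assert reg.events[1].start_time == 12.0
    assert len(reg.events) == 8  # loading + 7 maintenance before 96 h


def test_typical_subject_without_iiv_hits_accumulation_value(final_model):
    import dataclasses

    frozen = dataclasses.replace(final_model, omega2={"CL": 0.0, "V2": 0.0, "Q": 0.0})
    exp = simulate_exposures(frozen, RegimenSpec.fixed(200.0, 100.0), n=10, rng=0)
    # day-4 window sits slightly below the analytic steady state 200/2.86
    assert np.allclose(exp["auc_ss24"], exp["auc_ss24"].iloc[0])
    assert exp["auc_ss24"].iloc[0] == pytest.approx(200.0 / 2.86, rel=0.02)
    assert exp["auc_ss24"].iloc[0] < 200.0 / 2.86


def test_analytic_steady_state_mode(final_model):
    exp = simulate_exposures(final_model, RegimenSpec.fixed(200.0, 100.0),
                             n=2000, rng=4, ss_mode="analytic")
    np.testing.assert_allclose(exp["auc_ss24"], 200.0 / exp["CL"], rtol=1e-12)


def test_analytic_target_probability_closed_form(final_model):
    from scipy.stats import norm

    p = analytic_target_probability(final_model, 200.0)
    expected = norm.cdf((np.log(4) - np.log(2.86)) / np.sqrt(0.17)) - norm.cdf(
        (np.log(2) - np.log(2.86)) / np.sqrt(0.17)
    )
    assert p == pytest.approx(expected, abs=1e-12)
    assert p == pytest.approx(0.599, abs=1e-3)


def test_exposure_probability_trivia_and_boundaries():
    all_in = pd.DataFrame({"auc_ss24": np.full(10, 75.0)})
    probs = exposure_probabilities(all_in)
    assert probs["p_target"] == 100.0
    assert probs["p_toxicity"] == 0.0
    # inclusive target window, strict toxicity threshold
    edge = pd.DataFrame({"auc_ss24": [50.0, 100.0, 100.0000001, 49.999]})
    probs = exposure_probabilities(edge)
    assert probs["p_target"] == pytest.approx(50.0)
    assert probs["p_toxicity"] == pytest.approx(25.0)
    with pytest.raises(ValueError):
        exposure_probabilities(pd.DataFrame({"auc_ss24": []}))


def test_pta_monotone_in_mic(final_model):
    exp = simulate_exposures(final_model, RegimenSpec.fixed(150.0, 75.0), n=500, rng=2)
    vals = pta(exp)
    grid = list(vals)
    assert grid == sorted(grid)
    assert all(vals[grid[i]] >= vals[grid[i + 1]] for i in range(len(grid) - 1))
    assert 0.0 <= min(vals.values()) and max(vals.values()) <= 100.0


def test_pta_scale_equivariance(final_model):
    exp = simulate_exposures(final_model, RegimenSpec.fixed(150.0, 75.0), n=300, rng=8)
    doubled = exp.copy()
    doubled["auc_0_24"] = 2 * doubled["auc_0_24"]
    assert pta(doubled, mic_grid=(1.0,))[1.0] == pta(exp, mic_grid=(0.5,))[0.5]
    with pytest.raises(ValueError):
        pta(exp, mic_grid=())


def test_toxicity_nondecreasing_in_maintenance_dose(final_model):
    tox = []
    for spec in fixed_regimen_set():
        exp = simulate_exposures(final_model, spec, n=500, rng=11)
        tox.append(exposure_probabilities(exp)["p_toxicity"])
    assert tox == sorted(tox)


def test_table3_report_layout_and_reproducibility(final_model):
    t1, long1 = table3_report(final_model, n=200, rng=17)
    t2, long2 = table3_report(final_model, n=200, rng=17)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(long1, long2)
    assert len(t1) == 5 + 18  # five fixed + 18 weight-based rows
    for mic in MIC_GRID:
        assert f"pta_mic_{mic:g}" in t1.columns
    assert set(long1["regimen"]) == set(t1["regimen"])


def test_low_dose_gives_negligible_target_probability(final_model):
    tiny = simulate_exposures(final_model, RegimenSpec.fixed(1.0, 0.5), n=300, rng=3)
    probs = exposure_probabilities(tiny)
    assert probs["p_target"] == 0.0
    assert probs["p_toxicity"] == 0.0
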