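import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from polypk.diagnostics import cwres, pc_vpc
from polypk.estimation import ModelSpec, fit
from polypk.population_model import PopulationModel
from polypk.synthetic_data import StudyDesign, generate_cohort


def _runs_test_p(signs: np.ndarray) -> float:
    """Wald-Wolfowitz runs test p-value on a boolean sequence."""
    n1 = int(signs.sum())
    n2 = int(len(signs) - n1)
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2 * n1 * n2 / (n1 + n2) + 1
    var = 2 * n1 * n2 * (2 * n1 * n2 - n1 - n2) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    z = (runs - mu) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def test_cwres_reduces_to_weighted_residuals_without_random_effects(study_cohort):
    model = PopulationModel(omega2={}, sigma=0.24)
    tab = cwres(study_cohort, model)
    expected = (tab["DV"] - tab["PRED"]) / (0.24 * tab["PRED"])
    np.testing.assert_allclose(tab["CWRES"], expected, rtol=1e-9)
    assert np.allclose(tab["PRED"], tab["IPRED"])


def test_cwres_calibrated_on_self_simulated_data(final_model):
    # ~1000 observations simulated from the model evaluated at the truth
    design = StudyDesign(n_subjects=143, fraction_rich=1.0)
    ds = generate_cohort(design, final_model, 21)
    tab = cwres(ds, final_model)
    assert len(tab) == len(ds.without_blq().observations())
    assert abs(tab["CWRES"].mean()) < 0.1
    assert abs(tab["CWRES"].std() - 1.0) < 0.15
    assert np.all(np.isfinite(tab["CWRES"]))


def test_cwres_detects_structural_misspecification(final_model, fast_settings):
    """A one-compartment fit to two-compartment data leaves a time trend."""
    design = StudyDesign(n_subjects=40, fraction_rich=1.0)
    detected = 0
    for seed in (1, 2, 3):
        ds = generate_cohort(design, final_model, seed)
        spec1 = ModelSpec(
            random_effects=("CL",),
            fixed_theta={"V2": 1.0, "Q": 1e-4},  # peripheral compartment disabled
        )
        res = fit(ds, settings=fast_settings, spec=spec1)
        tab = cwres(ds, res).sort_values("TIME")
        p = _runs_test_p(tab["CWRES"].to_numpy() > 0)
        detected += p < 0.05
    assert detected >= 2


def test_pc_vpc_correction_is_identity_under_homogeneous_dosing(final_model):
    design = StudyDesign(n_subjects=20, fraction_rich=1.0,
                         loading_choices=(200.0,), maintenance_choices=(100.0,))
    ds = generate_cohort(design, final_model, 6)
    res = pc_vpc(ds, final_model, n_replicates=100, rng=0)
    obs = ds.without_blq().observations()
    # identical regimens => PRED constant within bin => corrected == raw
    raw_median_at_peak = obs[obs["TIME"] == 73.0]["DV"].median()
    row = res.table[res.table["bin_time"] == 1.0].iloc[0]
    assert row["obs_p50"] == pytest.approx(raw_median_at_peak, rel=1e-9)


def test_pc_vpc_bands_ordered_and_self_consistent(study_cohort, final_model):
    res = pc_vpc(study_cohort, final_model, n_replicates=400, rng=9)
    t = res.table
    for p in (5, 50, 95):
        assert (t[f"sim_p{p}_lo"] <= t[f"sim_p{p}_hi"]).all()
    # data were simulated from this very model: the observed median should
    # sit inside its band in nearly all bins
    inside = res.observed_within_band(50)
    assert inside.mean() >= 0.85
    assert t["n_obs"].sum() == len(study_cohort.without_blq().observations())


def test_pc_vpc_flags_gross_model_error(study_cohort, final_model):
    wrong = final_model.with_theta(CL=2 * 2.86)
    res = pc_vpc(study_cohort, wrong, n_replicates=300, rng=9)
    assert not res.observed_within_band(50).all()


def test_pc_vpc_band_width_shrinks_with_replicates(study_cohort, final_model):
    narrow = pc_vpc(study_cohort, final_model, n_replicates=1000, rng=5)
    wide = pc_vpc(study_cohort, final_model, n_replicates=100, rng=5)
    w_narrow = (narrow.table["sim_p50_hi"] - narrow.table["sim_p50_lo"]).mean()
    w_wide = (wide.table["sim_p50_hi"] - wide.table["sim_p50_lo"]).mean()
    assert w_narrow <= w_wide * 1.1


def test_pc_vpc_rejects_too_few_replicates(study_cohort, final_model):
    with pytest.raises(ValueError):
        pc_vpc(study_cohort, final_model, n_replicates=50)


def test_plot_files_created(tmp_path, study_cohort, final_model, study_fit):
    from polypk.diagnostics import gof_panels, vpc_plot

    tab = cwres(study_cohort, study_fit)
    gof_path = tmp_path / "gof.png"
    gof_panels(tab, str(gof_path))
    assert gof_path.exists() and gof_path.stat().st_size > 0
    res = pc_vpc(study_cohort, final_model, n_replicates=100, rng=1)
    vpc_path = tmp_path / "vpc.png"
    vpc_plot(res, str(vpc_path))
    assert vpc_path.exists() and vpc_path.stat().st_size > 0
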