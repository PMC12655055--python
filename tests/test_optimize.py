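"""Therapeutic-window regimen evaluation and dose optimization."""

import numpy as np
import pytest

from hfpbpk import (Regimen, SamplingSpec, WindowSpec, evaluate_regimen,
                    optimize_dose, sample_cohort, steady_state)


@pytest.fixture(scope="module")
def small_cohort(glycoside):
    return sample_cohort(glycoside.drug,
                         SamplingSpec(seed=21, n_subjects=30))


def test_unreachable_toxic_threshold_gives_zero_fraction(small_cohort,
                                                         glycoside_model):
    window = WindowSpec(toxic_threshold=1e9, effective_threshold=0.5)
    report = evaluate_regimen(small_cohort, glycoside_model,
                              Regimen.qd(0.25), window)
    assert report.fraction_cmax_over_toxic == 0.0
    assert report.n_subjects == 30


def test_single_subject_trough_fraction(glycoside, glycoside_model):
    cohort = sample_cohort(glycoside.drug,
                           SamplingSpec(seed=1, n_subjects=1,
                                        lower_frac=1.0, upper_frac=1.0))
    ss = steady_state(glycoside_model, Regimen.qd(0.25))
    trough = ss.plasma_conc_ng_ml.min()
    window = WindowSpec(toxic_threshold=1e9,
                        effective_threshold=trough * 0.9)
    report = evaluate_regimen(cohort, glycoside_model, Regimen.qd(0.25),
                              window)
    assert report.fraction_cmin_over_effective == 1.0
    assert report.cmin[0] == pytest.approx(trough, rel=1e-9)


def test_bid_lowers_peak_raises_trough(small_cohort, glycoside_model):
    """Splitting the same daily dose reduces peak-trough fluctuation."""
    qd = evaluate_regimen(small_cohort, glycoside_model, Regimen.qd(0.25))
    bid = evaluate_regimen(small_cohort, glycoside_model,
                           Regimen.bid(0.125))
    assert np.all(bid.cmax < qd.cmax)
    assert np.all(bid.cmin > qd.cmin)


def test_optimizer_unconstrained_returns_top_of_grid(small_cohort,
                                                     glycoside_model):
    grid = np.round(np.arange(0.005, 0.2001, 0.005), 10)
    window = WindowSpec(toxic_threshold=np.inf, effective_threshold=0.5)
    regimen, report = optimize_dose(small_cohort, glycoside_model,
                                    frequency="bid", window=window,
                                    dose_grid=grid)
    assert regimen.events[0].amount == pytest.approx(grid[-1])


def test_optimizer_closed_form_on_one_compartment_toy(uniform_toy_model):
    """For the near-one-compartment IV toy the steady-state peak is the
    post-bolus venous concentration D/V_ven on top of the well-mixed
    carryover trough D*e^(-k*tau)/(V*(1-e^(-k*tau))); the optimizer must
    land on the analytic maximal safe dose (snapped down to the grid)."""
    phys = uniform_toy_model.physiology
    drug = uniform_toy_model.drug
    cohort = sample_cohort(drug, SamplingSpec(seed=3, n_subjects=1,
                                              lower_frac=1.0,
                                              upper_frac=1.0))
    v_ml = sum(phys.volume(t) for t in phys.tissues)  # uniform ktp = 1
    a = drug.fu_b * drug.cl_kidney_int
    q = phys.flow("kidney")
    cl_ml_min = q * a / (q + a)
    k_per_h = cl_ml_min * 60.0 / v_ml
    tau = 24.0
    toxic = 2.0  # ng/mL
    trough_unit = (1e6 / v_ml) * (np.exp(-k_per_h * tau)
                                  / (1.0 - np.exp(-k_per_h * tau)))
    cmax_unit = 1e6 / phys.volume("venous_blood") + trough_unit
    analytic_dose = toxic / cmax_unit
    grid = np.round(np.arange(0.0001, 0.02, 0.0001), 10)
    window = WindowSpec(toxic_threshold=toxic, effective_threshold=1e-6)
    regimen, report = optimize_dose(cohort, uniform_toy_model,
                                    frequency="qd", window=window,
                                    dose_grid=grid, route="iv_bolus",
                                    allow_bid_fallback=False)
    got = regimen.events[0].amount
    expected = grid[grid * cmax_unit < toxic][-1]
    assert got == pytest.approx(expected, abs=0.00011)
    assert got == pytest.approx(analytic_dose, rel=0.05)
    assert report.fraction_cmax_over_toxic == 0.0


def test_window_fractions_monotone_in_dose(small_cohort, glycoside_model):
    doses = [0.1, 0.2, 0.4, 0.8]
    over_toxic, over_eff = [], []
    for d in doses:
        rep = evaluate_regimen(small_cohort, glycoside_model,
                               Regimen.qd(d))
        over_toxic.append(rep.fraction_cmax_over_toxic)
        over_eff.append(rep.fraction_cmin_over_effective)
    assert np.all(np.diff(over_toxic) >= 0)
    assert np.all(np.diff(over_eff) >= 0)


def test_optimum_satisfies_safety_for_all_subjects(small_cohort,
                                                   glycoside_model):
    regimen, report = optimize_dose(small_cohort, glycoside_model,
                                    frequency="bid")
    assert report.fraction_cmax_over_toxic == 0.0
    assert np.all(report.cmax < report.window.toxic_threshold)
    # one grid step higher would break the constraint for someone
    step_up = regimen.events[0].amount + 0.005
    rep_up = evaluate_regimen(small_cohort, glycoside_model,
                              Regimen.bid(step_up), report.window)
    assert rep_up.fraction_cmax_over_toxic > 0.0


def test_box_whisker_summary(small_cohort, glycoside_model):
    report = evaluate_regimen(small_cohort, glycoside_model,
                              Regimen.qd(0.25))
    bw = report.box_whisker()
    assert list(bw["metric"]) == ["cmax", "cmin"]
    row = bw.iloc[0]
    assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] \
        <= row["max"]


def test_window_validation():
    with pytest.raises(ValueError):
        WindowSpec(toxic_threshold=0.4, effective_threshold=0.5)
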