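"""Partition-coefficient prediction against independent closed forms."""

import numpy as np
import pytest

from hfpbpk import DrugParameters, PartitionSet, ktp_to_ktb, predict_ktp
from hfpbpk.partition import TissueComposition


def neutral(logp=1.26, fu_p=0.71, rb=1.0):
    return DrugParameters(name="probe", cl_liver_int=10.0,
                          cl_kidney_int=10.0, fu_p=fu_p, rb=rb, peff=1.0,
                          logp=logp, ion_class="neutral")


def test_limiting_case_composition_sum():
    """P = 1, fu_p = 1, no ionization, no protein binding: k_tp collapses to
    total water plus lipid fractions."""
    comp = {"blob": TissueComposition("blob", f_ew=0.2, f_iw=0.4, f_nl=0.1,
                                      f_np=0.05, ap_mg_g=0.0, ratio_alb=0.0,
                                      ratio_lip=0.0)}
    ps = predict_ktp(neutral(logp=0.0, fu_p=1.0), composition=comp,
                     method="rodgers")
    assert ps.ktp["blob"] == pytest.approx(0.2 + 0.4 + 0.1 + 0.05, rel=1e-12)


@pytest.mark.parametrize("tissue,f_ew,f_iw,f_nl,f_np,r_alb", [
    ("muscle", 0.118, 0.630, 0.0100, 0.0072, 0.064),
    ("adipose", 0.135, 0.017, 0.8440, 0.0016, 0.049),
    ("liver", 0.161, 0.573, 0.0348, 0.0252, 0.086),
])
def test_neutral_oracle(tissue, f_ew, f_iw, f_nl, f_np, r_alb):
    """Closed-form spreadsheet-style evaluation of the neutral equations,
    written out independently with the frozen composition constants."""
    logp, fu_p = 1.26, 0.71
    p = 10.0 ** logp
    p_mem = 0.3 * p + 0.7
    plasma_lipid = p * 0.0023 + p_mem * 0.0013
    kpu = (f_ew + f_iw + p * f_nl + p_mem * f_np
           + (1.0 / fu_p - 1.0 - plasma_lipid) * r_alb)
    expected = kpu * fu_p
    ps = predict_ktp(neutral(logp=logp, fu_p=fu_p), method="rodgers")
    assert ps.ktp[tissue] == pytest.approx(expected, rel=1e-12)


def test_ruark_differs_but_preserves_lipophilic_ranking():
    drug = neutral(logp=2.5)
    rodgers = predict_ktp(drug, method="rodgers").ktp
    ruark = predict_ktp(drug, method="ruark").ktp
    assert any(abs(rodgers[t] - ruark[t]) > 1e-6 for t in rodgers)
    lipo = ["adipose", "skin", "muscle"]
    assert (np.argsort([rodgers[t] for t in lipo]).tolist()
            == np.argsort([ruark[t] for t in lipo]).tolist())


def test_dose_independence_and_determinism():
    drug = neutral()
    a = predict_ktp(drug, method="rodgers").ktp
    b = predict_ktp(drug, method="rodgers").ktp
    assert a == b


@pytest.mark.parametrize("method", ["rodgers", "ruark"])
def test_fu_p_monotonicity(method):
    """k_tp varies monotonically over a fu_p grid, and the unbound-referenced
    partition grows without bound as plasma binding tightens."""
    grid = np.linspace(0.05, 1.0, 12)
    for tissue in ("muscle", "adipose", "kidney"):
        ktps = np.array([predict_ktp(neutral(fu_p=f), method=method)
                         .ktp[tissue] for f in grid])
        diffs = np.diff(ktps)
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)
        kpu = ktps / grid
        assert np.all(np.diff(kpu) < 0)  # Kpu increases as fu_p -> 0


def test_strong_base_uses_acidic_phospholipid_route():
    base = DrugParameters(name="base", cl_liver_int=10.0, cl_kidney_int=1.0,
                          fu_p=0.1, rb=1.1, peff=1.0, logp=2.0,
                          ion_class="monoprotic base", pka=9.0)
    weak = DrugParameters(name="weak", cl_liver_int=10.0, cl_kidney_int=1.0,
                          fu_p=0.1, rb=1.1, peff=1.0, logp=2.0,
                          ion_class="monoprotic base", pka=6.0)
    strong_kp = predict_ktp(base).ktp
    weak_kp = predict_ktp(weak).ktp
    # acidic-phospholipid-rich tissues partition much more strongly for the
    # strong base than the albumin route gives the weak base
    assert strong_kp["kidney"] > weak_kp["kidney"]
    assert all(v > 0 for v in strong_kp.values())


def test_acid_partitions_below_neutral_of_same_logp():
    acid = DrugParameters(name="acid", cl_liver_int=1.0, cl_kidney_int=1.0,
                          fu_p=0.5, rb=0.6, peff=1.0, logp=2.0,
                          ion_class="monoprotic acid", pka=4.0)
    neut = neutral(logp=2.0, fu_p=0.5)
    kp_acid = predict_ktp(acid).ktp
    kp_neut = predict_ktp(neut).ktp
    # ionization at physiological pH keeps the acid out of cells
    assert kp_acid["muscle"] < kp_neut["muscle"]


def test_override_bypasses_prediction_bit_exactly():
    ktp = {"muscle": 20.0, "lung": 2.0}
    ps = PartitionSet(ktp=dict(ktp), method="override")
    assert ps.ktp == ktp


def test_ktp_to_ktb_arithmetic():
    ps = PartitionSet(ktp={"a": 2.0, "b": 0.5}, method="override")
    assert ktp_to_ktb(ps, 1.0).ktb == {"a": 2.0, "b": 0.5}
    assert ktp_to_ktb(ps, 0.8).ktb["a"] == pytest.approx(2.5)
    assert ktp_to_ktb(ps, 2.0).ktb["b"] == pytest.approx(0.25)
    with pytest.raises(ValueError):
        ktp_to_ktb(ps, 0.0)


def test_error_paths():
    with pytest.raises(ValueError, match="unknown partition method"):
        predict_ktp(neutral(), method="nonsense")
    with pytest.raises(ValueError):
        PartitionSet(ktp={"muscle": -1.0})
    with pytest.raises(ValueError, match="requires a pKa"):
        DrugParameters(name="x", cl_liver_int=1, cl_kidney_int=1, fu_p=0.5,
                       rb=1.0, peff=1.0, logp=1.0,
                       ion_class="monoprotic acid")
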