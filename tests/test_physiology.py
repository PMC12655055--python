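"""Reconstruction of the published HF blood-flow table and flow closure."""

import pytest

from hfpbpk import (DEFAULT_FRACTIONS, Physiology, TissueSpec, apply_hf,
                    total_systemic_flow)
from hfpbpk.physiology import HEPATIC_GROUP, PERIPHERAL_GROUP
from hfpbpk.reference_data import (SYSTEMIC_TISSUES,
                                   TISSUE_VOLUMES_70KG_ML)

# Published per-class tissue blood flows, mL/min (70-kg subject).
PUBLISHED_FLOWS = {
    "II": {"lung": 4399.58, "muscle": 427.5, "adipose": 148.2, "skin": 171.0,
           "kidney": 967.2, "liver": 228.0, "spleen": 60.8, "stomach": 28.88,
           "duodenum": 89.68, "jejunum": 313.88, "ileum": 185.44,
           "cecum": 33.44, "colon": 213.56, "heart": 240.0, "brain": 700.0,
           "rest_of_body": 592.0},
    "III": {"lung": 3610.12, "muscle": 330.0, "adipose": 114.4,
            "skin": 132.0, "kidney": 682.0, "liver": 162.0, "spleen": 43.2,
            "stomach": 20.52, "duodenum": 63.72, "jejunum": 223.02,
            "ileum": 131.76, "cecum": 23.76, "colon": 151.74, "heart": 240.0,
            "brain": 700.0, "rest_of_body": 592.0},
    "IV": {"lung": 3378.28, "muscle": 210.0, "adipose": 72.8, "skin": 84.0,
           "kidney": 781.2, "liver": 138.0, "spleen": 36.8, "stomach": 17.48,
           "duodenum": 54.28, "jejunum": 189.98, "ileum": 112.24,
           "cecum": 20.24, "colon": 129.26, "heart": 240.0, "brain": 700.0,
           "rest_of_body": 592.0},
}


def test_healthy_baseline_key_flows(healthy):
    assert healthy.flow("heart") == 240.0
    assert healthy.flow("brain") == 700.0
    assert healthy.flow("rest_of_body") == 592.0
    assert healthy.flow("liver") == pytest.approx(300.0)   # 228 / 0.76
    assert healthy.flow("kidney") == pytest.approx(1240.0)  # 967.2 / 0.78
    assert healthy.cardiac_output == pytest.approx(5600.0)


@pytest.mark.parametrize("hf_class", ["II", "III", "IV"])
def test_hf_table_reconstruction(healthy, hf_class):
    """Every published flow cell is reproduced to within 0.01 mL/min."""
    phys = apply_hf(healthy, hf_class)
    for tissue, expected in PUBLISHED_FLOWS[hf_class].items():
        assert phys.flow(tissue) == pytest.approx(expected, abs=0.01), tissue


@pytest.mark.parametrize("hf_class", ["II", "III", "IV"])
def test_flow_closure(healthy, hf_class):
    phys = apply_hf(healthy, hf_class)
    lung = phys.cardiac_output
    assert abs(lung - total_systemic_flow(phys)) / lung < 1e-9


@pytest.mark.parametrize("hf_class", ["II", "III", "IV"])
def test_fraction_round_trip(healthy, hf_class):
    """apply_hf / baseline recovers the printed fractions per tissue group."""
    phys = apply_hf(healthy, hf_class)
    frac = DEFAULT_FRACTIONS.for_class(hf_class)
    for t in HEPATIC_GROUP:
        assert phys.flow(t) / healthy.flow(t) == pytest.approx(
            frac["hepatic_splanchnic"])
    assert phys.flow("kidney") / healthy.flow("kidney") == pytest.approx(
        frac["renal"])
    for t in PERIPHERAL_GROUP:
        assert phys.flow(t) / healthy.flow(t) == pytest.approx(
            frac["skin_adipose_muscle"])
    for t in ("heart", "brain", "rest_of_body"):
        assert phys.flow(t) == healthy.flow(t)
    for t in phys.tissues:
        assert phys.volume(t) == healthy.volume(t)


def test_healthy_class_is_identity(healthy):
    same = apply_hf(healthy, "healthy")
    for t in healthy.tissues:
        assert same.flow(t) == healthy.flow(t)


def test_apply_hf_rejects_unknown_class_and_nonhealthy_base(healthy):
    with pytest.raises(ValueError, match="unknown HF class"):
        apply_hf(healthy, "V")
    with pytest.raises(ValueError, match="healthy baseline"):
        apply_hf(apply_hf(healthy, "II"), "III")


def test_total_systemic_flow_arithmetic():
    """Only heart/brain/ROB perfused: systemic sum is their plain total."""
    tissues = {}
    keep = {"heart": 240.0, "brain": 700.0, "rest_of_body": 592.0}
    for name in SYSTEMIC_TISSUES:
        tissues[name] = TissueSpec(name, TISSUE_VOLUMES_70KG_ML[name],
                                   keep.get(name, 0.0))
    tissues["lung"] = TissueSpec("lung", TISSUE_VOLUMES_70KG_ML["lung"],
                                 1532.0)
    tissues["arterial_blood"] = TissueSpec("arterial_blood", 1800.0)
    tissues["venous_blood"] = TissueSpec("venous_blood", 3400.0)
    phys = Physiology(tissues=tissues)
    assert total_systemic_flow(phys) == 1532.0


def test_scaled_flow_restores_closure(healthy):
    scaled = healthy.with_scaled_flow("muscle", 3.0)
    assert scaled.flow("muscle") == pytest.approx(2250.0)
    assert scaled.cardiac_output == pytest.approx(
        total_systemic_flow(scaled))


def test_yaml_round_trip(tmp_path, healthy):
    path = tmp_path / "phys.yaml"
    phys = apply_hf(healthy, "IV")
    phys.to_yaml(path)
    back = Physiology.from_yaml(path)
    assert back.hf_class == "IV"
    for t in phys.tissues:
        assert back.flow(t) == phys.flow(t)
        assert back.volume(t) == phys.volume(t)


def test_tissue_spec_invariants():
    with pytest.raises(ValueError):
        TissueSpec("muscle", volume=-1.0, blood_flow=10.0)
    with pytest.raises(ValueError):
        TissueSpec("muscle", volume=100.0, blood_flow=-1.0)
    with pytest.raises(ValueError):
        TissueSpec("venous_blood", volume=100.0, blood_flow=5.0)
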