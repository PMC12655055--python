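"""Healthy and heart-failure physiologies for a 70-kg subject.

A :class:`Physiology` is a set of tissues with volumes (mL) and blood flows
(mL/min). Heart failure is modelled purely hemodynamically: NYHA class II/III/
IV physiologies are derived from the healthy baseline by scaling tissue blood
flows with published perfusion fractions (hepatic & splanchnic, renal, and
skin/adipose/muscle groups), leaving heart, brain and rest-of-body flows and
all tissue volumes unchanged. Pulmonary (total) flow is always recomputed as
the sum of systemic tissue flows, so the circulatory mass balance closes
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .reference_data import (
    ALL_TISSUES,
    BASELINE_FLOWS_ML_MIN,
    BLOOD_COMPARTMENTS,
    SPLANCHNIC_TISSUES,
    SYSTEMIC_TISSUES,
    TISSUE_VOLUMES_70KG_ML,
)

HF_CLASSES = ("healthy", "II", "III", "IV")

#: Tissues whose flow scales with the hepatic fraction (portal system + liver).
HEPATIC_GROUP = ("liver",) + SPLANCHNIC_TISSUES
#: Tissues whose flow scales with the peripheral fraction.
PERIPHERAL_GROUP = ("skin", "adipose", "muscle")
#: Flows held constant across HF classes.
UNCHANGED_GROUP = ("heart", "brain", "rest_of_body")


@dataclass
class TissueSpec:
    """One tissue: volume (mL) and blood flow (mL/min).

    Blood pools (arterial/venous) carry volume only; their ``blood_flow``
    is fixed at 0 because circulation is driven by the tissue flows.
    """

    name: str
    volume: float
    blood_flow: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValueError(f"{self.name}: blood_flow must be >= 0")
        if self.name in BLOOD_COMPARTMENTS and self.blood_flow != 0.0:
            raise ValueError(
                f"{self.name}: blood pools carry no independent flow entry")


@dataclass
class PerfusionFractions:
    """Per-class fractional reductions of regional blood flow.

    Each mapping is HF class -> fraction of the healthy flow retained.
    ``hepatic_splanchnic`` also governs the gastrointestinal and splenic
    flows, which change in parallel with hepatic flow.
    """

    hepatic_splanchnic: dict = field(
        default_factory=lambda: {"healthy": 1.0, "II": 0.76, "III": 0.54,
                                 "IV": 0.46})
    renal: dict = field(
        default_factory=lambda: {"healthy": 1.0, "II": 0.78, "III": 0.55,
                                 "IV": 0.63})
    skin_adipose_muscle: dict = field(
        default_factory=lambda: {"healthy": 1.0, "II": 0.57, "III": 0.44,
                                 "IV": 0.28})

    def __post_init__(self) -> None:
        for name in ("hepatic_splanchnic", "renal", "skin_adipose_muscle"):
            mapping = getattr(self, name)
            for cls, frac in mapping.items():
                if not 0 < frac <= 1:
                    raise ValueError(
                        f"{name}[{cls}] = {frac}: fraction must be in (0, 1]")
            if mapping.get("healthy", 1.0) != 1.0:
                raise ValueError(f"{name}: healthy fraction must be 1")

    def for_class(self, hf_class: str) -> dict:
        if hf_class not in HF_CLASSES:
            raise ValueError(f"unknown HF class {hf_class!r}; "
                             f"expected one of {HF_CLASSES}")
        return {
            "hepatic_splanchnic": self.hepatic_splanchnic[hf_class],
            "renal": self.renal[hf_class],
            "skin_adipose_muscle": self.skin_adipose_muscle[hf_class],
        }


DEFAULT_FRACTIONS = PerfusionFractions()


@dataclass
class Physiology:
    """Whole-body physiology: tissues keyed by name, plus disease class."""

    tissues: dict
    hf_class: str = "healthy"
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        if self.hf_class not in HF_CLASSES:
            raise ValueError(f"unknown HF class {self.hf_class!r}")
        missing = set(ALL_TISSUES) - set(self.tissues)
        if missing:
            raise ValueError(f"missing tissues: {sorted(missing)}")
        lung = self.tissues["lung"].blood_flow
        systemic = self.total_systemic_flow()
        if abs(lung - systemic) > 1e-9 * max(lung, 1.0):
            raise ValueError(
                f"flow closure violated: lung {lung} vs systemic sum "
                f"{systemic}")

    def total_systemic_flow(self) -> float:
        """Sum of arterial blood flows over all systemic tissues, mL/min."""
        return sum(self.tissues[t].blood_flow for t in SYSTEMIC_TISSUES)

    @property
    def cardiac_output(self) -> float:
        """Pulmonary blood flow (= total systemic flow), mL/min."""
        return self.tissues["lung"].blood_flow

    def flow(self, name: str) -> float:
        return self.tissues[name].blood_flow

    def volume(self, name: str) -> float:
        return self.tissues[name].volume

    @property
    def liver_inflow(self) -> float:
        """Total liver inlet flow: hepatic artery + portal (splanchnic) vein."""
        return self.flow("liver") + sum(self.flow(t)
                                        for t in SPLANCHNIC_TISSUES)

    def with_scaled_flow(self, name: str, fold: float) -> "Physiology":
        """Return a copy with one tissue flow rescaled and closure restored."""
        if fold <= 0:
            raise ValueError("flow scale factor must be > 0")
        if name not in SYSTEMIC_TISSUES:
            raise ValueError(f"{name!r} is not a systemic tissue")
        tissues = {k: replace(v) for k, v in self.tissues.items()}
        tissues[name].blood_flow *= fold
        lung_flow = sum(tissues[t].blood_flow for t in SYSTEMIC_TISSUES)
        tissues["lung"].blood_flow = lung_flow
        return Physiology(tissues=tissues, hf_class=self.hf_class,
                          body_weight=self.body_weight)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "hf_class": self.hf_class,
            "body_weight_kg": self.body_weight,
            "tissues": {
                name: {"volume_ml": t.volume,
                       "blood_flow_ml_min": t.blood_flow}
                for name, t in self.tissues.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Physiology":
        tissues = {
            name: TissueSpec(name=name, volume=v["volume_ml"],
                             blood_flow=v.get("blood_flow_ml_min", 0.0))
            for name, v in d["tissues"].items()
        }
        return cls(tissues=tissues, hf_class=d.get("hf_class", "healthy"),
                   body_weight=d.get("body_weight_kg", 70.0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Physiology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_healthy(volumes: dict | None = None,
                  flows: dict | None = None) -> Physiology:
    """Construct the healthy 70-kg reference physiology.

    Parameters
    ----------
    volumes, flows
        Optional overrides (mL, mL/min) merged over the packaged reference
        tables.
    """
    vols = dict(TISSUE_VOLUMES_70KG_ML)
    if volumes:
        vols.update(volumes)
    flw = dict(BASELINE_FLOWS_ML_MIN)
    if flows:
        flw.update(flows)
    tissues = {}
    for name in SYSTEMIC_TISSUES:
        tissues[name] = TissueSpec(name, vols[name], flw[name])
    lung_flow = sum(tissues[t].blood_flow for t in SYSTEMIC_TISSUES)
    tissues["lung"] = TissueSpec("lung", vols["lung"], lung_flow)
    for name in BLOOD_COMPARTMENTS:
        tissues[name] = TissueSpec(name, vols[name], 0.0)
    return Physiology(tissues=tissues, hf_class="healthy")


def apply_hf(base: Physiology, hf_class: str,
             fractions: PerfusionFractions = DEFAULT_FRACTIONS) -> Physiology:
    """Derive an HF-class physiology by scaling regional blood flows.

    Liver and the splanchnic organs scale with the hepatic fraction, kidney
    with the renal fraction, skin/adipose/muscle with the peripheral fraction;
    heart, brain and rest-of-body are unchanged, volumes are unchanged, and
    the pulmonary flow is recomputed as the systemic sum.
    """
    if base.hf_class != "healthy":
        raise ValueError("apply_hf expects a healthy baseline physiology")
    frac = fractions.for_class(hf_class)
    tissues = {k: replace(v) for k, v in base.tissues.items()}
    for name in HEPATIC_GROUP:
        tissues[name].blood_flow *= frac["hepatic_splanchnic"]
    tissues["kidney"].blood_flow *= frac["renal"]
    for name in PERIPHERAL_GROUP:
        tissues[name].blood_flow *= frac["skin_adipose_muscle"]
    lung_flow = sum(tissues[t].blood_flow for t in SYSTEMIC_TISSUES)
    tissues["lung"].blood_flow = lung_flow
    return Physiology(tissues=tissues, hf_class=hf_class,
                      body_weight=base.body_weight)


def total_systemic_flow(p: Physiology) -> float:
    """Sum of systemic tissue blood flows (equals pulmonary flow), mL/min."""
    return p.total_systemic_flow()
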