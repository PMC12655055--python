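"""Mechanistic tissue:plasma partition coefficient (Kt:p) prediction.

Two composition-based routes are provided:

``rodgers``
    The mechanistic equations of the Rodgers/Rowland framework: tissue water
    accessed according to ionization at intracellular vs plasma pH,
    octanol-calibrated neutral-lipid partitioning, a membrane (neutral
    phospholipid) term ``0.3*P + 0.7``, acidic-phospholipid association for
    moderate-to-strong bases (association constant recovered from the
    blood-cell partition implied by ``rb``), and albumin-type protein
    binding for neutrals, acids, weak bases and zwitterions.

``ruark``
    A calibrated variant of the same framework in which neutral-lipid
    partitioning uses the vegetable-oil:water relation
    ``log Kvo:w = 1.115*logP - 1.35`` instead of raw octanol; ionization and
    protein terms are handled identically.

Both return the plasma-referenced ``k_tp``; the blood-referenced ``k_tb``
(used by the flow equations) is ``k_tp / rb``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .drugs import DrugParameters
from .reference_data import (
    BLOOD_CELL_COMPOSITION,
    PH,
    PLASMA_COMPOSITION,
    TISSUE_COMPOSITION,
)

#: Monoprotic bases at or above this pKa use the acidic-phospholipid route.
STRONG_BASE_PKA = 7.0


@dataclass
class TissueComposition:
    """Fractional composition of one tissue for partition prediction."""

    name: str
    f_ew: float          # extracellular water fraction
    f_iw: float          # intracellular water fraction
    f_nl: float          # neutral lipid fraction
    f_np: float          # neutral phospholipid fraction
    ap_mg_g: float       # acidic phospholipid concentration, mg/g
    ratio_alb: float     # tissue:plasma albumin ratio
    ratio_lip: float     # tissue:plasma lipoprotein ratio

    def __post_init__(self) -> None:
        for attr in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValueError(f"{self.name}.{attr} = {v} outside [0, 1]")
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: water + lipid fractions exceed 1")


def default_composition() -> dict[str, TissueComposition]:
    """Packaged composition table keyed by tissue name."""
    return {
        name: TissueComposition(name, *values)
        for name, values in TISSUE_COMPOSITION.items()
    }


@dataclass
class PartitionSet:
    """Tissue -> partition coefficients; plasma (k_tp) and blood (k_tb)."""

    ktp: dict
    ktb: dict | None = None
    method: str = "override"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tissue, v in self.ktp.items():
            if v <= 0:
                raise ValueError(f"k_tp[{tissue}] must be > 0")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tissue": t, "k_tp": self.ktp[t],
             "k_tb": (self.ktb or {}).get(t)}
            for t in self.ktp
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ionization(drug: DrugParameters, ph: float) -> float:
    """1 + sum of ionized:neutral ratios at the given pH."""
    if drug.ion_class == "neutral":
        return 1.0
    if drug.ion_class == "monoprotic acid":
        return 1.0 + 10.0 ** (ph - drug.pka)
    if drug.ion_class == "monoprotic base":
        return 1.0 + 10.0 ** (drug.pka - ph)
    # zwitterion: pka is (acidic, basic)
    pka_a, pka_b = drug.pka
    return 1.0 + 10.0 ** (ph - pka_a) + 10.0 ** (pka_b - ph)


def _is_strong_base(drug: DrugParameters) -> bool:
    return (drug.ion_class == "monoprotic base"
            and drug.pka is not None and drug.pka >= STRONG_BASE_PKA)


def _lipid_affinity(logp: float, method: str) -> float:
    """Neutral-lipid partition coefficient for the chosen route."""
    if method == "rodgers":
        return 10.0 ** logp
    if method == "ruark":
        return 10.0 ** (1.115 * logp - 1.35)
    raise ValueError(f"unknown partition method {method!r}")


def predict_ktp(drug: DrugParameters,
                composition: dict[str, TissueComposition] | None = None,
                method: str = "rodgers",
                hematocrit: float = 0.45) -> PartitionSet:
    """Predict k_tp for every tissue in the composition table.

    Deterministic and dose-independent. Raises for an unknown method or for
    a zwitterion whose pKa is not an (acidic, basic) pair.
    """
    comp = composition if composition is not None else default_composition()
    p_nl = _lipid_affinity(drug.logp, method)
    p_mem = 0.3 * p_nl + 0.7
    y_p = _ionization(drug, PH["plasma"])
    plasma_lipid = (p_nl * PLASMA_COMPOSITION["f_nl"]
                    + p_mem * PLASMA_COMPOSITION["f_np"])

    ka_ap = None
    if _is_strong_base(drug):
        # Recover the acidic-phospholipid association constant from the
        # blood-cell partition implied by the blood:plasma ratio.
        bc = BLOOD_CELL_COMPOSITION
        kpu_bc = (hematocrit - 1.0 + drug.rb) / (hematocrit * drug.fu_p)
        x_bc = _ionization(drug, PH["blood_cell"])
        ka_ap = (kpu_bc * y_p - x_bc * bc["f_iw"]
                 - (p_nl * bc["f_nl"] + p_mem * bc["f_np"]))
        ka_ap /= bc["ap_mg_g"] * 10.0 ** (drug.pka - PH["blood_cell"])
        ka_ap = max(ka_ap, 0.0)

    ktp = {}
    for name, t in comp.items():
        x_iw = _ionization(drug, PH["intracellular"])
        kpu = t.f_ew + (x_iw / y_p) * t.f_iw
        kpu += (p_nl * t.f_nl + p_mem * t.f_np) / y_p
        if ka_ap is not None:
            kpu += (ka_ap * t.ap_mg_g
                    * 10.0 ** (drug.pka - PH["intracellular"])) / y_p
        else:
            bound = 1.0 / drug.fu_p - 1.0 - plasma_lipid / y_p
            kpu += bound * t.ratio_alb
        ktp[name] = max(kpu * drug.fu_p, 1e-6)
    return PartitionSet(ktp=ktp, method=method,
                        metadata={"drug": drug.name, "method": method,
                                  "hematocrit": hematocrit})


def ktp_to_ktb(ps: PartitionSet, rb: float) -> PartitionSet:
    """Populate blood-referenced coefficients, k_tb = k_tp / rb."""
    if rb <= 0:
        raise ValueError("rb must be > 0")
    return PartitionSet(
        ktp=dict(ps.ktp),
        ktb={t: v / rb for t, v in ps.ktp.items()},
        method=ps.method,
        metadata={**ps.metadata, "rb": rb},
    )
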