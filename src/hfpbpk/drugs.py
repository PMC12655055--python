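"""Drug-specific parameters.

Clearances are intrinsic (enzyme/transporter capacity, mL/min), combined
with organ blood flow and blood binding by the well-stirred model inside the
disposition model. The unbound fraction in blood is always derived as
``fu_b = fu_p / rb`` so plasma binding and the blood:plasma ratio stay
consistent; population sampling perturbs ``fu_p`` with ``rb`` fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

from .reference_data import SEGMENT_RADII_CM

ION_CLASSES = ("neutral", "monoprotic acid", "monoprotic base", "zwitterion")

ABSORBING_SEGMENTS = ("duodenum", "jejunum", "ileum")


@dataclass
class DrugParameters:
    """Physicochemical and kinetic parameters of one compound.

    Parameters
    ----------
    cl_liver_int, cl_kidney_int : float
        Intrinsic hepatic / renal clearance, mL/min.
    cl_gutwall : float
        Per-segment intestinal-wall intrinsic clearance, mL/min (default 0).
    fu_p : float
        Unbound fraction in plasma, (0, 1].
    rb : float
        Blood:plasma concentration ratio, > 0.
    peff : float
        Effective intestinal permeability, units of 1e-4 cm/s.
    ka_override : float or None
        If set, first-order absorption constant (1/h) applied uniformly to
        duodenum/jejunum/ileum instead of the permeability-derived values.
    logp : float
        Octanol:water log partition coefficient.
    pka : float or None
        Dissociation constant (None for neutrals).
    ion_class : str
        One of ``neutral``, ``monoprotic acid``, ``monoprotic base``,
        ``zwitterion``.
    """

    name: str
    cl_liver_int: float
    cl_kidney_int: float
    fu_p: float
    rb: float
    peff: float
    logp: float
    ion_class: str = "neutral"
    pka: float | None = None
    cl_gutwall: float = 0.0
    ka_override: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fu_p <= 1:
            raise ValueError("fu_p must be in (0, 1]")
        if self.rb <= 0:
            raise ValueError("rb must be > 0")
        for attr in ("cl_liver_int", "cl_kidney_int", "cl_gutwall"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.peff < 0:
            raise ValueError("peff must be >= 0")
        if self.ion_class not in ION_CLASSES:
            raise ValueError(f"unknown ion_class {self.ion_class!r}")
        if self.ion_class != "neutral" and self.pka is None:
            raise ValueError(f"{self.ion_class} requires a pKa")

    @property
    def fu_b(self) -> float:
        """Unbound fraction in whole blood, derived fu_p / rb."""
        return self.fu_p / self.rb

    def ka_per_segment(self, radii_cm: dict | None = None) -> dict:
        """First-order absorption constants (1/h) per absorbing segment.

        Without an override, k_a,i = 2 * Peff / r_i with packaged segment
        radii; Peff is supplied in 1e-4 cm/s so the result is converted to
        1/h.
        """
        if self.ka_override is not None:
            return {seg: self.ka_override for seg in ABSORBING_SEGMENTS}
        radii = dict(SEGMENT_RADII_CM)
        if radii_cm:
            radii.update(radii_cm)
        return {
            seg: 2.0 * self.peff * 1e-4 / radii[seg] * 3600.0
            for seg in ABSORBING_SEGMENTS
        }

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DrugParameters":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DrugParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "DrugParameters":
        d = self.to_dict()
        d.update(changes)
        return DrugParameters(**d)
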