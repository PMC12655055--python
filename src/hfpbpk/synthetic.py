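"""Synthetic drug fixtures and simulated "observed" datasets.

The compound archetypes emulate the parameter classes exercised by the
pipeline without reproducing any proprietary drug file:

``renal_neutral_digoxin_like``
    A neutral, renally cleared, narrow-window cardiac glycoside analogue:
    low hepatic and renal extraction, very large distribution volume with
    high muscle/skin/adipose affinity (supplied as a partition override,
    standing in for transporter-driven binding a composition-based
    prediction cannot produce), fu_p drawn from the literature-reported set
    {0.61, 0.71, 0.95}.

``hepatic_midazolam_like``
    An intermediate-extraction, hepatically cleared weak base whose
    partitions come from the mechanistic prediction.

``diuretic_acid_like``
    A highly protein-bound monoprotic acid cleared by renal secretion with
    a hepatic component.

All values are synthetic, chosen at literature-typical magnitudes; output
metadata labels them as such. Observations are generated by simulating one
cohort-drawn subject, subsampling to a sparse clinical schedule and
applying multiplicative lognormal error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drugs import DrugParameters
from .model import PBPKModel, Regimen, simulate
from .nca import ConcentrationProfile
from .partition import PartitionSet, ktp_to_ktb, predict_ktp
from .physiology import Physiology
from .population import SamplingSpec, sample_cohort
from .reference_data import DEFAULT_TRANSIT_PER_H

ARCHETYPES = ("renal_neutral_digoxin_like", "hepatic_midazolam_like",
              "diuretic_acid_like")

#: Default sparse clinical sampling schedule, h post dose.
CLINICAL_TIMES_H = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

#: Synthetic transporter-inflated partition override for the glycoside
#: archetype (tissue:plasma, unitless).
_GLYCOSIDE_KTP = {
    "lung": 2.0, "muscle": 20.0, "adipose": 9.0, "skin": 12.0,
    "kidney": 15.0, "liver": 10.0, "spleen": 5.0, "stomach": 6.0,
    "duodenum": 6.0, "jejunum": 6.0, "ileum": 6.0, "cecum": 6.0,
    "colon": 6.0, "heart": 15.0, "brain": 1.5, "rest_of_body": 4.0,
}


@dataclass
class DrugFixture:
    """A complete synthetic test compound."""

    archetype: str
    drug: DrugParameters
    partitions: PartitionSet
    transit_per_h: dict
    regimens: dict
    metadata: dict = field(default_factory=dict)

    def to_model(self, physiology: Physiology) -> PBPKModel:
        return PBPKModel(physiology=physiology, drug=self.drug,
                         partitions=self.partitions,
                         transit_per_h=dict(self.transit_per_h))


@dataclass
class SyntheticObservation:
    """Sparse noisy observations plus the generating ground truth."""

    profile: ConcentrationProfile
    truth: ConcentrationProfile
    multipliers: dict
    noise_cv: float
    seed: int


def make_fixture(archetype: str, seed: int = 0) -> DrugFixture:
    """Build a synthetic drug fixture (deterministic per seed)."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; "
                         f"expected one of {ARCHETYPES}")
    rng = np.random.default_rng(seed)
    if archetype == "renal_neutral_digoxin_like":
        fu_p = float(rng.choice([0.61, 0.71, 0.95]))
        drug = DrugParameters(
            name="digoxin_like", cl_liver_int=70.0, cl_kidney_int=240.0,
            fu_p=fu_p, rb=1.0, peff=1.0, logp=1.26, ion_class="neutral")
        partitions = ktp_to_ktb(
            PartitionSet(ktp=dict(_GLYCOSIDE_KTP), method="override",
                         metadata={"synthetic": True,
                                   "note": "transporter-inflated override"}),
            drug.rb)
        regimens = {"oral_qd": Regimen.qd(0.25),
                    "oral_bid": Regimen.bid(0.125),
                    "iv_single": Regimen.single("iv_bolus", 0.5)}
    elif archetype == "hepatic_midazolam_like":
        drug = DrugParameters(
            name="midazolam_like", cl_liver_int=26000.0, cl_kidney_int=10.0,
            fu_p=0.03, rb=0.66, peff=4.0, logp=3.1,
            ion_class="monoprotic base", pka=6.0)
        partitions = ktp_to_ktb(predict_ktp(drug, method="rodgers"), drug.rb)
        regimens = {"oral_single": Regimen.single("oral", 7.5),
                    "iv_single": Regimen.single("iv_bolus", 5.0)}
    else:  # diuretic_acid_like
        drug = DrugParameters(
            name="loop_diuretic_like", cl_liver_int=1150.0,
            cl_kidney_int=2300.0, fu_p=0.02, rb=0.55, peff=0.3, logp=2.03,
            ion_class="monoprotic acid", pka=3.9)
        partitions = ktp_to_ktb(predict_ktp(drug, method="rodgers"), drug.rb)
        regimens = {"oral_single": Regimen.single("oral", 40.0),
                    "iv_infusion": Regimen.single("iv_infusion", 40.0,
                                                  duration=0.05)}
    return DrugFixture(
        archetype=archetype, drug=drug, partitions=partitions,
        transit_per_h=dict(DEFAULT_TRANSIT_PER_H), regimens=regimens,
        metadata={"synthetic": True, "archetype": archetype, "seed": seed})


def perturbed_fixture(fixture: DrugFixture,
                      rng: np.random.Generator) -> DrugFixture:
    """Random variant of a fixture for property-style checks.

    Clearances and permeability are scaled log-uniformly over [0.5, 2];
    fu_p over [0.8, 1.2] capped at 1.
    """
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    drug = fixture.drug.replace(
        cl_liver_int=fixture.drug.cl_liver_int * lu(0.5, 2.0),
        cl_kidney_int=fixture.drug.cl_kidney_int * lu(0.5, 2.0),
        peff=fixture.drug.peff * lu(0.5, 2.0),
        fu_p=min(fixture.drug.fu_p * lu(0.8, 1.2), 1.0))
    return DrugFixture(
        archetype=fixture.archetype, drug=drug,
        partitions=fixture.partitions,
        transit_per_h=dict(fixture.transit_per_h),
        regimens=fixture.regimens,
        metadata={**fixture.metadata, "perturbed": True})


def random_fixture(seed: int) -> DrugFixture:
    """Archetype chosen and perturbed from one seed."""
    rng = np.random.default_rng(seed)
    archetype = ARCHETYPES[int(rng.integers(len(ARCHETYPES)))]
    return perturbed_fixture(make_fixture(archetype, seed=seed), rng)


def make_observations(fixture: DrugFixture, physiology: Physiology,
                      regimen: Regimen, noise_cv: float = 0.2,
                      sample_times_h: tuple = CLINICAL_TIMES_H,
                      seed: int = 0,
                      t_end: float | None = None,
                      typical: bool = False) -> SyntheticObservation:
    """Noisy sparse observations from one cohort-drawn subject.

    The generating subject's multipliers are drawn from the standard
    80-120% cohort distribution (or fixed at 1.0 with ``typical=True``);
    residual error is multiplicative lognormal with the given CV
    (median-unbiased, so the geometric mean of observed/true ratios tends
    to 1).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    spec = (SamplingSpec(seed=seed, n_subjects=1, lower_frac=1.0,
                         upper_frac=1.0) if typical
            else SamplingSpec(seed=seed, n_subjects=1))
    cohort = sample_cohort(fixture.drug, spec)
    drug = cohort.subject_drug(fixture.drug, 0)
    model = PBPKModel(physiology=physiology, drug=drug,
                      partitions=fixture.partitions,
                      transit_per_h=dict(fixture.transit_per_h))
    last = max(e.time + (e.duration or 0.0) for e in regimen.events)
    t_end = t_end if t_end is not None else last + max(sample_times_h)
    times = np.array([t for t in sample_times_h if t <= t_end])
    res = simulate(model, regimen, t_end, output_times=times)
    truth = res.plasma_conc_ng_ml
    rng = np.random.default_rng(seed + 1)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
        obs = truth * rng.lognormal(mean=0.0, sigma=sigma, size=len(times))
    else:
        obs = truth.copy()
    dose = regimen.total_dose
    return SyntheticObservation(
        profile=ConcentrationProfile(times, obs, dose=dose,
                                     label="synthetic_observed"),
        truth=ConcentrationProfile(times, truth, dose=dose,
                                   label="synthetic_truth"),
        multipliers={p: float(cohort.draws.iloc[0][p])
                     for p in cohort.spec.parameters},
        noise_cv=noise_cv, seed=seed)
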