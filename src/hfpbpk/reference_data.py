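"""Packaged physiological reference tables.

All tables refer to a 70-kg adult reference subject. Flows are mL/min, volumes
mL. The healthy blood-flow table is the unique baseline from which the
published NYHA class II-IV flow tables are recovered by the perfusion
fractions in :mod:`hfpbpk.physiology` (each class cell equals baseline times
its class fraction, e.g. kidney 1240 * 0.78 = 967.2 mL/min).

The tissue-volume table is a synthetic stand-in assembled from standard
reference-man anatomy; rest-of-body closes total body volume at unit density
(70 000 mL minus the named tissues and blood pools). The tissue-composition
table carries the standard fractional water/lipid contents and binding terms
used by mechanistic tissue:plasma partition predictions; values follow the
commonly reused composition compilations of the mechanistic Kt:p literature
and can be overridden through config.
"""

from __future__ import annotations

# Tissues perfused directly from arterial blood; their flow sum is the
# pulmonary (total) blood flow. "liver" here is the hepatic arterial supply;
# splanchnic organs drain through the portal vein into the liver.
SYSTEMIC_TISSUES = (
    "muscle", "adipose", "skin", "kidney", "liver", "spleen", "stomach",
    "duodenum", "jejunum", "ileum", "cecum", "colon", "heart", "brain",
    "rest_of_body",
)

SPLANCHNIC_TISSUES = (
    "spleen", "stomach", "duodenum", "jejunum", "ileum", "cecum", "colon",
)

BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")

ALL_TISSUES = ("lung",) + SYSTEMIC_TISSUES + BLOOD_COMPARTMENTS

#: Healthy 70-kg baseline tissue blood flows, mL/min. Cardiac output
#: (= lung flow) is the systemic sum, 5600 mL/min.
BASELINE_FLOWS_ML_MIN = {
    "muscle": 750.0,        # 427.5 / 0.57
    "adipose": 260.0,       # 148.2 / 0.57
    "skin": 300.0,          # 171 / 0.57
    "kidney": 1240.0,       # 967.2 / 0.78
    "liver": 300.0,         # hepatic artery; 228 / 0.76
    "spleen": 80.0,         # 60.8 / 0.76
    "stomach": 38.0,        # 28.88 / 0.76
    "duodenum": 118.0,      # 89.68 / 0.76
    "jejunum": 413.0,       # 313.88 / 0.76
    "ileum": 244.0,         # 185.44 / 0.76
    "cecum": 44.0,          # 33.44 / 0.76
    "colon": 281.0,         # 213.56 / 0.76
    "heart": 240.0,         # unchanged across HF classes
    "brain": 700.0,         # unchanged across HF classes
    "rest_of_body": 592.0,  # unchanged across HF classes
}

#: Synthetic stand-in 70-kg reference tissue volumes, mL (unit density).
#: rest_of_body = 70000 - sum(named + blood) so total body volume closes.
TISSUE_VOLUMES_70KG_ML = {
    "lung": 530.0,
    "muscle": 29000.0,
    "adipose": 13000.0,
    "skin": 3300.0,
    "kidney": 310.0,
    "liver": 1800.0,
    "spleen": 180.0,
    "stomach": 150.0,
    "duodenum": 70.0,
    "jejunum": 280.0,
    "ileum": 290.0,
    "cecum": 70.0,
    "colon": 370.0,
    "heart": 330.0,
    "brain": 1450.0,
    "rest_of_body": 13670.0,
    "arterial_blood": 1800.0,
    "venous_blood": 3400.0,
}

# ---------------------------------------------------------------------------
# Tissue composition for mechanistic Kt:p prediction.
# f_ew / f_iw: extracellular / intracellular water volume fractions
# f_nl / f_np: neutral lipid / neutral phospholipid volume fractions
# ap_mg_g: acidic phospholipid concentration (mg/g tissue)
# ratio_alb / ratio_lip: tissue:plasma albumin and lipoprotein ratios
# ---------------------------------------------------------------------------
TISSUE_COMPOSITION = {
    #            f_ew    f_iw    f_nl     f_np     ap     r_alb  r_lip
    "adipose":  (0.135, 0.017, 0.8440, 0.0016, 0.40, 0.049, 0.068),
    "brain":    (0.162, 0.620, 0.0391, 0.0015, 0.40, 0.048, 0.041),
    "heart":    (0.320, 0.456, 0.0115, 0.0166, 2.25, 0.157, 0.160),
    "kidney":   (0.273, 0.483, 0.0207, 0.0162, 5.03, 0.130, 0.137),
    "liver":    (0.161, 0.573, 0.0348, 0.0252, 4.56, 0.086, 0.161),
    "lung":     (0.336, 0.446, 0.0219, 0.0140, 3.91, 0.212, 0.168),
    "muscle":   (0.118, 0.630, 0.0100, 0.0072, 1.53, 0.064, 0.059),
    "skin":     (0.382, 0.291, 0.0284, 0.0111, 1.32, 0.277, 0.096),
    "spleen":   (0.207, 0.579, 0.0201, 0.0198, 3.18, 0.097, 0.207),
    "stomach":  (0.282, 0.475, 0.0487, 0.0163, 2.84, 0.158, 0.141),
    "duodenum": (0.282, 0.475, 0.0487, 0.0163, 2.84, 0.158, 0.141),
    "jejunum":  (0.282, 0.475, 0.0487, 0.0163, 2.84, 0.158, 0.141),
    "ileum":    (0.282, 0.475, 0.0487, 0.0163, 2.84, 0.158, 0.141),
    "cecum":    (0.282, 0.475, 0.0487, 0.0163, 2.84, 0.158, 0.141),
    "colon":    (0.282, 0.475, 0.0487, 0.0163, 2.84, 0.158, 0.141),
    # rest-of-body treated as a muscle-like lump
    "rest_of_body": (0.150, 0.550, 0.0300, 0.0100, 1.50, 0.100, 0.100),
}

#: Blood-cell composition used to back out acidic-phospholipid association
#: for strong bases (intracellular water, neutral lipid, neutral
#: phospholipid fractions and acidic phospholipid mg/g).
BLOOD_CELL_COMPOSITION = {"f_iw": 0.603, "f_nl": 0.0017, "f_np": 0.0029,
                          "ap_mg_g": 0.50}

#: Plasma neutral lipid / neutral phospholipid volume fractions.
PLASMA_COMPOSITION = {"f_nl": 0.0023, "f_np": 0.0013}

#: Compartmental pH used in the ionization terms.
PH = {"plasma": 7.4, "intracellular": 7.0, "blood_cell": 7.22}

#: Effective small-intestinal segment radii (cm) for deriving the first-order
#: absorption constant k_a,i = 2 * Peff / r_i.
SEGMENT_RADII_CM = {"duodenum": 1.6, "jejunum": 1.5, "ileum": 1.25}

#: Default first-order gastrointestinal transit constants, 1/h.
#: Gastric emptying half-time ~17 min; small-intestinal residence ~3.4 h
#: split over duodenum/jejunum/ileum; long colonic residence before fecal
#: exit. Synthetic stand-in values, overridable in config.
DEFAULT_TRANSIT_PER_H = {
    "gastric_emptying": 2.5,
    "duodenum": 3.8,
    "jejunum": 0.66,
    "ileum": 0.62,
    "cecum": 0.23,
    "colon": 0.05,
}
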