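"""Extrapolate the validated model to HF classes II-IV.

Computes dose-normalized exposure ratios (AUCR, CmaxR) of the glycoside
archetype versus healthy, and the steady-state interval exposure per class
under 0.25 mg once daily. Reduced perfusion lowers clearance, so AUCR > 1
everywhere; note the class III -> IV step: renal perfusion partially
recovers in class IV (63% vs 55% of baseline), so interval AUC dips
slightly while Cmax keeps rising with the monotone loss of muscle, skin
and adipose perfusion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hfpbpk import (ConcentrationProfile, Regimen, apply_hf, build_healthy,
                    exposure_ratio, make_fixture, nca, simulate,
                    steady_state, well_stirred_blood_clearance)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    healthy = build_healthy()
    fx = make_fixture("renal_neutral_digoxin_like", seed=1)
    single = Regimen.single("oral", 0.25)
    qd = Regimen.qd(0.25)

    summaries, rows = {}, []
    for cls in ("healthy", "II", "III", "IV"):
        phys = healthy if cls == "healthy" else apply_hf(healthy, cls)
        model = fx.to_model(phys)
        res = simulate(model, single, 72.0, n_points=289)
        summaries[cls] = nca(ConcentrationProfile(
            res.times_h, res.plasma_conc_ng_ml, dose=0.25))
        ss = steady_state(model, qd)
        conc = ss.plasma_conc_ng_ml
        rows.append({
            "hf_class": cls,
            "blood_cl_ml_min": round(
                well_stirred_blood_clearance(phys, fx.drug), 1),
            "ss_auc_ug_h_ml": np.trapezoid(conc, ss.times_h) / 1000.0,
            "ss_cmax_ng_ml": conc.max(),
            "ss_cmin_ng_ml": conc.min(),
        })
    df = pd.DataFrame(rows)
    for cls in ("II", "III", "IV"):
        r = exposure_ratio(summaries[cls], summaries["healthy"])
        df.loc[df["hf_class"] == cls, "aucr"] = r["aucr"]
        df.loc[df["hf_class"] == cls, "cmaxr"] = r["cmaxr"]
    df.to_csv(OUT / "hf_extrapolation.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("\nsteady-state Cmax rises monotonically with severity; AUC rises "
          "II->III and dips slightly at IV (renal perfusion fraction "
          "0.78 -> 0.55 -> 0.63 is itself non-monotone).")
    print(f"wrote {OUT / 'hf_extrapolation.csv'}")


if __name__ == "__main__":
    main()
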