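"""Build the healthy 70-kg physiology and the NYHA class II-IV variants.

Writes the per-class tissue blood-flow/volume table and prints the
cardiac-output closure check (pulmonary flow = sum of systemic flows).
"""

from pathlib import Path

import pandas as pd

from hfpbpk import apply_hf, build_healthy, total_systemic_flow

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    healthy = build_healthy()
    physiologies = {"healthy": healthy}
    for cls in ("II", "III", "IV"):
        physiologies[cls] = apply_hf(healthy, cls)

    rows = []
    for cls, phys in physiologies.items():
        for name in sorted(phys.tissues):
            t = phys.tissues[name]
            rows.append({"hf_class": cls, "tissue": name,
                         "volume_ml": t.volume,
                         "blood_flow_ml_min": round(t.blood_flow, 2)})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "physiology_flows.csv", index=False)

    print("cardiac output (pulmonary flow), mL/min:")
    for cls, phys in physiologies.items():
        closure = abs(phys.cardiac_output - total_systemic_flow(phys))
        print(f"  {cls:>8}: {phys.cardiac_output:9.2f}"
              f"  (closure residual {closure:.2e})")
    print(f"wrote {OUT / 'physiology_flows.csv'}")


if __name__ == "__main__":
    main()
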