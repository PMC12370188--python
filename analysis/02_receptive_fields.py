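"""Receptive-field progression of the reference backbone and the
PinholeNet family.

The calculator composes r_l = r_{l-1} + (k_l - 1) j_{l-1}, j_l = j_{l-1} s_l
over each architecture spec; the fifth-block values are the architecture
family's defining numbers (195 px for the reference backbone; 11/17/31/33 px
for the PinholeNets). Writes results/rf_progression.csv.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from gaborpath import model_zoo as mz  # noqa: E402

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    frames = []
    _, ref = mz.make_reference_backbone()
    df = mz.receptive_field(ref).to_frame()
    df.insert(0, "model", "reference")
    frames.append(df)
    print("reference backbone fifth-block RF:",
          mz.receptive_field(ref).rf_at("pool5"), "px")

    for variant in ("P11", "P17", "P31", "P33"):
        _, arch = mz.make_pinholenet(variant, input_size=64, head_width=16)
        rep = mz.receptive_field(arch)
        df = rep.to_frame()
        df.insert(0, "model", variant)
        frames.append(df)
        ext, trunc = mz.rf_footprint_oracle(arch,
                                            input_size=4 * rep.final_rf)
        print(f"{variant}: analytic {rep.final_rf} px, "
              f"impulse oracle {ext} px (truncated={trunc})")

    table = pd.concat(frames, ignore_index=True)
    table.to_csv(f"{OUT}/rf_progression.csv", index=False)
    print(f"wrote {OUT}/rf_progression.csv ({len(table)} layer rows)")


if __name__ == "__main__":
    main()
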