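"""Layer-by-layer contour-detection readout on desk-scale displays.

Trains frozen linear probes at every probe point of the full-RF toy
backbone and its pinhole twin on a small contour set (straight contours,
128-px displays) and writes the accuracy table to
results/probe_sweep.csv. With random frozen backbones accuracies hover
near chance at every layer; the contrast with fine-tuning is the subject
of 04_trend_full_vs_pinhole.py.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from gaborpath import model_zoo as mz, probe  # noqa: E402

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    train = probe.make_contour_dataset([0], 60, seed=301)
    test = probe.make_contour_dataset([0], 30, seed=302)
    cfg = probe.ProbeConfig(mode="frozen", epochs=10, learning_rate=1e-3,
                            optimizer="adamw", seed=0)

    tables = []
    for kind in ("full", "pinhole"):
        _, arch = mz.make_toy_net(kind, seed=0)
        layers = [n for n in arch.probe_points
                  if n not in ("center", "fc_out")]

        def factory(kind=kind):
            model, _ = mz.make_toy_net(kind, seed=0)
            return model

        table = probe.layer_sweep(factory, layers, train, test, cfg)
        table.insert(0, "backbone", kind)
        tables.append(table)
        print(f"{kind} backbone (frozen probes):")
        print(table[["layer", "accuracy", "ci95_low", "ci95_high"]]
              .to_string(index=False))

    import pandas as pd
    pd.concat(tables, ignore_index=True).to_csv(f"{OUT}/probe_sweep.csv",
                                                index=False)
    print(f"wrote {OUT}/probe_sweep.csv")


if __name__ == "__main__":
    main()
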