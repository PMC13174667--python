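#!/usr/bin/env python
"""Per-context scaled mutation rates at unmethylated and methylated states.

Predicts muT(x=0) = alphaT and muT(x=1) = (alpha+beta)T with Wald CIs from
the fitted 4-mer model, compares them against the simulation truth, and
reports the rank change between states (the context x methylation
interaction).
"""

import json
from pathlib import Path

import pandas as pd

from cpgmut.glm import fit_from_json, predict_scaled_rates, rates_to_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fit_path = RESULTS / "fit_4mer.json"
    if not fit_path.exists():
        raise SystemExit("results/fit_4mer.json missing - run analysis/02_fit_models.py first")
    fit = fit_from_json(fit_path)
    truth = json.loads((RESULTS / "truth.json").read_text())
    frames = []
    for x in (0, 1):
        f = rates_to_frame(predict_scaled_rates(fit, x))
        f["true_muT"] = [
            truth["alphaT"][c] + truth["betaT"][c] * x for c in f["context"]
        ]
        f["covered"] = (f["ci_low"] <= f["true_muT"]) & (f["true_muT"] <= f["ci_high"])
        frames.append(f)
    rates = pd.concat(frames, ignore_index=True)
    rates.to_csv(RESULTS / "rates_4mer.tsv", sep="\t", index=False, float_format="%.6g")

    unmeth = rates[rates.state == 0].sort_values("muT", ascending=False)
    meth = rates[rates.state == 1].sort_values("muT", ascending=False)
    print("top three contexts, unmethylated:", ", ".join(unmeth.head(3)["context"]))
    print("top three contexts, methylated:  ", ", ".join(meth.head(3)["context"]))
    same_order = list(unmeth["context"]) == list(meth["context"])
    print(f"context ranking identical across states: {same_order}")
    print(f"95% CI covers truth in {int(rates['covered'].sum())}/{len(rates)} cells")
    print(f"wrote {RESULTS/'rates_4mer.tsv'}")


if __name__ == "__main__":
    main()
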