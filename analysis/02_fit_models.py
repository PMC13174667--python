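#!/usr/bin/env python
"""Fit the 4-mer, additive single-flank and context-only models; compare fit.

Reads results/sites.tsv (from 01_simulate_data.py), fits each model by
exact maximum likelihood under the log(1-p) link, and tabulates AIC, BIC
and the proportion of null deviance explained.
"""

from pathlib import Path

import pandas as pd

from cpgmut.glm import build_design_matrix, fit_glm, fit_to_json, model_scores
from cpgmut.sites import read_site_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
MODELS_TO_FIT = ["4mer", "up1_down1", "context_only_4mer"]


def main() -> None:
    sites_path = RESULTS / "sites.tsv"
    if not sites_path.exists():
        raise SystemExit("results/sites.tsv missing - run analysis/01_simulate_data.py first")
    df = read_site_table(sites_path)
    rows = []
    for name in MODELS_TO_FIT:
        fit = fit_glm(build_design_matrix(df, name), keep_eta=False)
        fit_to_json(fit, RESULTS / f"fit_{name}.json")
        s = model_scores(fit)
        rows.append((name, fit.n_params, fit.loglik, s["AIC"], s["BIC"],
                     s["variance_explained"], fit.converged))
    table = pd.DataFrame(rows, columns=["model", "n_params", "logL", "AIC", "BIC",
                                        "variance_explained", "converged"])
    table.to_csv(RESULTS / "model_comparison.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(table.to_string(index=False))
    best = table.loc[table["BIC"].idxmin(), "model"]
    print(f"\nbest model by BIC: {best}")
    print(f"wrote {RESULTS/'model_comparison.tsv'} and per-model fit JSONs")


if __name__ == "__main__":
    main()
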