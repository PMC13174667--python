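"""Study-level validation runs: calibration, oracles and end-to-end checks.

Each function here reruns the full estimation machinery on freshly
simulated data under the default study conditions and measures one
property of the result — confidence-interval coverage, null calibration of
the asymmetry z-test, deviance nesting across model complexity, agreement
with closed-form and grid-search maximum likelihood, and byte-level
end-to-end fixture consistency.  All randomness derives from the single
seed passed in.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import MODELS, build_design_matrix, fit_glm, model_scores, predict_scaled_rates
from .pipeline import annotate_sites, extract_sites
from .simulate import (
    additive_flank_truth,
    default_truth,
    generate_fixture_bundle,
    simulate_site_table,
    write_site_table,
)
from .summaries import concordance, test_asymmetry

__all__ = [
    "ci_coverage",
    "asymmetry_null_rejection",
    "deviance_nesting",
    "intercept_mle_error",
    "stratum_closed_form_error",
    "grid_search_mle",
    "grid_oracle_max_diff",
    "fixture_pipeline_match",
    "flank_independence_concordance",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


# ---------------------------------------------------------------------------
# Calibration of Wald intervals
# ---------------------------------------------------------------------------

def ci_coverage(seed: int, n_reps: int = 200, n_per_context: int = 20_000) -> tuple[float, int]:
    """Fraction of 95% CIs covering the true muT over replicate fits.

    Each replicate draws fresh per-context truth and data, fits the full
    4-mer x methylation model and checks both methylation states in every
    context.  Returns (coverage, number of context x state cells).
    """
    hits = tot = 0
    for s in _spawn_seeds(seed, n_reps):
        truth = default_truth(s, n_per_context=n_per_context)
        df = simulate_site_table(truth)
        fit = fit_glm(build_design_matrix(df, "4mer"), keep_eta=False)
        for x in (0, 1):
            for e in predict_scaled_rates(fit, x):
                hits += int(e.ci_low <= truth.muT(e.context, x) <= e.ci_high)
                tot += 1
    return hits / tot, tot


def asymmetry_null_rejection(
    seed: int, n_reps: int = 50, n_per_context: int = 10_000, alpha: float = 0.05
) -> tuple[float, int]:
    """Rejection rate of the asymmetry z-test under a strand-symmetric truth.

    True rates are equal within every reverse-complement pair, so every
    rejection at level ``alpha`` is a false positive; a calibrated test
    rejects close to ``alpha``.  Six pairs x two states per replicate.
    """
    from scipy import stats

    zcrit = float(stats.norm.isf(alpha / 2.0))
    rej = tot = 0
    for s in _spawn_seeds(seed, n_reps):
        truth = default_truth(s, n_per_context=n_per_context, symmetric=True)
        df = simulate_site_table(truth)
        fit = fit_glm(build_design_matrix(df, "4mer"), keep_eta=False)
        rates = [e for x in (0, 1) for e in predict_scaled_rates(fit, x)]
        for r in test_asymmetry(rates, k=4, adjust="none"):
            rej += int(abs(r.z) > zcrit)
            tot += 1
    return rej / tot, tot


# ---------------------------------------------------------------------------
# Deviance nesting
# ---------------------------------------------------------------------------

_CHAIN_1 = ("up1_down1", "4mer", "6mer")
_CHAIN_2 = ("additive_positions", "up21_down12", "6mer")


def deviance_nesting(seed: int, n_per_context: int = 400) -> dict:
    """Residual deviances along the two nested model chains on one dataset.

    Simulates a 6-mer truth (256 contexts) and fits every model of both
    chains; residual deviance must be non-increasing and variance
    explained non-decreasing with model complexity.
    """
    truth = default_truth(seed, k=6, n_per_context=n_per_context)
    df = simulate_site_table(truth)
    dev: dict[str, float] = {}
    ve: dict[str, float] = {}
    for name in sorted(set(_CHAIN_1) | set(_CHAIN_2)):
        fit = fit_glm(build_design_matrix(df, name), keep_eta=False)
        dev[name] = fit.residual_deviance
        ve[name] = model_scores(fit)["variance_explained"]
    ok1 = dev[_CHAIN_1[0]] >= dev[_CHAIN_1[1]] >= dev[_CHAIN_1[2]]
    ok2 = dev[_CHAIN_2[0]] >= dev[_CHAIN_2[1]] >= dev[_CHAIN_2[2]]
    return {"deviance": dev, "variance_explained": ve, "chain1_ok": ok1, "chain2_ok": ok2,
            "n": len(df)}


# ---------------------------------------------------------------------------
# Closed-form and grid-search oracles
# ---------------------------------------------------------------------------

def intercept_mle_error(seed: int, n: int = 50_000) -> tuple[float, int]:
    """|fitted intercept-only muT - (-log(1 - k/n))|, the exact MLE."""
    truth = default_truth(seed, n_per_context=max(n // 16, 100))
    df = simulate_site_table(truth)
    one_level = df.assign(context4="ACGA")  # collapse contexts: intercept-only
    fit = fit_glm(build_design_matrix(one_level, "context_only_4mer"), keep_eta=False)
    closed = -np.log1p(-df["y"].mean())
    return float(abs(-fit.theta[0] - closed)), len(df)


def stratum_closed_form_error(seed: int, n_per_context: int = 5_000) -> tuple[float, int]:
    """Max |fitted muT - stratum closed form| when m is exactly 0 or 1.

    With binary methylation the saturating 4-mer x m model decouples into
    independent (context, state) cells whose MLE is -log(1 - k/n).
    """
    truth = default_truth(seed, n_per_context=n_per_context, m_kind="binary")
    df = simulate_site_table(truth)
    fit = fit_glm(build_design_matrix(df, "4mer"), keep_eta=False)
    worst = 0.0
    for x in (0, 1):
        for e in predict_scaled_rates(fit, x):
            cell = df[(df["context4"] == e.context) & (df["m"] == float(x))]
            closed = -np.log1p(-cell["y"].mean())
            worst = max(worst, abs(e.muT - closed))
    return worst, len(df)


def grid_search_mle(
    X: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    half_width: float = 0.5,
    points: int = 11,
    rounds: int = 12,
) -> np.ndarray:
    """Dense coordinate-grid maximum likelihood, independent of the Newton path.

    Evaluates the Bernoulli log-likelihood with p = 1 - exp(X theta)
    directly over an axis-aligned grid around ``theta0``, shrinking the
    grid each round.  Practical only for a handful of coefficients; used
    as an oracle for small models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)

    def ll(theta: np.ndarray) -> float:
        eta = X @ theta
        if eta.max() >= 0:
            return -np.inf
        p = -np.expm1(eta)
        return float(np.sum(np.where(y == 1, np.log(p), eta)))

    best = np.asarray(theta0, dtype=float).copy()
    width = half_width
    for _ in range(rounds):
        improved = True
        while improved:
            improved = False
            for j in range(len(best)):
                grid = best[j] + np.linspace(-width, width, points)
                lls = []
                trial = best.copy()
                for g in grid:
                    trial[j] = g
                    lls.append(ll(trial))
                jbest = int(np.argmax(lls))
                if grid[jbest] != best[j] and lls[jbest] > ll(best):
                    best[j] = grid[jbest]
                    improved = True
        width /= 4.0
    return best


def grid_oracle_max_diff(seed: int, n: int = 30_000) -> tuple[float, int]:
    """Max |Newton MLE - grid-search MLE| over a 3-coefficient model."""
    rng = np.random.default_rng(seed)
    contexts = np.array(["ACGA", "CCGC", "TCGT"])
    ctx = contexts[rng.integers(0, 3, size=n)]
    mu = np.select([ctx == c for c in contexts], [0.05, 0.15, 0.30])
    y = (rng.random(n) < -np.expm1(-mu)).astype(np.int8)
    df = pd.DataFrame({"context4": ctx, "m": 0.0, "y": y})
    dm = build_design_matrix(df, "context_only_4mer")
    fit = fit_glm(dm, keep_eta=False)
    start = np.zeros(dm.p)
    start[0] = np.log1p(-float(y.mean()))
    oracle = grid_search_mle(np.asarray(dm.X.todense()), dm.y, start)
    return float(np.abs(fit.theta - oracle).max()), n


# ---------------------------------------------------------------------------
# End-to-end fixture and flank independence
# ---------------------------------------------------------------------------

def fixture_pipeline_match(seed: int, outdir=None) -> tuple[bool, int]:
    """Pipeline output on the fixture bundle vs the independent oracle table.

    Returns (byte-identical after canonical sorting, number of site rows).
    """
    ctx = tempfile.TemporaryDirectory() if outdir is None else None
    base = Path(ctx.name if ctx else outdir)
    try:
        paths = generate_fixture_bundle(base / "fixture", seed=seed)
        records = extract_sites(paths["fasta"], paths["include_bed"], paths["exclude_bed"])
        table, _ = annotate_sites(records, paths["vcf"], paths["methylation"], model_k=4)
        table = table.sort_values(["chrom", "cpg_start", "strand"], ignore_index=True)
        out = base / "pipeline_sites.tsv"
        write_site_table(table, out)
        match = out.read_bytes() == Path(paths["expected_sites"]).read_bytes()
        return match, len(table)
    finally:
        if ctx:
            ctx.cleanup()


def flank_independence_concordance(
    seed: int, n_per_context: int = 100_000, interaction: float = 0.0
) -> tuple[dict[int, float], int]:
    """Pearson r between 4-mer and additive single-flank rate estimates.

    Data are simulated with exactly independent upstream/downstream flank
    effects (unless ``interaction`` is nonzero), so the additive model is
    correctly specified and the two estimates should agree closely.
    """
    truth = additive_flank_truth(seed, n_per_context=n_per_context, interaction=interaction)
    df = simulate_site_table(truth)
    fit_full = fit_glm(build_design_matrix(df, "4mer"), keep_eta=False)
    fit_add = fit_glm(build_design_matrix(df, "up1_down1"), keep_eta=False)
    full = [e for x in (0, 1) for e in predict_scaled_rates(fit_full, x)]
    add = [e for x in (0, 1) for e in predict_scaled_rates(fit_add, x)]
    r, table = concordance(full, add, by_state=True)
    return r, len(df)
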