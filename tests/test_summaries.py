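"""Concordance, asymmetry tests, methylation bins and stratified refits."""

import numpy as np
import pandas as pd
import pytest

from cpgmut.glm import ScaledRateEstimate, build_design_matrix, fit_glm, predict_scaled_rates
from cpgmut.simulate import additive_flank_truth, default_truth, simulate_site_table
from cpgmut.summaries import (
    binned_rates,
    bins_to_frame,
    concordance,
    stratified_refit,
    test_asymmetry,
)


def est(context, state, mu, se=0.01):
    return ScaledRateEstimate(context, state, mu, se, mu - 1.96 * se, mu + 1.96 * se)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_identity_and_reversal():
    a = [est("ACGA", 0, 1.0), est("ACGC", 0, 2.0), est("ACGG", 0, 3.0)]
    b = [est("ACGA", 0, 3.0), est("ACGC", 0, 2.0), est("ACGG", 0, 1.0)]
    r_same, table = concordance(a, a, by_state=False)
    assert r_same == pytest.approx(1.0)
    assert len(table) == 3
    r_rev, _ = concordance(a, b, by_state=False)
    assert r_rev == pytest.approx(-1.0)


def test_concordance_needs_three_shared_contexts():
    a = [est("ACGA", 0, 1.0), est("ACGC", 0, 2.0)]
    with pytest.raises(ValueError):
        concordance(a, a, by_state=False)


def test_cross_model_concordance_under_independent_flanks():
    """4-mer vs additive single-flank estimates agree when flanks act independently."""
    df = simulate_site_table(additive_flank_truth(17, n_per_context=100_000))
    full = fit_glm(build_design_matrix(df, "4mer"), keep_eta=False)
    add = fit_glm(build_design_matrix(df, "up1_down1"), keep_eta=False)
    r, _ = concordance(
        [e for x in (0, 1) for e in predict_scaled_rates(full, x)],
        [e for x in (0, 1) for e in predict_scaled_rates(add, x)],
        by_state=True,
    )
    assert r[0] > 0.99 and r[1] > 0.99


def test_interaction_reduces_cross_model_concordance():
    """Injecting a U1xD1 interaction must lower 4mer-vs-additive agreement."""
    n = 20_000
    r_add, _ = concordance(*_two_model_rates(additive_flank_truth(23, n)), by_state=False)
    r_int, _ = concordance(
        *_two_model_rates(additive_flank_truth(23, n, interaction=0.03)), by_state=False
    )
    assert r_int < r_add


def _two_model_rates(truth):
    df = simulate_site_table(truth)
    full = fit_glm(build_design_matrix(df, "4mer"), keep_eta=False)
    add = fit_glm(build_design_matrix(df, "up1_down1"), keep_eta=False)
    return (
        [e for x in (0, 1) for e in predict_scaled_rates(full, x)],
        [e for x in (0, 1) for e in predict_scaled_rates(add, x)],
    )


# ---------------------------------------------------------------------------
# asymmetry
# ---------------------------------------------------------------------------

def test_asymmetry_z_statistic_arithmetic():
    rates = [est("ACGC", 0, 1.0, 0.1), est("GCGT", 0, 0.7, 0.1)]
    (r,) = test_asymmetry(rates, adjust="none")
    assert (r.context_a, r.context_b) == ("ACGC", "GCGT")
    assert r.delta == pytest.approx(0.3)
    assert r.se_delta == pytest.approx(0.14142, abs=1e-5)
    assert r.z == pytest.approx(2.1213, abs=1e-4)


def test_asymmetry_equal_rates_give_z_zero_and_p_one():
    rates = [est("ACGC", 0, 1.0, 0.1), est("GCGT", 0, 1.0, 0.1)]
    (r,) = test_asymmetry(rates, adjust="none")
    assert r.z == 0.0 and r.p == pytest.approx(1.0)


def test_asymmetry_is_antisymmetric_in_pair_order():
    fwd = test_asymmetry([est("ACGC", 0, 1.0, 0.1), est("GCGT", 0, 0.7, 0.1)], adjust="none")
    # swap the values carried by the two contexts: delta and z must flip sign
    rev = test_asymmetry([est("ACGC", 0, 0.7, 0.1), est("GCGT", 0, 1.0, 0.1)], adjust="none")
    assert fwd[0].delta == pytest.approx(-rev[0].delta)
    assert fwd[0].z == pytest.approx(-rev[0].z)
    assert fwd[0].p == pytest.approx(rev[0].p)


def test_asymmetry_excludes_palindromes_and_adjusts():
    rates = [est(c, s, 1.0 + 0.1 * s, 0.05) for s in (0, 1)
             for c in ("ACGC", "GCGT", "ACGT", "CCGG")]
    results = test_asymmetry(rates, adjust="bonferroni")
    assert {(r.context_a, r.context_b) for r in results} == {("ACGC", "GCGT")}
    assert len(results) == 2  # two states, palindromes skipped
    for r in results:
        assert r.p_adjusted == pytest.approx(min(1.0, r.p * 2))


def test_asymmetry_skips_incomplete_pairs():
    rates = [est("ACGC", 0, 1.0), est("GCGT", 0, 0.9), est("ACGA", 0, 1.0)]
    results = test_asymmetry(rates, adjust="none")
    assert {(r.context_a, r.context_b) for r in results} == {("ACGC", "GCGT")}


# ---------------------------------------------------------------------------
# methylation bins
# ---------------------------------------------------------------------------

def test_binned_rates_bin_placement_and_edges():
    df = pd.DataFrame({"m": [0.5] * 10 + [1.0] * 5, "y": [1] * 3 + [0] * 12})
    bins = binned_rates(df)
    assert len(bins) == 20
    assert bins[10].low == 0.5 and bins[10].n == 10  # [0.50, 0.55)
    assert bins[19].n == 5  # last bin closed: m = 1 included
    assert sum(b.n for b in bins) == len(df)
    assert sum(b.n_poly for b in bins) == df["y"].sum()


def test_binned_rates_zero_count_wilson_interval():
    df = pd.DataFrame({"m": np.full(100, 0.12), "y": np.zeros(100, dtype=int)})
    bins = binned_rates(df)
    b = bins[2]
    assert b.n == 100 and b.rate == 0.0
    assert b.ci_low == 0.0 and 0 < b.ci_high < 0.05


def test_binned_rates_empty_bins_emitted():
    df = pd.DataFrame({"m": [0.01], "y": [0]})
    frame = bins_to_frame(binned_rates(df))
    assert len(frame) == 20
    assert np.isnan(frame.loc[7, "rate"]) and frame.loc[7, "n"] == 0


def test_binned_rates_track_saturating_curve(sites_small):
    """Observed bin rates rise with m and flatten, as 1-exp(-muT) does."""
    bins = [b for b in binned_rates(sites_small) if b.n > 500]
    rates = [b.rate for b in bins]
    assert rates[0] < rates[-1]


# ---------------------------------------------------------------------------
# stratified refits
# ---------------------------------------------------------------------------

def test_stratified_refit_duplicated_strata_identical(sites_small):
    doubled = pd.concat([sites_small, sites_small], ignore_index=True)
    labels = np.repeat(["a", "b"], len(sites_small))
    fits, info = stratified_refit(doubled, labels, "4mer")
    assert np.allclose(fits["a"].theta, fits["b"].theta, atol=1e-8)
    assert info["missing_levels"] == {"a": None, "b": None}
    assert info["concordance"]["a"][1] == pytest.approx(1.0, abs=1e-9)


def test_stratified_refit_random_split_concordant():
    df = simulate_site_table(default_truth(29, n_per_context=50_000))
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, size=len(df))
    fits, info = stratified_refit(df, labels, "4mer")
    # pairwise concordance of methylated-state estimates across strata
    per_stratum = {
        lab: {e.context: e.muT for e in predict_scaled_rates(fits[lab], 1)} for lab in fits
    }
    labs = sorted(per_stratum)
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            xs = [per_stratum[a][c] for c in sorted(per_stratum[a])]
            ys = [per_stratum[b][c] for c in sorted(per_stratum[b])]
            assert np.corrcoef(xs, ys)[0, 1] > 0.95
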