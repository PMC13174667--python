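"""Shared fixtures: small simulated datasets and the byte-level fixture bundle."""

import numpy as np
import pandas as pd
import pytest

from cpgmut.glm import build_design_matrix, fit_glm
from cpgmut.simulate import default_truth, generate_fixture_bundle, simulate_site_table


@pytest.fixture(scope="session")
def truth_small():
    """Default study conditions at a modest per-context size."""
    return default_truth(1, n_per_context=5_000)


@pytest.fixture(scope="session")
def sites_small(truth_small):
    return simulate_site_table(truth_small)


@pytest.fixture(scope="session")
def fit_4mer_small(sites_small):
    return fit_glm(build_design_matrix(sites_small, "4mer"))


@pytest.fixture(scope="session")
def truth_k6():
    """6-mer truth for nesting and parameter-count checks."""
    return default_truth(31, k=6, n_per_context=400)


@pytest.fixture(scope="session")
def sites_k6(truth_k6):
    return simulate_site_table(truth_k6)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_fixture_bundle(outdir, seed=7)


def random_masked_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence with occasional N and lowercase, CpG-enriched."""
    bases = rng.choice(list("ACGT"), size=length)
    for pos in rng.choice(length - 1, size=length // 15, replace=False):
        bases[pos], bases[pos + 1] = "C", "G"
    for pos in rng.choice(length, size=length // 30, replace=False):
        bases[pos] = "N"
    for pos in rng.choice(length, size=length // 30, replace=False):
        if bases[pos] != "N":
            bases[pos] = bases[pos].lower()
    return "".join(bases)
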