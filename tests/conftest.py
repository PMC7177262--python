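"""Shared fixtures: one simulated study reused across the suite."""

import numpy as np
import pandas as pd
import pytest

import drypea as dp
import drypea.phenostats as ps
from drypea.genotypes import GenotypeMatrix
from drypea.qc import filter_markers, knn_impute

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """Default ('reference') simulated study: three connected RIL
    families, three environments."""
    return dp.simulate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def imputed(study):
    """QC-filtered and KNN-imputed observed genotype matrix."""
    g, _ = filter_markers(study.genotypes_observed, maf_min=0.025, missing_max=0.2)
    return knn_impute(g, k=4)


@pytest.fixture(scope="session")
def varcomps(study):
    return {
        env: ps.fit_varcomp(study.plots, env, "yield")
        for env in study.trait_model.environments
    }


@pytest.fixture(scope="session")
def blups(study, varcomps):
    return {
        env: ps.blup_line_values(ps.line_means(study.plots, env, "yield"), varcomps[env])
        for env in study.trait_model.environments
    }


@pytest.fixture()
def toy_genotypes():
    """Six inbred lines x four markers, fully called."""
    calls = pd.DataFrame(
        [
            [0, 0, 2, 2],
            [0, 2, 2, 0],
            [2, 0, 0, 2],
            [2, 2, 0, 0],
            [0, 0, 0, 0],
            [2, 2, 2, 2],
        ],
        index=[f"l{i}" for i in range(6)],
        columns=[f"m{j + 1}" for j in range(4)],
        dtype=float,
    )
    return GenotypeMatrix(calls)


def balanced_rcb(n_lines, n_blocks, sigma_g, sigma_e, seed, env="E1", mu=10.0):
    """Balanced single-environment RCB plot table with known components."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, sigma_g, n_lines)
    rows = []
    for b in range(n_blocks):
        beff = rng.normal(0.0, 0.1)
        for i in range(n_lines):
            rows.append(
                (env, f"b{b + 1}", f"l{i:03d}", "pop1",
                 mu + g[i] + beff + rng.normal(0.0, sigma_e))
            )
    return pd.DataFrame(rows, columns=["env", "block", "line", "population", "yield"])
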