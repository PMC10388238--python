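"""Shared fixtures: parameter sets, specs and small synthetic studies."""

import dataclasses

import numpy as np
import pytest

from emrmpt import (
    EmrParameterSet,
    redefined_baseline_spec,
    tabulate_categories,
)
from emrmpt.synthetic_data import SyntheticDesign, generate_study, TABLE_PARAMS

E_COLS = [f"E{i}" for i in range(1, 13)]


@pytest.fixture(scope="session")
def table_params():
    """Published posterior-mean parameter sets for both conditions."""
    return TABLE_PARAMS


@pytest.fixture(scope="session")
def redefined_spec():
    return redefined_baseline_spec()


@pytest.fixture(scope="session")
def study_counts(table_params):
    """Aggregated per-condition counts of one study-scale synthetic data set
    (31/40 participants, no person heterogeneity)."""
    design = dataclasses.replace(
        SyntheticDesign(), n_per_condition={"alcohol": 31, "placebo": 40},
        heterogeneity_sd=0.0, seed=20260901)
    trials, participants = generate_study(design)
    person, tables = tabulate_categories(trials)
    return tables


@pytest.fixture(scope="session")
def hetero_person_counts():
    """Per-person category counts for one condition with latent-trait
    heterogeneity (probit SD 0.4), n = 40 persons."""
    design = dataclasses.replace(
        SyntheticDesign(), n_per_condition={"alcohol": 40},
        heterogeneity_sd=0.4, seed=555)
    trials, _ = generate_study(design)
    person, _ = tabulate_categories(trials)
    return person[E_COLS].to_numpy(float)


def multinomial_counts(params_by_condition, n_pairs_by_condition, rng):
    """Aggregated counts drawn directly from the analytic category
    probabilities (fast path for calibration simulations)."""
    from emrmpt import CategoryTable, category_probabilities
    out = {}
    for cond, params in params_by_condition.items():
        p = category_probabilities(params).values
        out[cond] = CategoryTable(cond, rng.multinomial(
            n_pairs_by_condition[cond], p).astype(float))
    return out
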