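"""Structure of the EMR tree: branches, category probabilities, model specs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrmpt import (
    CategoryTable,
    EmrParameterSet,
    ModelSpec,
    baseline_spec,
    category_probabilities,
    degrees_of_freedom,
    enumerate_branches,
    full_spec,
    generalized_spec,
    log_likelihood,
    redefined_baseline_spec,
)
from emrmpt.emr_model import PARAM_NAMES, ConfigurationError


def mc_category_frequencies(params: EmrParameterSet, n_draws: int, seed: int):
    """Monte-Carlo branch-sampling oracle: walk the tree with vectorised coin
    flips, independently of the analytic branch enumeration."""
    rng = np.random.default_rng(seed)
    u = lambda: rng.uniform(size=n_draws)
    encoded = u() < params.e
    initial = encoded & (u() < params.r_c)
    m = np.where(initial, params.m_s, params.m_u)
    maintained = encoded & (u() < m)
    assoc = maintained & (u() < params.r_f)
    s = np.where(initial, params.s_s, params.s_u)
    u_par = np.where(initial, params.u_s, params.u_u)
    # per-word production probability at free recall
    word_p = np.where(maintained, s, np.where(encoded, u_par, params.u_u))
    w1 = u() < word_p
    w2 = u() < word_p
    n_words = np.where(assoc, 2, w1.astype(int) + w2.astype(int))
    free_col = np.select([n_words == 2, n_words == 1], [0, 1], default=2)
    final = maintained & (u() < params.r_c)
    cat = 6 * (~initial) + 3 * (~final) + free_col  # 0-based E index
    return np.bincount(cat, minlength=12) / n_draws


class TestBranches:
    def test_full_tree_has_32_branches(self):
        assert len(enumerate_branches()) == 32

    def test_every_category_reachable(self):
        assert {b.category for b in enumerate_branches()} == set(range(1, 13))

    def test_degenerate_parameters_single_live_branch(self):
        params = EmrParameterSet(1, 1, 1, 1, 1, 1, 1, 1, 1)
        probs = [b.probability(params) for b in enumerate_branches()]
        assert sum(p > 0 for p in probs) == 1

    def test_malformed_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_branches("not a spec")


class TestCategoryProbabilities:
    def test_all_processes_succeed_gives_e1(self):
        p = EmrParameterSet(e=1, m_s=1, m_u=0.3, r_f=1, r_c=1,
                            s_s=0.2, s_u=0.2, u_s=0.2, u_u=0.2)
        probs = category_probabilities(p).values
        assert probs[0] == pytest.approx(1.0)

    def test_nothing_encoded_no_words_gives_e12(self):
        p = EmrParameterSet(e=0, m_s=0.5, m_u=0.5, r_f=0.5, r_c=0.5,
                            s_s=0.5, s_u=0.5, u_s=0.5, u_u=0.0)
        probs = category_probabilities(p).values
        assert probs[11] == pytest.approx(1.0)

    def test_matches_monte_carlo_branch_sampling(self):
        params = EmrParameterSet.from_dict(
            dict(e=.6, r_c=.98, m=.9, r_f=.5, s=.1, u_s=.2, u_u=.1))
        n = 400_000
        freq = mc_category_frequencies(params, n, seed=1)
        exact = category_probabilities(params).values
        se = np.sqrt(np.clip(exact * (1 - exact), 1e-12, None) / n)
        assert np.all(np.abs(freq - exact) <= 3.5 * se + 1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=9, max_size=9))
    def test_probabilities_sum_to_one(self, values):
        params = EmrParameterSet.from_array(values)
        assert category_probabilities(params).values.sum() == pytest.approx(
            1.0, abs=1e-12)

    def test_random_parameter_sets_against_oracle(self):
        rng = np.random.default_rng(7)
        for seed in range(20):
            params = EmrParameterSet.from_array(rng.uniform(0.05, 0.95, 9))
            n = 50_000
            freq = mc_category_frequencies(params, n, seed=seed)
            exact = category_probabilities(params).values
            se = np.sqrt(np.clip(exact * (1 - exact), 1e-12, None) / n)
            assert np.all(np.abs(freq - exact) <= 4.5 * se + 1e-9)


class TestLogLikelihood:
    def test_zero_counts_zero_loglik(self):
        params = EmrParameterSet.from_array(np.full(9, 0.5))
        tab = CategoryTable("a", np.zeros(12))
        assert log_likelihood({"a": tab}, {"a": params}) == 0.0

    def test_all_mass_on_certain_category(self):
        params = EmrParameterSet(e=1, m_s=1, m_u=0, r_f=1, r_c=1,
                                 s_s=0, s_u=0, u_s=0, u_u=0)
        counts = np.zeros(12)
        counts[0] = 40
        assert log_likelihood({"a": CategoryTable("a", counts)},
                              {"a": params}) == pytest.approx(0.0)

    def test_impossible_count_is_minus_inf(self):
        params = EmrParameterSet(e=0, m_s=0, m_u=0, r_f=0, r_c=0,
                                 s_s=0, s_u=0, u_s=0, u_u=0)
        counts = np.zeros(12)
        counts[0] = 1
        assert log_likelihood({"a": CategoryTable("a", counts)},
                              {"a": params}) == -np.inf

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            params = {c: EmrParameterSet.from_array(rng.uniform(0.1, 0.9, 9))
                      for c in ("x", "y")}
            counts = {c: CategoryTable(c, rng.integers(0, 50, 12).astype(float))
                      for c in ("x", "y")}
            naive = 0.0
            for c in ("x", "y"):
                p = category_probabilities(params[c]).values
                for i in range(12):
                    if counts[c].values[i] > 0:
                        naive += counts[c].values[i] * np.log(p[i])
            assert log_likelihood(counts, params) == pytest.approx(naive)


class TestModelSpecs:
    @pytest.mark.parametrize("factory, expected_df, expected_free", [
        (baseline_spec, 11, 11),
        (generalized_spec, 5, 17),
        (redefined_baseline_spec, 9, 13),
    ])
    def test_degrees_of_freedom(self, factory, expected_df, expected_free):
        spec = factory()
        assert spec.n_free == expected_free
        assert degrees_of_freedom(spec) == expected_df

    def test_constraints_relabel_but_never_change_branches(self):
        assert len(enumerate_branches(baseline_spec())) == 32
        assert len(enumerate_branches(full_spec())) == 32

    def test_nesting(self):
        assert baseline_spec().is_nested_in(generalized_spec())
        assert redefined_baseline_spec().is_nested_in(generalized_spec())
        assert baseline_spec().is_nested_in(redefined_baseline_spec())
        assert not generalized_spec().is_nested_in(baseline_spec())

    def test_expand_honours_equalities(self):
        spec = baseline_spec()
        values = np.linspace(0.1, 0.9, spec.n_free)
        params = spec.expand(values)
        for cond in spec.conditions:
            assert params[cond].m_s == params[cond].m_u
            assert params[cond].s_s == params[cond].s_u
        assert params["alcohol"].r_c == params["placebo"].r_c

    def test_yaml_round_trip(self, tmp_path):
        spec = redefined_baseline_spec()
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = ModelSpec.from_yaml(path)
        assert back.free_labels() == spec.free_labels()
        assert degrees_of_freedom(back) == 9

    def test_category_table_round_trip(self, tmp_path):
        tabs = [CategoryTable("a", np.arange(12, dtype=float)),
                CategoryTable("b", np.ones(12))]
        path = tmp_path / "counts.tsv"
        CategoryTable.write_tsv(tabs, path)
        back = CategoryTable.read_tsv(path)
        assert [t.condition for t in back] == ["a", "b"]
        np.testing.assert_allclose(back[0].values, tabs[0].values)
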