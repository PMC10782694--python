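"""Shapley attributions: exact-subset-enumeration oracle, local accuracy,
and the median-based interaction / distance analyses."""

import itertools
import math

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from guidemix.interpretation import (
    attribute,
    distance_effect_profile,
    interaction_combination_table,
    mean_abs_importance,
)
from guidemix.treeshap import conditional_expectation


def brute_force_shapley(model, x, n_features):
    """Exhaustive Shapley values over the full subset lattice, using the
    same path-dependent conditional expectation. Exponential; tiny cases
    only."""
    trees = getattr(model, "estimators_", [model])

    def val(subset):
        known = np.zeros(n_features, dtype=bool)
        known[list(subset)] = True
        return np.mean([conditional_expectation(t, x, known) for t in trees])

    phi = np.zeros(n_features)
    others = list(range(n_features))
    for i in range(n_features):
        rest = [j for j in others if j != i]
        for r in range(len(rest) + 1):
            for subset in itertools.combinations(rest, r):
                w = (
                    math.factorial(len(subset))
                    * math.factorial(n_features - len(subset) - 1)
                    / math.factorial(n_features)
                )
                phi[i] += w * (val(set(subset) | {i}) - val(subset))
    return phi


def test_depth1_tree_matches_two_player_lattice():
    """Single binary split: attributions equal the brute-force Shapley
    value over the 2^2 subset lattice."""
    X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]] * 5)
    y = (X[:, 0] > 0.5).astype(float)
    tree = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
    attr = attribute(tree, X[:4])
    for r in range(4):
        oracle = brute_force_shapley(tree, X[r], 2)
        assert np.allclose(attr.values[r], oracle, atol=1e-12)


def test_small_forest_matches_subset_enumeration():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 4))
    y = X[:, 0] + 2 * (X[:, 1] > 0) + X[:, 2] * X[:, 1] + rng.normal(0, 0.1, 200)
    forest = RandomForestRegressor(
        n_estimators=10, max_depth=3, random_state=1, n_jobs=1
    ).fit(X, y)
    attr = attribute(forest, X[:10])
    for r in range(10):
        oracle = brute_force_shapley(forest, X[r], 4)
        assert np.allclose(attr.values[r], oracle, atol=1e-8)


def test_local_accuracy_on_random_rows():
    """base + row sum equals the forest prediction to 1e-6 on 100 rows."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 8))
    y = X @ rng.normal(size=8) + np.sin(X[:, 0] * 3)
    forest = RandomForestRegressor(
        n_estimators=30, max_depth=6, random_state=2, n_jobs=1
    ).fit(X, y)
    rows = X[rng.choice(300, size=100, replace=False)]
    attr = attribute(forest, rows)
    recon = attr.base_value + attr.values.sum(axis=1)
    assert np.max(np.abs(recon - forest.predict(rows))) <= 1e-6


def test_constant_model_zero_attributions():
    X = np.ones((20, 3))
    y = np.full(20, 2.5)
    tree = DecisionTreeRegressor(max_depth=2, random_state=0).fit(X, y)
    attr = attribute(tree, X)
    assert np.all(attr.values == 0)
    assert attr.base_value == pytest.approx(2.5)


def test_unused_feature_gets_exactly_zero():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(200, 5))
    y = X[:, 0] * 2.0  # only feature 0 matters
    forest = RandomForestRegressor(
        n_estimators=20, max_depth=4, random_state=0, n_jobs=1
    ).fit(X, y)
    used = {f for t in forest.estimators_ for f in t.tree_.feature if f >= 0}
    attr = attribute(forest, X[:30])
    for j in range(5):
        if j not in used:
            assert np.all(attr.values[:, j] == 0)
    assert 0 in used


def test_permutation_fallback_approximates_exact():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 3))
    y = X[:, 0] + (X[:, 1] > 0)
    tree = DecisionTreeRegressor(max_depth=3, random_state=0).fit(X, y)
    exact = attribute(tree, X[:5], method="exact_tree")
    approx = attribute(tree, X[:5], method="permutation", n_permutations=200, seed=0)
    assert np.allclose(exact.values, approx.values, atol=0.05)
    assert exact.base_value == approx.base_value


def test_attribute_rejects_unsupported_models():
    with pytest.raises(TypeError, match="unsupported model"):
        attribute(object(), np.zeros((1, 2)))
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 3))
    tree = DecisionTreeRegressor(max_depth=2).fit(X, X[:, 0])
    with pytest.raises(ValueError, match="unknown attribution method"):
        attribute(tree, X, method="magic")


# --- importance ----------------------------------------------------------


def test_mean_abs_importance_ranking():
    from guidemix.interpretation import AttributionMatrix

    vals = np.array([[0.0, 1.0, -2.0], [0.0, -1.0, 2.0], [0.0, 1.0, -2.0]])
    attr = AttributionMatrix(vals, 0.0, ("a", "b", "c"))
    ranked = mean_abs_importance(attr)
    assert ranked == [("c", 2.0), ("b", 1.0), ("a", 0.0)]
    zero = AttributionMatrix(np.zeros((2, 2)), 0.0, ("a", "b"))
    assert all(v == 0 for _, v in mean_abs_importance(zero))


# --- interaction combination table ---------------------------------------


def _presence(n, frac, rng):
    return rng.random(n) < frac


def test_additive_attributions_have_zero_deviation():
    """If each feature's attribution does not depend on the partner,
    observed +/+ equals the additive expectation."""
    rng = np.random.default_rng(2)
    n = 400
    p1, p2 = _presence(n, 0.5, rng), _presence(n, 0.5, rng)
    a1 = np.where(p1, 0.7, -0.1)  # depends only on own presence
    a2 = np.where(p2, -0.4, 0.2)
    tab = interaction_combination_table(a1, a2, p1, p2)
    assert tab["deviation"]["+/+"] == pytest.approx(0.0, abs=1e-9)
    assert tab["deviation"]["-/-"] == pytest.approx(0.0, abs=1e-9)


def test_xor_attributions_flag_interaction():
    """Hand-built 8-row table where each feature's attribution flips sign
    with partner presence: the +/+ deviation is nonzero."""
    p1 = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=bool)
    p2 = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=bool)
    a1 = np.where(p1 & p2, -1.0, np.where(p1, 1.0, 0.0))
    a2 = np.where(p1 & p2, -1.0, np.where(p2, 1.0, 0.0))
    tab = interaction_combination_table(a1, a2, p1, p2)
    # observed +/+ = -2; expected = 1 + 1 = 2
    assert tab["observed"]["+/+"] == pytest.approx(-2.0)
    assert tab["expected"]["+/+"] == pytest.approx(2.0)
    assert abs(tab["deviation"]["+/+"]) > 0


def test_combination_symmetry_under_pair_swap():
    rng = np.random.default_rng(4)
    n = 300
    p1, p2 = _presence(n, 0.4, rng), _presence(n, 0.6, rng)
    a1, a2 = rng.normal(size=n), rng.normal(size=n)
    t12 = interaction_combination_table(a1, a2, p1, p2)
    t21 = interaction_combination_table(a2, a1, p2, p1)
    assert t12["deviation"]["+/+"] == pytest.approx(t21["deviation"]["+/+"])
    assert t12["observed"]["+/+"] == pytest.approx(t21["observed"]["+/+"])


def test_missing_strata_flagged():
    p = np.ones(10, dtype=bool)
    tab = interaction_combination_table(np.ones(10), np.ones(10), p, p)
    assert set(tab["missing"]) == {"-/-", "+/-", "-/+"}
    assert tab["deviation"]["+/+"] is None  # expectation needs +/- and -/+


# --- distance profile ----------------------------------------------------


def test_distance_profile_flat_attribution():
    from guidemix.interpretation import AttributionMatrix

    n = 100
    vals = np.zeros((n, 2))
    vals[:, 0] = 0.5
    attr = AttributionMatrix(vals, 0.0, ("dist_start_codon", "other"))
    dist = np.arange(n) * 3
    prof = distance_effect_profile(attr, dist)
    assert prof["difference"] == pytest.approx(0.0)


def test_distance_profile_recovers_simulated_window_bonus(default_screen_fit):
    """The simulator grants extra depletion within 60 nt of the start
    codon; the distance feature's attribution must be more negative
    (depletion-promoting) inside the window."""
    _, guides, obs, _, fm, _, state = default_screen_fit
    idx = np.arange(400)
    attr = attribute(state.forest, fm.fixed[idx], fm.fixed_names)
    dist = fm.fixed[idx, list(fm.fixed_names).index("dist_start_codon")]
    first = fm.fixed[idx, list(fm.fixed_names).index("targets_first_gene")] > 0
    prof = distance_effect_profile(attr, dist, first_gene=first)
    assert prof["difference"] < 0
    assert prof["inside"]["n"] > 0 and prof["outside"]["n"] > 0


def test_distance_profile_empty_stratum_flagged():
    from guidemix.interpretation import AttributionMatrix

    attr = AttributionMatrix(np.ones((5, 1)), 0.0, ("dist_start_codon",))
    prof = distance_effect_profile(attr, np.full(5, 10))
    assert prof["outside"]["mean"] is None
    assert prof["difference"] is None


def test_compiled_kernel_matches_reference_recursion():
    """The compiled attribution kernel and the reference recursion are the
    same arithmetic."""
    from guidemix.treeshap import tree_shap_values, tree_shap_values_reference

    rng = np.random.default_rng(12)
    X = rng.normal(size=(150, 6))
    y = X[:, 0] - X[:, 3] * (X[:, 1] > 0) + rng.normal(0, 0.2, 150)
    forest = RandomForestRegressor(
        n_estimators=5, max_depth=7, random_state=3, n_jobs=1
    ).fit(X, y)
    for t in forest.estimators_:
        pk, bk = tree_shap_values(t, X[:20])
        pr, br = tree_shap_values_reference(t, X[:20])
        assert np.allclose(pk, pr, atol=1e-12)
        assert bk == br
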