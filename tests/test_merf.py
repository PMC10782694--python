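"""Mixed-effect forest: BLUP formulas, EM degeneracies, variance-component
recovery against closed-form oracles, and parameter recovery on simulated
screens with known truth."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr
from sklearn.ensemble import RandomForestRegressor

from guidemix.merf import (
    Hyperparams,
    estep_blups,
    fit_merf,
    predict_fixed,
    predict_full,
    sample_hyperparams,
    tune_hyperparameters,
    with_intercept,
)


def test_hyperparams_range_validation():
    with pytest.raises(ValueError):
        Hyperparams(n_estimators=10)
    with pytest.raises(ValueError):
        Hyperparams(max_depth=40)
    with pytest.raises(ValueError):
        Hyperparams(max_features=0.0)


# --- BLUP ----------------------------------------------------------------


def test_blup_scalar_woodbury_identity():
    """Intercept-only BLUP has the closed scalar form
    b = d n rbar / (d n + sigma2); the matrix formula must agree."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 15))
        d = float(rng.uniform(0.1, 4.0))
        s2 = float(rng.uniform(0.1, 2.0))
        r = rng.normal(size=n)
        b = estep_blups(np.array([[d]]), s2, np.ones((n, 1)), r)
        expected = d * n * r.mean() / (d * n + s2)
        assert b[0] == pytest.approx(expected, rel=1e-10)


def test_blup_zero_covariance_and_limits():
    Z = np.column_stack([np.ones(4), np.arange(4.0)])
    r = np.array([1.0, 2.0, 0.5, -1.0])
    assert np.allclose(estep_blups(np.zeros((2, 2)), 1.0, Z, r), 0.0)
    # sigma2 -> 0 with full-rank Z: Z b approaches the projection of r
    b = estep_blups(np.eye(2), 1e-10, Z, r)
    proj = Z @ np.linalg.lstsq(Z, r, rcond=None)[0]
    assert np.allclose(Z @ b, proj, atol=1e-6)


def test_blup_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        estep_blups(np.eye(2), 1.0, np.ones((3, 1)), np.zeros(3))


# --- EM degeneracies ------------------------------------------------------


def _toy_data(seed=0, n_clusters=20, per=8, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_clusters * per, p))
    clusters = np.repeat([f"c{i}" for i in range(n_clusters)], per)
    g = rng.normal(scale=1.5, size=n_clusters)
    y = X[:, 0] * 1.0 + np.repeat(g, per) + rng.normal(scale=0.4, size=len(X))
    return X, clusters, y, g


def test_pinned_d_zero_equals_plain_forest():
    X, clusters, y, _ = _toy_data()
    Z = with_intercept(np.zeros((len(y), 0)))
    hp = Hyperparams(n_estimators=60, max_depth=5)
    state = fit_merf(X, Z, clusters, y, hp=hp, seed=3, pin_d_zero=True)
    plain = RandomForestRegressor(
        n_estimators=60, max_depth=5, max_features=hp.max_features,
        min_samples_leaf=hp.min_samples_leaf, min_samples_split=hp.min_samples_split,
        bootstrap=True, random_state=3, n_jobs=1,
    ).fit(X, y)
    assert np.array_equal(predict_fixed(state, X), plain.predict(X))
    assert all(np.all(b == 0) for b in state.b.values())


def test_variance_components_match_anova_oracle():
    """Constant fixed effect + intercept-only Z on balanced clusters: the
    EM estimates of sigma2 and d must match one-way random-intercept
    method-of-moments (MSW and (MSB-MSW)/n) within 5% relative error."""
    rng = np.random.default_rng(42)
    m, n_per = 60, 10
    d_true, s2_true = 2.0, 0.5
    g = rng.normal(scale=np.sqrt(d_true), size=m)
    y = (np.repeat(g, n_per) + rng.normal(scale=np.sqrt(s2_true), size=m * n_per))
    X = np.ones((m * n_per, 1))  # constant predictor -> forest fits the mean
    Z = np.ones((m * n_per, 1))
    clusters = np.repeat([f"c{i}" for i in range(m)], n_per)
    state = fit_merf(X, Z, clusters, y, hp=Hyperparams(n_estimators=50, max_depth=2),
                     max_iter=80, tol=1e-6, seed=0)
    # independent closed-form oracle
    means = y.reshape(m, n_per).mean(axis=1)
    msw = float(np.sum((y.reshape(m, n_per) - means[:, None]) ** 2) / (m * (n_per - 1)))
    msb = float(n_per * np.sum((means - means.mean()) ** 2) / (m - 1))
    d_mom = (msb - msw) / n_per
    assert abs(state.sigma2 - msw) / msw <= 0.05
    assert abs(state.D[0, 0] - d_mom) / d_mom <= 0.05


def test_sigma2_recovery_with_no_cluster_effects():
    """With true D = 0 the residual-variance estimate lands within 15% of
    truth at n = 3000."""
    rng = np.random.default_rng(1)
    n = 3000
    X = rng.normal(size=(n, 3))
    s2_true = 0.8
    y = np.sin(X[:, 0]) + rng.normal(scale=np.sqrt(s2_true), size=n)
    clusters = np.repeat([f"c{i}" for i in range(300)], 10)
    Z = with_intercept(np.zeros((n, 0)))
    state = fit_merf(X, Z, clusters, y, hp=Hyperparams(n_estimators=80, max_depth=6),
                     max_iter=25, seed=2)
    assert abs(state.sigma2 - s2_true) / s2_true <= 0.15


def test_gll_trace_stabilizes_and_d_psd():
    X, clusters, y, _ = _toy_data(seed=5)
    Z = with_intercept(np.zeros((len(y), 0)))
    state = fit_merf(X, Z, clusters, y, hp=Hyperparams(n_estimators=60, max_depth=5),
                     max_iter=50, tol=1e-3, seed=0)
    t = np.array(state.gll_trace)
    # relative GLL change settles to the sub-percent range on this toy
    assert abs(t[-1] - t[-2]) / abs(t[-2]) < 5e-3
    assert np.allclose(state.D, state.D.T)
    assert np.linalg.eigvalsh(state.D).min() >= -1e-8


def test_em_converges_on_default_preset(default_screen_fit):
    """EM reaches the relative-GLL stopping rule within its iteration cap
    on the default simulated screen."""
    *_, state = default_screen_fit
    assert state.converged
    assert len(state.gll_trace) <= 30


def test_non_finite_y_rejected():
    X, clusters, y, _ = _toy_data()
    y = y.copy()
    y[0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_merf(X, with_intercept(np.zeros((len(y), 0))), clusters, y,
                 hp=Hyperparams(n_estimators=50, max_depth=3))


# --- prediction contracts -------------------------------------------------


def test_predict_fixed_ignores_gene_context(default_screen_fit):
    _, _, obs, _, fm, y, state = default_screen_fit
    a = predict_fixed(state, fm.fixed[:50])
    # same X, shuffled Z / clusters: identical output by contract
    b = predict_full(state, fm.fixed[:50],
                     np.zeros((50, state.D.shape[0])), ["unseen"] * 50)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError, match="must be"):
        predict_fixed(state, fm.fixed[:5, :100])


def test_predict_full_uses_blups_and_shrinks_residuals(default_screen_fit):
    _, _, obs, _, fm, y, state = default_screen_fit
    Z = with_intercept(fm.random)
    full = predict_full(state, fm.fixed, Z, fm.clusters)
    fixed = predict_fixed(state, fm.fixed)
    assert np.var(y - full) < np.var(y - fixed)


def test_predict_full_unseen_cluster_equals_fixed(default_screen_fit):
    _, _, _, _, fm, _, state = default_screen_fit
    Z = with_intercept(fm.random[:10])
    out = predict_full(state, fm.fixed[:10], Z, ["never_seen"] * 10)
    assert np.array_equal(out, predict_fixed(state, fm.fixed[:10]))


# --- parameter recovery on the simulator preset ---------------------------


def test_parameter_recovery_default_preset(default_screen_fit):
    """On the default simulated screen (gene-effect SD 2.0, guide SD 1.0,
    noise SD 0.5) the fixed effect recovers guide-effect ranks and the
    per-gene random-effect BLUP prediction Z.b recovers gene effects.

    The full random effect (intercept plus slopes) is the model's gene-
    effect estimate: the generator couples gene effects to expression and
    operon context, and the EM rightly attributes that share to the
    corresponding slopes rather than the intercept."""
    _, _, obs, truth, fm, y, state = default_screen_fit
    pred = predict_fixed(state, fm.fixed)
    tg = np.array([truth.guide_effects[o.guide_id] for o in obs])
    assert spearmanr(pred, tg).statistic >= 0.7
    Z = with_intercept(fm.random)
    first_row = {}
    for i, c in enumerate(fm.clusters):
        first_row.setdefault(c, i)
    genes = sorted(state.b)
    eta = np.array([Z[first_row[g]] @ state.b[g] for g in genes])
    ge = np.array([truth.gene_effects[g] for g in genes])
    assert pearsonr(eta, ge).statistic >= 0.9


def test_merf_advantage_collapses_without_gene_effects():
    """When the simulation has no gene-level confounding, removing cluster
    effects cannot help: the mixed model and a plain forest perform the
    same within a small margin."""
    from guidemix.features import build_feature_matrix
    from guidemix.sim import PRESETS, design_guides, simulate_genome, simulate_screen
    from guidemix.thermo import ConstantEngine
    from dataclasses import replace

    cfg = replace(PRESETS["no_gene_effect"], n_genes=80)
    genome = simulate_genome(cfg)
    guides = design_guides(genome, cfg)
    obs, truth = simulate_screen(genome, guides, cfg)
    fm = build_feature_matrix(guides, genome.genes, obs, ConstantEngine(-1.0),
                              datasets=("sim", "_u1", "_u2"), od_caps={})
    y = np.array([o.logfc for o in obs])
    tg = np.array([truth.guide_effects[o.guide_id] for o in obs])
    hp = Hyperparams(n_estimators=100)
    Z = with_intercept(fm.random)
    merf = fit_merf(fm.fixed, Z, fm.clusters, y, hp=hp, max_iter=15, seed=4)
    plain = fit_merf(fm.fixed, Z, fm.clusters, y, hp=hp, seed=4, pin_d_zero=True)
    rho_merf = spearmanr(predict_fixed(merf, fm.fixed), tg).statistic
    rho_plain = spearmanr(predict_fixed(plain, fm.fixed), tg).statistic
    assert rho_merf - rho_plain <= 0.05


# --- hyperparameter search ------------------------------------------------


def test_sampled_configs_respect_ranges():
    rng = np.random.default_rng(10)
    for _ in range(100):
        hp = sample_hyperparams(rng)
        assert 50 <= hp.n_estimators <= 1000 and hp.n_estimators % 10 == 0
        assert 0 < hp.max_features <= 1
        assert 2 <= hp.max_depth <= 30
        assert 1 <= hp.min_samples_leaf <= 20
        assert 2 <= hp.min_samples_split <= 20
        assert isinstance(hp.bootstrap, bool)


def test_tuning_budget_monotone_and_valid():
    def objective(hp):
        return -abs(hp.max_depth - 17) - abs(hp.n_estimators - 300) / 100

    best1, score1 = tune_hyperparameters(objective, budget=1, seed=0)
    best20, score20 = tune_hyperparameters(objective, budget=20, seed=0)
    assert isinstance(best1, Hyperparams)
    assert score20 >= score1
    with pytest.raises(ValueError):
        tune_hyperparameters(objective, budget=0)


def test_tuning_failed_trials_logged_not_fatal(caplog):
    calls = []

    def flaky(hp):
        calls.append(hp)
        if len(calls) % 2:
            raise RuntimeError("boom")
        return float(len(calls))

    with caplog.at_level("WARNING"):
        best, score = tune_hyperparameters(flaky, budget=6, seed=1)
    assert score == 6.0
    assert any("scored -inf" in r.message for r in caplog.records)
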