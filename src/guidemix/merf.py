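"""Mixed-effect random forest for depletion screens.

The model for observation j of gene cluster i is

    y_ij = f(X_ij) + Z_ij . b_i + eps_ij,
    b_i ~ N(0, D),   eps_ij ~ N(0, sigma^2),

where f is a random-forest regressor over the 129 guide features (the
fixed effect: everything manipulable in guide design), and b_i is a
per-gene coefficient vector over an intercept plus the 9 standardized
gene/dataset features (the random effect: depletion scale and gene-level
confounders). Fitting alternates, EM-style, between

  M-step (forest): refit f on y with the current cluster effects removed;
  E-step (BLUP):   b_i = D Z_i' V_i^-1 (y_i - f(X_i)),
                   V_i = Z_i D Z_i' + sigma^2 I;
  M-step (variance components): closed-form updates of sigma^2 and D,

monitoring the generalized log-likelihood (GLL) until its relative change
falls below tolerance. The per-gene random intercept is what absorbs
between-screen and between-gene depletion scale, so raw logFCs can be
fused without explicit normalization. Prediction for new guides uses the
fixed effect only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparams:
    """Forest hyperparameters; defaults are midpoints of the search space."""

    bootstrap: bool = True
    n_estimators: int = 500
    max_features: float = 0.3
    max_depth: int = 15
    min_samples_leaf: int = 5
    min_samples_split: int = 2

    def __post_init__(self) -> None:
        if not 50 <= self.n_estimators <= 1000:
            raise ValueError("n_estimators must be in [50, 1000]")
        if not 0 < self.max_features <= 1:
            raise ValueError("max_features must be in (0, 1]")
        if not 2 <= self.max_depth <= 30:
            raise ValueError("max_depth must be in [2, 30]")
        if not 1 <= self.min_samples_leaf <= 20:
            raise ValueError("min_samples_leaf must be in [1, 20]")
        if not 2 <= self.min_samples_split <= 20:
            raise ValueError("min_samples_split must be in [2, 20]")

    def make_forest(self, seed: int, n_jobs: int = 1) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            bootstrap=self.bootstrap,
            random_state=seed,
            n_jobs=n_jobs,
        )


@dataclass
class MerfState:
    """A fitted mixed-effect forest."""

    forest: RandomForestRegressor
    D: np.ndarray
    sigma2: float
    b: dict[str, np.ndarray]
    gll_trace: list[float]
    hp: Hyperparams
    seed: int
    n_features: int
    converged: bool = False

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")


def with_intercept(Z: np.ndarray) -> np.ndarray:
    """Prepend the random-intercept column to the gene feature block."""
    Z = np.asarray(Z, dtype=float)
    return np.hstack([np.ones((Z.shape[0], 1)), Z])


def estep_blups(
    D: np.ndarray, sigma2: float, Z_i: np.ndarray, resid_i: np.ndarray
) -> np.ndarray:
    """BLUP of one cluster's random-effect coefficients."""
    Z_i = np.atleast_2d(np.asarray(Z_i, dtype=float))
    resid_i = np.asarray(resid_i, dtype=float)
    if Z_i.shape[0] != resid_i.shape[0] or D.shape != (Z_i.shape[1], Z_i.shape[1]):
        raise ValueError("dimension mismatch between D, Z_i and residuals")
    V = Z_i @ D @ Z_i.T + sigma2 * np.eye(Z_i.shape[0])
    return D @ Z_i.T @ np.linalg.solve(V, resid_i)


def _logdet_psd(D: np.ndarray) -> tuple[float, np.ndarray]:
    """log|D| and D^-1 with ridge jitter if D is numerically singular."""
    jitter = 0.0
    for _ in range(6):
        try:
            sign, logdet = np.linalg.slogdet(D + jitter * np.eye(D.shape[0]))
            if sign > 0:
                inv = np.linalg.inv(D + jitter * np.eye(D.shape[0]))
                if jitter:
                    logger.info("D ridge-regularized with jitter %.1e", jitter)
                return logdet, inv
        except np.linalg.LinAlgError:
            pass
        jitter = 1e-10 if jitter == 0 else jitter * 100
    raise np.linalg.LinAlgError("D not invertible even with ridge jitter")


def fit_merf(
    X: np.ndarray,
    Z: np.ndarray,
    clusters,
    y: np.ndarray,
    hp: Hyperparams | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int = 0,
    pin_d_zero: bool = False,
    n_jobs: int = 1,
) -> MerfState:
    """Fit the mixed-effect forest by EM.

    ``Z`` must already include the intercept column (see
    :func:`with_intercept`). ``tol`` is a relative GLL-change threshold.
    The forest is refit with the same ``seed`` every iteration so the
    fitted state is a deterministic function of (data, hp, seed).

    With ``pin_d_zero`` the random effects are switched off (D = 0,
    b = 0): the result is exactly a plain seeded forest on y, useful as a
    degenerate-case control.
    """
    hp = hp or Hyperparams()
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n, q = Z.shape
    labels = np.asarray(clusters)
    uniq, inv = np.unique(labels, return_inverse=True)
    groups = [np.flatnonzero(inv == k) for k in range(len(uniq))]

    if pin_d_zero:
        forest = hp.make_forest(seed, n_jobs).fit(X, y)
        resid = y - forest.predict(X)
        return MerfState(
            forest=forest,
            D=np.zeros((q, q)),
            sigma2=max(float(np.mean(resid**2)), np.finfo(float).tiny),
            b={g: np.zeros(q) for g in uniq},
            gll_trace=[],
            hp=hp,
            seed=seed,
            n_features=X.shape[1],
            converged=True,
        )

    # Initialization: no cluster effects, unit variance components.
    b = np.zeros((len(uniq), q))
    D = np.eye(q)
    sigma2 = 1.0
    gll_trace: list[float] = []
    converged = False
    forest = None

    for it in range(max_iter):
        # M-step, forest: remove current cluster effects and refit.
        y_star = y - np.einsum("ij,ij->i", Z, b[inv])
        forest = hp.make_forest(seed, n_jobs).fit(X, y_star)
        f = forest.predict(X)

        # E-step (BLUPs) and variance-component updates.
        sigma2_acc = 0.0
        D_acc = np.zeros((q, q))
        gll = 0.0
        logdet_D, D_inv = _logdet_psd(D)
        for k, idx in enumerate(groups):
            Zi = Z[idx]
            ni = len(idx)
            Vi = Zi @ D @ Zi.T + sigma2 * np.eye(ni)
            Vi_inv = np.linalg.inv(Vi)
            ri = y[idx] - f[idx]
            bi = D @ Zi.T @ Vi_inv @ ri
            b[k] = bi
            eps = ri - Zi @ bi
            sigma2_acc += eps @ eps + sigma2 * (ni - sigma2 * np.trace(Vi_inv))
            D_acc += np.outer(bi, bi) + (D - D @ Zi.T @ Vi_inv @ Zi @ D)
            gll += (
                eps @ eps / sigma2
                + bi @ D_inv @ bi
                + logdet_D
                + ni * np.log(sigma2)
            )
        sigma2 = max(sigma2_acc / n, np.finfo(float).tiny)
        D = D_acc / len(groups)
        D = 0.5 * (D + D.T)
        gll_trace.append(float(gll))
        if it > 0:
            denom = abs(gll_trace[-2]) + 1e-12
            if abs(gll_trace[-1] - gll_trace[-2]) / denom < tol:
                converged = True
                break

    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)
    return MerfState(
        forest=forest,
        D=D,
        sigma2=float(sigma2),
        b={g: b[k].copy() for k, g in enumerate(uniq)},
        gll_trace=gll_trace,
        hp=hp,
        seed=seed,
        n_features=X.shape[1],
        converged=converged,
    )


def predict_fixed(state: MerfState, X: np.ndarray) -> np.ndarray:
    """Guide-efficiency score: the fixed-effect (forest) prediction only.

    Independent of gene features and cluster identity by construction —
    this is what makes the score usable for new genes.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.n_features:
        raise ValueError(
            f"X must be (m, {state.n_features}), got {X.shape}"
        )
    return state.forest.predict(X)


def predict_full(
    state: MerfState, X: np.ndarray, Z: np.ndarray, clusters
) -> np.ndarray:
    """Fixed plus random-effect prediction; unseen clusters fall back to
    the fixed effect (b = 0)."""
    f = predict_fixed(state, X)
    Z = np.asarray(Z, dtype=float)
    out = f.copy()
    unseen = set()
    for i, c in enumerate(np.asarray(clusters)):
        bi = state.b.get(c)
        if bi is None:
            unseen.add(c)
            continue
        out[i] += Z[i] @ bi
    if unseen:
        logger.info("unseen clusters predicted with fixed effect only: %d", len(unseen))
    return out


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

SEARCH_SPACE = {
    "bootstrap": (False, True),
    "n_estimators": tuple(range(50, 1001, 10)),
    "max_features": (0.0, 1.0),  # continuous, open at 0
    "max_depth": tuple(range(2, 31)),
    "min_samples_leaf": tuple(range(1, 21)),
    "min_samples_split": tuple(range(2, 21)),
}


def sample_hyperparams(rng: np.random.Generator, space=None) -> Hyperparams:
    space = space or SEARCH_SPACE
    lo, hi = space["max_features"]
    mf = float(rng.uniform(lo, hi))
    mf = max(mf, 1e-6)  # open interval at 0
    return Hyperparams(
        bootstrap=bool(rng.choice(space["bootstrap"])),
        n_estimators=int(rng.choice(space["n_estimators"])),
        max_features=mf,
        max_depth=int(rng.choice(space["max_depth"])),
        min_samples_leaf=int(rng.choice(space["min_samples_leaf"])),
        min_samples_split=int(rng.choice(space["min_samples_split"])),
    )


def tune_hyperparameters(
    objective,
    space=None,
    budget: int = 20,
    seed: int = 0,
) -> tuple[Hyperparams, float]:
    """Seeded random search over the forest hyperparameter space.

    ``objective(hp) -> float`` is maximized (e.g. median per-gene Spearman
    under gene-wise cross-validation). Failed trials score -inf and are
    logged. Returns (best configuration, best score).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best_hp, best_score = None, -np.inf
    for t in range(budget):
        hp = sample_hyperparams(rng, space)
        try:
            score = float(objective(hp))
        except Exception as exc:  # noqa: BLE001 - trial isolation
            logger.warning("trial %d failed (%s); scored -inf", t, exc)
            score = -np.inf
        if score > best_score or best_hp is None:
            best_hp, best_score = hp, score
    return best_hp, best_score
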