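"""Multiple linear regression, genetic-algorithm subset selection, and the
frozen published equations.

The workhorse is :class:`DescriptorMLR`, an ordinary-least-squares regressor
in the scikit-learn estimator idiom that additionally exposes the QSAR fit
diagnostics (standardized coefficients, hat diagonal, s, F) needed by the
validation battery. :class:`GAFeatureSelector` evolves descriptor subsets of
bounded size (three, by convention of the published model) with
leave-one-out Q-squared as the fitness, elitism guaranteeing monotone best
fitness, and full seed reproducibility. The two published three-descriptor
equations for log % lipoxygenase inhibition are frozen in
:data:`PUBLISHED_EQUATIONS` and served by :func:`predict_published`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DescriptorMLR",
    "GAFeatureSelector",
    "GAConfig",
    "ols_fit",
    "standardized_coefficients",
    "ga_select",
    "PUBLISHED_EQUATIONS",
    "predict_published",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _ols_core(X: np.ndarray, y: np.ndarray):
    """Intercept-augmented least squares via QR.

    Returns (beta, residuals, hat_diag); beta[0] is the intercept. Raises
    ``np.linalg.LinAlgError`` on rank deficiency.
    """
    n = X.shape[0]
    Xa = np.column_stack([np.ones(n), X])
    Q, R = np.linalg.qr(Xa)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        raise np.linalg.LinAlgError(
            f"design matrix is rank-deficient (collinear columns at positions "
            f"{[int(b) - 1 for b in bad]})"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - Xa @ beta
    hat = np.sum(Q**2, axis=1)
    return beta, resid, hat


def _q2_loo_fast(X: np.ndarray, y: np.ndarray) -> float:
    """Closed-form leave-one-out Q2 (PRESS over hat residuals)."""
    try:
        _, resid, hat = _ols_core(X, y)
    except np.linalg.LinAlgError:
        return -np.inf
    one_minus_h = 1.0 - hat
    if np.any(one_minus_h <= 1e-12):
        return -np.inf
    press = np.sum((resid / one_minus_h) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return -np.inf
    return 1.0 - press / tss


class DescriptorMLR(BaseEstimator, RegressorMixin):
    """Ordinary least squares with QSAR diagnostics.

    Fitted attributes
    -----------------
    coef_, intercept_ : regression coefficients
    std_coef_ : standardized coefficients beta_j = b_j sd(x_j)/sd(y)
    residuals_, hat_diag_ : training residuals and leverages
    r2_, r2_adj_, s_, f_ : fit statistics (s is the residual standard
        deviation with n - p' denominator, F the overall regression F ratio)
    """

    def fit(self, X, y):
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n != len(y):
            raise ValueError("X and y have different lengths")
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
        beta, resid, hat = _ols_core(X, y)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.residuals_ = resid
        self.hat_diag_ = hat
        self.n_train_ = n
        sy = y.std(ddof=1)
        if sy == 0:
            raise ValueError("response has zero variance")
        self.std_coef_ = self.coef_ * X.std(axis=0, ddof=1) / sy
        rss = float(np.sum(resid**2))
        tss = float(np.sum((y - y.mean()) ** 2))
        p_prime = p + 1
        self.r2_ = 1.0 - rss / tss
        self.r2_adj_ = 1.0 - (1.0 - self.r2_) * (n - 1) / (n - p_prime)
        self.s_ = float(np.sqrt(rss / (n - p_prime)))
        self.f_ = (
            (self.r2_ / p) / ((1.0 - self.r2_) / (n - p_prime))
            if self.r2_ < 1.0
            else np.inf
        )
        self.X_train_ = X
        self.y_train_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X, _ = _as_matrix(X)
        return self.intercept_ + X @ self.coef_

    def q2_loo_(self) -> float:
        check_is_fitted(self, "coef_")
        return _q2_loo_fast(self.X_train_, self.y_train_)


def ols_fit(X, y) -> DescriptorMLR:
    """Fit an OLS model; thin wrapper over :class:`DescriptorMLR`."""
    return DescriptorMLR().fit(X, y)


def standardized_coefficients(model: DescriptorMLR) -> np.ndarray:
    """Standardized coefficients of a fitted model (unit-variance scale)."""
    check_is_fitted(model, "std_coef_")
    return model.std_coef_.copy()


@dataclass
class GAConfig:
    """Hyperparameters of the genetic subset search."""

    population_size: int = 200
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    subset_size: int = 3
    elitism: int = 5
    patience: int = 50
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


class GAFeatureSelector(BaseEstimator, TransformerMixin):
    """Genetic-algorithm descriptor-subset selection for MLR.

    Chromosomes are descriptor subsets of fixed size; fitness is the
    leave-one-out Q-squared of the OLS fit on the subset. Tournament
    selection, union-resampling crossover, per-gene replacement mutation,
    elitism, and a cache of evaluated subsets. Search stops early after
    ``patience`` generations without improvement. Fully reproducible for a
    given ``random_state``.
    """

    def __init__(
        self,
        subset_size: int = 3,
        population_size: int = 200,
        generations: int = 300,
        crossover_rate: float = 0.8,
        mutation_rate: float = 0.05,
        elitism: int = 5,
        patience: int = 50,
        top_k: int = 10,
        random_state: int = 0,
    ):
        self.subset_size = subset_size
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.patience = patience
        self.top_k = top_k
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            subset_size=self.subset_size,
            elitism=self.elitism,
            patience=self.patience,
            top_k=self.top_k,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        cfg = self._config()
        n, p = X.shape
        if p < cfg.subset_size:
            raise ValueError(f"need at least {cfg.subset_size} columns, got {p}")
        if n < cfg.subset_size + 3:
            raise ValueError(f"too few rows ({n}) for subsets of {cfg.subset_size}")
        rng = np.random.default_rng(cfg.seed)
        cache: dict[tuple[int, ...], float] = {}

        def fitness(subset: tuple[int, ...]) -> float:
            if subset not in cache:
                cache[subset] = _q2_loo_fast(X[:, list(subset)], y)
            return cache[subset]

        def random_subset() -> tuple[int, ...]:
            return tuple(sorted(rng.choice(p, size=cfg.subset_size, replace=False)))

        population = [random_subset() for _ in range(cfg.population_size)]
        scores = np.array([fitness(s) for s in population])
        best_history = []
        stagnant = 0
        for _gen in range(cfg.generations):
            order = np.argsort(-scores)
            population = [population[i] for i in order]
            scores = scores[order]
            best_history.append(float(scores[0]))
            if len(best_history) > 1 and best_history[-1] <= best_history[-2]:
                stagnant += 1
            else:
                stagnant = 0
            if stagnant >= cfg.patience:
                break
            next_pop = population[: cfg.elitism]
            while len(next_pop) < cfg.population_size:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(0, cfg.population_size, size=3)
                    parents.append(population[min(contenders)])  # pop is sorted
                if rng.random() < cfg.crossover_rate:
                    pool = sorted(set(parents[0]) | set(parents[1]))
                    child = tuple(
                        sorted(
                            rng.choice(pool, size=cfg.subset_size, replace=False)
                        )
                    )
                else:
                    child = parents[0]
                genes = list(child)
                for g in range(cfg.subset_size):
                    if rng.random() < cfg.mutation_rate:
                        free = np.setdiff1d(np.arange(p), genes)
                        genes[g] = int(rng.choice(free))
                next_pop.append(tuple(sorted(set(genes))) if len(set(genes)) == cfg.subset_size else random_subset())
            population = next_pop
            scores = np.array([fitness(s) for s in population])

        ranked = sorted(
            cache.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
        )[: cfg.top_k]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.ranking_ = [
            ([names[i] for i in subset], float(score)) for subset, score in ranked
        ]
        best_subset = ranked[0][0]
        self.best_subset_ = tuple(best_subset)
        self.best_fitness_ = float(ranked[0][1])
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[list(best_subset)] = True
        self.history_ = best_history
        self.best_model_ = DescriptorMLR().fit(X[:, list(best_subset)], y)
        self.best_model_.feature_names_in_ = np.asarray(
            [names[i] for i in best_subset], dtype=object
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, X.columns[self.support_]]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()


def ga_select(X, y, config: GAConfig | None = None) -> list[tuple[list[str], float]]:
    """Ranked (descriptor names, Q2_LOO) list from a seeded GA run."""
    config = config or GAConfig()
    sel = GAFeatureSelector(
        subset_size=config.subset_size,
        population_size=config.population_size,
        generations=config.generations,
        crossover_rate=config.crossover_rate,
        mutation_rate=config.mutation_rate,
        elitism=config.elitism,
        patience=config.patience,
        top_k=config.top_k,
        random_state=config.seed,
    ).fit(X, y)
    return sel.ranking_


#: The two frozen published equations for log % lipoxygenase inhibition,
#: in descriptor order (C-026, RDF035p, HATS8p). "std" holds the printed
#: standardized coefficients.
PUBLISHED_EQUATIONS: dict[str, dict] = {
    "eq1": {
        "intercept": 0.73,
        "coef": (0.40, 0.06, -1.59),
        "std": (0.66, 0.34, -0.30),
        "n_train": 29,
    },
    "eq2": {
        "intercept": 0.67,
        "coef": (0.42, 0.07, -1.85),
        "std": (0.72, 0.43, -0.36),
        "n_train": 28,
    },
}


def predict_published(
    c026: float, rdf035p: float, hats8p: float, model: str = "eq2"
) -> float:
    """log % inhibition from the frozen published coefficients."""
    try:
        eq = PUBLISHED_EQUATIONS[model]
    except KeyError:
        raise ValueError(f"model must be 'eq1' or 'eq2', got {model!r}") from None
    b1, b2, b3 = eq["coef"]
    return float(eq["intercept"] + b1 * c026 + b2 * rdf035p + b3 * hats8p)
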