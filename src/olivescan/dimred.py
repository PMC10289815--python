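"""Standardization, PCA, cardinality-constrained sparse PCA and GA search.

The modelling chain standardizes the colorimetric-index features on the
training split, then either

* projects onto the leading principal components retaining ~85% of the
  total variance (input to the PC-score network), or
* runs a sparse PCA whose per-component number of nonzero loadings
  (NNZL) is chosen by a small genetic algorithm, and keeps the raw
  indexes with a nonzero loading in any sparse component (input to the
  variable-selection network).

The sparse PCA is the elastic-net alternating scheme with a hard
cardinality constraint: each component's coefficient vector is obtained
by ridge regression (quadratic penalty 1e-6 by default) followed by
hard-thresholding to the NNZL largest-magnitude entries, alternating
with an orthogonal Procrustes update of the orthonormal basis, for at
most 200 iterations.  Adjusted explained variance of the sparse scores
is computed from their QR decomposition, so correlation between sparse
components is not double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureStandardizer",
    "VarianceCutoffPCA",
    "CardinalitySparsePCA",
    "GAConfig",
    "ReductionResult",
    "fit_pca",
    "fit_spca",
    "ga_select_nnzl",
    "select_variables",
]


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of a PCA or sparse-PCA fit.

    ``loadings`` is a p x k DataFrame (rows = feature names when known),
    ``scores`` the n x k score matrix, ``explained_variance_fraction``
    per-component fractions of total variance; ``nnzl`` and
    ``retained_variables`` are populated for sparse fits only.
    """

    loadings: pd.DataFrame
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    k_retained: int
    nnzl: np.ndarray | None = None
    retained_variables: tuple[str, ...] | None = None


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Center/scale features using training-split statistics only.

    Columns with zero training standard deviation are flagged constant
    and dropped (with a warning) so downstream eigendecompositions stay
    well posed.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        constant = sd.index[sd == 0].tolist()
        if constant:
            warnings.warn(f"dropping constant feature columns: {constant}", stacklevel=2)
        keep = [c for c in X.columns if c not in constant]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.columns_ = keep
        self.constant_columns_ = constant
        self.mean_ = mean[keep]
        self.scale_ = sd[keep]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = self._as_frame(X)
        return (X[self.columns_] - self.mean_) / self.scale_

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _sign_convention(loadings: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


class VarianceCutoffPCA(TransformerMixin, BaseEstimator):
    """PCA retaining the smallest k with cumulative variance >= cutoff.

    Operates on already-standardized data: the eigendecomposition is of
    ``X.T @ X / (n - 1)`` (the feature correlation matrix for
    unit-variance input).  ``transform`` projects onto the retained
    components using training-fitted loadings only.
    """

    def __init__(self, variance_cutoff: float = 0.85):
        self.variance_cutoff = variance_cutoff

    def fit(self, X, y=None):
        X, names = _as_matrix(X)
        if np.isnan(X).any():
            raise ValueError("input contains NaN; impute before PCA")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least two samples")
        cov = X.T @ X / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = _sign_convention(evecs[:, order])
        total = evals.sum()
        frac = evals / total if total > 0 else np.zeros_like(evals)
        cum = np.cumsum(frac)
        k = int(np.searchsorted(cum, self.variance_cutoff) + 1)
        k = min(k, len(evals))
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.eigenvalues_ = evals
        self.loadings_ = evecs
        self.explained_variance_ratio_ = frac
        self.k_retained_ = k
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X, _ = _as_matrix(X)
        return X @ self.loadings_[:, : self.k_retained_]

    def to_result(self, X) -> ReductionResult:
        check_is_fitted(self, "loadings_")
        k = self.k_retained_
        loadings = pd.DataFrame(
            self.loadings_[:, :k],
            index=list(self.feature_names_in_),
            columns=[f"PC{j + 1}" for j in range(k)],
        )
        return ReductionResult(
            loadings=loadings,
            scores=self.transform(X),
            explained_variance_fraction=self.explained_variance_ratio_[:k],
            k_retained=k,
        )


class CardinalitySparsePCA(TransformerMixin, BaseEstimator):
    """Sparse PCA with a per-component cardinality (NNZL) constraint.

    Parameters
    ----------
    nnzl : sequence of int
        Number of nonzero loadings allowed per component; its length sets
        the number of components.
    max_iter : int
        Maximum alternating iterations (default 200).
    ridge_penalty : float
        Quadratic penalty of the ridge step (default 1e-6).
    tol : float
        Convergence threshold on the max absolute change of the
        unit-normalized loadings.
    """

    def __init__(
        self,
        nnzl=(10, 10),
        max_iter: int = 200,
        ridge_penalty: float = 1e-6,
        tol: float = 1e-6,
    ):
        self.nnzl = nnzl
        self.max_iter = max_iter
        self.ridge_penalty = ridge_penalty
        self.tol = tol

    def fit(self, X, y=None):
        X, names = _as_matrix(X)
        n, p = X.shape
        nnzl = np.asarray(self.nnzl, dtype=int)
        k = nnzl.size
        if np.any(nnzl < 1) or np.any(nnzl > p):
            raise ValueError(f"nnzl entries must lie in [1, {p}], got {nnzl}")
        if k > p:
            raise ValueError("more components than features")

        xtx = X.T @ X
        evals, evecs = np.linalg.eigh(xtx)
        order = np.argsort(evals)[::-1]
        A = evecs[:, order[:k]]
        chol = linalg.cho_factor(xtx + self.ridge_penalty * np.eye(p))

        B_norm_prev = np.zeros((p, k))
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            B = linalg.cho_solve(chol, xtx @ A)
            for j in range(k):
                keep = np.argsort(np.abs(B[:, j]))[::-1][: nnzl[j]]
                mask = np.zeros(p, dtype=bool)
                mask[keep] = True
                B[~mask, j] = 0.0
            B_norm = _unit_columns(B)
            # Procrustes update of the orthonormal basis
            u, _, vt = np.linalg.svd(xtx @ B, full_matrices=False)
            A = u @ vt
            if np.max(np.abs(B_norm - B_norm_prev)) < self.tol:
                B_norm_prev = B_norm
                break
            B_norm_prev = B_norm

        loadings = _sign_convention(B_norm_prev)
        scores = X @ loadings
        total_var = np.trace(xtx) / (n - 1)
        # adjusted explained variance via QR of the sparse scores
        r_diag = np.abs(np.diag(np.linalg.qr(scores, mode="r")))
        adj_var = r_diag**2 / (n - 1)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.loadings_ = loadings
        self.nnzl_ = nnzl
        self.n_iter_ = n_iter
        self.adjusted_variance_fraction_ = (
            adj_var / total_var if total_var > 0 else np.zeros(k)
        )
        self.apev_ = float(self.adjusted_variance_fraction_.sum())
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X, _ = _as_matrix(X)
        return X @ self.loadings_

    def to_result(self, X) -> ReductionResult:
        check_is_fitted(self, "loadings_")
        k = self.nnzl_.size
        loadings = pd.DataFrame(
            self.loadings_,
            index=list(self.feature_names_in_),
            columns=[f"SPC{j + 1}" for j in range(k)],
        )
        retained = tuple(
            str(name)
            for name, row in zip(self.feature_names_in_, self.loadings_)
            if np.any(row != 0)
        )
        return ReductionResult(
            loadings=loadings,
            scores=self.transform(X),
            explained_variance_fraction=self.adjusted_variance_fraction_,
            k_retained=k,
            nnzl=self.nnzl_,
            retained_variables=retained,
        )


def _unit_columns(B: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(B, axis=0)
    out = B.copy()
    nz = norms > 0
    out[:, nz] = out[:, nz] / norms[nz]
    return out


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


# ---------------------------------------------------------------------------
# functional surface


def fit_pca(X, variance_cutoff: float = 0.85) -> ReductionResult:
    """PCA of standardized features with a cumulative-variance cutoff."""
    est = VarianceCutoffPCA(variance_cutoff=variance_cutoff).fit(X)
    return est.to_result(X)


def fit_spca(
    X,
    nnzl,
    max_iter: int = 200,
    ridge_penalty: float = 1e-6,
    tol: float = 1e-6,
) -> ReductionResult:
    """Cardinality-constrained sparse PCA (see :class:`CardinalitySparsePCA`)."""
    est = CardinalitySparsePCA(
        nnzl=nnzl, max_iter=max_iter, ridge_penalty=ridge_penalty, tol=tol
    ).fit(X)
    return est.to_result(X)


def select_variables(result: ReductionResult) -> tuple[str, ...]:
    """Names with a nonzero loading in any sparse component, counted once."""
    nonzero = (result.loadings.to_numpy() != 0).any(axis=1)
    return tuple(str(n) for n, nz in zip(result.loadings.index, nonzero) if nz)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the per-component NNZL search."""

    population_size: int = 20
    n_generations: int = 50
    tournament_size: int = 3
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_count: int = 1
    sparsity_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def ga_fitness(X, nnzl, cpv_pca: float, sparsity_weight: float) -> float:
    """Fitness of one NNZL chromosome.

    Adjusted explained variance of the sparse fit relative to the
    retained-PCA cumulative variance, minus a sparsity penalty
    proportional to the total cardinality.
    """
    nnzl = np.asarray(nnzl, dtype=int)
    k = nnzl.size
    p = X.shape[1] if not isinstance(X, pd.DataFrame) else X.shape[1]
    apev = fit_spca(X, nnzl).explained_variance_fraction.sum()
    return float(apev / cpv_pca - sparsity_weight * nnzl.sum() / (k * p))


def ga_select_nnzl(X, k: int, config: GAConfig) -> np.ndarray:
    """Choose per-component NNZL by a seeded genetic algorithm.

    Integer chromosomes of length ``k`` with genes in ``[1, p]`` evolve
    under tournament selection, uniform crossover, one-step integer
    mutation and elitism; fitness is :func:`ga_fitness`.  Deterministic
    for a fixed ``config.seed``.
    """
    Xm, _ = _as_matrix(X)
    n, p = Xm.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(f"k={k} exceeds the number of features p={p}")

    pca = fit_pca(X, variance_cutoff=1.1)  # keep everything, slice below
    cpv = float(np.sort(pca.explained_variance_fraction)[::-1][:k].sum())
    if cpv <= 0:
        raise ValueError("data has no variance")

    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = tuple(int(c) for c in chrom)
        if key not in cache:
            cache[key] = ga_fitness(X, chrom, cpv, config.sparsity_weight)
        return cache[key]

    pop = rng.integers(1, p + 1, size=(config.population_size, k))
    best: np.ndarray | None = None
    best_fit = -np.inf
    for _ in range(config.n_generations):
        fits = np.array([fitness(c) for c in pop])
        order = np.argsort(fits)[::-1]
        if fits[order[0]] > best_fit:
            best_fit = float(fits[order[0]])
            best = pop[order[0]].copy()
        new_pop = [pop[i].copy() for i in order[: config.elitism_count]]
        while len(new_pop) < config.population_size:
            pa = _tournament(pop, fits, config.tournament_size, rng)
            pb = _tournament(pop, fits, config.tournament_size, rng)
            if rng.random() < config.crossover_prob:
                swap = rng.random(k) < 0.5
                child = np.where(swap, pb, pa)
            else:
                child = pa.copy()
            mutate = rng.random(k) < config.mutation_prob
            step = rng.choice([-1, 1], size=k)
            child = np.clip(child + mutate * step, 1, p).astype(int)
            new_pop.append(child)
        pop = np.array(new_pop)
    fits = np.array([fitness(c) for c in pop])
    i = int(np.argmax(fits))
    if fits[i] > best_fit:
        best, best_fit = pop[i].copy(), float(fits[i])
    assert best is not None
    return np.asarray(best, dtype=int)


def _tournament(pop: np.ndarray, fits: np.ndarray, size: int, rng) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=size)
    return pop[idx[np.argmax(fits[idx])]]
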