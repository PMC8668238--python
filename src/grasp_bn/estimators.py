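"""Scikit-learn-style estimators wrapping the three learning stages.

:class:`DoubleFilter` is the constraint-based screen alone (fit -> fitted
``skeleton_``); :class:`GRASP` is the full pipeline — screen, adaptive-SMC
orientation search, random-order hill climbing — whose fitted attributes are
the learned DAG and its BIC.  Both follow the sklearn estimator contract
(``get_params``/``set_params``, ``fit(X)``, trailing-underscore fitted
attributes), so they compose with ``sklearn.base.clone`` and grid search.

``X`` may be an integer matrix of category indices (arities inferred as
``max+1`` per column), or a :class:`~grasp_bn.data_model.CategoricalDataset`.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .adsmc import SMCParams, run_adsmc, select_best
from .data_model import CategoricalDataset, Variable
from .rohc import refine_samples
from .scoring import ScoreCache, network_bic
from .skeleton_df import run_df

__all__ = ["DoubleFilter", "GRASP", "as_dataset"]


def as_dataset(X) -> CategoricalDataset:
    """Coerce an integer matrix (or pass through a dataset) for learning."""
    if isinstance(X, CategoricalDataset):
        return X
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array of category indices")
    if not np.issubdtype(X.dtype, np.integer):
        Xf = X.astype(float)
        if np.isnan(Xf).any():
            raise ValueError("X contains missing values")
        Xi = Xf.astype(np.int64)
        if not np.array_equal(Xi, Xf):
            raise ValueError("X must contain integer category indices")
        X = Xi
    if X.min() < 0:
        raise ValueError("category indices must be nonnegative")
    arities = X.max(axis=0).astype(int) + 1
    variables = [
        Variable(f"X{j}", max(int(a), 1), tuple(f"c{s}" for s in range(max(int(a), 1))))
        for j, a in enumerate(arities)
    ]
    return CategoricalDataset(variables, X)


class DoubleFilter(BaseEstimator):
    """Constraint-based skeleton screen (stage 1 only).

    Parameters
    ----------
    alpha : float, default 0.01
        Per-test significance level of the marginal and conditional G-tests.
    variant : {"dseparation", "literal"}, default "dseparation"
        Which reading of the conditional prune to apply; see
        :mod:`grasp_bn.skeleton_df`.

    Attributes
    ----------
    skeleton_ : Skeleton
        Estimated undirected edge cover.
    n_features_in_ : int
    """

    def __init__(self, alpha: float = 0.01, variant: str = "dseparation"):
        self.alpha = alpha
        self.variant = variant

    def fit(self, X, y=None):
        data = as_dataset(X)
        self.skeleton_ = run_df(data, self.alpha, variant=self.variant)
        self.n_features_in_ = data.p
        return self

    def transform(self, X):
        """Pass-through; fitting is the product.  Present for pipelines."""
        check_is_fitted(self, "skeleton_")
        return X


class GRASP(BaseEstimator):
    """Three-stage Bayesian-network structure learner.

    Stage 1 screens edges with marginal and single-conditioning G-tests;
    stage 2 orients the surviving skeleton with an adaptive SMC sampler at
    Boltzmann temperature ``temperature``; stage 3 hill-climbs extra edges
    (in random parent order) to reclaim anything the screen missed.  The
    fitted model is the highest-BIC network over all SMC samples.

    Parameters
    ----------
    alpha : float, default 0.01
        Significance level of the screening tests.
    temperature : float, default 0.001
        Boltzmann temperature of the configuration sampler; smaller is
        greedier.
    n_samples : int, default 2000
        Number of independent SMC samples.
    rohc_rounds : int, default 5
        Hill-climbing sweeps per refined sample (0 disables stage 3).
    rohc_top_k : int or None, default None
        Refine only the k best samples; None refines all.
    search_limit : int or None, default None
        Hill-climbing evaluation budget per network; None means 2*p^2.
    random_state : int, default 0
        Base seed; sample s derives its own generator from (seed, s).
    n_jobs : int, default 1
        Parallel workers for SMC sampling (results are worker-invariant).
    df_variant : str, default "dseparation"
        Screening variant, as in :class:`DoubleFilter`.

    Attributes
    ----------
    dag_ : DAG
        Learned structure.
    score_ : float
        Its network BIC (higher-is-better scale: ln L - (k/2) ln n).
    skeleton_ : Skeleton
        The stage-1 screen output.
    samples_scores_ : ndarray
        Scores of all refined SMC samples.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        temperature: float = 0.001,
        n_samples: int = 2000,
        rohc_rounds: int = 5,
        rohc_top_k: int | None = None,
        search_limit: int | None = None,
        random_state: int = 0,
        n_jobs: int = 1,
        df_variant: str = "dseparation",
    ):
        self.alpha = alpha
        self.temperature = temperature
        self.n_samples = n_samples
        self.rohc_rounds = rohc_rounds
        self.rohc_top_k = rohc_top_k
        self.search_limit = search_limit
        self.random_state = random_state
        self.n_jobs = n_jobs
        self.df_variant = df_variant

    def _params(self) -> SMCParams:
        if not isinstance(self.random_state, numbers.Integral):
            raise ValueError("random_state must be an integer seed")
        return SMCParams(
            n_samples=self.n_samples,
            temperature=self.temperature,
            seed=int(self.random_state),
            rohc_rounds=self.rohc_rounds,
            rohc_top_k=self.rohc_top_k,
            search_limit=self.search_limit,
            n_jobs=self.n_jobs,
        )

    def fit(self, X, y=None, skeleton=None):
        """Learn a structure from X; ``skeleton`` overrides stage 1."""
        data = as_dataset(X)
        params = self._params()
        self.skeleton_ = (
            skeleton
            if skeleton is not None
            else run_df(data, self.alpha, variant=self.df_variant)
        )
        cache = ScoreCache()
        samples = run_adsmc(data, self.skeleton_, params, cache)
        samples = refine_samples(
            data,
            samples,
            rounds=params.rohc_rounds,
            seed=params.seed,
            top_k=params.rohc_top_k,
            search_limit=params.search_limit,
            cache=cache,
        )
        best = select_best(samples)
        self.dag_ = best.dag
        self.score_ = best.score
        self.samples_scores_ = np.array([s.score for s in samples])
        self.n_features_in_ = data.p
        return self

    def score(self, X, y=None) -> float:
        """Network BIC of the fitted structure on (possibly new) data."""
        check_is_fitted(self, "dag_")
        return network_bic(as_dataset(X), self.dag_)
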