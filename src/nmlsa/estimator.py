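"""Scikit-learn style estimator for network-based modular latent structure
analysis.

`NMLSA` follows the decomposition-estimator contract: ``fit`` on an
(n_samples, n_features) matrix learns the modules, their latent factors and
the sparse loading matrix; ``transform`` maps (new) samples onto the K
recovered factors. The step-level pipeline functions in the sibling modules
remain usable on the features-by-samples orientation native to expression
data; this class is the recommended entry point.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .config import RunConfig
from .factors import extract_module_factors
from .global_model import build_global_model
from .io import ExpressionMatrix
from .modules import detect_communities, filter_small, merge_outliers
from .network import build_network


class NMLSA(BaseEstimator, TransformerMixin):
    """Network-based modular latent structure analysis.

    Decomposes expression data into quasi-independent modules, each driven
    by one or more (possibly correlated) latent factors, yielding the
    global model G = L B + E with sparse loadings L.

    Parameters mirror :class:`~nmlsa.config.RunConfig`; see there for
    semantics and defaults.

    Attributes (after ``fit``)
    --------------------------
    n_modules_ : int
    labels_ : ndarray (n_features,)
        Module label per feature; -1 for features in no module.
    module_models_ : list of ModuleFactorModel
    components_ : ndarray (K, n_features)
        Transposed global loading matrix (sklearn decomposition layout).
    factor_scores_ : ndarray (n_samples_fit_, K)
        Factor activities of the training samples (B transposed).
    factor_module_map_ : ndarray (K,)
    graph_ : CoexpressionGraph
    """

    def __init__(self, lfdr_threshold: float = 0.2, walktrap_steps: int = 4,
                 min_module_size: int = 10, variance_fraction: float = 0.05,
                 interactivity_alpha: float = 0.05,
                 loading_mode: str = "per_module_ols",
                 positive_only: bool = False, standardize: bool = False,
                 correlation_method: str = "pearson",
                 random_state: int | None = None):
        self.lfdr_threshold = lfdr_threshold
        self.walktrap_steps = walktrap_steps
        self.min_module_size = min_module_size
        self.variance_fraction = variance_fraction
        self.interactivity_alpha = interactivity_alpha
        self.loading_mode = loading_mode
        self.positive_only = positive_only
        self.standardize = standardize
        self.correlation_method = correlation_method
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            lfdr_threshold=self.lfdr_threshold,
            walktrap_steps=self.walktrap_steps,
            min_module_size=self.min_module_size,
            variance_fraction=self.variance_fraction,
            interactivity_alpha=self.interactivity_alpha,
            loading_mode=self.loading_mode,
            positive_only=self.positive_only,
            standardize=self.standardize,
            correlation_method=self.correlation_method,
            seed=self.random_state if self.random_state is not None else 0)

    def fit(self, X, y=None) -> "NMLSA":
        """Learn modules, factors and loadings from (n_samples, n_features)
        data."""
        X = check_array(X, dtype=float)
        cfg = self._config()
        G = X.T                                   # features x samples
        if self.standardize:
            G = (G - G.mean(axis=1, keepdims=True)) / G.std(axis=1,
                                                            keepdims=True)
        expr = ExpressionMatrix(G,
                                [f"f{i}" for i in range(G.shape[0])],
                                [f"s{j}" for j in range(G.shape[1])])
        graph = build_network(expr, cfg)
        partition = detect_communities(graph, steps=cfg.walktrap_steps)
        if partition.n_communities >= 2:
            partition = merge_outliers(partition, graph)
        partition = filter_small(partition, cfg.min_module_size, graph)
        models = [extract_module_factors(G[sorted(members)],
                                         cfg.variance_fraction,
                                         cfg.interactivity_alpha)
                  for members in partition.communities]
        gm = build_global_model(G, models, partition, cfg.loading_mode)

        self.n_features_in_ = G.shape[0]
        self.n_samples_fit_ = G.shape[1]
        self.graph_ = graph
        self.partition_ = partition
        self.labels_ = partition.labels(G.shape[0])
        self.n_modules_ = partition.n_communities
        self.module_models_ = models
        self.global_model_ = gm
        self.components_ = gm.L.T
        self.factor_scores_ = gm.B.T
        self.factor_module_map_ = gm.factor_module_map
        self.feature_means_ = G.mean(axis=1)
        return self

    def transform(self, X) -> np.ndarray:
        """Project samples onto the fitted factors by least squares against
        the loading matrix: b = argmin ||g - L b||^2 per sample."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted model")
        if self.components_.shape[0] == 0:
            return np.zeros((X.shape[0], 0))
        L = self.components_.T                      # (p, K)
        Xc = X - self.feature_means_[None, :]
        return np.linalg.lstsq(L, Xc.T, rcond=None)[0].T

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.factor_scores_

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct expression from factor activities."""
        check_is_fitted(self, "components_")
        scores = np.asarray(scores, dtype=float)
        return scores @ self.components_ + self.feature_means_[None, :]


def fit_pipeline(expr: ExpressionMatrix, cfg: RunConfig | None = None) -> NMLSA:
    """Run the full pipeline on a features-by-samples ExpressionMatrix."""
    cfg = cfg or RunConfig()
    est = NMLSA(lfdr_threshold=cfg.lfdr_threshold,
                walktrap_steps=cfg.walktrap_steps,
                min_module_size=cfg.min_module_size,
                variance_fraction=cfg.variance_fraction,
                interactivity_alpha=cfg.interactivity_alpha,
                loading_mode=cfg.loading_mode,
                positive_only=cfg.positive_only,
                standardize=cfg.standardize,
                correlation_method=cfg.correlation_method,
                random_state=cfg.seed)
    return est.fit(expr.values.T)
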