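"""Build the lfdr-thresholded co-expression graph.

Edges connect feature pairs whose correlation, transformed to an
approximately normal statistic, has local fdr below the configured
threshold — i.e. pairs unlikely to be independent given the ensemble of
all pairwise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .config import RunConfig
from .io import ExpressionMatrix
from .lfdr import MIN_STATISTICS, edge_mask, estimate_lfdr

# t at |r| = 1 - 1e-12: finite stand-in for a perfectly correlated pair
_R_CLAMP = 1.0 - 1e-12


@dataclass
class CoexpressionGraph:
    """Undirected graph over features; edges carry (r, lfdr)."""

    n_features: int
    edges: np.ndarray       # int (m, 2), i < j, 0-based
    edge_r: np.ndarray      # float (m,)
    edge_lfdr: np.ndarray   # float (m,)
    threshold_used: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must satisfy i < j (no self-loops)")
        if self.edges.size:
            uniq = {(int(i), int(j)) for i, j in self.edges}
            if len(uniq) != len(self.edges):
                raise ValueError("duplicate edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def pairwise_correlation(X: ExpressionMatrix | np.ndarray,
                         method: str = "pearson") -> np.ndarray:
    """Correlations r_ij for all feature pairs i < j, in condensed order
    (the row-major upper triangle, matching scipy's squareform)."""
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if np.any(values.var(axis=1) == 0.0):
        raise ValueError("zero-variance feature row; drop it before "
                         "computing correlations")
    if method == "spearman":
        values = rankdata(values, axis=1)
    corr = np.corrcoef(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return np.clip(corr[iu], -1.0, 1.0)


def correlation_to_t(r: np.ndarray, n: int) -> np.ndarray:
    """Map correlations to t = r * sqrt((n - 2) / (1 - r^2)).

    Under pairwise independence this statistic is close to standard normal
    for moderate n. |r| = 1 is clamped to keep the statistic finite.
    """
    if n <= 2:
        raise ValueError("need more than 2 samples for the t-transform")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    return r * np.sqrt((n - 2) / (1.0 - r * r))


def build_network(X: ExpressionMatrix, cfg: RunConfig | None = None) -> CoexpressionGraph:
    """Compose correlation -> t-transform -> lfdr -> thresholding.

    Isolated features are permitted; they simply join no module downstream.
    """
    cfg = cfg or RunConfig()
    r = pairwise_correlation(X, method=cfg.correlation_method)
    t = correlation_to_t(r, X.n_samples)
    if t.size >= MIN_STATISTICS:
        fit = estimate_lfdr(t, n_bins=cfg.lfdr_bins,
                            spline_df=cfg.lfdr_spline_df,
                            null_method=cfg.null_method,
                            random_state=cfg.seed)
        lfdr_values = fit.lfdr_values
    else:
        # Too few pairs to estimate the mixture density: fall back to a
        # conservative surrogate, the BH-adjusted two-sided p-value under
        # the theoretical normal null.
        from statsmodels.stats.multitest import multipletests
        pvals = 2.0 * norm.sf(np.abs(t))
        lfdr_values = multipletests(pvals, method="fdr_bh")[1]
    mask = lfdr_values < cfg.lfdr_threshold
    if cfg.positive_only:
        mask &= r > 0
    iu = np.triu_indices(X.n_features, k=1)
    edges = np.column_stack([iu[0][mask], iu[1][mask]])
    return CoexpressionGraph(n_features=X.n_features, edges=edges,
                             edge_r=r[mask], edge_lfdr=lfdr_values[mask],
                             threshold_used=cfg.lfdr_threshold)


def write_edge_list(graph: CoexpressionGraph, path,
                    feature_ids=None) -> None:
    """Edge list TSV: feature_i, feature_j, r, lfdr."""
    import pandas as pd

    def fid(i):
        return feature_ids[i] if feature_ids is not None else str(i)

    df = pd.DataFrame({
        "feature_i": [fid(i) for i in graph.edges[:, 0]],
        "feature_j": [fid(j) for j in graph.edges[:, 1]],
        "r": graph.edge_r,
        "lfdr": graph.edge_lfdr,
    })
    df.to_csv(path, sep="\t", index=False)
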