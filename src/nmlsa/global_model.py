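"""Assemble module factors into the global sparse factor model G = L B + E.

B stacks the factor score rows of every module (K x n); L (p x K) is filled
either by regressing each gene on the factors of its own module only
(block-sparse by construction) or by lasso over all K factors with
BIC-selected penalty and an OLS refit on the chosen support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import lasso_path

from .factors import ModuleFactorModel
from .io import ExpressionMatrix
from .modules import ModulePartition

logger = logging.getLogger("nmlsa")


@dataclass
class GlobalFactorModel:
    """Combined factor activity B (K x n), sparse loadings L (p x K) and
    residuals E = G_centered - L B."""

    B: np.ndarray
    L: np.ndarray
    E: np.ndarray
    factor_module_map: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.B.shape[0]


def assemble_factors(models: Sequence[ModuleFactorModel]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Row-stack module factor scores into B; map each row to its module."""
    if len(models) == 0:
        return np.zeros((0, 0)), np.zeros(0, dtype=int)
    ns = {m.factor_scores.shape[1] for m in models}
    if len(ns) != 1:
        raise ValueError("module factor models disagree on sample count")
    B = np.vstack([m.factor_scores for m in models])
    fmap = np.concatenate([np.full(m.n_factors, c, dtype=int)
                           for c, m in enumerate(models)])
    return B, fmap


def loadings_per_module_ols(X: ExpressionMatrix | np.ndarray,
                            B: np.ndarray,
                            partition: ModulePartition,
                            factor_module_map: np.ndarray) -> np.ndarray:
    """OLS of each centered feature on the factors of its own module.

    Features assigned to no module get zero rows, so L's sparsity pattern
    is exactly the module-membership block pattern.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    Xc = values - values.mean(axis=1, keepdims=True)
    p = Xc.shape[0]
    K = B.shape[0]
    L = np.zeros((p, K))
    for c, members in enumerate(partition.communities):
        cols = np.where(factor_module_map == c)[0]
        if cols.size == 0 or len(members) == 0:
            continue
        F = B[cols]                     # (r, n)
        if F.shape[0] >= F.shape[1]:
            raise ValueError("module factor count must be below the "
                             "sample count for OLS")
        rows = sorted(members)
        gram = F @ F.T
        try:
            coef = np.linalg.solve(gram, F @ Xc[rows].T)
        except np.linalg.LinAlgError:
            logger.warning("collinear factors in module %d; ridge fallback", c)
            coef = np.linalg.solve(gram + 1e-8 * np.eye(len(cols)),
                                   F @ Xc[rows].T)
        L[np.ix_(rows, cols)] = coef.T
    return L


def _best_support_by_bic(y: np.ndarray, coefs: np.ndarray, B: np.ndarray,
                         max_support: int) -> np.ndarray:
    """Scan the distinct supports along a lasso path and return the one
    minimizing BIC = n log(RSS/n) + df log(n), with RSS from the OLS refit
    on the support (the shrunken-path RSS keeps rewarding smaller
    penalties through debiasing of the true coefficients, which makes it
    overselect). Ties go to the sparser support."""
    n = y.size
    tss = float(y @ y)
    best_bic = n * np.log(max(tss, 1e-300) / n)   # empty support
    best: np.ndarray = np.array([], dtype=int)
    seen = set()
    for j in range(coefs.shape[1]):
        support = np.flatnonzero(coefs[:, j])
        key = support.tobytes()
        if key in seen or not 0 < support.size <= max_support:
            continue
        seen.add(key)
        Fs = B[support]
        coef = np.linalg.lstsq(Fs.T, y, rcond=None)[0]
        resid = y - Fs.T @ coef
        rss = max(float(resid @ resid), 1e-300)
        bic = n * np.log(rss / n) + support.size * np.log(n)
        if bic < best_bic - 1e-12 or (abs(bic - best_bic) <= 1e-12
                                      and support.size < best.size):
            best_bic, best = bic, support
    return best


def loadings_lasso_bic(X: ExpressionMatrix | np.ndarray,
                       B: np.ndarray,
                       n_lambdas: int = 100,
                       lambda_min_ratio: float = 1e-3) -> np.ndarray:
    """Sparse loadings by per-gene lasso over all factors with BIC model
    selection, coefficients refit by OLS on the selected support.

    The penalty grid is log-spaced from lambda_max (smallest penalty
    zeroing every coefficient) down to lambda_max * lambda_min_ratio.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if B.shape[0] < 1:
        raise ValueError("need at least one factor")
    Xc = values - values.mean(axis=1, keepdims=True)
    p, n = Xc.shape
    K = B.shape[0]
    design = B.T                                       # (n, K)
    L = np.zeros((p, K))
    max_support = min(K, n - 1)
    for i in range(p):
        y = Xc[i]
        lam_max = np.max(np.abs(design.T @ y)) / n
        if lam_max <= 0:
            continue
        lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
        _, coefs, _ = lasso_path(design, y, alphas=lams)
        support = _best_support_by_bic(y, coefs, B, max_support)
        if support.size == 0:
            continue
        Fs = B[support]
        coef = np.linalg.solve(Fs @ Fs.T, Fs @ y)      # debiasing refit
        L[i, support] = coef
    return L


def build_global_model(X: ExpressionMatrix | np.ndarray,
                       models: Sequence[ModuleFactorModel],
                       partition: ModulePartition,
                       loading_mode: str = "per_module_ols"
                       ) -> GlobalFactorModel:
    """Assemble B and fill L by the configured mode; E is the exact
    remainder of the centered data."""
    B, fmap = assemble_factors(models)
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    Xc = values - values.mean(axis=1, keepdims=True)
    if B.shape[0] == 0:
        return GlobalFactorModel(B=np.zeros((0, values.shape[1])),
                                 L=np.zeros((values.shape[0], 0)),
                                 E=Xc, factor_module_map=fmap)
    if loading_mode == "per_module_ols":
        L = loadings_per_module_ols(values, B, partition, fmap)
    elif loading_mode == "lasso_bic":
        L = loadings_lasso_bic(values, B)
    else:
        raise ValueError(f"unknown loading_mode: {loading_mode}")
    E = Xc - L @ B
    return GlobalFactorModel(B=B, L=L, E=E, factor_module_map=fmap)
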