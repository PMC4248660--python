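"""Latent factor extraction within a module.

Each module's centered expression submatrix is eigendecomposed (SVD); the
right singular vectors live in sample space and are the candidate factor
score vectors. Candidates explaining at least a configured fraction of the
module variance are screened with the "interactivity" rule: two
eigenvectors are interactive when the projection lengths of the module's
features onto them are significantly correlated across features — the
signature of genes co-regulated by several factors at once. A greedy
sequential pass keeps eigenvectors while each new one is interactive with
the already-selected set; the survivors are obliquely rotated (quartimin)
into interpretable, possibly correlated, factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from statsmodels.multivariate.factor_rotation import rotate_factors

logger = logging.getLogger("nmlsa")


@dataclass
class ProjectionProfile:
    """Projection lengths |x_i . v_j| of module features onto eigenvectors."""

    lengths: np.ndarray  # (m_features, n_eigenvectors), entries >= 0

    def __post_init__(self) -> None:
        if np.any(self.lengths < 0):
            raise ValueError("projection lengths are magnitudes, must be >= 0")
        if self.lengths.ndim != 2 or self.lengths.shape[1] < 1:
            raise ValueError("need at least one eigenvector column")


@dataclass
class ModuleFactorModel:
    """Per-module factor model G_module ~= L F + E.

    factor_scores F is r x n with each row scaled to unit sample variance;
    loadings L is q x r; residuals E = G_centered - L F by construction.
    """

    factor_scores: np.ndarray
    loadings: np.ndarray
    residuals: np.ndarray
    variance_explained: np.ndarray
    row_means: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.factor_scores.shape[0]


def module_eigenvectors(X_module: np.ndarray,
                        variance_fraction: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sample-space eigenvectors of the module and their variance fractions.

    Rows are centered here. Returns the right singular vectors (rows of the
    returned array, each an n-vector) whose variance fraction
    eigenvalue / sum(eigenvalues) is at least ``variance_fraction``; the
    leading eigenvector is always retained.
    """
    X_module = np.asarray(X_module, dtype=float)
    if X_module.shape[0] < 2:
        raise ValueError("module must contain at least 2 features")
    Xc = X_module - X_module.mean(axis=1, keepdims=True)
    total = float(np.sum(Xc * Xc))
    if total == 0.0:
        raise ValueError("module matrix has rank 0 after centering")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    fractions = (s * s) / total
    n_keep = max(1, int(np.sum(fractions >= variance_fraction)))
    return vt[:n_keep], fractions[:n_keep]


def projection_lengths(X_module: np.ndarray,
                       eigenvectors: np.ndarray) -> ProjectionProfile:
    """Magnitudes of scalar projections of centered features onto each
    eigenvector: l_i(j) = |row_i . v_j|."""
    X_module = np.asarray(X_module, dtype=float)
    eigenvectors = np.asarray(eigenvectors, dtype=float)
    if X_module.shape[1] != eigenvectors.shape[1]:
        raise ValueError("sample dimension mismatch between module matrix "
                         "and eigenvectors")
    Xc = X_module - X_module.mean(axis=1, keepdims=True)
    return ProjectionProfile(lengths=np.abs(Xc @ eigenvectors.T))


def interactive_pair(profile: ProjectionProfile, a: int, b: int,
                     alpha: float = 0.05) -> bool:
    """Whether eigenvectors a and b are 'interactive': the projection
    lengths of the features onto the two are significantly correlated
    (two-sided Pearson test at level alpha)."""
    x = profile.lengths[:, a]
    y = profile.lengths[:, b]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return False
    return bool(pearsonr(x, y).pvalue < alpha)


def select_interacting_set(profile: ProjectionProfile,
                           alpha: float = 0.05) -> list[int]:
    """Greedy sequential eigenvector selection.

    Start with the leading eigenvector; walk the rest in eigenvalue order,
    adding each that is interactive with ANY already-selected vector, and
    stop at the first that is not.
    """
    n_vec = profile.lengths.shape[1]
    selected = [0]
    for j in range(1, n_vec):
        if any(interactive_pair(profile, j, k, alpha) for k in selected):
            selected.append(j)
        else:
            break
    return selected


def _order_and_sign(F: np.ndarray, L: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic output convention: factors ordered by explained
    variance (sum of squared loadings, unit-variance scores), each signed
    so its largest-|loading| feature loads positive."""
    var_exp = np.sum(L * L, axis=0)
    order = np.argsort(-var_exp)
    F, L, var_exp = F[order], L[:, order], var_exp[order]
    for k in range(L.shape[1]):
        top = int(np.argmax(np.abs(L[:, k])))
        if L[top, k] < 0:
            L[:, k] = -L[:, k]
            F[k] = -F[k]
    return F, L, var_exp


def oblique_rotate(X_module: np.ndarray,
                   eigenvectors: np.ndarray,
                   selected: list[int] | None = None,
                   max_iter: int = 1000) -> ModuleFactorModel:
    """Turn selected eigenvectors into a module factor model.

    With one factor the eigenvector itself (unit-variance scaled) is the
    score vector. With several, the principal-axis loading matrix is
    rotated by quartimin (oblimin, gamma=0) gradient projection; the
    rotated scores are rescaled to unit variance and loadings refit by
    least squares. Non-convergent rotation falls back to the unrotated
    axes with a warning.
    """
    X_module = np.asarray(X_module, dtype=float)
    eigenvectors = np.asarray(eigenvectors, dtype=float)
    if selected is None:
        selected = list(range(eigenvectors.shape[0]))
    if len(selected) < 1:
        raise ValueError("need at least one selected eigenvector")
    row_means = X_module.mean(axis=1, keepdims=True)
    Xc = X_module - row_means
    n = Xc.shape[1]
    V = eigenvectors[selected]                      # (r, n)
    A = Xc @ V.T                                    # signed projections (q, r)
    sd = V.std(axis=1, ddof=0)
    F = V / sd[:, None]                             # unit-variance scores
    # loadings consistent with unit-variance scores: Xc ~= (A * sd) F
    L = A * sd[None, :]
    if len(selected) >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                L_rot, T = rotate_factors(L, "quartimin",
                                          max_tries=max_iter)
            F = T.T @ F          # L F == L_rot (T.T F)
            L = L_rot
            sd_rot = F.std(axis=1, ddof=0)
            F = F / sd_rot[:, None]
            L = L * sd_rot[None, :]
        except Exception:       # non-convergence: keep unrotated axes
            logger.warning("oblique rotation failed to converge; "
                           "returning unrotated eigenvectors")
    # refit loadings by least squares on the (possibly correlated) scores
    L = Xc @ F.T @ np.linalg.inv(F @ F.T)
    F, L, var_exp = _order_and_sign(F, L)
    E = Xc - L @ F
    return ModuleFactorModel(factor_scores=F, loadings=L, residuals=E,
                             variance_explained=var_exp,
                             row_means=row_means.ravel())


def extract_module_factors(X_module: np.ndarray,
                           variance_fraction: float = 0.05,
                           alpha: float = 0.05) -> ModuleFactorModel:
    """Full per-module pipeline: eigenvectors -> interactivity screening ->
    oblique rotation."""
    vecs, _ = module_eigenvectors(X_module, variance_fraction)
    profile = projection_lengths(X_module, vecs)
    selected = select_interacting_set(profile, alpha)
    return oblique_rotate(X_module, vecs, selected)
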