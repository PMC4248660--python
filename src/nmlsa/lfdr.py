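"""Efron-style local false discovery rate estimation.

The two-group model treats the observed statistics z_1..z_N as draws from
the mixture f(z) = pi0 * f0(z) + (1 - pi0) * f1(z). The local fdr is the
posterior null probability

    lfdr(z) = pi0 * f0(z) / f(z),

with the mixture density f estimated by a Poisson-regression spline fit to
histogram counts and the null density f0 either the standard normal
("theoretical") or a normal with mean/sd fit to the central peak of the
statistics ("central_matching" — the default, since the pairwise
correlation statistic is only approximately normal under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

MIN_STATISTICS = 1000


@dataclass
class LfdrFit:
    """Result of a local-fdr fit over a vector of statistics."""

    statistics: np.ndarray
    lfdr_values: np.ndarray
    null_mean: float
    null_sd: float
    pi0: float
    n_bins: int
    spline_df: int

    def __post_init__(self) -> None:
        if self.lfdr_values.shape != self.statistics.shape:
            raise ValueError("lfdr_values and statistics lengths differ")
        if np.any(self.lfdr_values < 0) or np.any(self.lfdr_values > 1):
            raise ValueError("lfdr values must lie in [0, 1]")
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in (0, 1]")


def _natural_spline_basis(x: np.ndarray, df: int,
                          lo: float, hi: float) -> np.ndarray:
    """Natural cubic spline design matrix with ``df`` columns (no
    intercept), knots at uniform quantiles of ``x`` with boundaries at
    [lo, hi]. Linear beyond the boundary knots."""
    knots = np.quantile(x, np.linspace(0.0, 1.0, df + 1))
    knots[0], knots[-1] = lo, hi
    knots = np.unique(knots)
    K = len(knots)

    def d(k: int, t: np.ndarray) -> np.ndarray:
        num = (np.maximum(t - knots[k], 0.0) ** 3
               - np.maximum(t - knots[-1], 0.0) ** 3)
        return num / (knots[-1] - knots[k])

    cols = [x]
    dlast = d(K - 2, x)
    for k in range(K - 2):
        cols.append(d(k, x) - dlast)
    return np.column_stack(cols)


class LocalFdr(BaseEstimator):
    """Local false discovery rate estimator for a vector of z-like statistics.

    Parameters
    ----------
    n_bins : int
        Number of equal-width histogram bins spanning the data range.
    spline_df : int
        Degrees of freedom of the spline basis in the Poisson regression
        estimating the mixture density.
    null_method : {"central_matching", "theoretical"}
        Empirical null fit to the central peak, or the standard normal.
    max_fit : int or None
        If the statistic vector exceeds this length, the density is fit on
        a uniform random subsample of this size and evaluated everywhere by
        interpolating the fitted curve.
    random_state : int or None
        Seed for the subsampling step.

    Attributes
    ----------
    null_mean_, null_sd_ : float
        Fitted empirical-null location and scale.
    pi0_ : float
        Estimated null proportion, capped at 1.
    grid_ : ndarray
        Bin midpoints on which the lfdr curve is tabulated.
    lfdr_grid_ : ndarray
        Tail-monotonized lfdr curve on ``grid_``.
    """

    def __init__(self, n_bins: int = 120, spline_df: int = 7,
                 null_method: str = "central_matching",
                 max_fit: int | None = 10_000_000,
                 random_state: int | None = None):
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.null_method = null_method
        self.max_fit = max_fit
        self.random_state = random_state

    def fit(self, z: np.ndarray, y=None) -> "LocalFdr":
        z = np.asarray(z, dtype=float).ravel()
        if z.size < MIN_STATISTICS:
            raise ValueError(
                f"need at least {MIN_STATISTICS} statistics to fit the "
                "mixture density (got %d); use the theoretical null on a "
                "larger pool or skip lfdr estimation" % z.size)
        if not np.isfinite(z).all():
            raise ValueError("statistics must be finite")
        if np.ptp(z) == 0.0:
            raise ValueError("statistics are constant; lfdr is undefined")

        zfit = z
        if self.max_fit is not None and z.size > self.max_fit:
            rng = np.random.default_rng(self.random_state)
            zfit = rng.choice(z, size=self.max_fit, replace=False)

        lo, hi = float(zfit.min()), float(zfit.max())
        edges = np.linspace(lo, hi, self.n_bins + 1)
        # (equal-width bins over the full data range: with a contaminated
        # ensemble the coarser central resolution lets the empirical null
        # absorb flank dispersion, which is the adaptive behavior wanted
        # when baseline correlations are pervasive)
        mids = 0.5 * (edges[:-1] + edges[1:])
        counts, _ = np.histogram(zfit, bins=edges)
        width = edges[1] - edges[0]
        n_total = zfit.size

        # mixture density: Poisson regression of counts on a spline basis
        basis = sm.add_constant(
            _natural_spline_basis(mids, self.spline_df, lo, hi))
        glm = sm.GLM(counts, basis, family=sm.families.Poisson())
        fitted = np.maximum(glm.fit().fittedvalues, 1e-12)
        f_grid = fitted / (n_total * width)

        if self.null_method == "theoretical":
            mu, sd = 0.0, 1.0
            pi0 = self._pi0_at_mode(mids, fitted, mu, sd, n_total, width)
        else:
            mu, sd, pi0 = self._central_matching(
                zfit, mids, counts, fitted, n_total, width)

        f0_grid = norm.pdf(mids, loc=mu, scale=sd)
        lfdr_grid = np.clip(pi0 * f0_grid / f_grid, 0.0, 1.0)
        lfdr_grid = self._monotonize_tails(mids, lfdr_grid, mu, sd)

        self.null_mean_ = float(mu)
        self.null_sd_ = float(sd)
        self.pi0_ = float(pi0)
        self.grid_ = mids
        self.lfdr_grid_ = lfdr_grid
        self.f_grid_ = f_grid
        return self

    @staticmethod
    def _pi0_at_mode(mids, fitted, mu, sd, n_total, width) -> float:
        """pi0 from the ratio of mixture to null mass at the null mode."""
        j = int(np.argmin(np.abs(mids - mu)))
        f_mode = fitted[j] / (n_total * width)
        return float(min(1.0, f_mode / norm.pdf(mids[j], loc=mu, scale=sd)))

    def _central_matching(self, z, mids, counts, fitted, n_total, width):
        """Central matching: quadratic fit to the log of the fitted counts
        over the central 50% of the data; the implied normal is the
        empirical null and its mass gives pi0."""
        q25, q75 = np.quantile(z, [0.25, 0.75])
        sel = (mids >= q25) & (mids <= q75)
        if sel.sum() < 5:
            order = np.argsort(np.abs(mids - np.median(z)))
            sel = np.zeros_like(sel)
            sel[order[:5]] = True
        x = mids[sel]
        logc = np.log(np.maximum(fitted[sel], 1e-12))
        c2, c1, c0 = np.polyfit(x, logc, 2)
        if c2 >= 0:  # no central peak: fall back to robust moments
            mu = float(np.median(z))
            sd = float((q75 - q25) / 1.349)
            pi0 = self._pi0_at_mode(mids, fitted, mu, sd, n_total, width)
            return mu, sd, min(pi0, 1.0)
        sd = float(np.sqrt(-1.0 / (2.0 * c2)))
        mu = float(c1 * sd * sd)
        # exp(c0 + c1 z + c2 z^2) ~= pi0 * N * width * phi((z-mu)/sd)/sd
        log_mass = c0 + mu * mu / (2.0 * sd * sd)
        pi0 = np.exp(log_mass) * sd * np.sqrt(2.0 * np.pi) / (n_total * width)
        return mu, sd, float(min(1.0, pi0))

    @staticmethod
    def _monotonize_tails(mids, lfdr_grid, mu, sd):
        """Force the lfdr curve non-increasing in |z - mu| beyond mu +/- 2 sd.

        Spline wiggle in sparse tails would otherwise create spurious
        high-lfdr pockets between strongly associated pairs.
        """
        out = lfdr_grid.copy()
        right = np.where(mids >= mu + 2.0 * sd)[0]
        if right.size > 1:
            iso = IsotonicRegression(increasing=False,
                                     y_min=0.0, y_max=float(out[right[0]]))
            out[right] = iso.fit_transform(mids[right], out[right])
        left = np.where(mids <= mu - 2.0 * sd)[0]
        if left.size > 1:
            iso = IsotonicRegression(increasing=True,
                                     y_min=0.0, y_max=float(out[left[-1]]))
            out[left] = iso.fit_transform(mids[left], out[left])
        return out

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        """Interpolate the fitted lfdr curve at arbitrary statistics."""
        z = np.asarray(z, dtype=float)
        return np.interp(z, self.grid_, self.lfdr_grid_,
                         left=self.lfdr_grid_[0], right=self.lfdr_grid_[-1])


def estimate_lfdr(statistics: np.ndarray, n_bins: int = 120,
                  spline_df: int = 7,
                  null_method: str = "central_matching",
                  random_state: int | None = None) -> LfdrFit:
    """Fit the two-group mixture and return per-statistic lfdr values."""
    statistics = np.asarray(statistics, dtype=float).ravel()
    est = LocalFdr(n_bins=n_bins, spline_df=spline_df,
                   null_method=null_method,
                   random_state=random_state).fit(statistics)
    return LfdrFit(statistics=statistics,
                   lfdr_values=est.evaluate(statistics),
                   null_mean=est.null_mean_, null_sd=est.null_sd_,
                   pi0=est.pi0_, n_bins=n_bins, spline_df=spline_df)


def edge_mask(fit: LfdrFit, threshold: float) -> np.ndarray:
    """Pairs whose lfdr is strictly below ``threshold`` become edges."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return fit.lfdr_values < threshold
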