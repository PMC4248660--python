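"""Run configuration for the modular latent structure pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class RunConfig:
    """Parameters controlling every stage of the pipeline.

    Parameters
    ----------
    lfdr_threshold : float in (0, 1)
        Pairs whose local false discovery rate falls strictly below this
        value become network edges.
    walktrap_steps : int
        Random-walk length for community detection.
    min_module_size : int
        Communities smaller than this are dropped before factor extraction.
    variance_fraction : float in (0, 1)
        Minimum fraction of a module's variance an eigenvector must explain
        to be considered a candidate latent factor.
    interactivity_alpha : float in (0, 1)
        Two-sided significance level for the projection-length correlation
        test between candidate eigenvectors.
    loading_mode : {"per_module_ols", "lasso_bic"}
        How the global loading matrix is filled.
    positive_only : bool
        Restrict network edges to positively correlated pairs.
    standardize : bool
        Standardize each feature (mean 0, variance 1) before the correlation
        step. Off by default.
    correlation_method : {"pearson", "spearman"}
        Pairwise association measure for the network step.
    seed : int
        Seeds all randomness (subsampling, simulations).
    """

    lfdr_threshold: float = 0.2
    walktrap_steps: int = 4
    min_module_size: int = 10
    variance_fraction: float = 0.05
    interactivity_alpha: float = 0.05
    loading_mode: str = "per_module_ols"
    positive_only: bool = False
    standardize: bool = False
    correlation_method: str = "pearson"
    lfdr_bins: int = 120
    lfdr_spline_df: int = 7
    null_method: str = "central_matching"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.lfdr_threshold < 1.0:
            raise ValueError("lfdr_threshold must lie in (0, 1)")
        if self.walktrap_steps < 1:
            raise ValueError("walktrap_steps must be a positive integer")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be a positive integer")
        if not 0.0 < self.variance_fraction < 1.0:
            raise ValueError("variance_fraction must lie in (0, 1)")
        if not 0.0 < self.interactivity_alpha < 1.0:
            raise ValueError("interactivity_alpha must lie in (0, 1)")
        if self.loading_mode not in ("per_module_ols", "lasso_bic"):
            raise ValueError("loading_mode must be per_module_ols or lasso_bic")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be pearson or spearman")
        if self.null_method not in ("theoretical", "central_matching"):
            raise ValueError("null_method must be theoretical or central_matching")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
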