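"""Reading and writing expression matrices and pipeline outputs.

The canonical orientation is features in rows, samples (conditions) in
columns, matching the factor model G_{p x n} = L F + E where p features are
measured under n conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .factors import ModuleFactorModel
    from .global_model import GlobalFactorModel
    from .modules import ModulePartition

logger = logging.getLogger("nmlsa")

MIN_SAMPLES = 4


@dataclass
class ExpressionMatrix:
    """A p x n expression matrix with unique feature and sample IDs.

    Invariants enforced at construction: no missing values, at least 2
    features and 4 samples, unique IDs, and nonzero variance in every row.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        p, n = self.values.shape
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError("ID lengths do not match matrix shape")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if p < 2:
            raise ValueError(f"need at least 2 features, got {p}")
        if n < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains missing or non-finite values")
        if np.any(self.values.var(axis=1) == 0.0):
            raise ValueError("matrix contains zero-variance rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)


def from_frame(df: pd.DataFrame, features_in_rows: bool = True) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from a DataFrame, applying the
    row-filtering rules (drop rows with missing values or zero variance)."""
    if not features_in_rows:
        df = df.T
    values = df.to_numpy(dtype=float)
    keep_finite = np.isfinite(values).all(axis=1)
    n_missing = int((~keep_finite).sum())
    if n_missing:
        logger.warning("dropped %d rows with missing values", n_missing)
    values = values[keep_finite]
    idx = df.index[keep_finite]
    keep_var = values.var(axis=1) > 0.0
    n_const = int((~keep_var).sum())
    if n_const:
        logger.warning("dropped %d zero-variance rows", n_const)
    return ExpressionMatrix(values[keep_var], list(idx[keep_var]),
                            list(df.columns))


def load_expression(path: str | Path, delimiter: str = "\t",
                    features_in_rows: bool = True) -> ExpressionMatrix:
    """Load a delimited expression table.

    The first column holds feature IDs and the first row sample IDs (the
    transpose if ``features_in_rows`` is False). Rows containing missing
    values or with zero variance are dropped with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates if features_in_rows else df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate feature IDs")
    return from_frame(df, features_in_rows=features_in_rows)


def write_results(partition: "ModulePartition",
                  models: Sequence["ModuleFactorModel"],
                  global_model: "GlobalFactorModel | None",
                  outdir: str | Path,
                  feature_ids: Sequence[str] | None = None,
                  sample_ids: Sequence[str] | None = None,
                  config: dict | None = None) -> dict[str, Path]:
    """Write module membership, factor scores B, loadings L and a JSON run
    summary under ``outdir``. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def fid(i: int) -> str:
        return feature_ids[i] if feature_ids is not None else str(i)

    rows = [(fid(i), c) for c, members in enumerate(partition.communities)
            for i in sorted(members)]
    membership = pd.DataFrame(rows, columns=["feature_id", "module_id"])
    paths["membership"] = outdir / "module_membership.tsv"
    membership.to_csv(paths["membership"], sep="\t", index=False)

    if global_model is not None:
        k = global_model.B.shape[0]
        factor_names = [f"factor_{j}" for j in range(k)]
        cols = (list(sample_ids) if sample_ids is not None
                else [f"s{j}" for j in range(global_model.B.shape[1])])
        b_df = pd.DataFrame(global_model.B, index=factor_names, columns=cols)
        paths["factor_scores"] = outdir / "factor_scores.tsv"
        b_df.to_csv(paths["factor_scores"], sep="\t")

        p = global_model.L.shape[0]
        idx = (list(feature_ids) if feature_ids is not None
               else [str(i) for i in range(p)])
        l_df = pd.DataFrame(global_model.L, index=idx, columns=factor_names)
        paths["loadings"] = outdir / "loadings.tsv"
        l_df.to_csv(paths["loadings"], sep="\t")

    summary = {
        "n_modules": len(partition.communities),
        "module_sizes": [len(c) for c in partition.communities],
        "factors_per_module": [m.factor_scores.shape[0] for m in models],
        "n_factors_total": int(sum(m.factor_scores.shape[0] for m in models)),
        "parameters": config or {},
    }
    paths["summary"] = outdir / "run_summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths
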