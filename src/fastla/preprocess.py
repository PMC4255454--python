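"""Expression-matrix container and preprocessing.

The pipeline expects each gene (row) to be marginally standard normal before
any liquid-association statistic is computed.  Preprocessing therefore runs,
in order: a missingness filter, a per-gene normal quantile transform, and a
per-gene standardization to exact sample moments (mean 0, variance 1,
denominator n-1).  Missing values are preserved throughout (all statistics
are computed on non-missing entries only) and are handled downstream per
controller gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger("fastla")


class PreprocessError(ValueError):
    """Raised for degenerate inputs during preprocessing."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with missing values as NaN.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Sample identifiers, one per column.
    values
        Float array of shape (G, N); NaN marks a missing measurement.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise PreprocessError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise PreprocessError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise PreprocessError("gene ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (G, N) mask, True where the measurement is missing."""
        return np.isnan(self.values)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Restrict to the given samples (order as given)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, idx].copy())


def filter_missing(matrix: ExpressionMatrix,
                   max_missing_frac: float = 0.30) -> ExpressionMatrix:
    """Drop genes whose fraction of missing samples exceeds the threshold.

    Gene order is preserved; the number of removed genes is logged.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise PreprocessError("max_missing_frac must be in [0, 1]")
    frac = matrix.missing_mask.mean(axis=1)
    keep = frac <= max_missing_frac
    n_removed = int((~keep).sum())
    if not keep.any():
        raise PreprocessError(
            f"no genes left after removing those with more than "
            f"{max_missing_frac:.0%} missing values"
        )
    if n_removed:
        logger.info("filter_missing: removed %d of %d genes (> %.0f%% missing)",
                    n_removed, matrix.n_genes, 100 * max_missing_frac)
    return ExpressionMatrix(
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        list(matrix.sample_ids),
        matrix.values[keep].copy(),
    )


def normal_quantile_transform(values: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles of their ranks.

    Non-missing entries are replaced by Phi^-1(rank / (n + 1)) with 1-based
    average ranks among the n non-missing values, so ties share a rank and
    the transform is rank-preserving; missing entries stay missing.  The
    n + 1 plotting position keeps the extremes finite.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    x = values[obs]
    if x.size < 3:
        raise PreprocessError("need at least 3 non-missing values")
    if np.unique(x).size == 1:
        raise PreprocessError("all values identical; ranks are undefined")
    ranks = rankdata(x, method="average")
    out = np.full_like(values, np.nan)
    out[obs] = norm.ppf(ranks / (x.size + 1))
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale non-missing entries to sample mean 0, variance 1.

    Uses the n-1 denominator.  Errors on fewer than 2 distinct values.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    x = values[obs]
    if np.unique(x).size < 2:
        raise PreprocessError("need at least 2 distinct non-missing values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise PreprocessError("zero variance; cannot standardize")
    out = np.full_like(values, np.nan)
    out[obs] = (x - x.mean()) / sd
    return out


def preprocess(matrix: ExpressionMatrix,
               max_missing_frac: float = 0.30,
               transform: bool = True) -> ExpressionMatrix:
    """Full preprocessing: missingness filter, quantile transform, standardize.

    After this every retained gene's non-missing values have sample mean 0
    and variance 1 to within 1e-9 and at most ``max_missing_frac`` missing.
    """
    filtered = filter_missing(matrix, max_missing_frac)
    out = np.empty_like(filtered.values)
    for i in range(filtered.n_genes):
        row = filtered.values[i]
        if transform:
            row = normal_quantile_transform(row)
        out[i] = standardize(row)
    return ExpressionMatrix(list(filtered.gene_ids), list(filtered.sample_ids), out)
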