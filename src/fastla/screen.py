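"""Stage 1: fast rho_diff screening over all ordered gene triplets.

For each controller gene X3, samples are split into equal-count tertiles of
the controller's expression.  For every gene pair (X1, X2) the screening
statistic is

    rho_diff = rho_high - rho_low,

the Pearson correlation of (X1, X2) over the top-tertile samples minus the
same over the bottom tertile.  rho_diff is bounded in [-2, 2] and tracks the
liquid-association measure closely while being computable for all pairs at
once as the difference of two correlation matrices, each a cross-product of
a per-bin re-standardized submatrix.  Triplets with |rho_diff| at or above
the threshold (default 0.5) go on to model-based estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix

logger = logging.getLogger("fastla")

#: Minimum per-bin sample count below which rho estimates get unstable.
MIN_STABLE_BIN = 15


class ScreenError(ValueError):
    """Raised for degenerate inputs during screening."""


@dataclass
class BinSpec:
    """Assignment of samples to low/middle/high controller bins.

    ``low_idx``/``mid_idx``/``high_idx`` are disjoint sample index arrays
    whose union is the set of samples with a non-missing controller value.
    ``boundaries`` holds the two cut values (low/mid and mid/high).  For a
    binary controller the middle bin is empty and ``binary`` is True.
    """

    controller_gene: str
    low_idx: np.ndarray
    mid_idx: np.ndarray
    high_idx: np.ndarray
    boundaries: tuple[float, float]
    binary: bool = False


@dataclass
class ScreenHit:
    """One screened triplet (X1, X2 | X3) with its tertile correlations."""

    x1: str
    x2: str
    x3: str
    rho_high: float
    rho_low: float
    rho_diff: float
    binary: bool = False


def _tertile_sizes(n: int) -> tuple[int, int, int]:
    # Remainder goes to the outer bins first (low, then high); mid smallest.
    q, r = divmod(n, 3)
    return q + (1 if r >= 1 else 0), q, q + (1 if r >= 2 else 0)


def tertile_bins(controller_values: np.ndarray,
                 controller_gene: str = "") -> BinSpec:
    """Split samples into equal-count low/middle/high bins of the controller.

    Samples with a missing controller value are excluded.  Ties are broken
    by a stable sort on (value, original sample index), so the split is
    deterministic.  When the sizes cannot be exactly equal the extra sample
    goes to the low bin first, then the high bin.  A controller with exactly
    two distinct values is treated as binary: the two groups become the low
    and high bins and the middle bin is empty.
    """
    controller_values = np.asarray(controller_values, dtype=float)
    obs_idx = np.flatnonzero(~np.isnan(controller_values))
    vals = controller_values[obs_idx]

    distinct = np.unique(vals)
    if distinct.size == 2:
        low = obs_idx[vals == distinct[0]]
        high = obs_idx[vals == distinct[1]]
        if min(low.size, high.size) < 3:
            raise ScreenError(
                f"binary controller {controller_gene!r}: each group needs >= 3 samples"
            )
        return BinSpec(controller_gene, low, np.array([], dtype=int), high,
                       (float(distinct[0]), float(distinct[1])), binary=True)

    if obs_idx.size < 9:
        raise ScreenError(
            f"controller {controller_gene!r}: need >= 9 non-missing values, "
            f"got {obs_idx.size}"
        )
    order = np.argsort(vals, kind="stable")  # stable: ties by original index
    n_low, n_mid, n_high = _tertile_sizes(obs_idx.size)
    if min(n_low, n_mid, n_high) < MIN_STABLE_BIN:
        warnings.warn(
            f"controller {controller_gene!r}: a tertile bin has fewer than "
            f"{MIN_STABLE_BIN} samples; correlation estimates may be unstable",
            stacklevel=2,
        )
    low = obs_idx[order[:n_low]]
    mid = obs_idx[order[n_low:n_low + n_mid]]
    high = obs_idx[order[n_low + n_mid:]]
    sorted_vals = vals[order]
    boundaries = (float(sorted_vals[n_low - 1]), float(sorted_vals[n_low + n_mid]))
    return BinSpec(controller_gene, low, mid, high, boundaries)


def _bin_corr(values: np.ndarray, idx: np.ndarray,
              method: str = "pearson") -> np.ndarray:
    """Correlation matrix of all genes over the samples in ``idx``.

    Computed as the cross-product of the per-bin re-standardized submatrix.
    Missing entries are mean-imputed within the bin (centered to 0), which is
    exact when the bin has no missing values.  Genes with zero variance in
    the bin get NaN rows/columns.
    """
    sub = values[:, idx].astype(float)
    if method == "spearman":
        for i in range(sub.shape[0]):
            obs = ~np.isnan(sub[i])
            if obs.sum() > 1:
                sub[i, obs] = rankdata(sub[i, obs], method="average")
    elif method != "pearson":
        raise ScreenError(f"unknown correlation method {method!r}")
    mask = np.isnan(sub)
    filled = np.where(mask, 0.0, sub)
    n_obs = (~mask).sum(axis=1)
    means = filled.sum(axis=1) / np.maximum(n_obs, 1)
    centered = np.where(mask, 0.0, sub - means[:, None])
    norms = np.sqrt((centered ** 2).sum(axis=1))
    bad = (norms == 0.0) | (n_obs < 2)
    safe = np.where(bad, 1.0, norms)
    z = centered / safe[:, None]
    corr = z @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    return corr


def bin_correlations(matrix: ExpressionMatrix, controller: str,
                     method: str = "pearson") -> tuple[np.ndarray, np.ndarray, BinSpec]:
    """(rho_high, rho_low) correlation matrices for one controller gene."""
    c = matrix.gene_index(controller)
    bins = tertile_bins(matrix.values[c], controller)
    r_high = _bin_corr(matrix.values, bins.high_idx, method)
    r_low = _bin_corr(matrix.values, bins.low_idx, method)
    return r_high, r_low, bins


def rho_diff_for_controller(matrix: ExpressionMatrix, controller: str,
                            method: str = "pearson") -> np.ndarray:
    """G x G matrix of rho_diff for one controller; diagonal 0, NaN undefined."""
    r_high, r_low, _ = bin_correlations(matrix, controller, method)
    d = r_high - r_low
    np.fill_diagonal(d, 0.0)
    n_bad = int(np.isnan(d).any(axis=1).sum())
    if n_bad:
        logger.info("controller %s: %d genes with undefined within-bin "
                    "correlation excluded", controller, n_bad)
    return d


def _hits_for_controller(matrix: ExpressionMatrix, c: int, threshold: float,
                         method: str) -> list[ScreenHit]:
    controller = matrix.gene_ids[c]
    r_high, r_low, bins = bin_correlations(matrix, controller, method)
    d = r_high - r_low
    np.fill_diagonal(d, 0.0)
    d[c, :] = np.nan  # controller cannot be X1/X2 of its own triplet
    d[:, c] = np.nan
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(np.triu(np.abs(d) >= threshold, k=1))
    hits = []
    for i, j in zip(ii, jj):
        g1, g2 = matrix.gene_ids[i], matrix.gene_ids[j]
        if g2 < g1:
            g1, g2 = g2, g1
        hits.append(ScreenHit(g1, g2, controller,
                              float(r_high[i, j]), float(r_low[i, j]),
                              float(d[i, j]), binary=bins.binary))
    return hits


def screen_all(matrix: ExpressionMatrix, threshold: float = 0.5,
               method: str = "pearson", jobs: int = 1) -> Iterator[ScreenHit]:
    """Stream all triplets with |rho_diff| >= threshold.

    Iterates one controller at a time so memory stays bounded at one G x G
    matrix; with ``jobs`` > 1 controllers are processed in parallel but the
    emitted order (by controller, then row-major pair index) is unchanged.
    """
    if not 0.0 < threshold <= 2.0:
        raise ScreenError("threshold must be in (0, 2]")
    controllers = range(matrix.n_genes)
    if jobs == 1:
        for c in controllers:
            yield from _hits_for_controller(matrix, c, threshold, method)
    else:
        batches = Parallel(n_jobs=jobs)(
            delayed(_hits_for_controller)(matrix, c, threshold, method)
            for c in controllers
        )
        for batch in batches:
            yield from batch


def count_triplets(G: int) -> int:
    """Number of ordered triplets (unordered pair, distinct controller).

    G * (G-1) * (G-2) / 2, i.e. 3 * C(G, 3).
    """
    if G < 3:
        raise ScreenError("need at least 3 genes to form a triplet")
    return G * (G - 1) * (G - 2) // 2
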