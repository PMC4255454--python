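"""Synthetic data generators and validation analyses.

Two generators back the test battery: an i.i.d. standard-normal null matrix
(independent genes, identity covariance — nothing to find), and a
single-triplet generator that draws (X1, X2) from the conditional normal
model given a standard-normal controller, for power and parameter-recovery
studies.

The validation analyses mirror how the screening statistic was vetted
against the exhaustive estimate: for matrices small enough to enumerate
every triplet, compare |rho_diff| against the direct |MLA| estimate
(correlation, regression slope, sign agreement), and trace how many of the
top-|MLA| triplets a given |rho_diff| threshold would miss.  The analytic
anchor is the ratio of the two statistics' maxima: |rho_diff| can reach 2
while |MLA| on marginally normal data tops out near sqrt(2/pi), giving
2 / sqrt(2/pi) = 2.507.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimate import EstimationError, binned_controller, equal_count_bins
from .preprocess import ExpressionMatrix
from .screen import bin_correlations


class SimulationError(ValueError):
    """Raised for infeasible simulation requests."""


@dataclass
class ConcordanceReport:
    """Agreement between the screen statistic and the MLA estimate across
    all triplets of one matrix."""

    corr_abs: float        # Pearson corr of |rho_diff| vs |MLA|
    corr_signed: float     # same on signed values
    slope: float           # OLS slope of |rho_diff| on |MLA|
    intercept: float
    sign_agreement: float  # fraction of triplets with matching sign
    n_triplets: int


#: Ratio of the attainable maxima: max |rho_diff| = 2, max |MLA| = sqrt(2/pi).
MAX_RATIO = 2.0 / np.sqrt(2.0 / np.pi)


def simulate_null(G: int, N: int, seed: int) -> ExpressionMatrix:
    """Matrix of independent standard-normal genes (identity covariance)."""
    if G < 3 or N < 9:
        raise SimulationError("need G >= 3 genes and N >= 9 samples")
    rng = np.random.default_rng(seed)
    width = len(str(G))
    ids = [f"G{i + 1:0{width}d}" for i in range(G)]
    samples = [f"S{j + 1}" for j in range(N)]
    return ExpressionMatrix(ids, samples, rng.standard_normal((G, N)))


def simulate_la_triplet(N: int, c0: float, c1: float,
                        mean_coefs: tuple = (0.0, 0.0, 0.0, 0.0),
                        logvar_coefs: tuple = (0.0, 0.0, 0.0, 0.0),
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one triplet from the conditional normal model.

    z ~ N(0, 1); given z, (x1, x2) is bivariate normal with means
    m_i0 + m_i1 z, variances exp(v_i0 + v_i1 z) and correlation
    tanh(c0 + c1 z).  Returns (x1, x2, z).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(N)
    m10, m11, m20, m21 = mean_coefs
    v10, v11, v20, v21 = logvar_coefs
    r = np.tanh(c0 + c1 * z)
    u1 = rng.standard_normal(N)
    u2 = r * u1 + np.sqrt(1.0 - r * r) * rng.standard_normal(N)
    x1 = m10 + m11 * z + np.exp(0.5 * (v10 + v11 * z)) * u1
    x2 = m20 + m21 * z + np.exp(0.5 * (v20 + v21 * z)) * u2
    return x1, x2, z


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mu) / sd


def _conditional_z(values: np.ndarray, bins: list[np.ndarray]) -> np.ndarray:
    """Within-bin (population-sd) standardization of every gene row."""
    z = np.empty_like(values)
    for idx in bins:
        sub = values[:, idx]
        sd = sub.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise EstimationError("zero within-bin variance")
        z[:, idx] = (sub - sub.mean(axis=1, keepdims=True)) / sd
    return z


def all_triplet_stats(matrix: ExpressionMatrix,
                      n_bins: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """(rho_diff, mla) over every ordered triplet, exhaustively.

    One pass per controller: rho_diff comes from the difference of the two
    tertile correlation matrices; the direct MLA for all pairs at once from
    the cross-product of the within-bin standardized matrix weighted by the
    controller values.  Requires a complete (no missing) matrix; feasible
    up to a few hundred genes.
    """
    if matrix.missing_mask.any():
        raise SimulationError("exhaustive enumeration requires a complete matrix")
    G, N = matrix.n_genes, matrix.n_samples
    vals = matrix.values
    iu = np.triu_indices(G, k=1)
    rho_list, mla_list = [], []
    for c in range(G):
        r_high, r_low, _ = bin_correlations(matrix, matrix.gene_ids[c])
        d = r_high - r_low
        bins = equal_count_bins(vals[c], n_bins)
        z = _conditional_z(vals, bins)
        m = (z * binned_controller(vals[c], bins)) @ z.T / N
        keep = (iu[0] != c) & (iu[1] != c)
        rho_list.append(d[iu][keep])
        mla_list.append(m[iu][keep])
    return np.concatenate(rho_list), np.concatenate(mla_list)


def concordance_report(matrix: ExpressionMatrix,
                       n_bins: int = 3) -> ConcordanceReport:
    """Exhaustive rho_diff vs MLA agreement for a (small) matrix."""
    rho, mla = all_triplet_stats(matrix, n_bins)
    a_rho, a_mla = np.abs(rho), np.abs(mla)
    slope, intercept = np.polyfit(a_mla, a_rho, 1)
    return ConcordanceReport(
        corr_abs=float(np.corrcoef(a_rho, a_mla)[0, 1]),
        corr_signed=float(np.corrcoef(rho, mla)[0, 1]),
        slope=float(slope),
        intercept=float(intercept),
        sign_agreement=float(np.mean(np.sign(rho) == np.sign(mla))),
        n_triplets=rho.size,
    )


def sensitivity_curve(matrix: ExpressionMatrix, thresholds: np.ndarray,
                      top_k: int, n_bins: int = 3) -> list[tuple[float, float]]:
    """Fraction of the exhaustive top-``top_k`` |MLA| triplets that each
    |rho_diff| threshold would miss.  Non-decreasing in the threshold."""
    rho, mla = all_triplet_stats(matrix, n_bins)
    if top_k > rho.size:
        raise SimulationError(
            f"top_k ({top_k}) exceeds triplet count ({rho.size})"
        )
    top = np.argsort(-np.abs(mla), kind="stable")[:top_k]
    top_rho = np.abs(rho[top])
    return [(float(t), float(np.mean(top_rho < t))) for t in thresholds]
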