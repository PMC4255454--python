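"""Assemble per-triplet results, adjust for multiple testing, rank, output.

The number of triplets that enter model-based estimation is genome-scale
(tens of millions in a full run), so the false-discovery-rate adjustment is
Benjamini-Hochberg step-up with the *global* fitted-triplet count as the
test count — callers may hold only a slice of the p-values (e.g. a top
list) while adjusting against the full count.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .estimate import EstimationError, estimate_triplet, robust_estimate
from .io import RunConfig, write_results
from .preprocess import ExpressionMatrix
from .screen import ScreenHit, _hits_for_controller

logger = logging.getLogger("fastla")


@dataclass
class TripletResult:
    """One output row: triplet IDs, screening statistic, MLA estimate,
    Wald statistic, raw and adjusted p-value, and model code (F/S/R)."""

    x1: str
    x2: str
    x3: str
    rho_diff: float
    mla: float
    wald: float
    pvalue: float
    padj: float | None
    model: str


def bh_adjust(pvalues: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``n_tests`` is the total number of tests performed, which may exceed the
    length of ``pvalues`` when only a subset of p-values is being adjusted;
    adjusted_(i) = min_{j >= i} min(1, n_tests * p_(j) / j) over the sorted
    vector.  Defaults to the vector length.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if n_tests is None:
        n_tests = m
    if n_tests < m:
        raise ValueError(f"n_tests ({n_tests}) < number of p-values ({m})")
    if m == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    scaled = n_tests * p[order] / ranks
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def _triplet_seed(base_seed: int, x1: str, x2: str, x3: str) -> int:
    """Deterministic per-triplet seed, independent of processing order."""
    h = zlib.crc32(f"{x1}\t{x2}\t{x3}".encode())
    ss = np.random.SeedSequence([base_seed & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _estimate_hit(matrix: ExpressionMatrix, hit: ScreenHit,
                  config: RunConfig) -> TripletResult | None:
    i1 = matrix.gene_index(hit.x1)
    i2 = matrix.gene_index(hit.x2)
    i3 = matrix.gene_index(hit.x3)
    x1, x2, x3 = matrix.values[i1], matrix.values[i2], matrix.values[i3]
    seed = _triplet_seed(config.seed, hit.x1, hit.x2, hit.x3)
    try:
        if hit.binary:
            # binary controller: rho_diff itself is the LA measure; no CNM
            est = _binary_estimate(x1, x2, x3, hit, config, seed)
        else:
            est = estimate_triplet(
                x1, x2, x3, n_bins=config.n_bins, n_boot=config.n_boot,
                seed=seed, lof_corr_tol=config.lof_corr_tol,
                lof_alpha=config.lof_alpha, max_iter=config.optimizer_max_iter,
            )
    except EstimationError as exc:
        logger.warning("triplet (%s, %s | %s) skipped: %s",
                       hit.x1, hit.x2, hit.x3, exc)
        return None
    return TripletResult(hit.x1, hit.x2, hit.x3, hit.rho_diff,
                         est.mla, est.wald, est.pvalue, None, est.model)


def _binary_estimate(x1, x2, x3, hit: ScreenHit, config: RunConfig, seed: int):
    """Bootstrap rho_diff for a two-group (binary) controller."""
    from .estimate import TripletEstimate, _complete_cases
    from scipy.stats import norm

    x1, x2, x3 = _complete_cases(x1, x2, x3)
    lo, hi = np.unique(x3)

    def stat(a, b, c):
        la, lb = a[c == lo], b[c == lo]
        ha, hb = a[c == hi], b[c == hi]
        if min(la.std(), lb.std(), ha.std(), hb.std()) == 0:
            raise EstimationError("degenerate bootstrap group")
        return np.corrcoef(ha, hb)[0, 1] - np.corrcoef(la, lb)[0, 1]

    est = stat(x1, x2, x3)
    rng = np.random.default_rng(seed)
    boot = []
    draws = 0
    while len(boot) < config.n_boot:
        draws += 1
        if draws > 20 * config.n_boot:
            raise EstimationError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, x1.size, x1.size)
        try:
            boot.append(stat(x1[idx], x2[idx], x3[idx]))
        except EstimationError:
            continue
    se = float(np.std(boot, ddof=1))
    p = float(2 * norm.cdf(-abs(est) / se)) if se > 0 else 1.0
    wald = (est / se) ** 2 if se > 0 else np.nan
    return TripletEstimate(float(est), float(wald),
                           max(p, np.finfo(float).tiny), "R")


def _sort_results(results: list[TripletResult]) -> list[TripletResult]:
    return sorted(results, key=lambda r: (r.pvalue, -abs(r.mla),
                                          r.x1, r.x2, r.x3))


def _apply_adjustment(results: list[TripletResult],
                      bh_pool: str) -> list[TripletResult]:
    if not results:
        return results
    if bh_pool == "all":
        pool = results
    else:  # full_only: adjust only full-model tests against their own count
        pool = [r for r in results if r.model == "F"]
    if pool:
        adj = bh_adjust(np.array([r.pvalue for r in pool]), len(pool))
        adj_map = {id(r): a for r, a in zip(pool, adj)}
    else:
        adj_map = {}
    return [replace(r, padj=adj_map.get(id(r), np.nan)) for r in results]


def run_pipeline(matrix: ExpressionMatrix, config: RunConfig,
                 out_path: str | Path | None = None) -> list[TripletResult]:
    """Screen -> estimation cascade -> BH adjustment -> ranked results.

    ``matrix`` must already be preprocessed.  Deterministic given
    ``config.seed``.  With ``config.checkpoint`` set, per-controller results
    are appended to the checkpoint file as they complete and a restarted run
    resumes after the last finished controller, producing the same final
    table as an uninterrupted run.
    """
    ckpt = Path(config.checkpoint) if config.checkpoint else None
    done, cached = _load_checkpoint(ckpt)

    results: list[TripletResult] = []
    for c in range(matrix.n_genes):
        controller = matrix.gene_ids[c]
        if controller in done:
            results.extend(cached[controller])
            continue
        hits = _hits_for_controller(matrix, c, config.threshold, config.method)
        rows = []
        for hit in hits:
            r = _estimate_hit(matrix, hit, config)
            if r is not None:
                rows.append(r)
        results.extend(rows)
        if ckpt is not None:
            _append_checkpoint(ckpt, controller, rows)
        logger.info("controller %s: %d hits", controller, len(rows))

    results = _apply_adjustment(results, config.bh_pool)
    results = _sort_results(results)
    if out_path is not None:
        write_results(results, out_path, config)
    return results


# --- checkpointing (tab-separated, one "#done" marker per controller) ------

_CKPT_FIELDS = 9


def _load_checkpoint(path: Path | None):
    done: set[str] = set()
    cached: dict[str, list[TripletResult]] = {}
    if path is None or not path.exists():
        return done, cached
    pending: dict[str, list[TripletResult]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#done\t"):
                ctrl = line.split("\t", 1)[1]
                done.add(ctrl)
                cached[ctrl] = pending.pop(ctrl, [])
            elif line:
                f = line.split("\t")
                if len(f) != _CKPT_FIELDS:
                    continue  # partial write; controller lacks #done marker
                r = TripletResult(f[0], f[1], f[2], float(f[3]), float(f[4]),
                                  float(f[5]), float(f[6]), None, f[8])
                pending.setdefault(f[2], []).append(r)
    if done:
        logger.info("checkpoint: resuming past %d controllers", len(done))
    return done, cached


def _append_checkpoint(path: Path, controller: str,
                       rows: list[TripletResult]) -> None:
    with open(path, "a") as fh:
        for r in rows:
            fh.write("\t".join([r.x1, r.x2, r.x3, repr(r.rho_diff),
                                repr(r.mla), repr(r.wald), repr(r.pvalue),
                                "NA", r.model]) + "\n")
        fh.write(f"#done\t{controller}\n")
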