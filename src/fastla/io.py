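"""Run configuration and tab-separated readers/writers.

Expression input is plain TSV: first column gene IDs, first row sample IDs,
empty fields or "NA" marking missing values.  Result tables mirror the same
layout as the published top-triplet tables: one row per triplet with the
screening statistic, the MLA estimate, the Wald statistic, raw and adjusted
p-values, and the model code (F/S/R).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix


class InputError(ValueError):
    """Raised on malformed input files."""


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every source of randomness flows from
    ``seed`` so equal configs give identical output."""

    seed: int
    threshold: float = 0.5            # |rho_diff| cutoff, in (0, 2]
    max_missing_frac: float = 0.30    # gene missingness filter
    n_bins: int = 3                   # bins for the direct MLA estimator
    n_boot: int = 1000                # bootstrap replicates (robust path)
    method: str = "pearson"           # or "spearman"
    bh_pool: str = "all"              # "all" or "full_only"
    lof_corr_tol: float = 0.35
    lof_alpha: float = 0.01
    optimizer_max_iter: int = 500
    jobs: int = 1
    transform: bool = True            # normal quantile transform on input
    checkpoint: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 2.0:
            raise InputError("threshold must be in (0, 2]")
        if self.method not in ("pearson", "spearman"):
            raise InputError(f"unknown method {self.method!r}")
        if self.bh_pool not in ("all", "full_only"):
            raise InputError(f"unknown bh_pool {self.bh_pool!r}")

    def header_lines(self) -> list[str]:
        return [f"# {k} = {v}" for k, v in asdict(self).items()]


RESULT_COLUMNS = ["X1", "X2", "X3", "rho_diff", "MLA", "Wald",
                  "p-value", "p-adj", "model"]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes x samples, "NA"/empty = missing).

    Rejects duplicate gene IDs, ragged rows and non-numeric cells, naming
    the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n = len(sample_ids)
        if n == 0:
            raise InputError(f"{path}: no sample columns in header")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n + 1:
                raise InputError(
                    f"{path}:{lineno}: expected {n + 1} fields, got {len(fields)}"
                )
            gid = fields[0]
            if gid in set(gene_ids):
                raise InputError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            row = []
            for col, cell in enumerate(fields[1:], start=2):
                cell = cell.strip()
                if cell in ("", "NA", "NaN", "nan"):
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            gene_ids.append(gid)
            rows.append(row)
    if not rows:
        raise InputError(f"{path}: no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the same TSV format ``read_expression``
    accepts (missing values as "NA")."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def _format_row(r) -> str:
    return "\t".join([
        r.x1, r.x2, r.x3,
        f"{r.rho_diff:.3f}", f"{r.mla:.3f}", f"{r.wald:.3f}",
        f"{r.pvalue:.3E}",
        "NA" if r.padj is None or not np.isfinite(r.padj) else f"{r.padj:.3E}",
        r.model,
    ])


def write_results(results: Iterable, path: str | Path | TextIO,
                  config: RunConfig | None = None) -> None:
    """Write triplet results as TSV, config echoed in a commented header.

    p-values are printed in scientific notation with 4 significant digits;
    rho_diff, MLA and Wald with 3 decimals.
    """
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(_format_row(r) + "\n")
    finally:
        if own:
            fh.close()


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by ``write_results``."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
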