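"""Cell-quality filtering and log-normalization of RPKM matrices.

Cells are kept when they detect at least ``min_genes`` genes (strictly
positive values) and their total RPKM lies inside the inclusive interval
``[min_total, max_total]``. Normalization scales each cell to a common
library size and applies ln(1 + x).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LOGNORM, RPKM, ExpressionMatrix, StateError

REASON_PASS = "pass"
REASON_LOW_GENES = "low_genes"
REASON_LOW_TOTAL = "low_total"
REASON_HIGH_TOTAL = "high_total"


def filter_cells(
    matrix: ExpressionMatrix,
    min_genes: int = 400,
    min_total: float = 150_000.0,
    max_total: float = 8_000_000.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the cell-quality filter; bounds are inclusive.

    Returns the filtered matrix (gene set unchanged) and a per-cell QC
    report covering every input cell with columns ``genes_detected``,
    ``total_rpkm``, ``pass`` and ``reason``. When several rules fail the
    reported reason is the first of low_genes, low_total, high_total.
    """
    if matrix.space_tag != RPKM:
        raise StateError("filter_cells requires an RPKM-space matrix")
    genes_detected = (matrix.values > 0).sum(axis=1)
    total = matrix.values.sum(axis=1)

    reasons = np.full(matrix.n_cells, REASON_PASS, dtype=object)
    reasons[total > max_total] = REASON_HIGH_TOTAL
    reasons[total < min_total] = REASON_LOW_TOTAL
    reasons[genes_detected < min_genes] = REASON_LOW_GENES
    passed = reasons == REASON_PASS

    report = pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_rpkm": total,
            "pass": passed,
            "reason": reasons,
        },
        index=list(matrix.cell_ids),
    )
    report.index.name = "cell_id"
    return matrix.subset_cells(passed), report


def lognormalize(matrix: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform.

    Each value v becomes ln(1 + v / cell_total * scale_factor); zeros stay
    zero, and per cell sum(exp(x) - 1) equals ``scale_factor`` exactly up
    to floating error.
    """
    if matrix.space_tag != RPKM:
        raise StateError("matrix is already log-normalized")
    totals = matrix.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {matrix.cell_ids[zero[0]]!r} has zero total expression; "
            "run filter_cells first"
        )
    values = np.log1p(matrix.values / totals[:, None] * scale_factor)
    return ExpressionMatrix(values, matrix.cell_ids.copy(), matrix.gene_ids.copy(),
                            LOGNORM, matrix.cell_meta, matrix.gene_meta)
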