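"""Per-cluster marker derivation and bin-matched module scores.

Markers come from a two-sided Wilcoxon rank-sum test of each gene between a
cluster and all remaining cells (normal approximation with tie correction;
exact enumeration when both groups have <= 10 cells), with BH correction
across tested genes. Module scores subtract the mean of expression-bin
matched control genes from the mean of the gene set, per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import LOGNORM, ExpressionMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Differentially expressed genes for one cluster vs the rest."""

    cluster: str
    table: pd.DataFrame  # gene, log2_fold_change, p_raw, p_adj, pct_in, pct_out

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def _log2_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """log2((mean expm1 + 1) / (mean expm1 + 1)) on log-normalized data."""
    return np.log2(
        (np.expm1(x_in).mean(axis=0) + 1.0) / (np.expm1(x_out).mean(axis=0) + 1.0)
    )


def rank_sum_de(
    matrix: ExpressionMatrix,
    labels: pd.Series | Sequence,
    cluster: str,
    min_pct: float = 0.10,
    min_abs_log2fc: float = 0.25,
    adj_p_max: float = 0.01,
    only_pos: bool = False,
) -> SignatureSet:
    """Wilcoxon rank-sum markers for ``cluster`` against all other cells.

    Genes expressed in less than ``min_pct`` of cells in both groups, or
    with |log2FC| < ``min_abs_log2fc``, or constant across all cells, are
    not tested. Remaining genes are BH-corrected; entries with
    ``p_adj <= adj_p_max`` are returned, sorted by (p_adj, |log2FC| desc).
    """
    lab = pd.Series(np.asarray(labels, dtype=object), index=list(matrix.cell_ids)) \
        if not isinstance(labels, pd.Series) else labels.reindex(list(matrix.cell_ids))
    if lab.isna().any():
        raise ValueError("labels missing for some cells")
    in_mask = (lab == cluster).to_numpy()
    if in_mask.sum() == 0:
        raise ValueError(f"unknown cluster label {cluster!r}")
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError("both the cluster and its complement need >= 3 cells")

    x_in = matrix.values[in_mask]
    x_out = matrix.values[~in_mask]
    pct_in = (x_in > 0).mean(axis=0)
    pct_out = (x_out > 0).mean(axis=0)
    lfc = _log2_fold_change(x_in, x_out)
    constant = matrix.values.max(axis=0) == matrix.values.min(axis=0)
    testable = (
        (np.maximum(pct_in, pct_out) >= min_pct)
        & (np.abs(lfc) >= min_abs_log2fc)
        & ~constant
    )
    if only_pos:
        testable &= lfc > 0
    cols = np.flatnonzero(testable)
    if cols.size == 0:
        return SignatureSet(cluster, pd.DataFrame(
            columns=["gene", "log2_fold_change", "p_raw", "p_adj",
                     "pct_in", "pct_out"]))

    if n_in <= 10 and n_out <= 10:
        p = np.array([
            sps.mannwhitneyu(x_in[:, c], x_out[:, c], alternative="two-sided",
                             method="exact").pvalue
            for c in cols
        ])
    else:
        res = sps.mannwhitneyu(x_in[:, cols], x_out[:, cols],
                               alternative="two-sided", method="asymptotic",
                               axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    p = np.minimum(p, 1.0)
    q = bh_adjust(p)

    table = pd.DataFrame({
        "gene": matrix.gene_ids[cols],
        "log2_fold_change": lfc[cols],
        "p_raw": p,
        "p_adj": q,
        "pct_in": pct_in[cols],
        "pct_out": pct_out[cols],
    })
    table = table[table["p_adj"] <= adj_p_max].copy()
    table["_abs"] = table["log2_fold_change"].abs()
    table = (table.sort_values(["p_adj", "_abs"], ascending=[True, False],
                               kind="stable")
             .drop(columns="_abs").reset_index(drop=True))
    return SignatureSet(cluster, table)


def find_all_markers(matrix: ExpressionMatrix, labels: pd.Series | Sequence,
                     **kwargs) -> dict[str, SignatureSet]:
    """Run :func:`rank_sum_de` for every cluster label."""
    lab = labels if isinstance(labels, pd.Series) else pd.Series(
        np.asarray(labels, dtype=object), index=list(matrix.cell_ids))
    return {cl: rank_sum_de(matrix, lab, cl, **kwargs)
            for cl in sorted(pd.unique(lab.to_numpy()))}


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per-cell score
    gene_set_name: str
    used_genes: list[str]
    dropped_genes: list[str]
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0


def module_score(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    gene_set_name: str = "module",
) -> ModuleScoreResult:
    """Bin-matched module score per cell.

    All genes are binned into ``n_bins`` equal-frequency bins by average
    expression across cells; for each set gene ``n_ctrl`` control genes are
    drawn with replacement from its bin, pooled, and the pooled control mean
    is subtracted from the set mean. Genes absent from the matrix or with
    zero expression in every cell are dropped (logged); an empty effective
    set is an error listing them.
    """
    if matrix.space_tag != LOGNORM:
        raise ValueError("module_score expects a log-normalized matrix")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    all_zero = matrix.values.max(axis=0) == 0
    dropped = [g for g in gene_set
               if g not in gene_pos or all_zero[gene_pos[g]]]
    used = [g for g in gene_set if g not in set(dropped)]
    if dropped:
        logger.info("module %s: dropped %d absent/zero genes: %s",
                    gene_set_name, len(dropped), ", ".join(map(str, dropped)))
    if not used:
        raise ValueError(
            f"gene set {gene_set_name!r} empty after dropping: {dropped}")

    avg = matrix.values.mean(axis=0)
    # equal-frequency bins; rank with stable tie-break keeps this deterministic
    order_rank = pd.Series(avg).rank(method="first").to_numpy()
    bins = np.asarray(pd.qcut(order_rank, q=min(n_bins, matrix.n_genes),
                              labels=False))
    rng = np.random.default_rng(seed)
    set_idx = np.array([gene_pos[g] for g in used], dtype=int)
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)

    scores = matrix.values[:, set_idx].mean(axis=1) - matrix.values[:, ctrl].mean(axis=1)
    return ModuleScoreResult(
        scores=pd.Series(scores, index=list(matrix.cell_ids)),
        gene_set_name=gene_set_name,
        used_genes=used,
        dropped_genes=dropped,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def compare_module_scores(scores: pd.Series, group_a_cells, group_b_cells,
                          exact_max: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-cell scores."""
    a = list(group_a_cells)
    b = list(group_b_cells)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    if set(a) & set(b):
        raise ValueError("groups overlap")
    from .stats import mann_whitney

    return mann_whitney(scores.loc[a].to_numpy(), scores.loc[b].to_numpy(),
                        exact_max=exact_max)
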