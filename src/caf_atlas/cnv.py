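"""Copy-number inference from smoothed relative expression and malignancy calls.

The profile construction follows the reference-anchored recipe: genes are
ordered genomically, relative log expression against a stromal reference is
clipped to +/- 1, smoothed by a centered moving average (window 101 genes,
never crossing chromosome boundaries), and each cell's median is recentered
to zero. Cells are scored by the mean of squared profile values (SoS) and by
Pearson correlation to a per-sample malignant reference profile; the
three-way call uses lineage-specific quadrant cutoffs:

    keratinocyte  r >= 0.45, SoS >= 0.017
    melanocyte    r >= 0.40, SoS >= 0.026

SoS is the MEAN of squares (gene-count invariant); the raw sum is available
via ``cnv_score(..., mean=False)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LOGNORM, ExpressionMatrix
from .stats import pearson_r_rows

CALL_PLUS = "CNV_plus"
CALL_MINUS = "CNV_minus"
CALL_UNDEFINED = "undefined"

#: lineage -> (pearson r cutoff, SoS cutoff)
LINEAGE_CUTOFFS = {
    "keratinocyte": (0.45, 0.017),
    "melanocyte": (0.40, 0.026),
}


def _chrom_rank(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: chr1..chr22 < chrX < chrY < chrM < other."""
    m = re.fullmatch(r"(?:chr)?(\d+|X|Y|M|MT)", str(chrom), flags=re.IGNORECASE)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return int(tok), ""
        return {"X": 1000, "Y": 1001, "M": 1002, "MT": 1002}[tok], ""
    return 2000, str(chrom)


@dataclass
class GenomeOrder:
    """Total genomic order over genes plus chromosome block boundaries."""

    genes: np.ndarray
    chroms: np.ndarray
    dropped: list = field(default_factory=list)

    def blocks(self) -> list[tuple[int, int]]:
        """Half-open [start, end) index ranges, one per chromosome."""
        out = []
        start = 0
        for i in range(1, len(self.chroms) + 1):
            if i == len(self.chroms) or self.chroms[i] != self.chroms[start]:
                out.append((start, i))
                start = i
        return out


def order_genes_genomically(gene_meta: pd.DataFrame) -> GenomeOrder:
    """Order genes by (chromosome rank, start, gene symbol).

    Genes lacking chromosome or start coordinates are excluded with a
    warning and listed in ``GenomeOrder.dropped``.
    """
    meta = gene_meta.copy()
    bad = meta["chrom"].isna() | meta["start"].isna()
    dropped = list(meta.index[bad])
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes without coordinates excluded "
            f"(first: {dropped[0]!r})", stacklevel=2)
        meta = meta.loc[~bad]
    keys = sorted(
        meta.index,
        key=lambda g: (*_chrom_rank(meta.at[g, "chrom"]),
                       float(meta.at[g, "start"]), str(g)),
    )
    return GenomeOrder(
        genes=np.asarray(keys, dtype=object),
        chroms=np.asarray([meta.at[g, "chrom"] for g in keys], dtype=object),
        dropped=dropped,
    )


@dataclass
class CNVProfile:
    """Per-cell smoothed CNV estimates over genomically ordered positions."""

    values: np.ndarray  # cells x positions
    cell_ids: np.ndarray
    window_gene_map: np.ndarray  # gene symbol per position
    chroms: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, keep) -> "CNVProfile":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        elif not np.issubdtype(idx.dtype, np.integer):
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in idx], dtype=int)
        return CNVProfile(self.values[idx].copy(), self.cell_ids[idx],
                          self.window_gene_map, self.chroms)


def _moving_average_block(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows."""
    n = block.shape[1]
    half = window // 2
    csum = np.cumsum(block, axis=1)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def infer_cnv_profiles(
    matrix: ExpressionMatrix,
    reference_cells,
    min_cells_per_gene: int = 3,
    window: int = 101,
    clip: float = 1.0,
    genome_order: GenomeOrder | None = None,
) -> CNVProfile:
    """Reference-anchored smoothed CNV profiles for every cell.

    Genes detected in fewer than ``min_cells_per_gene`` cells are dropped.
    Relative expression is the cell value minus the reference-cell mean,
    clipped to ``[-clip, +clip]``, then averaged over a centered window of
    ``window`` genes within each chromosome; finally each cell's median is
    recentered to zero.
    """
    if matrix.space_tag != LOGNORM:
        raise ValueError("infer_cnv_profiles requires a log-normalized matrix")
    ref_idx = ExpressionMatrix._resolve(np.asarray(reference_cells), matrix.cell_ids)
    if len(ref_idx) == 0:
        raise ValueError("reference cell set is empty")

    if genome_order is None:
        if matrix.gene_meta is None:
            raise ValueError("gene_meta required to order genes genomically")
        genome_order = order_genes_genomically(matrix.gene_meta)
    in_matrix = set(matrix.gene_ids)
    keep_genes = [g for g in genome_order.genes if g in in_matrix]
    keep_chroms = [c for g, c in zip(genome_order.genes, genome_order.chroms)
                   if g in in_matrix]
    gpos = {g: i for i, g in enumerate(matrix.gene_ids)}
    cols = np.array([gpos[g] for g in keep_genes], dtype=int)

    x = matrix.values[:, cols]
    detected = (x > 0).sum(axis=0)
    ok = detected >= min_cells_per_gene
    x = x[:, ok]
    genes = np.asarray(keep_genes, dtype=object)[ok]
    chroms = np.asarray(keep_chroms, dtype=object)[ok]
    if x.shape[1] == 0:
        raise ValueError("no genes left after min_cells_per_gene filter")

    rel = x - x[ref_idx].mean(axis=0)[None, :]
    np.clip(rel, -clip, clip, out=rel)

    order = GenomeOrder(genes, chroms)
    smoothed = np.empty_like(rel)
    for start, end in order.blocks():
        w = window
        if end - start < window:
            w = end - start
            warnings.warn(
                f"window {window} shrunk to {w} for chromosome block "
                f"{chroms[start]!r}", stacklevel=2)
        smoothed[:, start:end] = _moving_average_block(rel[:, start:end], w)

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    return CNVProfile(smoothed, matrix.cell_ids.copy(), genes, chroms)


def cnv_score(profile: CNVProfile | np.ndarray, mean: bool = True) -> np.ndarray:
    """Per-cell SoS statistic: mean (default) or sum of squared estimates."""
    values = profile.values if isinstance(profile, CNVProfile) else np.asarray(profile, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] == 0:
        raise ValueError("empty profile")
    if not np.all(np.isfinite(values)):
        raise ValueError("profile contains non-finite values")
    sq = values**2
    return sq.mean(axis=1) if mean else sq.sum(axis=1)


def malignant_reference_profile(
    profile: CNVProfile,
    sample_of_cell: pd.Series,
    top_fraction: float = 0.10,
) -> dict[str, np.ndarray]:
    """Per-sample malignant reference: mean profile of the top-SoS cells.

    For each sample the ``top_fraction`` of cells ranked by SoS is averaged;
    samples too small for the fraction fall back to the single top cell with
    a warning.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    sos = cnv_score(profile)
    refs: dict[str, np.ndarray] = {}
    samples = sample_of_cell.reindex(list(profile.cell_ids))
    if samples.isna().any():
        raise ValueError("sample_of_cell missing entries for some cells")
    sarr = samples.to_numpy()
    for sample in sorted(pd.unique(sarr)):
        idx = np.flatnonzero(sarr == sample)
        n_top = int(np.floor(top_fraction * idx.size))
        if n_top < 1:
            warnings.warn(
                f"sample {sample!r} has {idx.size} cells; using top-1 cell "
                "for the malignant reference", stacklevel=2)
            n_top = 1
        top = idx[np.argsort(sos[idx], kind="stable")[::-1][:n_top]]
        refs[str(sample)] = profile.values[top].mean(axis=0)
    return refs


def classify_malignancy(r, sos, lineage: str) -> np.ndarray:
    """Quadrant call from (r, SoS) at lineage-specific cutoffs.

    CNV_plus requires both r >= r_cut and SoS >= s_cut; CNV_minus requires
    both strictly below; anything else is undefined.
    """
    if lineage not in LINEAGE_CUTOFFS:
        raise ValueError(
            f"unknown lineage {lineage!r}; expected one of {sorted(LINEAGE_CUTOFFS)}")
    r_cut, s_cut = LINEAGE_CUTOFFS[lineage]
    r = np.atleast_1d(np.asarray(r, dtype=float))
    sos = np.atleast_1d(np.asarray(sos, dtype=float))
    r = np.where(np.isfinite(r), r, 0.0)
    calls = np.full(r.shape, CALL_UNDEFINED, dtype=object)
    calls[(r >= r_cut) & (sos >= s_cut)] = CALL_PLUS
    calls[(r < r_cut) & (sos < s_cut)] = CALL_MINUS
    return calls


def score_and_classify(
    profile: CNVProfile,
    sample_of_cell: pd.Series,
    lineage: str,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Convenience wrapper: SoS + r against the per-sample reference + call.

    Returns a DataFrame indexed by cell id with columns sos, r, call.
    """
    sos = cnv_score(profile)
    refs = malignant_reference_profile(profile, sample_of_cell, top_fraction)
    samples = sample_of_cell.reindex(list(profile.cell_ids))
    r = np.zeros(len(profile.cell_ids))
    for sample, ref in refs.items():
        mask = (samples == sample).to_numpy()
        r[mask] = pearson_r_rows(profile.values[mask], ref)
    calls = classify_malignancy(r, sos, lineage)
    return pd.DataFrame({"sos": sos, "r": r, "call": calls},
                        index=list(profile.cell_ids))


def flag_ptch_high(
    matrix: ExpressionMatrix,
    candidate_cells,
    healthy_cells,
    k_sd: float = 2.0,
    genes: tuple[str, ...] = ("PTCH1", "PTCH2"),
) -> pd.Series:
    """Flag cells whose PTCH1 or PTCH2 expression exceeds the healthy
    cluster mean by more than ``k_sd`` standard deviations for that gene."""
    present = [g for g in genes if g in set(matrix.gene_ids)]
    if not present:
        raise ValueError(f"none of {genes} present in the matrix")
    cand_idx = ExpressionMatrix._resolve(np.asarray(candidate_cells), matrix.cell_ids)
    healthy_idx = ExpressionMatrix._resolve(np.asarray(healthy_cells), matrix.cell_ids)
    if len(healthy_idx) == 0:
        raise ValueError("healthy reference cluster is empty")
    flags = np.zeros(len(cand_idx), dtype=bool)
    for g in present:
        col = matrix.gene_index(g)
        healthy = matrix.values[healthy_idx, col]
        thresh = healthy.mean() + k_sd * healthy.std(ddof=0)
        flags |= matrix.values[cand_idx, col] > thresh
    return pd.Series(flags, index=list(matrix.cell_ids[cand_idx]))
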