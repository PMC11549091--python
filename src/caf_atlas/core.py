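"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: value-space tags for :class:`ExpressionMatrix`
RPKM = "rpkm"
LOGNORM = "lognorm"


class StateError(RuntimeError):
    """Operation applied to a matrix in the wrong value space."""


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class FixtureParseError(ValueError):
    """Malformed on-disk fixture (names the offending file)."""


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression matrix with aligned metadata.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` nonnegative float array. RPKM scale on input,
        natural-log scale after :func:`caf_atlas.qc.lognormalize`.
    cell_ids, gene_ids
        Unique identifiers for rows / columns.
    space_tag
        Either ``"rpkm"`` or ``"lognorm"``.
    cell_meta
        Optional per-cell table indexed by cell id (columns such as
        ``donor``, ``sample``, ``lineage``, ``cluster``).
    gene_meta
        Optional per-gene table indexed by gene symbol (columns ``chrom``,
        ``start``, ``end``).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    space_tag: str = RPKM
    cell_meta: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if self.space_tag not in (RPKM, LOGNORM):
            raise ValueError(f"unknown space_tag {self.space_tag!r}")
        if self.cell_meta is not None:
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]
        if self.gene_meta is not None:
            missing = [g for g in self.gene_ids if g not in self.gene_meta.index]
            if missing:
                raise ValueError(
                    f"{len(missing)} genes missing from gene_meta "
                    f"(first: {missing[0]!r})"
                )
            self.gene_meta = self.gene_meta.loc[list(self.gene_ids)]

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in matrix")
        return int(idx[0])

    def cell_index(self, cell: str) -> int:
        idx = np.flatnonzero(self.cell_ids == cell)
        if idx.size == 0:
            raise KeyError(f"cell {cell!r} not in matrix")
        return int(idx[0])

    # -- subsetting ----------------------------------------------------------

    def subset_cells(self, keep: Sequence) -> "ExpressionMatrix":
        """Return a copy restricted to the given cells.

        ``keep`` may be a boolean mask, integer positions, or cell ids.
        """
        idx = self._resolve(keep, self.cell_ids)
        meta = self.cell_meta.iloc[idx] if self.cell_meta is not None else None
        return ExpressionMatrix(
            self.values[idx].copy(),
            self.cell_ids[idx],
            self.gene_ids.copy(),
            self.space_tag,
            meta,
            self.gene_meta,
        )

    def subset_genes(self, keep: Sequence) -> "ExpressionMatrix":
        idx = self._resolve(keep, self.gene_ids)
        gmeta = self.gene_meta.iloc[idx] if self.gene_meta is not None else None
        return ExpressionMatrix(
            self.values[:, idx].copy(),
            self.cell_ids.copy(),
            self.gene_ids[idx],
            self.space_tag,
            self.cell_meta,
            gmeta,
        )

    @staticmethod
    def _resolve(keep: Sequence, ids: np.ndarray) -> np.ndarray:
        arr = np.asarray(keep)
        if arr.dtype == bool:
            if arr.shape != ids.shape:
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr
        pos = {v: i for i, v in enumerate(ids)}
        try:
            return np.array([pos[v] for v in arr], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        """Cells x genes DataFrame view (copies the values)."""
        return pd.DataFrame(
            self.values.copy(), index=list(self.cell_ids), columns=list(self.gene_ids)
        )


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic atlas."""

    cell_cluster: pd.Series
    cell_donor: pd.Series
    is_malignant: pd.Series
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    lr_circuits: pd.DataFrame = field(default_factory=pd.DataFrame)
    cnv_segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        cells = list(self.cell_cluster.index)
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate cells in ground truth")
        for s in (self.cell_donor, self.is_malignant):
            if list(s.index) != cells:
                raise ValueError("ground-truth series are not aligned")
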