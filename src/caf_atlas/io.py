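"""Reading and writing expression fixtures (MTX / dense TSV + metadata).

Layout written by :func:`write_fixture` into a directory:

* ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``  (MatrixMarket, genes x cells)
  or ``matrix.tsv``                               (dense genes x cells)
* ``cell_meta.tsv``  — cell_id, donor, sample, lineage, cluster
* ``genes.bed``      — chrom, start, end, gene_symbol (0-based half-open)

Both dialects round-trip losslessly to the same in-memory objects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import ExpressionMatrix, FixtureParseError

CELL_META_COLUMNS = ["donor", "sample", "lineage", "cluster"]


def write_fixture(matrix: ExpressionMatrix, outdir: str | Path,
                  fmt: str = "mtx") -> dict[str, Path]:
    """Write a matrix plus metadata; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "mtx":
        paths["matrix"] = outdir / "matrix.mtx"
        # genes x cells, coordinate format
        spio.mmwrite(str(paths["matrix"]), sparse.coo_matrix(matrix.values.T))
        paths["genes"] = outdir / "genes.tsv"
        paths["cells"] = outdir / "cells.tsv"
        pd.Series(matrix.gene_ids).to_csv(paths["genes"], sep="\t",
                                          index=False, header=False)
        pd.Series(matrix.cell_ids).to_csv(paths["cells"], sep="\t",
                                          index=False, header=False)
    elif fmt == "tsv":
        paths["matrix"] = outdir / "matrix.tsv"
        df = pd.DataFrame(matrix.values.T, index=list(matrix.gene_ids),
                          columns=list(matrix.cell_ids))
        df.to_csv(paths["matrix"], sep="\t", index_label="gene")
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")

    if matrix.cell_meta is not None:
        paths["cell_meta"] = outdir / "cell_meta.tsv"
        meta = matrix.cell_meta.copy()
        meta.index.name = "cell_id"
        meta.to_csv(paths["cell_meta"], sep="\t")
    if matrix.gene_meta is not None:
        paths["gene_bed"] = outdir / "genes.bed"
        bed = matrix.gene_meta.reset_index()
        bed.columns = ["gene_symbol", "chrom", "start", "end"]
        bed[["chrom", "start", "end", "gene_symbol"]].to_csv(
            paths["gene_bed"], sep="\t", index=False, header=False)
    return paths


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """BED-like gene map -> DataFrame indexed by gene symbol."""
    path = Path(path)
    try:
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "gene_symbol"],
                          dtype={"chrom": str, "gene_symbol": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with file name
        raise FixtureParseError(f"{path}: {exc}") from exc
    if bed["gene_symbol"].isna().any() or bed["start"].isna().any():
        raise FixtureParseError(f"{path}: missing fields in BED file")
    if bed["gene_symbol"].duplicated().any():
        dup = bed.loc[bed["gene_symbol"].duplicated(), "gene_symbol"].iloc[0]
        raise FixtureParseError(f"{path}: duplicate gene {dup!r}")
    return bed.set_index("gene_symbol")[["chrom", "start", "end"]]


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise FixtureParseError(f"{path}: missing 'cell_id' column")
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FixtureParseError(f"{path}: missing columns {missing}")
    if meta["cell_id"].duplicated().any():
        raise FixtureParseError(f"{path}: duplicate cell ids")
    return meta.set_index("cell_id")


def read_fixture(indir: str | Path, space_tag: str = "rpkm",
                 require_gene_meta: bool = True) -> ExpressionMatrix:
    """Read a fixture directory (either dialect) back into memory.

    A gene present in the matrix but absent from ``genes.bed`` is an error
    naming the file; extra genes in the BED are ignored.
    """
    indir = Path(indir)
    mtx, tsv = indir / "matrix.mtx", indir / "matrix.tsv"
    if mtx.exists():
        try:
            values = np.asarray(spio.mmread(str(mtx)).todense(), dtype=float).T
        except Exception as exc:  # noqa: BLE001
            raise FixtureParseError(f"{mtx}: {exc}") from exc
        gene_ids = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
        cell_ids = pd.read_csv(indir / "cells.tsv", sep="\t", header=None)[0]
        gene_ids = np.asarray(gene_ids, dtype=object)
        cell_ids = np.asarray(cell_ids, dtype=object)
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise FixtureParseError(
                f"{mtx}: matrix is {values.shape[::-1]} but index files give "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells")
    elif tsv.exists():
        try:
            df = pd.read_csv(tsv, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise FixtureParseError(f"{tsv}: {exc}") from exc
        values = df.to_numpy(dtype=float).T
        gene_ids = np.asarray(df.index, dtype=object)
        cell_ids = np.asarray(df.columns, dtype=object)
    else:
        raise FixtureParseError(f"{indir}: no matrix.mtx or matrix.tsv found")

    cell_meta = None
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        cell_meta = read_cell_meta(meta_path)
        missing = [c for c in cell_ids if c not in cell_meta.index]
        if missing:
            raise FixtureParseError(
                f"{meta_path}: cell {missing[0]!r} absent from metadata")

    gene_meta = None
    bed_path = indir / "genes.bed"
    if bed_path.exists():
        gene_meta = read_gene_bed(bed_path)
        missing = [g for g in gene_ids if g not in gene_meta.index]
        if missing:
            raise FixtureParseError(
                f"{bed_path}: gene {missing[0]!r} in matrix but not in "
                "gene-position file")
    elif require_gene_meta:
        raise FixtureParseError(f"{indir}: genes.bed missing")

    return ExpressionMatrix(values, cell_ids, gene_ids, space_tag,
                            cell_meta, gene_meta)
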