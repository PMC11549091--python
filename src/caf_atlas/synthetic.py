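"""Synthetic multi-donor atlas and ROI-table generators with known ground truth.

The expression model is a per-gene log-normal baseline; cluster markers,
ligand/receptor circuits and copy-number segments act multiplicatively in
linear space (additively in log space), so planted fold changes are exactly
recoverable downstream. Copy-number folds are applied to the raw matrix
before QC so the malignancy caller sees realistic coupling of signal and
noise. Dropout is independent per-cell-per-gene Bernoulli zeroing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, ExpressionMatrix, GroundTruth, RPKM


@dataclass
class ClusterSpec:
    """One cell cluster: size per donor, marker program, lineage label."""

    name: str
    n_cells_per_donor: int
    markers: Mapping[str, float] = field(default_factory=dict)
    lineage: str = "stromal"


@dataclass
class CNVSegment:
    """Contiguous genomic gain/loss: ``start_gene_idx`` is 0-based within
    the chromosome; ``fold`` multiplies linear expression (e.g. 1.5, 0.5)."""

    chrom: str
    start_gene_idx: int
    length_genes: int
    fold: float


@dataclass
class LRCircuit:
    """Planted directed ligand->receptor circuit between two clusters."""

    source_cluster: str
    target_cluster: str
    ligand_gene: str
    receptor_gene: str
    delta: float


@dataclass
class SimConfig:
    n_donors: int
    clusters: Sequence[ClusterSpec]
    n_genes: int
    n_chromosomes: int = 4
    cnv_segments: Sequence[CNVSegment] = field(default_factory=list)
    malignant_cluster: str | None = None
    lr_circuits: Sequence[LRCircuit] = field(default_factory=list)
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.4
    dropout_rate: float = 0.3
    #: optional cluster -> per-donor weights, to plant donor skew
    donor_weights: Mapping[str, Sequence[float]] | None = None
    seed: int = 0


def _gene_map(n_genes: int, n_chromosomes: int) -> pd.DataFrame:
    """Evenly split ``n_genes`` over chromosomes; BED-like coordinates."""
    width = max(4, len(str(n_genes - 1)))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    sizes = np.full(n_chromosomes, n_genes // n_chromosomes)
    sizes[: n_genes % n_chromosomes] += 1
    chroms, starts = [], []
    for c, size in enumerate(sizes):
        chroms.extend([f"chr{c + 1}"] * size)
        starts.extend(10_000 * (np.arange(size) + 1))
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": np.asarray(starts) + 1_000},
        index=genes,
    )


def _validate(config: SimConfig, gene_meta: pd.DataFrame) -> None:
    names = [c.name for c in config.clusters]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate cluster names")
    if config.n_donors < 1:
        raise ConfigurationError("n_donors must be >= 1")
    for c in config.clusters:
        if c.n_cells_per_donor < 1:
            raise ConfigurationError(f"cluster {c.name!r} must have >= 1 cell")
        for g, d in c.markers.items():
            if g not in gene_meta.index:
                raise ConfigurationError(f"marker gene {g!r} not in gene map")
            if not np.isfinite(d):
                raise ConfigurationError(f"non-finite marker delta for {g!r}")
    if config.cnv_segments and config.malignant_cluster is None:
        raise ConfigurationError("cnv_segments given without malignant_cluster")
    if config.malignant_cluster is not None and config.malignant_cluster not in names:
        raise ConfigurationError(
            f"unknown malignant_cluster {config.malignant_cluster!r}"
        )
    chrom_sizes = gene_meta.groupby("chrom").size()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in config.cnv_segments:
        if seg.chrom not in chrom_sizes.index:
            raise ConfigurationError(f"unknown chromosome {seg.chrom!r}")
        if seg.length_genes < 1 or not np.isfinite(seg.fold) or seg.fold <= 0:
            raise ConfigurationError("invalid CNV segment length or fold")
        end = seg.start_gene_idx + seg.length_genes
        if seg.start_gene_idx < 0 or end > chrom_sizes[seg.chrom]:
            raise ConfigurationError(
                f"CNV segment exceeds {seg.chrom} bounds "
                f"({seg.start_gene_idx}:{end} of {chrom_sizes[seg.chrom]})"
            )
        for s, e in by_chrom.get(seg.chrom, []):
            if seg.start_gene_idx < e and s < end:
                raise ConfigurationError(f"overlapping CNV segments on {seg.chrom}")
        by_chrom.setdefault(seg.chrom, []).append((seg.start_gene_idx, end))
    for circ in config.lr_circuits:
        for cl in (circ.source_cluster, circ.target_cluster):
            if cl not in names:
                raise ConfigurationError(f"unknown cluster {cl!r} in lr_circuits")
        for g in (circ.ligand_gene, circ.receptor_gene):
            if g not in gene_meta.index:
                raise ConfigurationError(f"LR gene {g!r} not in gene map")
        if not np.isfinite(circ.delta):
            raise ConfigurationError("non-finite LR delta")


def generate_atlas(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a multi-donor RPKM atlas with planted signals.

    Returns the RPKM-space matrix (cell and gene metadata attached) and the
    planted :class:`~caf_atlas.core.GroundTruth`. Identical configs and
    seeds give bit-identical output.
    """
    gene_meta = _gene_map(config.n_genes, config.n_chromosomes)
    _validate(config, gene_meta)
    rng = np.random.default_rng(config.seed)
    genes = np.asarray(gene_meta.index, dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}

    base_log = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          config.n_genes)

    # cell bookkeeping: cluster blocks x donors
    cell_ids: list[str] = []
    clusters: list[str] = []
    donors: list[str] = []
    lineages: list[str] = []
    donor_names = [f"D{d}" for d in range(config.n_donors)]
    for spec in config.clusters:
        total = spec.n_cells_per_donor * config.n_donors
        if config.donor_weights and spec.name in config.donor_weights:
            w = np.asarray(config.donor_weights[spec.name], dtype=float)
            if w.size != config.n_donors or np.any(w < 0) or w.sum() == 0:
                raise ConfigurationError(f"bad donor weights for {spec.name!r}")
            counts = rng.multinomial(total, w / w.sum())
        else:
            counts = np.full(config.n_donors, spec.n_cells_per_donor)
        for d, n in zip(donor_names, counts):
            for i in range(n):
                cell_ids.append(f"{spec.name}.{d}.{i}")
                clusters.append(spec.name)
                donors.append(d)
                lineages.append(spec.lineage)
    n_cells = len(cell_ids)
    cluster_arr = np.asarray(clusters, dtype=object)

    log_x = base_log[None, :] + rng.normal(0.0, config.noise_sd,
                                           (n_cells, config.n_genes))

    marker_rows = []
    for spec in config.clusters:
        mask = cluster_arr == spec.name
        for g, delta in spec.markers.items():
            log_x[mask, gene_pos[g]] += delta
            marker_rows.append({"cluster": spec.name, "gene": g, "delta": delta})

    lr_rows = []
    for circ in config.lr_circuits:
        log_x[cluster_arr == circ.source_cluster, gene_pos[circ.ligand_gene]] += circ.delta
        log_x[cluster_arr == circ.target_cluster, gene_pos[circ.receptor_gene]] += circ.delta
        lr_rows.append({
            "source_cluster": circ.source_cluster,
            "target_cluster": circ.target_cluster,
            "ligand": circ.ligand_gene,
            "receptor": circ.receptor_gene,
            "delta": circ.delta,
        })

    is_malignant = np.zeros(n_cells, dtype=bool)
    cnv_rows = []
    if config.malignant_cluster is not None:
        is_malignant = cluster_arr == config.malignant_cluster
    chrom_offsets = {}
    off = 0
    for chrom, size in gene_meta.groupby("chrom", sort=False).size().items():
        chrom_offsets[chrom] = off
        off += size
    for seg in config.cnv_segments:
        lo = chrom_offsets[seg.chrom] + seg.start_gene_idx
        hi = lo + seg.length_genes
        log_x[np.ix_(is_malignant, np.arange(lo, hi))] += np.log(seg.fold)
        cnv_rows.append({
            "chrom": seg.chrom, "start_gene_idx": seg.start_gene_idx,
            "length_genes": seg.length_genes, "fold": seg.fold,
            "global_start": lo, "global_end": hi,
        })

    values = np.exp(log_x)
    if config.dropout_rate > 0:
        values[rng.random(values.shape) < config.dropout_rate] = 0.0

    cell_meta = pd.DataFrame(
        {
            "donor": donors,
            "sample": donors,  # one sample per donor by default
            "lineage": lineages,
            "cluster": clusters,
        },
        index=cell_ids,
    )
    matrix = ExpressionMatrix(values, np.asarray(cell_ids, dtype=object), genes,
                              RPKM, cell_meta, gene_meta)
    truth = GroundTruth(
        cell_cluster=cell_meta["cluster"].copy(),
        cell_donor=cell_meta["donor"].copy(),
        is_malignant=pd.Series(is_malignant, index=cell_ids),
        markers=pd.DataFrame(marker_rows),
        lr_circuits=pd.DataFrame(lr_rows),
        cnv_segments=pd.DataFrame(cnv_rows),
    )
    return matrix, truth


def generate_roi_table(
    n_samples_per_class: int,
    class_rates: Mapping[str, Mapping[str, float]],
    exclusion_beta: float = 0.0,
    noise_sd: float = 0.1,
    areas: tuple[float, float] = (0.1, 0.5),
    n_rois_per_sample: int = 5,
    seed: int = 0,
    cd3_alpha: float = 2.5,
    nest_area_frac: float = 0.4,
    exclusion_phenotype: str = "mCAF",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a per-ROI phenotype count table with planted effects.

    Counts are Poisson(rate x area). CD3-in-nest densities follow the
    log-linear exclusion model
    ``log10(cd3 + 1) = cd3_alpha + exclusion_beta * log10(caf_density + 1) + eps``
    against the observed density of ``exclusion_phenotype``, so a fitted
    log-log regression with pseudocount 1 recovers ``exclusion_beta``.
    CD3 nest counts are stored unrounded so noiseless configurations are
    exactly linear.
    """
    if n_rois_per_sample < 5:
        raise ConfigurationError("n_rois_per_sample must be >= 5")
    lo, hi = areas
    if lo <= 0 or hi < lo:
        raise ConfigurationError("ROI areas must be positive")
    phenotypes: list[str] = []
    for cls, rates in class_rates.items():
        for ph, rate in rates.items():
            if rate <= 0:
                raise ConfigurationError(f"rate for {cls}/{ph} must be > 0")
            if ph not in phenotypes:
                phenotypes.append(ph)
    if exclusion_phenotype not in phenotypes:
        raise ConfigurationError(
            f"exclusion_phenotype {exclusion_phenotype!r} absent from class_rates"
        )

    rng = np.random.default_rng(seed)
    rows = []
    for cls, rates in class_rates.items():
        for s in range(n_samples_per_class):
            sample = f"{cls}_S{s}"
            for r in range(n_rois_per_sample):
                area = float(rng.uniform(lo, hi))
                row = {
                    "sample_id": sample,
                    "tumor_class": cls,
                    "roi_id": f"{sample}_R{r}",
                    "area_mm2": area,
                }
                for ph in phenotypes:
                    rate = rates.get(ph, 0.0)
                    row[ph] = int(rng.poisson(rate * area)) if rate > 0 else 0
                caf_density = row[exclusion_phenotype] / area
                log_cd3 = (
                    cd3_alpha
                    + exclusion_beta * np.log10(caf_density + 1.0)
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                )
                cd3_density = max(10.0 ** log_cd3 - 1.0, 0.0)
                nest_area = nest_area_frac * area
                row["nest_area_mm2"] = nest_area
                row["cd3_in_nest_count"] = cd3_density * nest_area
                rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "exclusion_beta": exclusion_beta,
        "cd3_alpha": cd3_alpha,
        "class_rates": {c: dict(r) for c, r in class_rates.items()},
        "exclusion_phenotype": exclusion_phenotype,
        "phenotypes": phenotypes,
    }
    return table, truth
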