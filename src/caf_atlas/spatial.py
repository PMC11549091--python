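"""In-situ quantification: phenotyping, ROI densities, class comparisons,
and T-cell exclusion statistics.

Phenotypes from marker positivity:

* totalCAF: COL1A1+
* iCAF:     COL1A1+ MMP1+
* mCAF:     COL1A1+ COL11A1+ MMP1-

Sample densities pool counts over ROIs: sum(counts) / sum(area), never a
mean of per-ROI ratios; at least five ROIs per sample are required. T-cell
exclusion is tested by OLS of log10(CD3 density + pseudocount) on
log10(CAF density + pseudocount) and by a high/low density stratification
compared with an unpaired two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import mann_whitney

MIN_ROIS_PER_SAMPLE = 5

PHENOTYPES = ("totalCAF", "iCAF", "mCAF")

ROI_REQUIRED_COLUMNS = ("sample_id", "tumor_class", "roi_id", "area_mm2")


def phenotype_cells(marker_calls: pd.DataFrame) -> pd.DataFrame:
    """Multi-label phenotype from per-cell boolean marker calls.

    ``marker_calls`` needs boolean columns COL1A1, MMP1, COL11A1. Returns a
    boolean frame with columns totalCAF, iCAF, mCAF, none; iCAF and mCAF are
    mutually exclusive and both imply totalCAF.
    """
    for col in ("COL1A1", "MMP1", "COL11A1"):
        if col not in marker_calls.columns:
            raise ValueError(f"missing marker call column {col!r}")
        if marker_calls[col].isna().any():
            raise ValueError(f"missing marker call values in {col!r}")
    col1a1 = marker_calls["COL1A1"].astype(bool)
    mmp1 = marker_calls["MMP1"].astype(bool)
    col11a1 = marker_calls["COL11A1"].astype(bool)
    out = pd.DataFrame(index=marker_calls.index)
    out["totalCAF"] = col1a1
    out["iCAF"] = col1a1 & mmp1
    out["mCAF"] = col1a1 & col11a1 & ~mmp1
    out["none"] = ~col1a1
    return out


def validate_roi_table(roi_table: pd.DataFrame) -> None:
    missing = [c for c in ROI_REQUIRED_COLUMNS if c not in roi_table.columns]
    if missing:
        raise ValueError(f"ROI table missing columns {missing}")
    if (roi_table["area_mm2"] <= 0).any():
        bad = roi_table.loc[roi_table["area_mm2"] <= 0, "roi_id"].iloc[0]
        raise ValueError(f"nonpositive ROI area (roi {bad!r})")


@dataclass
class DensityRecord:
    sample_id: str
    tumor_class: str
    phenotype: str
    density: float  # cells per mm^2
    n_rois: int
    total_count: float
    total_area: float


def aggregate_density(roi_table: pd.DataFrame, sample_id: str,
                      phenotype: str) -> DensityRecord:
    """Pooled sample density: sum of ROI counts over sum of ROI areas.

    Requires at least five ROIs for the sample.
    """
    validate_roi_table(roi_table)
    if phenotype not in roi_table.columns:
        raise ValueError(f"phenotype column {phenotype!r} absent from ROI table")
    sub = roi_table[roi_table["sample_id"] == sample_id]
    if len(sub) == 0:
        raise ValueError(f"sample {sample_id!r} not in ROI table")
    if len(sub) < MIN_ROIS_PER_SAMPLE:
        raise ValueError(
            f"sample {sample_id!r} has {len(sub)} ROIs; a minimum of "
            f"{MIN_ROIS_PER_SAMPLE} representative ROIs is required")
    total_area = float(sub["area_mm2"].sum())
    if total_area <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total area")
    total_count = float(sub[phenotype].sum())
    return DensityRecord(
        sample_id=sample_id,
        tumor_class=str(sub["tumor_class"].iloc[0]),
        phenotype=phenotype,
        density=total_count / total_area,
        n_rois=len(sub),
        total_count=total_count,
        total_area=total_area,
    )


def sample_densities(roi_table: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    """Aggregate every sample; returns sample_id, tumor_class, density."""
    recs = [aggregate_density(roi_table, s, phenotype)
            for s in pd.unique(roi_table["sample_id"])]
    return pd.DataFrame([{
        "sample_id": r.sample_id, "tumor_class": r.tumor_class,
        "phenotype": r.phenotype, "density": r.density,
    } for r in recs])


def compare_classes(densities: pd.DataFrame, class_a: str, class_b: str,
                    exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-sample densities of two tumor classes.

    Exact null when both classes have <= ``exact_max`` samples, otherwise
    the tie-corrected normal approximation.
    """
    vals = {}
    for cls in (class_a, class_b):
        sub = densities.loc[densities["tumor_class"] == cls, "density"]
        if len(sub) == 0:
            raise ValueError(f"tumor class {cls!r} absent")
        if len(sub) < 3:
            raise ValueError(f"tumor class {cls!r} has fewer than 3 samples")
        vals[cls] = sub.to_numpy(dtype=float)
    return mann_whitney(vals[class_a], vals[class_b], exact_max=exact_max)


def exclusion_regression(cd3_nest_density, caf_density,
                         pseudocount: float = 1.0) -> tuple[float, float, float]:
    """OLS of log10(cd3 + pc) on log10(caf + pc): (slope, intercept, R^2).

    A constant response gives slope 0 and R^2 = 0; a zero-variance
    predictor is an error.
    """
    y = np.log10(np.asarray(cd3_nest_density, dtype=float) + pseudocount)
    x = np.log10(np.asarray(caf_density, dtype=float) + pseudocount)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equally sized 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values after log transform; check pseudocount")
    if np.all(x == x[0]):
        raise ValueError("zero variance in predictor")
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    slope = float((xc * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sstot == 0 else 1.0 - float((resid**2).sum()) / sstot
    return slope, intercept, r2


def stratify_high_low(caf_density, cd3_density, cutoff: float,
                      pseudocount: float = 1.0,
                      equal_var: bool = False) -> dict:
    """Split observations at a CAF-density cutoff (high iff density >= cutoff,
    inclusive) and compare log10 CD3 densities by unpaired two-sided t-test
    (Welch by default; pooled with ``equal_var=True``)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    caf = np.asarray(caf_density, dtype=float)
    cd3 = np.asarray(cd3_density, dtype=float)
    if caf.shape != cd3.shape:
        raise ValueError("inputs must be equally sized")
    high = caf >= cutoff
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"empty stratum at cutoff {cutoff} (high={n_high}, low={n_low})")
    log_high = np.log10(cd3[high] + pseudocount)
    log_low = np.log10(cd3[~high] + pseudocount)
    t, p = sps.ttest_ind(log_high, log_low, equal_var=equal_var)
    return {
        "n_high": n_high,
        "n_low": n_low,
        "mean_log_cd3_high": float(log_high.mean()),
        "mean_log_cd3_low": float(log_low.mean()),
        "t": float(t),
        "p": float(p),
        "high_mask": high,
    }
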