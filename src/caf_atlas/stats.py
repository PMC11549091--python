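"""Small shared statistics helpers: BH step-up and rank-sum wrappers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input p-values must lie in (0, 1]. Monotonicity is enforced by the
    running minimum from the largest p downward; q-values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing q along increasing p
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mann_whitney(x, y, exact_max: int = 10, alternative: str = "two-sided"):
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Uses the exact null when both groups have at most ``exact_max``
    observations, otherwise the tie-corrected normal approximation.
    Degenerate input where every pooled value is identical returns
    ``p = 1`` with the null-mean U statistic.

    Returns
    -------
    (U, p) for the first sample ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    method = "exact" if (x.size <= exact_max and y.size <= exact_max) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_r_rows(profiles: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``profiles`` against ``reference``.

    Rows (or a reference) with zero variance get r = 0 by convention, so
    degenerate flat profiles can never clear a positive correlation cutoff.
    """
    prof = np.asarray(profiles, dtype=float)
    ref = np.asarray(reference, dtype=float)
    pc = prof - prof.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom_p = np.sqrt((pc**2).sum(axis=1))
    denom_r = np.sqrt((rc**2).sum())
    if denom_r == 0:
        return np.zeros(prof.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ rc) / (denom_p * denom_r)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)
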