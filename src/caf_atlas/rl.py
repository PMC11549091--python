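"""Permutation-based receptor-ligand enrichment between cluster pairs.

For every directed cluster pair that satisfies the donor co-presence
prerequisite (some donor contributes >= 2.5% of the cells of both clusters),
the number of database ligand-receptor pairs formed by the two signatures is
compared against a null built by resampling equally sized ligand and
receptor pools uniformly without replacement from the database universes,
10,000 times by default. Empirical p-values use the add-one estimator
(1 + #{null >= observed}) / (n_perm + 1) and are BH-corrected in one family
across all tested pairs. Replicates are seeded individually (counter-based)
so results do not depend on worker count or evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import SignatureSet
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class LRDatabase:
    """Deduplicated directed ligand->receptor pair database."""

    pairs: list[tuple[str, str]]
    ligand_universe: list[str]
    receptor_universe: list[str]
    sources: dict[tuple[str, str], set] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def load_lr_database(table: str | Path | pd.DataFrame) -> LRDatabase:
    """Load a ligand/receptor CSV (columns ``ligand``, ``receptor``,
    optional ``source``); duplicate pairs are merged, keeping all tags."""
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = table.copy()
    missing = [c for c in ("ligand", "receptor") if c not in df.columns]
    if missing:
        raise ValueError(f"LR database missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("LR database is empty")
    sources: dict[tuple[str, str], set] = {}
    for _, row in df.iterrows():
        pair = (str(row["ligand"]), str(row["receptor"]))
        tag = str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else "unknown"
        sources.setdefault(pair, set()).add(tag)
    pairs = sorted(sources)
    n_dup = len(df) - len(pairs)
    logger.info("LR database: %d rows, %d unique pairs, %d duplicates",
                len(df), len(pairs), n_dup)
    return LRDatabase(
        pairs=pairs,
        ligand_universe=sorted({l for l, _ in pairs}),
        receptor_universe=sorted({r for _, r in pairs}),
        sources=sources,
    )


def _signature_genes(sig) -> set[str]:
    if isinstance(sig, SignatureSet):
        return set(sig.genes)
    return set(sig)


def candidate_pairs(sig_source, sig_target, db: LRDatabase) -> list[tuple[str, str]]:
    """Directed (ligand, receptor) pairs formed by the two signatures."""
    ligands = _signature_genes(sig_source) & set(db.ligand_universe)
    receptors = _signature_genes(sig_target) & set(db.receptor_universe)
    return [(l, r) for l, r in db.pairs if l in ligands and r in receptors]


def donor_copresence(cell_meta: pd.DataFrame, cluster_a: str, cluster_b: str,
                     min_frac: float = 0.025) -> bool:
    """True iff some donor contributes >= ``min_frac`` of the cells of BOTH
    clusters."""
    a = cell_meta.loc[cell_meta["cluster"] == cluster_a, "donor"]
    b = cell_meta.loc[cell_meta["cluster"] == cluster_b, "donor"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"empty cluster in donor co-presence check: "
            f"{cluster_a!r} ({len(a)}) / {cluster_b!r} ({len(b)})")
    frac_a = a.value_counts() / len(a)
    frac_b = b.value_counts() / len(b)
    shared = frac_a.index.intersection(frac_b.index)
    return bool(((frac_a[shared] >= min_frac) & (frac_b[shared] >= min_frac)).any())


def _replicate_rng(seed, rep: int) -> np.random.Generator:
    base = list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]
    return np.random.default_rng([*base, rep])


def permutation_null_counts(n_ligands: int, n_receptors: int, db: LRDatabase,
                            n_perm: int, seed) -> np.ndarray:
    """Null distribution of database-pair counts for random equal-size pools."""
    nl, nr = len(db.ligand_universe), len(db.receptor_universe)
    if n_ligands > nl or n_receptors > nr:
        raise ValueError("pool size exceeds database universe")
    lig_pos = {g: i for i, g in enumerate(db.ligand_universe)}
    rec_pos = {g: i for i, g in enumerate(db.receptor_universe)}
    pl = np.array([lig_pos[l] for l, _ in db.pairs], dtype=int)
    pr = np.array([rec_pos[r] for _, r in db.pairs], dtype=int)
    counts = np.empty(n_perm, dtype=int)
    lmask = np.zeros(nl, dtype=bool)
    rmask = np.zeros(nr, dtype=bool)
    for rep in range(n_perm):
        rng = _replicate_rng(seed, rep)
        lmask[:] = False
        rmask[:] = False
        lmask[rng.choice(nl, n_ligands, replace=False)] = True
        rmask[rng.choice(nr, n_receptors, replace=False)] = True
        counts[rep] = int(np.count_nonzero(lmask[pl] & rmask[pr]))
    return counts


def permutation_enrichment(n_obs: int, n_ligands: int, n_receptors: int,
                           db: LRDatabase, n_perm: int = 10_000,
                           seed=0) -> float:
    """Add-one empirical p-value for observing >= ``n_obs`` database pairs."""
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    counts = permutation_null_counts(n_ligands, n_receptors, db, n_perm, seed)
    return (1 + int((counts >= n_obs).sum())) / (n_perm + 1)


@dataclass
class InteractionResult:
    source_cluster: str
    target_cluster: str
    candidate_pairs: list[tuple[str, str]]
    n_obs: int
    n_perm: int
    donor_prerequisite_met: bool
    p_empirical: float | None = None
    q_bh: float | None = None
    significant: bool | None = None
    seed: int = 0


def run_rl_analysis(
    signatures: Mapping[str, SignatureSet | Sequence[str]],
    cell_meta: pd.DataFrame,
    db: LRDatabase,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    min_donor_frac: float = 0.025,
    seed: int = 0,
) -> list[InteractionResult]:
    """Full enrichment screen over every ordered cluster pair.

    Pairs failing the donor prerequisite appear in the output with
    ``donor_prerequisite_met=False`` and no p/q. BH correction spans all
    tested pairs as one family; ``significant`` flags q <= ``alpha``.
    """
    clusters = sorted(signatures)
    if len(clusters) < 2:
        raise ValueError("need signatures for at least two clusters")
    results: list[InteractionResult] = []
    tested: list[InteractionResult] = []
    k = 0
    for src in clusters:
        for tgt in clusters:
            if src == tgt:
                continue
            ok = donor_copresence(cell_meta, src, tgt, min_donor_frac)
            cands = candidate_pairs(signatures[src], signatures[tgt], db)
            res = InteractionResult(
                source_cluster=src, target_cluster=tgt,
                candidate_pairs=cands, n_obs=len(cands), n_perm=n_perm,
                donor_prerequisite_met=ok, seed=seed)
            if ok:
                n_lig = len(_signature_genes(signatures[src]) & set(db.ligand_universe))
                n_rec = len(_signature_genes(signatures[tgt]) & set(db.receptor_universe))
                res.p_empirical = permutation_enrichment(
                    res.n_obs, n_lig, n_rec, db, n_perm=n_perm, seed=[seed, k])
                tested.append(res)
            results.append(res)
            k += 1
    if tested:
        q = bh_adjust([r.p_empirical for r in tested])
        for r, qv in zip(tested, q):
            r.q_bh = float(qv)
            r.significant = bool(qv <= alpha)
    return results


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    """Flatten interaction results for TSV output."""
    return pd.DataFrame([
        {
            "source": r.source_cluster,
            "target": r.target_cluster,
            "n_obs": r.n_obs,
            "p": r.p_empirical,
            "q": r.q_bh,
            "donor_ok": r.donor_prerequisite_met,
            "significant": r.significant,
            "pairs": ";".join(f"{l}>{rc}" for l, rc in r.candidate_pairs),
        }
        for r in results
    ])
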