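"""End-to-end orchestration: config validation, staged runs, demo fixture."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import io as io_mod
from . import markers as markers_mod
from . import qc as qc_mod
from . import rl as rl_mod
from . import spatial as spatial_mod
from . import synthetic
from .core import RPKM, ConfigurationError

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "cnv", "markers", "rl", "spatial")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "paths": {},
    "qc": {"min_genes": 400, "min_total": 150_000.0, "max_total": 8_000_000.0,
           "scale_factor": 1e4},
    "cnv": {"reference_cluster": "stromal", "lineage": "keratinocyte",
            "min_cells_per_gene": 3, "window": 101, "clip": 1.0,
            "top_fraction": 0.10},
    "markers": {"min_pct": 0.10, "min_abs_log2fc": 0.25, "adj_p_max": 0.01,
                "only_pos": True},
    "rl": {"n_perm": 10_000, "alpha": 0.05, "min_donor_frac": 0.025},
    "spatial": {"phenotypes": ["totalCAF", "iCAF", "mCAF"],
                "compare": [], "exclusion_phenotype": "mCAF",
                "pseudocount": 1.0, "cutoffs": {}},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    cfg["_config_dir"] = str(Path(path).resolve().parent)
    return cfg


def _resolve_path(cfg: dict, key: str) -> Path:
    p = Path(cfg["paths"][key])
    if not p.is_absolute() and "_config_dir" in cfg:
        p = Path(cfg["_config_dir"]) / p
    return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(cfg: dict) -> None:
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    needed = set()
    if {"qc", "cnv", "markers", "rl"} & set(stages):
        needed.add("matrix_dir")
    if "rl" in stages:
        needed.add("lrdb")
    if "spatial" in stages:
        needed.add("roi")
    for key in sorted(needed):
        if key not in cfg.get("paths", {}):
            raise ConfigurationError(f"config paths.{key} is required")
        p = _resolve_path(cfg, key)
        if not p.exists():
            raise ConfigurationError(f"configured path does not exist: {p}")


def run_pipeline(cfg: dict, outdir: str | Path) -> Path:
    """Run the configured stages, writing TSV artifacts plus a manifest.

    The manifest records parameters, the seed, input checksums and per-stage
    row counts; identical config + seed gives identical outputs. A stage
    failure aborts the run with the failing stage named and the manifest
    marked incomplete.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    manifest: dict = {
        "seed": cfg["seed"],
        "stages": stages,
        "parameters": {k: cfg[k] for k in ("qc", "cnv", "markers", "rl", "spatial")},
        "inputs": {},
        "stage_results": {},
        "status": "incomplete",
    }
    for key in cfg.get("paths", {}):
        p = _resolve_path(cfg, key)
        if p.is_file():
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        elif p.is_dir():
            manifest["inputs"][key] = {
                "path": str(p),
                "sha256": {f.name: _sha256(f) for f in sorted(p.iterdir())
                           if f.is_file()},
            }
    manifest_path = outdir / "manifest.json"

    def _write_manifest() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    matrix = None
    signatures = None
    current = None
    try:
        if {"qc", "cnv", "markers", "rl"} & set(stages):
            matrix = io_mod.read_fixture(_resolve_path(cfg, "matrix_dir"),
                                         space_tag=RPKM)

        if "qc" in stages:
            current = "qc"
            matrix, report = qc_mod.filter_cells(
                matrix, cfg["qc"]["min_genes"], cfg["qc"]["min_total"],
                cfg["qc"]["max_total"])
            report.to_csv(outdir / "qc_report.tsv", sep="\t")
            manifest["stage_results"]["qc"] = {
                "cells_in": len(report), "cells_retained": int(report["pass"].sum()),
            }

        if matrix is not None and matrix.space_tag == RPKM:
            matrix = qc_mod.lognormalize(matrix, cfg["qc"]["scale_factor"])

        if "cnv" in stages:
            current = "cnv"
            ccfg = cfg["cnv"]
            ref_cells = matrix.cell_ids[
                (matrix.cell_meta["cluster"] == ccfg["reference_cluster"]).to_numpy()]
            profile = cnv_mod.infer_cnv_profiles(
                matrix, ref_cells,
                min_cells_per_gene=ccfg["min_cells_per_gene"],
                window=ccfg["window"], clip=ccfg["clip"])
            calls = cnv_mod.score_and_classify(
                profile, matrix.cell_meta["sample"], ccfg["lineage"],
                top_fraction=ccfg["top_fraction"])
            calls.index.name = "cell_id"
            calls.to_csv(outdir / "cnv_calls.tsv", sep="\t")
            manifest["stage_results"]["cnv"] = {
                "cells_scored": len(calls),
                "cnv_plus": int((calls["call"] == cnv_mod.CALL_PLUS).sum()),
            }

        if "markers" in stages or "rl" in stages:
            current = "markers"
            mcfg = cfg["markers"]
            signatures = markers_mod.find_all_markers(
                matrix, matrix.cell_meta["cluster"],
                min_pct=mcfg["min_pct"], min_abs_log2fc=mcfg["min_abs_log2fc"],
                adj_p_max=mcfg["adj_p_max"], only_pos=mcfg["only_pos"])
            if "markers" in stages:
                for cl, sig in signatures.items():
                    sig.table.to_csv(outdir / f"sig_{cl}.tsv", sep="\t",
                                     index=False)
                manifest["stage_results"]["markers"] = {
                    cl: len(sig) for cl, sig in signatures.items()}

        if "rl" in stages:
            current = "rl"
            rcfg = cfg["rl"]
            db = rl_mod.load_lr_database(_resolve_path(cfg, "lrdb"))
            results = rl_mod.run_rl_analysis(
                signatures, matrix.cell_meta, db,
                n_perm=rcfg["n_perm"], alpha=rcfg["alpha"],
                min_donor_frac=rcfg["min_donor_frac"], seed=cfg["seed"])
            frame = rl_mod.results_to_frame(results)
            frame.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
            manifest["stage_results"]["rl"] = {
                "pairs_total": len(frame),
                "pairs_tested": int(frame["p"].notna().sum()),
                "pairs_significant": int((frame["significant"] == True).sum()),  # noqa: E712
            }

        if "spatial" in stages:
            current = "spatial"
            scfg = cfg["spatial"]
            roi = pd.read_csv(_resolve_path(cfg, "roi"))
            spatial_mod.validate_roi_table(roi)
            dens_frames = [spatial_mod.sample_densities(roi, ph)
                           for ph in scfg["phenotypes"]]
            densities = pd.concat(dens_frames, ignore_index=True)
            densities.to_csv(outdir / "densities.tsv", sep="\t", index=False)
            comp_rows = []
            for ph in scfg["phenotypes"]:
                dsub = densities[densities["phenotype"] == ph]
                for pair in scfg["compare"]:
                    a, b = pair
                    u, p = spatial_mod.compare_classes(dsub, a, b)
                    comp_rows.append({"phenotype": ph, "class_a": a,
                                      "class_b": b, "U": u, "p": p})
            if comp_rows:
                pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.tsv",
                                               sep="\t", index=False)
            excl_rows = []
            if "cd3_in_nest_count" in roi.columns:
                cd3_dens = roi["cd3_in_nest_count"] / roi["nest_area_mm2"]
                for ph in scfg["phenotypes"]:
                    caf_dens = roi[ph] / roi["area_mm2"]
                    slope, intercept, r2 = spatial_mod.exclusion_regression(
                        cd3_dens, caf_dens, pseudocount=scfg["pseudocount"])
                    row = {"phenotype": ph, "slope": slope,
                           "intercept": intercept, "r_squared": r2}
                    cutoff = scfg["cutoffs"].get(ph)
                    if cutoff is not None:
                        strat = spatial_mod.stratify_high_low(
                            caf_dens, cd3_dens, cutoff,
                            pseudocount=scfg["pseudocount"])
                        row.update({k: strat[k] for k in
                                    ("n_high", "n_low", "t", "p")})
                    excl_rows.append(row)
                pd.DataFrame(excl_rows).to_csv(outdir / "exclusion.tsv",
                                               sep="\t", index=False)
            manifest["stage_results"]["spatial"] = {
                "rois": len(roi), "samples": int(roi["sample_id"].nunique()),
            }
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        _write_manifest()
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    _write_manifest()
    return outdir


# ---------------------------------------------------------------------------
# demo fixture


def demo_sim_config(seed: int = 0) -> synthetic.SimConfig:
    """Small atlas: 600 cells, 2000 genes, 3 donors, 4 clusters, planted
    gain/loss segments in the tumor cluster, one 10-gene LR circuit."""
    n_genes = 2000

    def gname(i: int) -> str:
        return f"G{i:04d}"

    marker_blocks = {
        "stromal": range(1000, 1015),
        "tumor": range(1050, 1065),
        "iCAF": range(1100, 1115),
        "immune": range(1150, 1165),
    }
    ligands = [gname(i) for i in range(1500, 1510)]
    receptors = [gname(i) for i in range(1600, 1610)]
    clusters = [
        synthetic.ClusterSpec("stromal", 60,
                              {gname(i): 2.0 for i in marker_blocks["stromal"]},
                              lineage="stromal"),
        synthetic.ClusterSpec("tumor", 60,
                              {gname(i): 2.0 for i in marker_blocks["tumor"]},
                              lineage="keratinocyte"),
        synthetic.ClusterSpec("iCAF", 40,
                              {gname(i): 2.0 for i in marker_blocks["iCAF"]},
                              lineage="stromal"),
        synthetic.ClusterSpec("immune", 40,
                              {gname(i): 2.0 for i in marker_blocks["immune"]},
                              lineage="immune"),
    ]
    circuits = [
        synthetic.LRCircuit("iCAF", "immune", l, r, 2.5)
        for l, r in zip(ligands, receptors)
    ]
    return synthetic.SimConfig(
        n_donors=3,
        clusters=clusters,
        n_genes=n_genes,
        n_chromosomes=4,
        cnv_segments=[
            synthetic.CNVSegment("chr1", 100, 300, 1.5),
            synthetic.CNVSegment("chr2", 100, 300, 0.5),
        ],
        malignant_cluster="tumor",
        lr_circuits=circuits,
        seed=seed,
    )


def demo_lr_database(config: synthetic.SimConfig, seed: int = 0) -> pd.DataFrame:
    """Planted circuit pairs plus random background pairs over other genes."""
    rng = np.random.default_rng([seed, 9_417])
    planted = [(c.ligand_gene, c.receptor_gene) for c in config.lr_circuits]
    planted_genes = {g for pair in planted for g in pair}
    # background universes drawn from genes with no planted signal and no
    # CNV segment (chr4 tail), so cluster signatures stay clean of them
    candidates = [f"G{i:04d}" for i in range(1700, 2000)
                  if f"G{i:04d}" not in planted_genes]
    picks = rng.choice(len(candidates), size=160, replace=False)
    bg_ligands = [candidates[i] for i in picks[:80]]
    bg_receptors = [candidates[i] for i in picks[80:]]
    rows = [{"ligand": l, "receptor": r, "source": "planted"} for l, r in planted]
    seen = set(planted)
    while len(rows) < len(planted) + 200:
        l = bg_ligands[int(rng.integers(len(bg_ligands)))]
        r = bg_receptors[int(rng.integers(len(bg_receptors)))]
        if (l, r) not in seen:
            seen.add((l, r))
            rows.append({"ligand": l, "receptor": r, "source": "background"})
    return pd.DataFrame(rows)


def demo_roi_config() -> dict:
    return {
        "n_samples_per_class": 8,
        "class_rates": {
            "nodular BCC": {"totalCAF": 150.0, "iCAF": 30.0, "mCAF": 40.0},
            "infiltrative BCC": {"totalCAF": 300.0, "iCAF": 80.0, "mCAF": 90.0},
        },
        "exclusion_beta": -0.5,
        "noise_sd": 0.15,
        "areas": (0.2, 0.6),
        "n_rois_per_sample": 6,
    }


def make_demo(seed: int, outdir: str | Path, n_perm: int = 2000) -> Path:
    """Write the bundled synthetic fixture plus a ready-to-run config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = demo_sim_config(seed)
    matrix, truth = synthetic.generate_atlas(sim)
    io_mod.write_fixture(matrix, outdir / "fixture", fmt="mtx")

    db = demo_lr_database(sim, seed=seed)
    db.to_csv(outdir / "lrdb.csv", index=False)

    roi_cfg = demo_roi_config()
    roi, _ = synthetic.generate_roi_table(seed=seed, **roi_cfg)
    roi.to_csv(outdir / "rois.csv", index=False)

    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    truth.markers.to_csv(truth_dir / "markers.tsv", sep="\t", index=False)
    truth.lr_circuits.to_csv(truth_dir / "lr_circuits.tsv", sep="\t", index=False)
    truth.cnv_segments.to_csv(truth_dir / "cnv_segments.tsv", sep="\t", index=False)
    truth.is_malignant.rename("is_malignant").to_csv(
        truth_dir / "malignant_cells.tsv", sep="\t")

    cfg = {
        "seed": seed,
        "stages": list(ALL_STAGES),
        "paths": {"matrix_dir": "fixture", "lrdb": "lrdb.csv", "roi": "rois.csv"},
        "cnv": {"reference_cluster": "stromal", "lineage": "keratinocyte"},
        "rl": {"n_perm": n_perm},
        "spatial": {
            "compare": [["nodular BCC", "infiltrative BCC"]],
            "cutoffs": {"totalCAF": 140.0, "mCAF": 40.0, "iCAF": 40.0},
        },
    }
    with open(outdir / "demo.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return outdir
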