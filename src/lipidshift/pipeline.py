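"""End-to-end orchestration: clean -> selection scan -> conservation /
pocket -> swap / mutational scan, driven by one declarative config.

Every run emits a manifest recording the tool version, a config
snapshot, input checksums, seeds, and each stage's parameters, so a
deterministic run can be reproduced byte-identically from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import affinity as aff
from .alignment import (
    clean_codon_alignment,
    percent_identity,
    read_alignment,
    translate,
    write_alignment,
)
from .codon_model import build_f3x4
from .likelihood import PruningEngine, read_tree
from .pocket import cavity_volume
from .site_models import (
    benjamini_hochberg,
    classify_selected_sites,
    fit_m0,
    fit_site_model,
    lrt,
    neb_site_posteriors,
)
from .slac import fitch_ancestral, slac_site_scan
from .structure import read_structure

DEFAULTS = {
    "seed": 0,
    "models": ["M7", "M8"],
    "k_categories": 10,
    "n_starts": 5,
    "posterior_cut": 0.9,       # NEB posterior threshold
    "p_cut": 0.1,               # counting-test p threshold
    "probe_radius": 0.75,       # angstrom
    "grid_spacing": 0.5,
    "temperature": 298.15,      # kelvin
    "swap_threshold": 1.0,
    "exo_ligand": "DDM",
    "gap_policy": "exclude_gap_columns",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    tool_version: str
    config: dict
    input_checksums: dict[str, str]
    seeds: dict[str, int]
    stage_parameters: dict[str, dict]
    outputs: dict[str, str]
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "tool_version": self.tool_version,
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                    "seeds": self.seeds,
                    "stage_parameters": self.stage_parameters,
                    "outputs": self.outputs,
                    "stages_run": self.stages_run,
                    "stages_skipped": self.stages_skipped,
                },
                fh,
                sort_keys=True,
            )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _tool_version() -> str:
    try:
        return pkg_version("lipidshift")
    except PackageNotFoundError:
        return "unknown"


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULTS)
    merged.update(cfg)
    return merged


def run_pipeline(config: str | Path | dict) -> RunManifest:
    """Run the configured stages in dependency order.

    Stages with missing inputs are skipped and noted in the manifest;
    a failing stage aborts the run with a :class:`StageError` naming the
    stage, and downstream stages are not run.
    """
    cfg = load_config(config)
    out_dir = Path(cfg.get("output_dir", "lipidshift_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=_tool_version(),
        config=cfg,
        input_checksums={},
        seeds={"master": int(cfg["seed"])},
        stage_parameters={},
        outputs={},
    )
    for key in ("alignment", "tree", "dg_table", "dg_table_mutant"):
        if cfg.get(key):
            manifest.input_checksums[key] = _sha256(cfg[key])
    for p in cfg.get("structures", []) or []:
        manifest.input_checksums[str(p)] = _sha256(p)

    site_table_rows: list[dict] = []

    # ---- selection stage -------------------------------------------------
    if cfg.get("alignment") and cfg.get("tree"):
        try:
            aln = read_alignment(cfg["alignment"], kind="nucleotide")
            tree = read_tree(cfg["tree"])
            cleaned, log = clean_codon_alignment(aln)
            log.write(out_dir / "removed_columns.tsv")
            write_alignment(cleaned, out_dir / "cleaned_alignment.fasta")
            prot = translate(cleaned)
            identity = percent_identity(prot, cfg["gap_policy"])
            pi = build_f3x4(cleaned)
            engine = PruningEngine(cleaned, tree)
            m0 = fit_m0(cleaned, tree, pi=pi, engine=engine)
            fits = {"M0": m0}
            for model_id in cfg["models"]:
                fits[model_id] = fit_site_model(
                    cleaned, tree, model_id,
                    k_categories=int(cfg["k_categories"]),
                    n_starts=int(cfg["n_starts"]),
                    seed=int(cfg["seed"]),
                    pi=pi, engine=engine, m0=m0,
                )
            lrts = {}
            for null_id, alt_id in (("M7", "M8"), ("M1", "M2")):
                if null_id in fits and alt_id in fits:
                    lrts[f"{null_id}_vs_{alt_id}"] = lrt(
                        fits[null_id], fits[alt_id]
                    )
            pos_fit = fits.get("M8") or fits.get("M2")
            neb = (
                neb_site_posteriors(pos_fit, cleaned, tree, pi=pi,
                                    engine=engine)
                if pos_fit is not None
                else []
            )
            ancestors = fitch_ancestral(cleaned, tree)
            slac = slac_site_scan(cleaned, tree, ancestors,
                                  kappa=m0.kappa)
            selected = (
                classify_selected_sites(
                    neb, slac,
                    posterior_cut=float(cfg["posterior_cut"]),
                    p_cut=float(cfg["p_cut"]),
                )
                if neb
                else set()
            )
            pvals = np.array(
                [r.p_value if r.p_value is not None else 1.0 for r in slac]
            )
            qvals = benjamini_hochberg(pvals)
            for r_neb, r_slac, q in zip(neb, slac, qvals):
                site_table_rows.append(
                    {
                        "site": r_slac.site,
                        "posterior": (
                            "" if not neb else f"{r_neb.posterior_pos:.4f}"
                        ),
                        "dn": "" if r_slac.dn is None else f"{r_slac.dn:.4f}",
                        "ds": "" if r_slac.ds is None else f"{r_slac.ds:.4f}",
                        "p": (
                            "" if r_slac.p_value is None
                            else f"{r_slac.p_value:.4g}"
                        ),
                        "q": f"{q:.4g}",
                        "selected": int(r_slac.site in selected),
                    }
                )
            site_path = out_dir / "site_scan.tsv"
            with open(site_path, "w") as fh:
                cols = ["site", "posterior", "dn", "ds", "p", "q",
                        "selected"]
                fh.write("\t".join(cols) + "\n")
                for row in site_table_rows:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
            fit_meta = {
                "percent_identity": identity,
                "fits": {
                    mid: {
                        "lnL": f.lnL,
                        "params": f.params,
                        "kappa": f.kappa,
                        "branch_scale": f.branch_scale,
                        "converged": f.converged,
                        "n_starts": f.n_starts,
                    }
                    for mid, f in fits.items()
                },
                "lrt": {
                    k: {"statistic": v.statistic, "df": v.df,
                        "p_value": v.p_value}
                    for k, v in lrts.items()
                },
                "selected_sites": sorted(selected),
                "seed": int(cfg["seed"]),
            }
            meta_path = out_dir / "selection_fits.json"
            meta_path.write_text(json.dumps(fit_meta, indent=2))
            manifest.outputs["site_scan"] = str(site_path)
            manifest.outputs["selection_fits"] = str(meta_path)
            manifest.outputs["cleaned_alignment"] = str(
                out_dir / "cleaned_alignment.fasta"
            )
            manifest.stage_parameters["selection"] = {
                "models": list(cfg["models"]),
                "k_categories": int(cfg["k_categories"]),
                "posterior_cut": float(cfg["posterior_cut"]),
                "p_cut": float(cfg["p_cut"]),
                "gap_policy": cfg["gap_policy"],
            }
            manifest.stages_run.append("selection")
        except Exception as exc:  # noqa: BLE001
            raise StageError("selection", exc) from exc
    else:
        manifest.stages_skipped.append("selection")

    # ---- pocket stage ----------------------------------------------------
    structures = cfg.get("structures") or []
    if structures:
        try:
            rows = []
            for spath in structures:
                model = read_structure(spath)
                res = cavity_volume(
                    model,
                    probe_radius=float(cfg["probe_radius"]),
                    spacing=float(cfg["grid_spacing"]),
                    count_portals=True,
                )
                rows.append(
                    (model.label, res.volume, res.n_cavity_voxels,
                     res.portal_count, res.grid_spacing, res.probe_radius)
                )
            pocket_path = out_dir / "pocket_volumes.tsv"
            with open(pocket_path, "w") as fh:
                fh.write(
                    "model\tvolume_A3\tn_voxels\tportals\tspacing\tprobe\n"
                )
                for row in rows:
                    fh.write("\t".join(str(x) for x in row) + "\n")
            manifest.outputs["pocket_volumes"] = str(pocket_path)
            manifest.stage_parameters["pocket"] = {
                "probe_radius": float(cfg["probe_radius"]),
                "grid_spacing": float(cfg["grid_spacing"]),
            }
            manifest.stages_run.append("pocket")
        except Exception as exc:  # noqa: BLE001
            raise StageError("pocket", exc) from exc
    else:
        manifest.stages_skipped.append("pocket")

    # ---- affinity stage --------------------------------------------------
    if cfg.get("dg_table"):
        try:
            records = aff.read_dg_table(cfg["dg_table"])
            by_receptor: dict[str, list] = {}
            for r in records:
                by_receptor.setdefault(r.receptor, []).append(r)
            calls = {
                rec: aff.swap_feasibility(
                    rs, cfg["exo_ligand"],
                    threshold=float(cfg["swap_threshold"]),
                    temperature=float(cfg["temperature"]),
                )
                for rec, rs in by_receptor.items()
            }
            swap_path = out_dir / "swap_calls.csv"
            with open(swap_path, "w") as fh:
                fh.write(
                    "receptor,best_endogenous,best_endogenous_kd,"
                    "exogenous,exogenous_kd,fold,verdict,threshold,"
                    "temperature\n"
                )
                for rec in sorted(calls):
                    c = calls[rec]
                    fh.write(
                        f"{c.receptor},{c.best_endogenous},"
                        f"{c.best_endogenous_kd!r},{c.exogenous},"
                        f"{c.exogenous_kd!r},{c.fold!r},{c.verdict},"
                        f"{c.threshold},{c.temperature}\n"
                    )
            manifest.outputs["swap_calls"] = str(swap_path)
            if cfg.get("dg_table_mutant"):
                mut_records = aff.read_dg_table(cfg["dg_table_mutant"])
                comparison = aff.mutational_scan(
                    records, mut_records,
                    exo_ligand=cfg["exo_ligand"],
                    threshold=float(cfg["swap_threshold"]),
                    temperature=float(cfg["temperature"]),
                )
                scan_path = out_dir / "mutational_scan.txt"
                with open(scan_path, "w") as fh:
                    fh.write(comparison.summary() + "\n")
                    for ch in comparison.changes:
                        fh.write(
                            f"{ch.ligand}\t{ch.ligand_class}\t"
                            f"{ch.kd_wt!r}\t{ch.kd_mut!r}\t{ch.fold!r}\t"
                            f"{ch.direction}\n"
                        )
                manifest.outputs["mutational_scan"] = str(scan_path)
            manifest.stage_parameters["affinity"] = {
                "temperature": float(cfg["temperature"]),
                "swap_threshold": float(cfg["swap_threshold"]),
                "exo_ligand": cfg["exo_ligand"],
            }
            manifest.stages_run.append("affinity")
        except Exception as exc:  # noqa: BLE001
            raise StageError("affinity", exc) from exc
    else:
        manifest.stages_skipped.append("affinity")

    manifest_path = out_dir / "manifest.yaml"
    manifest.write(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest
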