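"""One-shot reproducible pipeline: simulate/load → build → metrics → stats
→ classify → report.

A single YAML config drives the run; every intermediate artifact, a log
and a manifest (package version, config hash, seed) are written into the
run directory, so re-running an identical config reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .atlas import attach_wholebrain_indices, build_wm_node_set, load_default_lookup, read_lookup
from .builder import build_multiscale
from .classify import classify, render_summary
from .io import read_connectome, read_covariates, read_volumes, write_connectome
from .metrics import compute_metric_table
from .simulate import SimConfig, generate_cohort
from .stats import run_group_analysis

__all__ = ["run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a YAML mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    if "out_dir" not in cfg:
        raise PipelineError("config must set out_dir")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise PipelineError("config needs a 'simulate' or an 'inputs' section")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("connectome_dir", "covariates", "volumes"):
            if key not in inputs:
                raise PipelineError(f"inputs section missing {key!r}")


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures abort with the failing stage named; artifacts written
    before the failure are retained.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    _validate_config(cfg)
    run_dir = Path(cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("wmnet").addHandler(handler)
    stage = "setup"
    try:
        hierarchy = build_wm_node_set()
        lookup_path = cfg.get("inputs", {}).get("lookup")
        lookup = read_lookup(lookup_path) if lookup_path else load_default_lookup()
        hierarchy = attach_wholebrain_indices(hierarchy, lookup)

        stage = "simulate" if "simulate" in cfg else "load"
        if "simulate" in cfg:
            sim_cfg = SimConfig(**(cfg["simulate"] or {}))
            connectomes, covariates, volumes = generate_cohort(sim_cfg, hierarchy)
            covariates.to_csv(run_dir / "covariates.tsv", sep="\t", index=False)
            volumes.to_csv(run_dir / "volumes.tsv", sep="\t", index=False)
            (run_dir / "sim_config.json").write_text(json.dumps(asdict(sim_cfg), indent=2))
        else:
            inputs = cfg["inputs"]
            covariates = read_covariates(inputs["covariates"])
            volumes = read_volumes(inputs["volumes"])
            conn_dir = Path(inputs["connectome_dir"])
            connectomes = [
                read_connectome(p, 379, subject_id=p.stem)
                for p in sorted(conn_dir.glob("*.csv"))
            ]
            if not connectomes:
                raise PipelineError(f"no *.csv matrices found in {conn_dir}")

        stage = "build"
        norm = (cfg.get("build") or {}).get("norm", "sum")
        write_mats = (cfg.get("build") or {}).get("write_matrices", False)
        fine, coarse = [], []
        mat_dir = run_dir / "matrices"
        for c in connectomes:
            f, co = build_multiscale(c, volumes, hierarchy, norm=norm)
            fine.append(f)
            coarse.append(co)
            if write_mats:
                mat_dir.mkdir(exist_ok=True)
                write_connectome(f, mat_dir / f"{c.subject_id}_fine76.csv")
                write_connectome(co, mat_dir / f"{c.subject_id}_coarse24.csv")

        stage = "metrics"
        m_cfg = cfg.get("metrics") or {}
        mt_fine = compute_metric_table(
            fine, hierarchy, "fine76", partition=m_cfg.get("fine_partition")
        )
        mt_coarse = compute_metric_table(
            coarse, hierarchy, "coarse24", partition=m_cfg.get("coarse_partition")
        )
        mt_fine.data.to_csv(run_dir / "metrics_fine76.tsv", sep="\t", index=False)
        mt_coarse.data.to_csv(run_dir / "metrics_coarse24.tsv", sep="\t", index=False)

        stage = "stats"
        s_cfg = cfg.get("stats") or {}
        kw = {
            "alpha": s_cfg.get("alpha", 0.05),
            "robust": s_cfg.get("robust", "HC3"),
            "family": s_cfg.get("family", "per-metric-scale"),
        }
        res_fine = run_group_analysis(mt_fine, covariates, **kw)
        res_coarse = run_group_analysis(mt_coarse, covariates, **kw)
        res_fine.to_csv(run_dir / "results_fine76.tsv", sep="\t", index=False)
        res_coarse.to_csv(run_dir / "results_coarse24.tsv", sep="\t", index=False)

        stage = "classify"
        c_cfg = cfg.get("classify") or {}
        report = classify(
            res_fine, res_coarse, hierarchy,
            pool_hemispheres=c_cfg.get("pool_hemispheres", True),
        )
        report.to_csv(run_dir / "crossscale_report.tsv", sep="\t", index=False)

        stage = "report"
        plot = run_dir / "summary_grid.png" if c_cfg.get("plot", False) else None
        grid = render_summary(report, plot_path=plot)
        grid.to_csv(run_dir / "summary_grid.tsv", sep="\t")

        manifest = {
            "tool": "wmnet",
            "version": __version__,
            "config_hash": _config_hash(cfg),
            "config": cfg,
            "n_subjects": len(connectomes),
            "seed": cfg.get("simulate", {}).get("seed") if "simulate" in cfg else None,
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as e:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {e}") from e
    finally:
        logging.getLogger("wmnet").removeHandler(handler)
        handler.close()
    return run_dir
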