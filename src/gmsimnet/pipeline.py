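"""Orchestration: simulate -> extract -> metrics -> compare, with provenance.

A single YAML/dict config drives the whole run; every stage draws its seed
deterministically from the master seed by hashing the stage name, so adding
a stage never shifts another stage's random stream.  The run manifest lists
every output file with a SHA-256 digest; re-running the same config
reproduces identical digests for all deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import aggregate_to_rois, compute_global_metrics, compute_nodal_metrics
from .simnet import extract_cube_network
from .stats import (
    adjusted_association,
    ancova_group_effect,
    demographics_tests,
    posthoc_pairwise,
)
from .synthetic import SimulationConfig, simulate_cohort
from .volume_io import read_atlas, read_volume, smooth_gaussian, validate_pair

__all__ = ["run_pipeline", "load_config", "validate_config", "stage_seed"]

log = logging.getLogger("gmsimnet")

_TOP_KEYS = {"seed", "out_dir", "simulate", "inputs", "extract", "metrics",
             "compare", "write_volumes"}
_SIM_KEYS = set(SimulationConfig.__dataclass_fields__) - {"seed"}
_EXTRACT_KEYS = {"alpha", "n_perm", "fwhm_mm"}
_METRICS_KEYS = {"small_world", "n_null"}
_COMPARE_KEYS = {"covariates", "fdr", "outcomes"}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed by hashing the stage name into the master seed."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    text = Path(path_or_dict).read_text()
    return yaml.safe_load(text) or {}


def validate_config(config: dict) -> list[str]:
    """Collect every schema violation; empty list means the config is valid."""
    errors = []
    for k in config:
        if k not in _TOP_KEYS:
            errors.append(f"unknown top-level key: {k!r}")
    if "seed" in config and not isinstance(config["seed"], int):
        errors.append("seed must be an integer")
    if "out_dir" not in config:
        errors.append("missing required key: out_dir")
    has_sim = "simulate" in config
    has_inputs = "inputs" in config
    if not has_sim and not has_inputs:
        errors.append("config must provide either a 'simulate' or an 'inputs' section")
    if has_sim:
        for k in config["simulate"] or {}:
            if k not in _SIM_KEYS:
                errors.append(f"unknown simulate key: {k!r}")
    if has_inputs:
        inp = config["inputs"] or {}
        for req in ("atlas", "cohort"):
            if req not in inp:
                errors.append(f"inputs section missing {req!r} path")
        for key in ("atlas", "cohort"):
            if key in inp and not Path(inp[key]).exists():
                errors.append(f"inputs.{key} does not exist: {inp[key]}")
        vols = inp.get("volumes", {})
        if not vols:
            errors.append("inputs section missing 'volumes' (subject_id -> path)")
        else:
            for sid, p in vols.items():
                if not Path(p).exists():
                    errors.append(f"inputs.volumes[{sid!r}] does not exist: {p}")
    for section, allowed in (("extract", _EXTRACT_KEYS),
                             ("metrics", _METRICS_KEYS),
                             ("compare", _COMPARE_KEYS)):
        for k in config.get(section) or {}:
            if k not in allowed:
                errors.append(f"unknown {section} key: {k!r}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    Raises before any stage runs if the config is invalid; a failure inside
    a stage is re-raised with the stage name, after writing a partial
    manifest.
    """
    config = load_config(config)
    errors = validate_config(config)
    if errors:
        raise ValueError(
            "invalid pipeline config:\n  - " + "\n  - ".join(errors)
        )
    master_seed = int(config.get("seed", 0))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "gmsimnet",
        "version": __version__,
        "config": config,
        "master_seed": master_seed,
        "stage_seeds": {},
        "stages": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path = out / "manifest.json"

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    def finish_stage(stage: str, t0: float, seed: int | None) -> None:
        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3), "seed": seed}
        log.info("stage=%s seed=%s elapsed=%.2fs", stage, seed, elapsed)

    current_stage = "simulate"
    try:
        # ---- stage 1: simulate (or load) ------------------------------
        t0 = time.perf_counter()
        if "simulate" in config:
            seed = stage_seed(master_seed, "simulate")
            manifest["stage_seeds"]["simulate"] = seed
            sim_cfg = SimulationConfig(**(config["simulate"] or {}), seed=seed)
            sim = simulate_cohort(sim_cfg, out_dir=out if config.get("write_volumes")
                                  else None)
            atlas, volumes, cohort = sim["atlas"], sim["volumes"], sim["table"]
            cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
            record(out / "cohort.tsv")
            if config.get("write_volumes"):
                for sid in sim["paths"]:
                    record(Path(sim["paths"][sid]))
                record(out / "atlas.nii.gz")
                record(out / "ground_truth.json")
        else:
            inp = config["inputs"]
            atlas = read_atlas(inp["atlas"])
            cohort = pd.read_csv(inp["cohort"], sep="\t")
            volumes = {sid: read_volume(p) for sid, p in inp["volumes"].items()}
        finish_stage("simulate", t0, manifest["stage_seeds"].get("simulate"))

        # ---- stage 2: extract -----------------------------------------
        current_stage = "extract"
        t0 = time.perf_counter()
        ex = config.get("extract") or {}
        alpha = float(ex.get("alpha", 0.05))
        n_perm = int(ex.get("n_perm", 200))
        fwhm = ex.get("fwhm_mm")
        seed = stage_seed(master_seed, "extract")
        manifest["stage_seeds"]["extract"] = seed
        networks, parcs = {}, {}
        for k, (sid, vol) in enumerate(sorted(volumes.items())):
            if fwhm:
                vol = smooth_gaussian(vol, float(fwhm))
            validate_pair(vol, atlas)
            parc, _sim, net = extract_cube_network(
                vol, atlas, alpha=alpha, n_perm=n_perm,
                seed=(seed + k) % (2**31),
            )
            networks[sid], parcs[sid] = net, parc
        finish_stage("extract", t0, seed)

        # ---- stage 3: metrics -----------------------------------------
        current_stage = "metrics"
        t0 = time.perf_counter()
        me = config.get("metrics") or {}
        seed = stage_seed(master_seed, "metrics")
        manifest["stage_seeds"]["metrics"] = seed
        subject_rows, roi_rows = [], []
        for sid in sorted(networks):
            net, parc = networks[sid], parcs[sid]
            nodal = compute_nodal_metrics(net)
            glob = compute_global_metrics(
                net,
                include_small_world=bool(me.get("small_world", False)),
                n_null=int(me.get("n_null", 100)),
                seed=seed,
            )
            roi_tab = aggregate_to_rois(nodal, parc, atlas.n_rois)
            roi_tab = roi_tab.reset_index()
            roi_tab.insert(0, "subject_id", sid)
            roi_rows.append(roi_tab)
            row = {"subject_id": sid, **glob,
                   "mean_degree": float(nodal["degree_centrality"].mean()),
                   "mean_betweenness": float(
                       nodal["betweenness_centrality"].mean())}
            subject_rows.append(row)
        subject_metrics = pd.DataFrame(subject_rows)
        roi_metrics = pd.concat(roi_rows, ignore_index=True)
        subject_metrics.to_csv(out / "metrics.tsv", sep="\t", index=False,
                               float_format="%.10g")
        roi_metrics.to_csv(out / "roi_metrics.tsv", sep="\t", index=False,
                           float_format="%.10g")
        record(out / "metrics.tsv")
        record(out / "roi_metrics.tsv")
        finish_stage("metrics", t0, seed)

        # ---- stage 4: compare -----------------------------------------
        current_stage = "compare"
        t0 = time.perf_counter()
        cp = config.get("compare") or {}
        covariates = tuple(cp.get("covariates", ["age", "sex", "education"]))
        fdr_q = float(cp.get("fdr", 0.05))
        merged = cohort.merge(subject_metrics, on="subject_id")
        metric_cols = ["mean_degree", "global_efficiency", "local_efficiency",
                       "mean_betweenness", "density"]
        demo = demographics_tests(merged)
        anc = ancova_group_effect(merged, metric_cols, covariates, q=fdr_q)
        sig = list(anc.loc[anc["significant"], "term"])
        post = posthoc_pairwise(merged, sig, covariates) if sig else pd.DataFrame()
        outcomes = cp.get("outcomes", ["score_cog", "csf_ttau"])
        assoc_rows = []
        for outcome in outcomes:
            if outcome not in merged.columns:
                continue
            for m in metric_cols:
                try:
                    assoc_rows.append(
                        adjusted_association(merged, m, outcome, covariates)
                    )
                except ValueError:
                    pass  # no stratum with enough complete cases
        assoc = (pd.concat(assoc_rows, ignore_index=True)
                 if assoc_rows else pd.DataFrame())
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False,
                    float_format="%.10g")
        anc.to_csv(out / "group_stats.tsv", sep="\t", index=False,
                   float_format="%.10g")
        post.to_csv(out / "posthoc.tsv", sep="\t", index=False,
                    float_format="%.10g")
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False,
                     float_format="%.10g")
        for f in ("demographics.tsv", "group_stats.tsv", "posthoc.tsv",
                  "associations.tsv"):
            record(out / f)
        finish_stage("compare", t0, seed=None)
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
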