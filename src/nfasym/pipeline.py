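"""End-to-end orchestration: simulate -> feedback -> EEG -> GLM -> network -> psych.

A single config dict (usually loaded from YAML) drives every stage; all
randomness flows from ``seeds.master``.  Outputs are TSV/JSON tables plus a
manifest recording the config hash, so a re-run with an identical config can
reuse the completed output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from . import eeg as eeg_mod
from . import glm as glm_mod
from . import synth
from .feedback import run_closed_loop
from .paradigm import build_schedule, write_events
from .stats import psych_report

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "config_hash"]

log = logging.getLogger("nfasym.pipeline")

DEFAULT_CONFIG: dict = {
    "paradigm": {
        "n_runs": 10,
        "rest_s": 20.0,
        "view_s": 40.0,
        "up_s": 60.0,
        "buffer_s": 10.0,
        "tr": 2.0,
        "eeg_rate": 250.0,
    },
    "cohort": {
        "n_experimental": 18,
        "n_control": 14,
        "asym_effect": 0.3,
        "bold_noise_sd": 0.5,
        "with_eeg": True,
    },
    "analysis": {
        "voxel_p": 0.01,
        "cluster_p": 0.01,
        "q": 0.05,
        "band": [8.0, 12.0],
        "voxel_stage": False,
        "n_perm": 200,
    },
    "seeds": {"master": 0},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def validate_config(config: dict | None) -> dict:
    """Merge onto defaults and validate; raises listing offending fields."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    bad = []
    for key in ("voxel_p", "cluster_p", "q"):
        val = cfg["analysis"][key]
        if not (0.0 < val < 1.0):
            bad.append(f"analysis.{key}={val} not in (0, 1)")
    band = cfg["analysis"]["band"]
    if not (len(band) == 2 and 0 < band[0] < band[1]):
        bad.append(f"analysis.band={band} invalid")
    for key in ("n_experimental", "n_control"):
        if cfg["cohort"][key] < 1:
            bad.append(f"cohort.{key} must be >= 1")
    if bad:
        raise ConfigError("invalid config: " + "; ".join(bad))
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def _stage(name):
    log.info("stage start: %s", name)


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    Returns the manifest.  If the output directory already contains a
    manifest for the identical config, the cached results are reused.
    """
    cfg = validate_config(config)
    digest = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == digest and old.get("status") == "complete":
            log.info("cache hit (%s); reusing %s", digest, out)
            return old

    try:
        schedule = build_schedule(**cfg["paradigm"])
    except Exception as exc:
        raise RuntimeError(f"stage 'paradigm' failed: {exc}") from exc
    write_events(schedule, out / "events.tsv")

    _stage("simulate")
    master = int(cfg["seeds"]["master"])
    band = tuple(cfg["analysis"]["band"])
    spec = synth.CohortSpec(
        n_experimental=cfg["cohort"]["n_experimental"],
        n_control=cfg["cohort"]["n_control"],
        schedule=schedule,
        eeg=synth.EEGSimParams(asym_effect=cfg["cohort"]["asym_effect"], alpha_band=band),
        bold_noise_sd=cfg["cohort"]["bold_noise_sd"],
        master_seed=master,
    )
    try:
        cohort = synth.generate_cohort(spec, with_eeg=cfg["cohort"]["with_eeg"])
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    q = cfg["analysis"]["q"]

    if cfg["cohort"]["with_eeg"]:
        _stage("feedback")
        try:
            traces = []
            for sub in cohort["subjects"]:
                mode = "real" if sub["group"] == "experimental" else "sham"
                trace = run_closed_loop(
                    sub["eeg"], schedule, mode=mode, seed=sub["seed_eeg"], band=band
                )
                rec = trace.records.copy()
                rec.insert(0, "subject", sub["subject"])
                rec.insert(1, "mode", trace.mode)
                traces.append(rec)
            pd.concat(traces, ignore_index=True).to_csv(
                out / "feedback_traces.tsv", sep="\t", index=False
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'feedback' failed: {exc}") from exc

        _stage("eeg")
        try:
            table = eeg_mod.block_asymmetry_table(
                (
                    (s["subject"], s["group"], s["eeg"])
                    for s in cohort["subjects"]
                ),
                schedule,
                band=band,
            )
            table.to_csv(out / "block_asymmetry.tsv", sep="\t", index=False)
            stats_report = eeg_mod.asymmetry_group_stats(table, q=q)
            stats_report.to_csv(out / "asymmetry_stats.tsv", sep="\t", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'eeg' failed: {exc}") from exc

    _stage("roi-psc")
    try:
        psc_rows = []
        for sub in cohort["subjects"]:
            frame = sub["roi_bold"].frame
            for roi in frame.columns:
                psc_uv, psc_ur = glm_mod.psc_from_series(
                    frame[roi].to_numpy(), schedule
                )
                psc_rows.append(
                    {
                        "roi": roi,
                        "subject": sub["subject"],
                        "group": sub["group"],
                        "psc": psc_uv,
                        "psc_up_vs_rest": psc_ur,
                    }
                )
        psc_table = pd.DataFrame(psc_rows)
        psc_table.to_csv(out / "roi_psc.tsv", sep="\t", index=False)
        effects = glm_mod.roi_effect_sizes(psc_table, q=q)
        effects.to_csv(out / "roi_effects.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'roi-psc' failed: {exc}") from exc

    if cfg["analysis"]["voxel_stage"]:
        _stage("voxel-glm")
        try:
            rng = np.random.default_rng(master + 1)
            coords = np.array(
                [[4 + i, 4 + j, 2 + k] for i in range(3) for j in range(3) for k in range(3)]
            )
            vol = synth.simulate_voxel_bold(
                (16, 16, 8), [(coords, 2.0)], schedule, noise_sd=1.0,
                seed=int(rng.integers(2**31)),
            )
            design = glm_mod.build_design(schedule)
            clusters, labels = glm_mod.cluster_correct(
                vol, design, {"Upregulation": 1.0, "Rest": -1.0},
                voxel_p=cfg["analysis"]["voxel_p"],
                cluster_p=cfg["analysis"]["cluster_p"],
                n_perm=cfg["analysis"]["n_perm"], seed=master + 2,
            )
            pd.DataFrame(
                [
                    {"cluster_id": c.cluster_id, "size": c.size, "p_corrected": c.p_corrected}
                    for c in clusters
                ]
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'voxel-glm' failed: {exc}") from exc

    _stage("connectivity")
    try:
        block_corr = conn_mod.cohort_block_correlations(
            ((s["subject"], s["group"], s["roi_bold"]) for s in cohort["subjects"]),
            schedule,
        )
        edge_stats = conn_mod.edge_condition_tests(block_corr, q=q)
        edge_stats.to_csv(out / "edge_stats.tsv", sep="\t", index=False)
        network = conn_mod.differential_network(edge_stats, q=q)
        network.to_json(out / "network.json")
        network.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        if not network.edges.empty:
            dist = conn_mod.connectivity_distributions(block_corr, network.edges)
            with open(out / "connectivity_distributions.json", "w") as fh:
                json.dump(dist, fh, indent=2, default=float)
    except Exception as exc:
        raise RuntimeError(f"stage 'connectivity' failed: {exc}") from exc

    _stage("psych")
    try:
        cohort["scores"].to_csv(out / "scores.tsv", sep="\t", index=False)
        report = psych_report(cohort["scores"], q=q)
        report.to_csv(out / "psych_report.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'psych' failed: {exc}") from exc

    manifest = {
        "config": cfg,
        "config_hash": digest,
        "seeds": cohort["manifest"]["subject_seeds"],
        "status": "complete",
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %s", out)
    return manifest
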