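"""End-to-end orchestration: simulate -> preprocess -> connect -> metrics -> stats.

Every stage is a pure function of (inputs, config, seed) and writes its
outputs under the run directory:

    recordings/   raw synthetic recordings (binary container + yaml sidecar)
    flags/        flagged artifact/spike intervals per subject (TSV)
    segments/     clean broadband analysis windows (binary container)
    networks/     thresholded edge lists per subject x band (TSV)
    fc_table.tsv  regional FC statistic per subject x band
    metrics.tsv   graph metrics per subject x band
    report.json   group comparisons + ROC discrimination
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .bands import BAND_BY_NAME, DEFAULT_BANDS
from .connectivity import effective_sample_size, pairwise_correlation, threshold_network
from .graph_metrics import compute_metrics, metrics_table
from .group_analysis import (
    GT_PARAMETERS,
    compare_bands,
    correction_count,
    regional_fc,
    roc_table,
)
from .preprocessing import bandpass, detect_artifacts, flag_spikes, notch_filter, select_clean_segment
from .synthetic_meg import (
    DEFAULT_GROUPS,
    SimulationConfig,
    default_roles,
    generate_cohort,
)

__all__ = [
    "DEFAULT_CONFIG",
    "MissingStageError",
    "load_config",
    "study_config",
    "demo_config",
    "run_simulate",
    "run_preprocess",
    "run_connect",
    "run_metrics",
    "run_stats",
    "run_all",
]

log = logging.getLogger("megnet")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {
        "n_nodes": 12,
        "n_frontal": 4,
        "n_pcc": 4,
        "fs": 2000.0,
        "duration": 31.0,
        "noise_sd": 0.5,
        "subject_rho_sd": 0.05,
        "rho": 0.6,
        "impaired_multiplier": 0.4,
        "affected": [
            ["frontal", "frontal", "beta"],
            ["pcc", "pcc", "ripple"],
            ["pcc", "pcc", "fast_ripple"],
        ],
        "n_per_group": {"impaired": 17, "non_impaired": 18, "control": 18},
        "spike_rate_per_min": 0.0,
        "spike_amplitude_pt": 7.0,
    },
    "preprocessing": {
        "notch_hz": 50.0,
        "artifact_threshold_pt": 6.0,
        "spike_z": 6.0,
        "segment_s": 30.0,
    },
    "connectivity": {"alpha": 0.01, "k_policy": "bartlett"},
    "gt": {"edge_policy": "positive", "normalized_strength": True},
    "stats": {
        "fc_regions": ["frontal", "pcc"],
        "groups": list(DEFAULT_GROUPS),
        "n_bands": 7,
        "n_groups": 3,
    },
}


class MissingStageError(RuntimeError):
    """An upstream stage's outputs are missing; the message names the stage."""


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML pipeline config, merged over the packaged defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _clique_edges(roles: list[str], role: str, bands, rho: float):
    idx = [i for i, r in enumerate(roles) if r == role]
    return [(i, j, b.name, rho) for k, i in enumerate(idx) for j in idx[k + 1 :] for b in bands]


def study_config(cfg: dict) -> SimulationConfig:
    """Build the ground-truth SimulationConfig from a pipeline config dict.

    Plants full cliques of correlated edges (rho) among the frontal nodes
    and among the PCC nodes in every band; the impaired group's coupling is
    scaled by ``impaired_multiplier`` on the (role-pair, band) combinations
    listed under ``affected``.
    """
    sim = cfg["simulation"]
    roles = default_roles(sim["n_nodes"], sim["n_frontal"], sim["n_pcc"])
    bands = [b for b in DEFAULT_BANDS if b.hi <= sim["fs"] / 2]
    planted = _clique_edges(roles, "frontal", bands, sim["rho"]) + _clique_edges(roles, "pcc", bands, sim["rho"])
    effects = {
        "impaired": {tuple(key): sim["impaired_multiplier"] for key in map(tuple, sim["affected"])}
    }
    return SimulationConfig(
        n_nodes=sim["n_nodes"],
        node_roles=roles,
        fs=float(sim["fs"]),
        duration=float(sim["duration"]),
        bands=bands,
        planted_edges=planted,
        group_effects=effects,
        noise_sd=float(sim["noise_sd"]),
        subject_rho_sd=float(sim["subject_rho_sd"]),
        seed=int(cfg["seed"]),
    )


def demo_config() -> dict:
    """Small configuration for a fast end-to-end smoke run."""
    return load_config(
        overrides={
            "simulation": {
                "n_nodes": 20,
                "duration": 16.0,
                "n_per_group": {"impaired": 4, "non_impaired": 4, "control": 4},
            },
            "preprocessing": {"segment_s": 15.0},
        }
    )


def analyze_cohort(
    cfg: dict,
    cohort: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory simulate+preprocess+connect+metrics for one cohort.

    Returns the (fc_table, metrics_table) DataFrames the disk stages would
    produce. ``cohort`` may be a pre-generated list of (recording, group)
    pairs; otherwise the cohort is generated from the config.
    """
    from .preprocessing import CleanSegment

    sim_cfg = study_config(cfg)
    if cohort is None:
        cohort = generate_cohort(sim_cfg, cfg["simulation"]["n_per_group"])
    pp = cfg["preprocessing"]
    alpha = float(cfg["connectivity"]["alpha"])
    k_policy = cfg["connectivity"]["k_policy"]
    regions = cfg["stats"]["fc_regions"]
    gt = cfg["gt"]
    fc_rows, results = [], []
    for idx, (rec, group) in enumerate(cohort):
        sid = f"sub{idx:03d}"
        rec = notch_filter(rec, freq=float(pp["notch_hz"]))
        flags = detect_artifacts(rec, threshold=float(pp["artifact_threshold_pt"]))
        flags += flag_spikes(rec, z_thresh=float(pp["spike_z"]))
        seg = select_clean_segment(rec, flags, length_s=float(pp["segment_s"]))
        for band in sim_cfg.bands:
            seg_b = bandpass(
                CleanSegment(seg.data, seg.fs, "broadband", seg.start_s, seg.node_labels), band
            )
            cm = pairwise_correlation(seg_b)
            cm.node_roles = list(rec.node_roles)
            if k_policy == "bartlett":
                cm.K_eff = effective_sample_size(seg_b)
            net = threshold_network(cm, alpha=alpha, k_policy=k_policy)
            row = {"subject_id": sid, "group": group, "band": band.name}
            for region in regions:
                row[f"{region}_fc"] = regional_fc(net, region)
            fc_rows.append(row)
            res = compute_metrics(
                net, subject_id=sid, edge_policy=gt["edge_policy"],
                normalized_strength=bool(gt["normalized_strength"]),
            )
            res.band = band.name
            results.append((res, group))
    return pd.DataFrame(fc_rows), metrics_table(results)


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.tsv"


def _require(path: Path, stage: str) -> None:
    if not path.exists():
        raise MissingStageError(f"missing output {path.name}: run the '{stage}' stage first")


def run_simulate(cfg: dict, outdir: str | Path) -> pd.DataFrame:
    """Generate the synthetic cohort and write recordings + manifest."""
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    sim_cfg = study_config(cfg)
    log.info("simulate: seed=%s fs=%s duration=%ss nodes=%s", cfg["seed"], sim_cfg.fs, sim_cfg.duration, sim_cfg.n_nodes)
    cohort = generate_cohort(sim_cfg, cfg["simulation"]["n_per_group"])
    rows = []
    for idx, (rec, group) in enumerate(cohort):
        rate = float(cfg["simulation"].get("spike_rate_per_min", 0.0))
        if rate > 0:
            from .synthetic_meg import inject_spikes

            rec = inject_spikes(rec, rate, float(cfg["simulation"]["spike_amplitude_pt"]), seed=cfg["seed"] * 1000 + idx)
        sid = f"sub{idx:03d}"
        io.write_recording_binary(rec, outdir / "recordings" / sid)
        rows.append({"subject_id": sid, "group": group})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(_manifest_path(outdir), sep="\t", index=False)
    return manifest


def run_preprocess(cfg: dict, outdir: str | Path) -> None:
    """Notch, flag artifacts/spikes, and select the clean analysis window."""
    outdir = Path(outdir)
    _require(_manifest_path(outdir), "simulate")
    (outdir / "segments").mkdir(exist_ok=True)
    (outdir / "flags").mkdir(exist_ok=True)
    pp = cfg["preprocessing"]
    manifest = pd.read_csv(_manifest_path(outdir), sep="\t")
    for sid in manifest["subject_id"]:
        rec = io.read_recording_binary(outdir / "recordings" / sid)
        rec = notch_filter(rec, freq=float(pp["notch_hz"]))
        flags = detect_artifacts(rec, threshold=float(pp["artifact_threshold_pt"]))
        flags += flag_spikes(rec, z_thresh=float(pp["spike_z"]))
        io.write_flags(flags, outdir / "flags" / f"{sid}.tsv")
        seg = select_clean_segment(rec, flags, length_s=float(pp["segment_s"]))
        seg_rec = replace(rec, data=seg.data)
        io.write_recording_binary(seg_rec, outdir / "segments" / sid)
        log.info("preprocess %s: %d flags, segment start %.2fs", sid, len(flags), seg.start_s)


def run_connect(cfg: dict, outdir: str | Path) -> pd.DataFrame:
    """Band-pass each clean segment and build thresholded networks per band."""
    outdir = Path(outdir)
    _require(_manifest_path(outdir), "simulate")
    if not (outdir / "segments").exists():
        raise MissingStageError("missing output segments/: run the 'preprocess' stage first")
    (outdir / "networks").mkdir(exist_ok=True)
    manifest = pd.read_csv(_manifest_path(outdir), sep="\t")
    alpha = float(cfg["connectivity"]["alpha"])
    k_policy = cfg["connectivity"]["k_policy"]
    regions = cfg["stats"]["fc_regions"]
    bands = [b for b in DEFAULT_BANDS if b.hi <= cfg["simulation"]["fs"] / 2]
    rows = []
    for sid, group in zip(manifest["subject_id"], manifest["group"]):
        seg_rec = io.read_recording_binary(outdir / "segments" / sid)
        from .preprocessing import CleanSegment

        for band in bands:
            seg = CleanSegment(
                data=seg_rec.data, fs=seg_rec.fs, band="broadband", start_s=0.0, node_labels=seg_rec.node_labels
            )
            seg = bandpass(seg, band)
            cm = pairwise_correlation(seg)
            cm.node_roles = list(seg_rec.node_roles)
            if k_policy == "bartlett":
                cm.K_eff = effective_sample_size(seg)
            net = threshold_network(cm, alpha=alpha, k_policy=k_policy)
            io.write_network(net, outdir / "networks" / f"{sid}_{band.name}.tsv")
            row = {"subject_id": sid, "group": group, "band": band.name}
            for region in regions:
                row[f"{region}_fc"] = regional_fc(net, region)
            rows.append(row)
        log.info("connect %s: %d bands", sid, len(bands))
    fc = pd.DataFrame(rows)
    fc.to_csv(outdir / "fc_table.tsv", sep="\t", index=False)
    return fc


def run_metrics(cfg: dict, outdir: str | Path) -> pd.DataFrame:
    """Graph metrics for every stored subject x band network."""
    outdir = Path(outdir)
    _require(_manifest_path(outdir), "simulate")
    if not (outdir / "networks").exists():
        raise MissingStageError("missing output networks/: run the 'connect' stage first")
    manifest = pd.read_csv(_manifest_path(outdir), sep="\t")
    gt = cfg["gt"]
    bands = [b for b in DEFAULT_BANDS if b.hi <= cfg["simulation"]["fs"] / 2]
    results = []
    for sid, group in zip(manifest["subject_id"], manifest["group"]):
        for band in bands:
            net = io.read_network(outdir / "networks" / f"{sid}_{band.name}.tsv")
            res = compute_metrics(
                net,
                subject_id=sid,
                edge_policy=gt["edge_policy"],
                normalized_strength=bool(gt["normalized_strength"]),
            )
            res.band = band.name
            results.append((res, group))
    table = metrics_table(results)
    io.write_metrics(table, outdir / "metrics.tsv")
    return table


def run_stats(cfg: dict, outdir: str | Path) -> dict:
    """Band-wise group comparisons (Bonferroni) and ROC discrimination."""
    outdir = Path(outdir)
    for name, stage in (("fc_table.tsv", "connect"), ("metrics.tsv", "metrics")):
        _require(outdir / name, stage)
    st = cfg["stats"]
    fc = pd.read_csv(outdir / "fc_table.tsv", sep="\t")
    gt = pd.read_csv(outdir / "metrics.tsv", sep="\t")
    group_order = tuple(st["groups"])
    m_fc = correction_count(st["n_groups"], st["n_bands"])
    m_gt = correction_count(st["n_groups"], st["n_bands"], len(GT_PARAMETERS))
    fc_params = tuple(f"{r}_fc" for r in st["fc_regions"])
    fc_results = compare_bands(fc, fc_params, m=m_fc, group_order=group_order, gate_warnings=False)
    gt_results = compare_bands(gt, GT_PARAMETERS, m=m_gt, group_order=group_order, gate_warnings=False)

    # discriminate impaired vs non-impaired patients with GT parameters that
    # differ between them after correction
    patients = gt[gt["group"].isin(group_order[:2])]
    labels = (patients.drop_duplicates("subject_id").set_index("subject_id")["group"] == group_order[0]).astype(int)
    predictors = {}
    for res in gt_results:
        key = f"{res.band}_{res.parameter}"
        ab = f"{group_order[0]}_vs_{group_order[1]}"
        if res.p_bonferroni < 0.05 and res.pairwise_p.get(ab, 1.0) < 0.05:
            wide = patients[patients["band"] == res.band].set_index("subject_id")[res.parameter]
            predictors[key] = wide.loc[labels.index].to_numpy()
    roc = roc_table(predictors, labels.to_numpy()) if predictors else pd.DataFrame()

    def _cmp_dict(r):
        return {
            "band": r.band,
            "parameter": r.parameter,
            "F": r.F,
            "p_raw": r.p_raw,
            "p_bonferroni": r.p_bonferroni,
            "group_means": r.group_means,
            "pairwise_p": r.pairwise_p,
        }

    report = {
        "version": __version__,
        "seed": cfg["seed"],
        "thresholds": {
            "alpha": cfg["connectivity"]["alpha"],
            "artifact_threshold_pt": cfg["preprocessing"]["artifact_threshold_pt"],
            "segment_s": cfg["preprocessing"]["segment_s"],
            "bonferroni_fc": m_fc,
            "bonferroni_gt": m_gt,
        },
        "fc_comparisons": [_cmp_dict(r) for r in fc_results],
        "gt_comparisons": [_cmp_dict(r) for r in gt_results],
        "roc": roc.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame([_cmp_dict(r) for r in fc_results]).to_csv(outdir / "fc_comparisons.tsv", sep="\t", index=False)
    pd.DataFrame([_cmp_dict(r) for r in gt_results]).to_csv(outdir / "gt_comparisons.tsv", sep="\t", index=False)
    if len(roc):
        roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    log.info("stats: %d FC + %d GT comparisons, %d ROC predictors", len(fc_results), len(gt_results), len(roc))
    return report


def run_all(cfg: dict, outdir: str | Path) -> dict:
    """Run every stage in order and return the final report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_simulate(cfg, outdir)
    run_preprocess(cfg, outdir)
    run_connect(cfg, outdir)
    run_metrics(cfg, outdir)
    return run_stats(cfg, outdir)
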