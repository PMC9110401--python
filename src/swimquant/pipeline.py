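"""End-to-end runs from config files: simulate -> analyze -> stats -> report.

Every run writes a manifest (config, seed, config hash, package version)
next to its outputs; deterministic stages are byte-identical across reruns
of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, fluor, metrics, pattern
from .scenarios import (
    Scenario,
    default_cell_field_specs,
    default_fluor_scenarios,
    default_swim_scenarios,
)
from .schedule import SessionSpec, make_light_schedule, make_visuomotor_schedule
from .simulate import render_trace_image, simulate_cell_field, simulate_fluorescence_traces, simulate_swim_session
from .stats import anova_multi_comparisons, summarize_groups, two_group_test
from .targets import TARGETS, compute_target

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "validate_targets", "DEFAULT_CONFIG"]

ALL_ANALYSES = ("simulate", "metrics", "pattern", "visuomotor", "calcium", "cells", "stats")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "assay": "24-well",
    "session": {"duration_h": 72, "bin_s": 600},
    "groups": {"wt": 12, "mutant": 12},
    "analyses": ["metrics", "stats"],
    "calcium": {"region": "diencephalon", "n_rois": 12, "control_group": "sibling"},
    "cells": {"n_images": 10},
    "thresholds": {
        "outer_binarize": 9.0,
        "center_low": 100.0,
        "center_high": 550.0,
        "speed_cm_s": 0.5,
        "dff": 0.2,
        "alpha": 0.05,
    },
}


class RunConfig:
    """Validated run configuration (see ``DEFAULT_CONFIG`` for the schema)."""

    def __init__(self, data: dict):
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for k, v in data.items():
            if isinstance(v, dict) and isinstance(merged.get(k), dict):
                merged[k].update(v)
            else:
                merged[k] = v
        unknown = set(merged.get("analyses", [])) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        self.data = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]

    def session_spec(self, visuomotor: bool = False) -> SessionSpec:
        s = self.data["session"]
        if visuomotor:
            return SessionSpec(duration_s=6 * 3600, bin_s=60,
                               plate_format=self.data["assay"])
        return SessionSpec(
            duration_s=float(s["duration_h"]) * 3600,
            bin_s=float(s["bin_s"]),
            plate_format=self.data["assay"],
        )

    def swim_scenarios(self) -> dict[str, Scenario]:
        table = default_swim_scenarios()[self.data["assay"]]
        missing = set(self.data["groups"]) - set(table)
        if missing:
            raise ValueError(f"no scenario for group(s): {sorted(missing)}")
        return {g: table[g] for g in self.data["groups"]}

    def pattern_config(self) -> pattern.PatternConfig:
        t = self.data["thresholds"]
        return pattern.PatternConfig(
            outer_binarize_threshold=t["outer_binarize"],
            center_low_threshold=t["center_low"],
            center_high_threshold=t["center_high"],
        )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as Newick text."""
    from scipy.cluster.hierarchy import to_tree

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(to_tree(z)) + ";"


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except Exception as exc:  # re-raise with stage provenance
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _run_simulate(cfg: RunConfig, outdir: Path, with_traj: bool):
    spec = cfg.session_spec()
    schedule = make_light_schedule(spec)
    traj_bins = None
    if with_traj:
        b = schedule.bins
        mask = b["day_label"].isin(["d2", "d3"]) & (b["light_state"] == "light")
        traj_bins = b.loc[mask, "bin_index"].to_numpy()
    trajs, table = simulate_swim_session(
        cfg.swim_scenarios(), spec, dict(cfg.data["groups"]), seed=cfg.seed,
        with_trajectories=with_traj, trajectory_bins=traj_bins,
    )
    _write_csv(table, outdir / "tracking.csv")
    logger.info("tracking table: %d rows, %d fish", len(table), table["fish_id"].nunique())
    return spec, schedule, trajs, table


@_stage("metrics")
def _run_metrics(cfg: RunConfig, outdir: Path, table: pd.DataFrame) -> pd.DataFrame:
    pf = metrics.per_fish_metrics(metrics.select_period(table))
    _write_csv(pf, outdir / "fish_metrics.csv")
    groups = {g: s["daytime_distance"].to_numpy() for g, s in pf.groupby("group_label")}
    _write_csv(summarize_groups(groups), outdir / "group_summary_distance.csv")
    return pf


@_stage("pattern")
def _run_pattern(cfg: RunConfig, outdir: Path, trajs, spec: SessionSpec, table):
    pcfg = cfg.pattern_config()
    fish_groups = dict(zip(table["fish_id"], table["group_label"], strict=False))
    rows = []
    for (fish_id, b_idx), traj in sorted(trajs.items()):
        img = render_trace_image(traj, image_px=99, well_size_cm=spec.well_size_cm)
        rec = pattern.score_image(img, fish_id=fish_id, bin_index=b_idx, cfg=pcfg)
        rows.append({
            "fish_id": fish_id, "group_label": fish_groups[fish_id],
            "bin_index": b_idx, "perimeter_score": rec["perimeter_score"],
            "center_value": rec["center_value"], "center_class": rec["center_class"],
        })
    scores = pd.DataFrame(rows)
    _write_csv(scores, outdir / "pattern_scores.csv")

    mat = scores.pivot_table(index="fish_id", columns="bin_index",
                             values="perimeter_score", fill_value=0)
    mat.to_csv(outdir / "perimeter_score_matrix.csv")
    if len(mat) >= 2:
        z, order = pattern.cluster_score_matrix(mat.to_numpy())
        (outdir / "perimeter_dendrogram.nwk").write_text(
            _linkage_to_newick(z, list(mat.index)) + "\n"
        )
        _heatmap(mat.to_numpy()[order], outdir / "perimeter_heatmap.png")
    fr = pattern.daytime_pattern_fractions(scores)
    _write_csv(fr, outdir / "pattern_fractions.csv")
    return scores


def _heatmap(matrix: np.ndarray, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        logger.warning("matplotlib unavailable; skipping heatmap image")
        return
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(matrix, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("daytime bin")
    ax.set_ylabel("fish (clustered order)")
    fig.colorbar(im, ax=ax, label="perimeter score")
    fig.savefig(path, dpi=100)
    plt.close(fig)


@_stage("visuomotor")
def _run_visuomotor(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    spec = cfg.session_spec(visuomotor=True)
    schedule = make_visuomotor_schedule()
    _, table = simulate_swim_session(
        cfg.swim_scenarios(), spec, dict(cfg.data["groups"]),
        seed=cfg.seed + 1, schedule=schedule,
    )
    resp = metrics.visuomotor_response(table, schedule)
    _write_csv(resp, outdir / "visuomotor_response.csv")
    return resp


@_stage("calcium")
def _run_calcium(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    c = cfg.data["calcium"]
    scns = default_fluor_scenarios()[c["region"]]
    traces = []
    for i, (group, fscn) in enumerate(scns.items()):
        traces += simulate_fluorescence_traces(
            fscn, c["n_rois"], seed=cfg.seed + 10 + i, group_label=group,
            roi_prefix=f"{group}-roi",
        )
    long = pd.concat(
        [
            pd.DataFrame({
                "roi_id": tr.roi_id, "region": tr.region, "group": tr.group_label,
                "t_s": np.arange(len(tr.values)) / tr.rate_hz, "F": tr.values,
            })
            for tr in traces
        ],
        ignore_index=True,
    )
    _write_csv(long, outdir / "fluor_traces.csv")

    levels = fluor.relative_fluorescence_level(traces, control_group=c["control_group"])
    tcfg = fluor.TransientConfig(threshold=cfg.data["thresholds"]["dff"])
    levels["n_transients"] = [
        fluor.count_transients(fluor.compute_dff(tr), tcfg) for tr in traces
    ]
    _write_csv(levels, outdir / "fluor_levels.csv")
    return levels


@_stage("cells")
def _run_cells(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for j, (name, cfs) in enumerate(default_cell_field_specs().items()):
        thr = cfs.cell_intensity / 2.0
        for i in range(int(cfg.data["cells"]["n_images"])):
            img, truth = simulate_cell_field(cfs, seed=cfg.seed + 1000 + 101 * j + i)
            rows.append({
                "condition": name, "image_index": i,
                "count": fluor.quantify_objects(img, cfs.roi, "count", thr),
                "area_px": fluor.quantify_objects(img, cfs.roi, "area", thr),
                "true_count": truth["count"], "true_area_px": truth["area_px"],
            })
    df = pd.DataFrame(rows)
    _write_csv(df, outdir / "cell_quantification.csv")
    return df


@_stage("stats")
def _run_stats(cfg: RunConfig, outdir: Path, pf: pd.DataFrame) -> pd.DataFrame:
    alpha = cfg.data["thresholds"]["alpha"]
    groups = {g: s["daytime_activity"].to_numpy() for g, s in pf.groupby("group_label")}
    results = []
    if len(groups) >= 3:
        results = anova_multi_comparisons(groups, design="one-way", alpha=alpha)
    elif len(groups) == 2:
        (g1, a), (g2, b) = groups.items()
        results = [two_group_test(a, b, label=f"{g1} vs {g2}")]
    df = pd.DataFrame([vars(r) for r in results])
    _write_csv(df, outdir / "stat_tests.csv")
    return df


def run_experiment(cfg: RunConfig | dict, outdir: str | Path) -> dict:
    """Execute the configured analyses; returns the manifest dict."""
    if not isinstance(cfg, RunConfig):
        cfg = RunConfig(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analyses = list(cfg.data["analyses"])

    manifest = {
        "config": cfg.data,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "swimquant_version": __version__,
        "outputs": [],
    }

    pf = None
    if {"simulate", "metrics", "pattern", "stats"} & set(analyses):
        spec, schedule, trajs, table = _run_simulate(cfg, outdir, "pattern" in analyses)
        if "metrics" in analyses or "stats" in analyses:
            pf = _run_metrics(cfg, outdir, table)
        if "pattern" in analyses:
            _run_pattern(cfg, outdir, trajs, spec, table)
    if "visuomotor" in analyses:
        _run_visuomotor(cfg, outdir)
    if "calcium" in analyses:
        _run_calcium(cfg, outdir)
    if "cells" in analyses:
        _run_cells(cfg, outdir)
    if "stats" in analyses and pf is not None:
        _run_stats(cfg, outdir, pf)

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_targets(seed: int = 1, target_ids: list[str] | None = None) -> pd.DataFrame:
    """Recompute each recovery target and report observed vs expected.

    Failures are rows with ``passed == False``, not exceptions.
    """
    rows = []
    for tid in target_ids or list(TARGETS):
        spec = TARGETS[tid]
        res = compute_target(tid, seed)
        err = abs(res["value"] - spec.expected)
        rows.append({
            "target": tid,
            "description": spec.description,
            "observed": res["value"],
            "expected": spec.expected,
            "tolerance": spec.tolerance,
            "units": spec.units,
            "n": res["n"],
            "passed": bool(err <= max(spec.tolerance, 1e-12)),
        })
    return pd.DataFrame(rows)
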