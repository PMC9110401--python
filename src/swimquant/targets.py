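"""End-to-end recovery targets computed from the shipped scenarios.

Each target runs the full generate -> analyze path at a fixed, desk-scale
problem size and returns the recovered quantity.  Expected values come from
the generative calibration (e.g. the mutant bout rate is 0.635x the
sibling's, so the recovered median-activity reduction should be ~36.5 %);
tolerances are three analytic Monte-Carlo standard errors at the simulated
sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import fluor, metrics, pattern
from .scenarios import default_cell_field_specs, default_fluor_scenarios, default_swim_scenarios
from .schedule import SessionSpec, make_light_schedule
from .simulate import (
    make_pattern_trajectory,
    render_trace_image,
    simulate_cell_field,
    simulate_fluorescence_traces,
    simulate_swim_session,
)

__all__ = ["TargetSpec", "TARGETS", "compute_target", "compute_all_targets"]

TRACK_SPEC_96 = SessionSpec(duration_s=72 * 3600, bin_s=600, plate_format="96-well")
TRACK_SPEC_24 = SessionSpec(duration_s=72 * 3600, bin_s=600, plate_format="24-well")


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 100_003 + offset) % (2**31 - 1))


def _daytime_bin_indices(spec: SessionSpec) -> np.ndarray:
    sched = make_light_schedule(spec)
    b = sched.bins
    mask = b["day_label"].isin(["d2", "d3"]) & (b["light_state"] == "light")
    return b.loc[mask, "bin_index"].to_numpy()


def _session_median_activity(scenarios, ns, spec, seed) -> dict[str, float]:
    _, table = simulate_swim_session(scenarios, spec, ns, seed=seed)
    sel = metrics.select_period(table)
    pf = metrics.per_fish_metrics(sel)
    return pf.groupby("group_label")["daytime_activity"].median().to_dict()


def perimeter_score_full_lap(seed: int) -> tuple[float, int]:
    """Render one full-perimeter-lap trajectory and grid-score it (t4)."""
    traj = make_pattern_trajectory("full-lap", seed, well_size_cm=1.55, circular=True)
    img = render_trace_image(traj, image_px=99, well_size_cm=1.55)
    score = pattern.perimeter_score(pattern.grid_pixel_values(img))
    return float(score), 1


def activity_reduction_96well(
    seed: int, mutant_key: str, n_sib: int, n_mut: int, n_sessions: int
) -> tuple[float, int]:
    """Average per-session percent reduction of median daytime activity (t5/t6)."""
    scn = default_swim_scenarios()["96-well"]
    pair = {"sibling": scn["sibling"], mutant_key: scn[mutant_key]}
    refs, tests = [], []
    for k in range(n_sessions):
        med = _session_median_activity(
            pair, {"sibling": n_sib, mutant_key: n_mut}, TRACK_SPEC_96, seed + k
        )
        refs.append(med["sibling"])
        tests.append(med[mutant_key])
    return metrics.percent_reduction(refs, tests), n_sessions * (n_sib + n_mut)


def full_perimeter_fraction_reduction(
    seed: int, n_per_group: int = 24, n_sessions: int = 3
) -> tuple[float, int]:
    """Percent reduction in mutant full-perimeter daytime fraction (t7).

    Simulates 24-well daytime (d2-d3 light) bins, renders a trace image per
    fish per bin, grid-scores it, and compares per-fish full-lap fractions.
    """
    scn = default_swim_scenarios()["24-well"]
    pair = {"wt": scn["wt"], "mutant": scn["mutant"]}
    day_bins = _daytime_bin_indices(TRACK_SPEC_24)
    refs, tests = [], []
    for k in range(n_sessions):
        trajs, table = simulate_swim_session(
            pair, TRACK_SPEC_24, n_per_group, seed=seed + k,
            with_trajectories=True, trajectory_bins=day_bins,
        )
        fish_groups = dict(zip(table["fish_id"], table["group_label"], strict=False))
        rows = []
        for (fish_id, b_idx), traj in trajs.items():
            img = render_trace_image(traj, image_px=99, well_size_cm=1.55)
            rec = pattern.score_image(img, fish_id=fish_id, bin_index=b_idx)
            rows.append({
                "fish_id": fish_id,
                "group_label": fish_groups[fish_id],
                "perimeter_score": rec["perimeter_score"],
                "center_class": rec["center_class"],
            })
        fr = pattern.daytime_pattern_fractions(pd.DataFrame(rows))
        gm = fr.groupby("group_label")["frac_full"].mean()
        refs.append(float(gm["wt"]))
        tests.append(float(gm["mutant"]))
    return metrics.percent_reduction(refs, tests), n_sessions * 2 * n_per_group


def daytime_distance_24well(
    seed: int, group: str, n: int = 24, n_sessions: int = 3
) -> tuple[float, int]:
    """Group mean of per-fish mean daytime distance per 10-min bin (t8/t9)."""
    scn = default_swim_scenarios()["24-well"]
    vals = []
    for k in range(n_sessions):
        _, table = simulate_swim_session(
            {group: scn[group]}, TRACK_SPEC_24, n, seed=seed + k
        )
        pf = metrics.per_fish_metrics(metrics.select_period(table))
        vals.append(float(pf["daytime_distance"].mean()))
    return float(np.mean(vals)), n_sessions * n


def diencephalic_fold_change(seed: int, n_rois: int = 30) -> tuple[float, int]:
    """Sibling:mutant baseline-fluorescence fold ratio, diencephalon (t10)."""
    fscn = default_fluor_scenarios()["diencephalon"]
    traces = simulate_fluorescence_traces(
        fscn["sibling"], n_rois, seed=_derive_seed(seed, 1), group_label="sibling"
    ) + simulate_fluorescence_traces(
        fscn["mutant"], n_rois, seed=_derive_seed(seed, 2), group_label="mutant"
    )
    levels = fluor.relative_fluorescence_level(traces, control_group="sibling")
    return fluor.group_fold_change(levels, "sibling", "mutant"), 2 * n_rois


def neutrophil_area_reduction(seed: int, n_images: int = 20) -> tuple[float, int]:
    """Percent reduction in supra-threshold ROI area, morphant vs control (t11)."""
    specs = default_cell_field_specs()
    areas: dict[str, list[float]] = {"control": [], "morphant": []}
    for j, (name, cfs) in enumerate(specs.items()):
        thr = cfs.cell_intensity / 2.0
        for i in range(n_images):
            img, _ = simulate_cell_field(cfs, seed=_derive_seed(seed, 100 * (j + 1) + i))
            areas[name].append(fluor.quantify_objects(img, cfs.roi, "area", thr))
    return (
        metrics.percent_reduction(np.mean(areas["control"]), np.mean(areas["morphant"])),
        2 * n_images,
    )


@dataclass(frozen=True)
class TargetSpec:
    target_id: str
    description: str
    expected: float
    tolerance: float  # 3 analytic Monte-Carlo SE (0 = exact)
    units: str
    compute: Callable[[int], tuple[float, int]]


TARGETS: dict[str, TargetSpec] = {
    t.target_id: t
    for t in [
        TargetSpec(
            "t4", "perimeter score of a full-perimeter-lap trace image",
            expected=8.0, tolerance=0.0, units="score",
            compute=perimeter_score_full_lap,
        ),
        TargetSpec(
            "t5", "avg median daytime-activity reduction, mutant vs sibling (96-well)",
            expected=36.5, tolerance=13.6, units="%",
            compute=lambda s: activity_reduction_96well(s, "mutant", 24, 12, 3),
        ),
        TargetSpec(
            "t6", "avg median daytime-activity reduction, microglia-less vs sibling",
            expected=14.0, tolerance=18.4, units="%",
            compute=lambda s: activity_reduction_96well(s, "microglia-less", 24, 24, 2),
        ),
        TargetSpec(
            "t7", "reduction in full-perimeter daytime fraction, mutant vs wt (24-well)",
            expected=30.0, tolerance=4.0, units="%",
            compute=full_perimeter_fraction_reduction,
        ),
        TargetSpec(
            "t8", "mean daytime distance per 10-min bin, 24-well mutant",
            expected=15.5, tolerance=1.6, units="cm per 10 min",
            compute=lambda s: daytime_distance_24well(s, "mutant"),
        ),
        TargetSpec(
            "t9", "mean daytime distance per 10-min bin, 24-well wild-type",
            expected=35.6, tolerance=3.6, units="cm per 10 min",
            compute=lambda s: daytime_distance_24well(s, "wt"),
        ),
        TargetSpec(
            "t10", "sibling:mutant diencephalic baseline-fluorescence fold ratio",
            expected=4.0, tolerance=0.63, units="fold",
            compute=diencephalic_fold_change,
        ),
        TargetSpec(
            "t11", "percent reduction in neutrophil ROI area, morphant vs control",
            expected=90.0, tolerance=4.1, units="%",
            compute=neutrophil_area_reduction,
        ),
    ]
}


def compute_target(target_id: str, seed: int) -> dict:
    spec = TARGETS[target_id]
    value, n = spec.compute(seed)
    return {"value": float(value), "n": int(n)}


def compute_all_targets(seed: int) -> dict[str, dict]:
    return {tid: compute_target(tid, seed) for tid in TARGETS}
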