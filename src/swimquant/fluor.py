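"""Fluorescence quantification: dF/F0, transient calling, relative levels,
fold changes, and ROI object counts/areas.

F0 is the mean of the trace, so dF/F0 has zero mean by construction and is
used for event detection; baseline-level group comparisons instead use each
ROI's mean raw fluorescence normalized to the control group's mean (the
average relative change from a trace-mean baseline is identically ~0 and
cannot carry level information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import FluorTrace

__all__ = [
    "DffTrace",
    "TransientConfig",
    "compute_dff",
    "count_transients",
    "relative_fluorescence_level",
    "group_fold_change",
    "quantify_objects",
]


@dataclass
class DffTrace:
    """dF/F0 series of one ROI, with the baseline it was computed from."""

    roi_id: str
    f0: float
    dff: np.ndarray

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        self.dff = np.asarray(self.dff, dtype=float)


@dataclass(frozen=True)
class TransientConfig:
    """Spike-calling parameters.

    ``threshold`` is the dF/F0 level defining a supra-threshold timepoint
    (region-specific in practice; 0.2 by default).  Two supra-threshold runs
    separated by fewer than ``min_gap_timepoints`` sub-threshold samples
    merge into one event.
    """

    threshold: float = 0.2
    min_gap_timepoints: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_gap_timepoints < 1:
            raise ValueError("min_gap_timepoints must be >= 1")


def compute_dff(trace: FluorTrace) -> DffTrace:
    """dF/F0 with F0 = mean fluorescence over all timepoints."""
    f0 = float(np.mean(trace.values))
    if f0 <= 0:
        raise ValueError("trace mean must be positive")
    return DffTrace(roi_id=trace.roi_id, f0=f0, dff=(trace.values - f0) / f0)


def count_transients(dff: DffTrace | np.ndarray, cfg: TransientConfig | None = None) -> int:
    """Number of discrete supra-threshold events in a dF/F0 series.

    An event is a maximal run of samples above threshold; runs separated by
    at least ``min_gap_timepoints`` sub-threshold samples count separately,
    closer runs merge.
    """
    cfg = cfg or TransientConfig()
    x = dff.dff if isinstance(dff, DffTrace) else np.asarray(dff, dtype=float)
    above = x > cfg.threshold
    n_events = 0
    gap = cfg.min_gap_timepoints  # sub-threshold samples seen since last event
    in_event = False
    for a in above:
        if a:
            if not in_event and gap >= cfg.min_gap_timepoints:
                n_events += 1
            in_event = True
            gap = 0
        else:
            in_event = False
            gap += 1
    return n_events


def relative_fluorescence_level(
    traces: list[FluorTrace],
    control_group: str,
) -> pd.DataFrame:
    """Per-ROI mean fluorescence normalized to the region-matched control mean.

    Returns one row per ROI with ``level`` (mean raw fluorescence),
    ``relative_level`` (level / control-group mean level for the same
    region), plus region and group labels.
    """
    rows = [
        {
            "roi_id": tr.roi_id,
            "region": tr.region,
            "group_label": tr.group_label,
            "level": float(np.mean(tr.values)),
        }
        for tr in traces
    ]
    df = pd.DataFrame(rows)
    if control_group not in set(df["group_label"]):
        raise ValueError(f"control group {control_group!r} has no traces")
    ctrl = df[df["group_label"] == control_group].groupby("region")["level"].mean()
    missing = set(df["region"]) - set(ctrl.index)
    if missing:
        raise ValueError(f"no control traces for region(s): {sorted(missing)}")
    df["relative_level"] = df["level"] / df["region"].map(ctrl).to_numpy()
    return df


def group_fold_change(
    levels: pd.DataFrame,
    control_group: str,
    test_group: str,
    value_col: str = "level",
) -> float:
    """Control-group mean divided by test-group mean of ``value_col``."""
    ctrl = levels.loc[levels["group_label"] == control_group, value_col]
    test = levels.loc[levels["group_label"] == test_group, value_col]
    if ctrl.empty or test.empty:
        raise ValueError("both groups must be non-empty")
    mc, mt = float(ctrl.mean()), float(test.mean())
    if mc <= 0 or mt <= 0:
        raise ValueError("group means must be positive")
    return mc / mt


def quantify_objects(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    mode: str = "count",
    intensity_threshold: float = 100.0,
) -> float:
    """Count objects or total object area inside an ROI.

    ``count`` = number of 8-connected components of supra-threshold pixels;
    ``area`` = number of supra-threshold pixels.  ``roi`` is
    (row0, col0, row1, col1), half-open.
    """
    image = np.asarray(image)
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError("degenerate or out-of-bounds ROI")
    sub = image[r0:r1, c0:c1] > intensity_threshold
    if mode == "area":
        return float(sub.sum())
    if mode == "count":
        _, n = ndimage.label(sub, structure=np.ones((3, 3), dtype=int))
        return float(n)
    raise ValueError(f"unknown mode: {mode!r}")
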