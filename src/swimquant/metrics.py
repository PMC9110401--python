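"""Locomotor metrics from long-format tracking tables.

Daytime locomotion = mean swimming distance per 10-min bin, daytime
activity = mean bout count per bin, both averaged per fish over the selected
light periods (days 2-3 by default; day 1 is excluded as acclimation).
Mean speed = total distance / total active duration, i.e. the within-bout
speed, which is the quantity that stays constant when bout counts drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import LightSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "select_period",
    "per_fish_metrics",
    "classify_movement",
    "percent_reduction",
    "visuomotor_response",
]

DEFAULT_PERIODS = frozenset({("d2", "light"), ("d3", "light")})


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds and period selection for metric extraction.

    ``period_selector`` is a set of (day_label, light_state) pairs, or the
    string ``"all"`` to keep every bin.  ``exclude_fish`` lists fish removed
    a priori (e.g. health exclusions).
    """

    speed_threshold_cm_s: float = 0.5
    period_selector: frozenset | str = DEFAULT_PERIODS
    exclude_fish: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.speed_threshold_cm_s <= 0:
            raise ValueError("speed_threshold_cm_s must be positive")


def select_period(
    table: pd.DataFrame,
    schedule: LightSchedule | None = None,
    cfg: MetricConfig | None = None,
) -> pd.DataFrame:
    """Restrict a tracking table to the configured (day, light-state) periods.

    Raises ``ValueError`` if the selector matches no rows (e.g. a day label
    absent from the session).
    """
    cfg = cfg or MetricConfig()
    out = table
    if cfg.exclude_fish:
        out = out[~out["fish_id"].isin(cfg.exclude_fish)]
    if cfg.period_selector == "all":
        return out.copy()
    sel = {(d, s) for d, s in cfg.period_selector}
    mask = pd.Series(
        list(zip(out["day_label"], out["light_state"], strict=True)), index=out.index
    ).isin(sel)
    out = out[mask.to_numpy()]
    if out.empty:
        raise ValueError(f"period selector {sorted(sel)} matched no bins")
    return out.copy()


def per_fish_metrics(table: pd.DataFrame, cfg: MetricConfig | None = None) -> pd.DataFrame:
    """Per-fish metric averages over the rows supplied.

    Returns one row per fish: ``daytime_distance`` (cm per bin),
    ``daytime_activity`` (bouts per bin), ``mean_speed`` (cm/s, NaN with
    ``speed_defined=False`` when the fish never moved), ``n_bins``.
    Fish in the table but with zero rows after selection are simply absent
    (a warning is logged by :func:`select_period` callers).
    """
    if table.empty:
        raise ValueError("empty tracking table")
    grp = table.groupby(["fish_id", "group_label"], sort=True, observed=True)
    agg = grp.agg(
        daytime_distance=("distance_cm", "mean"),
        daytime_activity=("bout_count", "mean"),
        total_distance=("distance_cm", "sum"),
        total_active=("active_duration_s", "sum"),
        n_bins=("bin_index", "size"),
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = agg["total_distance"] / agg["total_active"]
    agg["speed_defined"] = agg["total_active"] > 0
    agg["mean_speed"] = np.where(agg["speed_defined"], speed, np.nan)
    n_undef = int((~agg["speed_defined"]).sum())
    if n_undef:
        logger.warning("%d fish with zero active duration: mean_speed undefined", n_undef)
    return agg.drop(columns=["total_distance", "total_active"])


def classify_movement(speed_cm_s: float, cfg: MetricConfig | None = None) -> str:
    """Classify a movement as ``"large"`` (speed >= threshold) or ``"small"``."""
    cfg = cfg or MetricConfig()
    if speed_cm_s < 0:
        raise ValueError("speed must be non-negative")
    return "large" if speed_cm_s >= cfg.speed_threshold_cm_s else "small"


def percent_reduction(reference, test) -> float:
    """Percent reduction of ``test`` relative to ``reference``.

    Scalars give ``100 * (reference - test) / reference``.  Sequences are
    treated as per-session pairs and the unweighted mean of the per-session
    reductions is returned (the "average median reduction" statistic when
    the inputs are group medians).
    """
    ref = np.atleast_1d(np.asarray(reference, dtype=float))
    tst = np.atleast_1d(np.asarray(test, dtype=float))
    if ref.shape != tst.shape:
        raise ValueError("reference and test must have the same length")
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    red = 100.0 * (ref - tst) / ref
    return float(red.mean())


def visuomotor_response(
    table: pd.DataFrame,
    schedule: LightSchedule,
    pre_bins: int = 3,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-fish response to every light-to-dark switch.

    For each switch: ``pre`` = mean distance over the ``pre_bins`` bins
    before the switch, ``post`` = distance in the first bin after, and
    ``response_ratio`` = post / (pre + eps).
    """
    if not schedule.transitions_s:
        raise ValueError("schedule has no light-to-dark transitions")
    recs = []
    bin_s = schedule.bin_s
    for fish_id, sub in table.groupby("fish_id", sort=True):
        sub = sub.sort_values("bin_index")
        dist = sub.set_index("bin_index")["distance_cm"]
        group = sub["group_label"].iloc[0]
        for k, t_sw in enumerate(schedule.transitions_s):
            b_sw = int(round(t_sw / bin_s))  # first dark bin
            pre_idx = range(max(b_sw - pre_bins, 0), b_sw)
            pre = float(dist.reindex(pre_idx).mean())
            post = float(dist.get(b_sw, np.nan))
            recs.append({
                "fish_id": fish_id,
                "group_label": group,
                "switch_index": k,
                "switch_time_s": t_sw,
                "pre_distance_cm": pre,
                "post_distance_cm": post,
                "response_ratio": post / (pre + eps),
            })
    return pd.DataFrame(recs)
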