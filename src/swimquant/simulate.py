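"""Synthetic-data generators for tracking tables, trace images, fluorescence
traces and labelled-cell fields.

The swim generator produces bouts as an inhomogeneous Poisson process whose
rate combines the scenario's daytime rate, night suppression, a
mean-preserving within-day decline, between-fish heterogeneity, and a
transient boost after every light-to-dark switch.  Each bout displaces the
fish by a log-normal draw; integration bins aggregate bout count, distance
and active duration exactly as a ZebraBox-style tracker would report them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk
from skimage.draw import line as _line

from .scenarios import PATTERN_MODES, CellFieldSpec, FluorScenario, Scenario
from .schedule import LightSchedule, SessionSpec, make_light_schedule

__all__ = [
    "Trajectory",
    "FluorTrace",
    "simulate_swim_session",
    "make_pattern_trajectory",
    "render_trace_image",
    "simulate_fluorescence_traces",
    "simulate_cell_field",
]

TRACKING_COLUMNS = [
    "fish_id", "group_label", "bin_index", "bin_start_s", "light_state",
    "day_label", "bout_count", "distance_cm", "active_duration_s",
]


@dataclass
class Trajectory:
    """Positions of one fish within one integration bin (well coordinates, cm)."""

    fish_id: str
    bin_index: int
    samples: np.ndarray  # (n, 3) columns t_s, x_cm, y_cm
    mode: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        t = self.samples[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass
class FluorTrace:
    """One ROI's fluorescence time series at a fixed sampling rate."""

    roi_id: str
    region: str
    group_label: str
    values: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be non-negative")


def _mean1_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Mean-one log-normal factor(s) with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _bin_rate_factors(schedule: LightSchedule, scn: Scenario) -> np.ndarray:
    """Per-bin expected bout rate (bouts/min) for an average fish.

    Light bins: day rate shaped by a mean-preserving linear decline across
    the light period (factor 1+d/2 at onset to 1-d/2 at the end, evaluated
    at the bin midpoint).  Dark bins: the rate factor decays exponentially
    from ``dark_switch_boost`` (x day rate) at the light-off switch to the
    steady night level; the factor is averaged analytically over the bin.
    """
    bins = schedule.bins
    starts = bins["bin_start_s"].to_numpy(float)
    is_light = (bins["light_state"] == "light").to_numpy()
    out = np.empty(len(bins), dtype=float)

    bounds = schedule.light_period_bounds()
    d = scn.within_day_decline
    for i, (t0, light, label) in enumerate(
        zip(starts, is_light, bins["day_label"], strict=True)
    ):
        if light:
            p0, p1 = bounds[label]
            frac = (t0 + schedule.bin_s / 2.0 - p0) / max(p1 - p0, 1e-9)
            out[i] = scn.day_bout_rate * (1.0 + d / 2.0 - d * frac)
        else:
            prev = [tr for tr in schedule.transitions_s if tr <= t0]
            if prev and scn.dark_switch_boost > scn.night_rate_multiplier:
                tau = max(scn.boost_decay_min * 60.0, 1e-9)
                a = t0 - prev[-1]
                b = a + schedule.bin_s
                decay_avg = tau * (np.exp(-a / tau) - np.exp(-b / tau)) / schedule.bin_s
                factor = scn.night_rate_multiplier + (
                    scn.dark_switch_boost - scn.night_rate_multiplier
                ) * decay_avg
            else:
                factor = scn.night_rate_multiplier
            out[i] = scn.day_bout_rate * factor
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# swim-pattern trajectory modes (unit-square well coordinates)
# ---------------------------------------------------------------------------

_PERIM_INSET = 0.05


def _perimeter_point(u: np.ndarray, circular: bool) -> np.ndarray:
    """Point(s) on the wall-hugging closed perimeter path, u in [0, 1)."""
    u = np.asarray(u, dtype=float) % 1.0
    if circular:
        r = 0.5 - _PERIM_INSET
        ang = 2 * np.pi * u
        return np.column_stack([0.5 + r * np.cos(ang), 0.5 + r * np.sin(ang)])
    lo, hi = _PERIM_INSET, 1.0 - _PERIM_INSET
    side = hi - lo
    s = u * 4.0 * side
    pts = np.empty((len(np.atleast_1d(s)), 2))
    s = np.atleast_1d(s)
    for i, si in enumerate(s):
        edge, off = int(si // side) % 4, si % side
        if edge == 0:
            pts[i] = (lo + off, lo)
        elif edge == 1:
            pts[i] = (hi, lo + off)
        elif edge == 2:
            pts[i] = (hi - off, hi)
        else:
            pts[i] = (lo, hi - off)
    return pts


def _mode_path(mode: str, rng: np.random.Generator, circular: bool) -> np.ndarray:
    """Unit-square waypoint path for one bin under the given pattern mode."""
    if mode == "quiescent":
        return rng.uniform(0.15, 0.85, size=(1, 2))

    if mode == "center-heavy":
        # dense dwell inside the central ninth of the well
        n = 60
        return 0.5 + rng.uniform(-0.12, 0.12, size=(n, 2))

    if mode == "partial":
        # back-and-forth over a contiguous arc covering ~k of 8 outer squares
        k = rng.integers(2, 7)
        u0 = rng.uniform(0, 1)
        span = k / 8.0
        us = np.linspace(u0, u0 + span, 16 * k)
        arc = _perimeter_point(us, circular)
        return np.vstack([arc, arc[::-1], arc])

    if mode == "full-lap":
        u0 = rng.uniform(0, 1)
        us = np.linspace(u0, u0 + 2.0, 257)  # two complete laps
        path = [_perimeter_point(us, circular)]
        # center transits: perimeter -> zigzag through the middle -> perimeter
        for _ in range(rng.integers(3, 5)):
            ua = rng.uniform(0, 1)
            entry = _perimeter_point(np.array([ua]), circular)
            exit_ = _perimeter_point(np.array([ua + 0.5]), circular)
            dwell = 0.5 + rng.uniform(-0.1, 0.1, size=(4, 2))
            path.extend([entry, dwell, exit_])
        return np.vstack(path)

    raise ValueError(f"unknown pattern mode: {mode!r}")


def _make_trajectory(
    fish_id: str,
    bin_index: int,
    bin_start_s: float,
    bin_s: float,
    mode: str,
    rng: np.random.Generator,
    well_size_cm: float,
    circular: bool,
) -> Trajectory:
    path = _mode_path(mode, rng, circular) * well_size_cm
    t = bin_start_s + np.linspace(0.0, bin_s, len(path), endpoint=False)
    samples = np.column_stack([t, path])
    return Trajectory(fish_id=fish_id, bin_index=bin_index, samples=samples, mode=mode)


def make_pattern_trajectory(
    mode: str,
    seed: int,
    well_size_cm: float = 1.55,
    circular: bool = True,
    fish_id: str = "fish",
    bin_index: int = 0,
    bin_s: float = 600.0,
) -> Trajectory:
    """Standalone single-bin trajectory of a given swim-pattern mode."""
    rng = np.random.default_rng(seed)
    return _make_trajectory(
        fish_id, bin_index, 0.0, bin_s, mode, rng, well_size_cm, circular
    )


# ---------------------------------------------------------------------------
# swim session
# ---------------------------------------------------------------------------

def simulate_swim_session(
    scenario_map: dict[str, Scenario],
    spec: SessionSpec,
    n_per_group: int | dict[str, int],
    seed: int,
    schedule: LightSchedule | None = None,
    with_trajectories: bool = False,
    trajectory_bins: np.ndarray | list[int] | None = None,
) -> tuple[dict[tuple[str, int], Trajectory], pd.DataFrame]:
    """Simulate one tracking session for several genotype groups.

    Parameters
    ----------
    scenario_map:
        Mapping group label -> :class:`Scenario`.
    spec:
        Session geometry/timing; the light schedule is derived from it unless
        ``schedule`` is supplied (e.g. the visuomotor program).
    n_per_group:
        Number of fish per group (int, or mapping group -> int; every key
        must name a scenario).
    seed:
        Master seed; per-fish substreams are spawned deterministically.
    with_trajectories:
        Also generate per-(fish, bin) trajectories for trace-image rendering
        (restricted to ``trajectory_bins`` when given).

    Returns
    -------
    (trajectories, tracking_table):
        ``trajectories`` maps (fish_id, bin_index) to :class:`Trajectory`
        (empty when ``with_trajectories`` is False); the tracking table is a
        long-format DataFrame with one row per fish per bin.
    """
    if schedule is None:
        schedule = make_light_schedule(spec)
    if isinstance(n_per_group, int):
        counts = {g: n_per_group for g in scenario_map}
    else:
        unknown = set(n_per_group) - set(scenario_map)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        counts = dict(n_per_group)
    if any(n < 1 for n in counts.values()):
        raise ValueError("n_per_group must be >= 1")

    traj_bins = None
    if trajectory_bins is not None:
        traj_bins = set(int(b) for b in trajectory_bins)

    bins = schedule.bins
    bin_min = schedule.bin_s / 60.0
    n_fish_total = sum(counts.values())
    children = np.random.SeedSequence(seed).spawn(n_fish_total)

    frames: list[pd.DataFrame] = []
    trajectories: dict[tuple[str, int], Trajectory] = {}
    mode_probs_cache = {g: np.asarray(s.pattern_mode_probs) for g, s in scenario_map.items()}

    child_i = 0
    for group, scn in scenario_map.items():
        if group not in counts:
            continue
        base_rate = _bin_rate_factors(schedule, scn)  # bouts/min per bin
        mu, sigma = scn.displacement_lognorm_params()
        for i in range(counts[group]):
            rng = np.random.default_rng(children[child_i])
            child_i += 1
            fish_id = f"{group}-{i:03d}"
            het = _mean1_lognormal(rng, scn.fish_rate_cv)
            lam = base_rate * het * bin_min
            n_bouts = rng.poisson(lam)
            total = int(n_bouts.sum())
            disp = rng.lognormal(mu, sigma, size=total)
            offsets = np.concatenate([[0], np.cumsum(n_bouts)[:-1]])
            dist = np.add.reduceat(disp, offsets) if total else np.zeros(len(n_bouts))
            dist[n_bouts == 0] = 0.0

            frames.append(pd.DataFrame({
                "fish_id": fish_id,
                "group_label": group,
                "bin_index": bins["bin_index"].to_numpy(),
                "bin_start_s": bins["bin_start_s"].to_numpy(),
                "light_state": bins["light_state"].to_numpy(),
                "day_label": bins["day_label"].to_numpy(),
                "bout_count": n_bouts.astype(int),
                "distance_cm": dist,
                "active_duration_s": n_bouts * scn.bout_duration_s,
            }))

            if with_trajectories:
                probs = mode_probs_cache[group]
                for b_idx, b_start in zip(
                    bins["bin_index"].to_numpy(), bins["bin_start_s"].to_numpy(), strict=True
                ):
                    if traj_bins is not None and int(b_idx) not in traj_bins:
                        continue
                    mode = PATTERN_MODES[rng.choice(len(PATTERN_MODES), p=probs)]
                    trajectories[(fish_id, int(b_idx))] = _make_trajectory(
                        fish_id, int(b_idx), float(b_start), schedule.bin_s,
                        mode, rng, spec.well_size_cm, spec.well_is_circular,
                    )

    table = pd.concat(frames, ignore_index=True)[TRACKING_COLUMNS]
    return trajectories, table


# ---------------------------------------------------------------------------
# trace-image rendering
# ---------------------------------------------------------------------------

def render_trace_image(
    traj: Trajectory,
    image_px: int = 99,
    well_size_cm: float | None = None,
) -> np.ndarray:
    """Rasterize one bin's trajectory into a square visit-count image.

    Consecutive samples are joined by pixel lines; the image accumulates the
    number of times each pixel is traversed (uint32).  A stationary fish
    yields a single nonzero pixel.
    """
    if image_px < 3:
        raise ValueError("image_px must be >= 3 (a 3x3 grid is applied downstream)")
    xy = traj.samples[:, 1:3]
    if well_size_cm is None:
        well_size_cm = float(max(xy.max(), 1e-9)) if len(xy) else 1.0
    img = np.zeros((image_px, image_px), dtype=np.uint32)
    if len(xy) == 0:
        return img

    scale = (image_px - 1) / well_size_cm
    cols = np.clip(np.rint(xy[:, 0] * scale), 0, image_px - 1).astype(int)
    rows = np.clip(np.rint(xy[:, 1] * scale), 0, image_px - 1).astype(int)

    if len(xy) == 1:
        img[rows[0], cols[0]] += 1
        return img
    for k in range(len(xy) - 1):
        rr, cc = _line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        if k < len(xy) - 2:  # avoid double-counting shared segment endpoints
            rr, cc = rr[:-1], cc[:-1]
        np.add.at(img, (rr, cc), 1)
    return img


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------

def simulate_fluorescence_traces(
    fscn: FluorScenario,
    n_rois: int,
    seed: int,
    group_label: str = "",
    roi_prefix: str = "roi",
) -> list[FluorTrace]:
    """Generate per-ROI GCaMP-like traces: baseline + exponential-decay
    transients + Gaussian noise (clipped at zero), seeded deterministically."""
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = fscn.n_samples
    t = np.arange(n) / fscn.rate_hz
    traces = []
    for i in range(n_rois):
        base = fscn.baseline_mean * _mean1_lognormal(rng, fscn.baseline_cv)
        n_ev = rng.poisson(fscn.transient_rate * fscn.duration_s / 600.0)
        f = np.full(n, base, dtype=float)
        for t_ev in np.sort(rng.uniform(0, fscn.duration_s, size=n_ev)):
            dt = t - t_ev
            mask = dt >= 0
            f[mask] += fscn.transient_amplitude_rel * base * np.exp(
                -dt[mask] / fscn.transient_decay_s
            )
        if fscn.noise_sd_rel > 0:
            f += rng.normal(0, fscn.noise_sd_rel * base, size=n)
        traces.append(
            FluorTrace(
                roi_id=f"{roi_prefix}-{i:03d}",
                region=fscn.region,
                group_label=group_label,
                values=np.clip(f, 0, None),
                rate_hz=fscn.rate_hz,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# labelled-cell fields
# ---------------------------------------------------------------------------

def simulate_cell_field(
    cfs: CellFieldSpec, seed: int
) -> tuple[np.ndarray, dict[str, float]]:
    """Draw a field of non-overlapping disk 'cells' inside an ROI.

    The cell count is Poisson with mean ``mean_cell_count x
    (1 - depletion_fraction)``.  Returns the grayscale image and a truth
    record with the realized count and total rasterized area (px).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    img = np.zeros(cfs.image_shape, dtype=np.uint16)
    r0, c0, r1, c1 = cfs.roi
    r = cfs.cell_radius_px
    n_target = rng.poisson(cfs.mean_cell_count * (1.0 - cfs.depletion_fraction))

    lo_r, hi_r = r0 + r, r1 - r - 1
    lo_c, hi_c = c0 + r, c1 - r - 1
    if n_target > 0 and (hi_r < lo_r or hi_c < lo_c):
        raise ValueError("ROI too small for the requested cell radius")

    centers: list[tuple[int, int]] = []
    min_d2 = (2 * r + 2) ** 2
    attempts = 0
    while len(centers) < n_target:
        attempts += 1
        if attempts > 20_000:
            raise ValueError("ROI too small to place the requested cell density")
        cr = rng.integers(lo_r, hi_r + 1)
        cc = rng.integers(lo_c, hi_c + 1)
        if all((cr - a) ** 2 + (cc - b) ** 2 >= min_d2 for a, b in centers):
            centers.append((int(cr), int(cc)))

    area = 0
    for cr, cc in centers:
        rr, cc_ = _disk((cr, cc), r + 0.5, shape=img.shape)
        img[rr, cc_] = cfs.cell_intensity
        area += len(rr)
    truth = {"count": float(len(centers)), "area_px": float(area)}
    return img, truth
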