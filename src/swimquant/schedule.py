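"""Light/dark session schedules for long-term tracking and visuomotor assays.

A tracking session is partitioned into fixed-width integration bins (10 min
for multi-day tracking, 1 min for the visuomotor assay).  Each bin carries a
light state and a period label: successive light periods are labelled
``d1, d2, ...`` (days) and dark periods ``n1, n2, ...`` (nights).  Bins are
half-open ``[t, t + bin_s)`` and take the light state at their start time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAY_S = 86_400

__all__ = [
    "SessionSpec",
    "LightSchedule",
    "make_light_schedule",
    "make_visuomotor_schedule",
    "parse_clock",
]


def parse_clock(clock: str | float) -> float:
    """Convert ``"HH:MM"`` (or seconds-since-midnight) to seconds since midnight."""
    if isinstance(clock, str):
        hh, mm = clock.split(":")
        sec = int(hh) * 3600 + int(mm) * 60
    else:
        sec = float(clock)
    if not 0 <= sec < DAY_S:
        raise ValueError(f"clock time out of range: {clock!r}")
    return float(sec)


@dataclass(frozen=True)
class SessionSpec:
    """Geometry and timing of one tracking session.

    Parameters
    ----------
    duration_s:
        Total session length in seconds; must be a positive multiple of
        ``bin_s``.
    bin_s:
        Integration-bin width in seconds (600 for long-term tracking, 60 for
        the visuomotor assay).
    lights_on_clock, lights_off_clock:
        Local time of day when lights switch on/off (default 07:00 / 21:00,
        i.e. a 14 h light : 10 h dark cycle).
    start_clock:
        Local time of day at which tracking starts (default 09:00, so a
        72 h session spans a partial first day, two full 14 h light periods
        d2/d3, and a partial d4 morning).
    plate_format:
        ``"96-well"`` (square wells) or ``"24-well"`` (circular wells).
    well_size_cm:
        Side length (square) or diameter (circular) of one well.
    """

    duration_s: float
    bin_s: float
    lights_on_clock: str | float = "07:00"
    lights_off_clock: str | float = "21:00"
    start_clock: str | float = "09:00"
    plate_format: str = "96-well"
    well_size_cm: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        n = self.duration_s / self.bin_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_s must divide duration_s exactly")
        on = parse_clock(self.lights_on_clock)
        off = parse_clock(self.lights_off_clock)
        if on >= off:
            raise ValueError("lights_on must precede lights_off within a day")
        if self.plate_format not in ("96-well", "24-well"):
            raise ValueError(f"unknown plate_format: {self.plate_format!r}")
        if self.well_size_cm is None:
            # 96-well square 0.9 cm side; 24-well circular 1.55 cm diameter
            object.__setattr__(
                self, "well_size_cm", 0.9 if self.plate_format == "96-well" else 1.55
            )

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_s / self.bin_s))

    @property
    def well_is_circular(self) -> bool:
        return self.plate_format == "24-well"


@dataclass
class LightSchedule:
    """Ordered, contiguous light/dark bin assignment for one session.

    Attributes
    ----------
    bins:
        DataFrame with one row per bin: ``bin_index``, ``bin_start_s``,
        ``light_state`` (``"light"``/``"dark"``) and ``day_label``
        (``d1, d2, ...`` for light periods, ``n1, n2, ...`` for dark).
    bin_s:
        Bin width in seconds.
    transitions_s:
        Session times (seconds) of every light-to-dark switch.
    """

    bins: pd.DataFrame
    bin_s: float
    transitions_s: list[float] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_s

    def light_period_bounds(self) -> dict[str, tuple[float, float]]:
        """Map each period label to its [start, end) interval in session seconds."""
        out: dict[str, tuple[float, float]] = {}
        for label, grp in self.bins.groupby("day_label", sort=False):
            out[label] = (
                float(grp["bin_start_s"].min()),
                float(grp["bin_start_s"].max() + self.bin_s),
            )
        return out


def _label_periods(states: np.ndarray) -> list[str]:
    """Label runs of equal light state d1,d2,... (light) / n1,n2,... (dark)."""
    labels: list[str] = []
    n_day = n_night = 0
    prev: str | None = None
    current = ""
    for s in states:
        if s != prev:
            if s == "light":
                n_day += 1
                current = f"d{n_day}"
            else:
                n_night += 1
                current = f"n{n_night}"
            prev = s
        labels.append(current)
    return labels


def make_light_schedule(spec: SessionSpec) -> LightSchedule:
    """Build the diurnal (clock-driven) schedule for a tracking session.

    Each bin is classified by the wall-clock time at its start: light iff
    ``lights_on <= clock < lights_off``.  A 72 h session at 600 s bins yields
    432 bins.
    """
    on = parse_clock(spec.lights_on_clock)
    off = parse_clock(spec.lights_off_clock)
    start = parse_clock(spec.start_clock)

    starts = np.arange(spec.n_bins) * spec.bin_s
    clock = (start + starts) % DAY_S
    is_light = (clock >= on) & (clock < off)
    states = np.where(is_light, "light", "dark")
    labels = _label_periods(states)

    bins = pd.DataFrame(
        {
            "bin_index": np.arange(spec.n_bins, dtype=int),
            "bin_start_s": starts.astype(float),
            "light_state": states,
            "day_label": labels,
        }
    )
    trans = [
        float(starts[i])
        for i in range(1, spec.n_bins)
        if states[i - 1] == "light" and states[i] == "dark"
    ]
    return LightSchedule(bins=bins, bin_s=spec.bin_s, transitions_s=trans)


def make_visuomotor_schedule(bin_s: float = 60.0) -> LightSchedule:
    """Build the 6 h light-dark visuomotor program at 1-min integration.

    The program is a 3 h full-light acclimation, then four alternating 30-min
    intervals starting with dark, then six alternating 10-min intervals
    starting with dark: 360 one-minute bins in total with exactly five
    light-to-dark switches.
    """
    blocks: list[tuple[float, str]] = [(180 * 60.0, "light")]
    for i in range(4):
        blocks.append((30 * 60.0, "dark" if i % 2 == 0 else "light"))
    for i in range(6):
        blocks.append((10 * 60.0, "dark" if i % 2 == 0 else "light"))

    states: list[str] = []
    for dur, state in blocks:
        n = int(round(dur / bin_s))
        if abs(n * bin_s - dur) > 1e-9:
            raise ValueError("bin_s must divide every program block exactly")
        states.extend([state] * n)
    states_arr = np.asarray(states)
    starts = np.arange(len(states_arr)) * bin_s
    labels = _label_periods(states_arr)

    bins = pd.DataFrame(
        {
            "bin_index": np.arange(len(states_arr), dtype=int),
            "bin_start_s": starts.astype(float),
            "light_state": states_arr,
            "day_label": labels,
        }
    )
    trans = [
        float(starts[i])
        for i in range(1, len(states_arr))
        if states_arr[i - 1] == "light" and states_arr[i] == "dark"
    ]
    return LightSchedule(bins=bins, bin_s=bin_s, transitions_s=trans)
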