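"""Generative scenario definitions and shipped defaults.

A :class:`Scenario` fixes the burst-and-glide bout process for one genotype
group: daytime bout rate, night suppression, within-day decline, bout
displacement distribution, between-fish heterogeneity, swim-pattern mode
probabilities, and the transient post light-off boost.  The shipped default
scenarios are calibrated so that rate x mean displacement reproduces the
published group means (e.g. wild-type 24-well daytime distance of
35.6 cm per 10 min from 7.12 bouts/min x 0.5 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Scenario",
    "FluorScenario",
    "CellFieldSpec",
    "PATTERN_MODES",
    "default_swim_scenarios",
    "default_fluor_scenarios",
    "default_cell_field_specs",
]

PATTERN_MODES = ("full-lap", "partial", "center-heavy", "quiescent")


@dataclass(frozen=True)
class Scenario:
    """Generative parameters of one genotype group's locomotor behavior.

    Parameters
    ----------
    group_label:
        Group name carried into every generated record.
    day_bout_rate:
        Mean daytime swim-bout rate, bouts per minute (averaged over the
        light period; the within-day decline reshapes but does not change
        this mean).
    night_rate_multiplier:
        Fraction of the day rate retained at night (0..1).
    bout_displacement_mean_cm, bout_displacement_cv:
        Mean and coefficient of variation of per-bout displacement, drawn
        from a log-normal.
    bout_duration_s:
        Nominal duration of one bout; active duration per bin is
        count x bout_duration_s.
    within_day_decline:
        Fraction of the bout rate lost linearly from the start to the end
        of each light period (applied as a mean-preserving ramp).
    fish_rate_cv:
        Between-fish rate heterogeneity (CV of a mean-one log-normal factor).
    pattern_mode_probs:
        Probabilities over the four per-bin swim-pattern modes
        (full-lap, partial, center-heavy, quiescent); must sum to 1.
    dark_switch_boost:
        Rate factor (x day rate) immediately after a light-to-dark switch;
        decays exponentially to the night level with time constant
        ``boost_decay_min``.
    """

    group_label: str
    day_bout_rate: float
    night_rate_multiplier: float = 0.1
    bout_displacement_mean_cm: float = 0.5
    bout_displacement_cv: float = 0.5
    bout_duration_s: float = 0.25
    within_day_decline: float = 0.3
    fish_rate_cv: float = 0.28
    pattern_mode_probs: tuple[float, float, float, float] = (0.40, 0.35, 0.15, 0.10)
    dark_switch_boost: float = 3.0
    boost_decay_min: float = 5.0

    def __post_init__(self) -> None:
        if self.day_bout_rate < 0:
            raise ValueError("day_bout_rate must be >= 0")
        if not 0 <= self.night_rate_multiplier <= 1:
            raise ValueError("night_rate_multiplier must be in [0, 1]")
        for name in (
            "bout_displacement_mean_cm",
            "bout_displacement_cv",
            "bout_duration_s",
            "fish_rate_cv",
            "dark_switch_boost",
            "boost_decay_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.within_day_decline <= 1:
            raise ValueError("within_day_decline must be in [0, 1]")
        p = self.pattern_mode_probs
        if len(p) != len(PATTERN_MODES) or any(x < 0 for x in p):
            raise ValueError("pattern_mode_probs needs 4 non-negative entries")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("pattern_mode_probs must sum to 1")

    @property
    def expected_day_distance_per_10min(self) -> float:
        """Expected daytime distance (cm) per 10-min bin for an average fish."""
        return self.day_bout_rate * 10.0 * self.bout_displacement_mean_cm

    @property
    def expected_day_bouts_per_10min(self) -> float:
        return self.day_bout_rate * 10.0

    def displacement_lognorm_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal with the scenario's mean and CV."""
        sigma2 = math.log1p(self.bout_displacement_cv**2)
        mu = math.log(self.bout_displacement_mean_cm) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


def default_swim_scenarios() -> dict[str, dict[str, Scenario]]:
    """Shipped scenario tables, keyed by assay then group label.

    24-well groups are calibrated to the published daytime distances
    (WT 35.6, mutant 15.5, macrophage-rescued mutant 36.7 cm per 10 min at
    0.5 cm mean bout displacement).  96-well groups encode the published
    relative effects: the mutant's bout rate is 0.635x the sibling's
    (36.5 % median activity reduction, distance reduction in the printed
    35-50 % band) and the microglia-less-only group is 0.86x with the
    displacement raised 1/0.86x so distance is unchanged (14 % activity
    reduction, no distance effect).
    """
    p_sib = (0.40, 0.35, 0.15, 0.10)
    # mutant full-lap probability is 0.70x the sibling's; difference moved to partial
    p_mut = (0.28, 0.47, 0.15, 0.10)

    w24 = {
        "wt": Scenario("wt", day_bout_rate=7.12, bout_displacement_mean_cm=0.5,
                       pattern_mode_probs=p_sib),
        "mutant": Scenario("mutant", day_bout_rate=3.10, bout_displacement_mean_cm=0.5,
                           pattern_mode_probs=p_mut),
        "rescued-mutant": Scenario("rescued-mutant", day_bout_rate=7.34,
                                   bout_displacement_mean_cm=0.5,
                                   pattern_mode_probs=p_sib),
    }
    sib96 = Scenario("sibling", day_bout_rate=6.0, bout_displacement_mean_cm=0.35,
                     pattern_mode_probs=p_sib)
    w96 = {
        "sibling": sib96,
        "mutant": replace(sib96, group_label="mutant",
                          day_bout_rate=6.0 * 0.635,
                          pattern_mode_probs=p_mut),
        "microglia-less": replace(sib96, group_label="microglia-less",
                                  day_bout_rate=6.0 * 0.86,
                                  bout_displacement_mean_cm=0.35 / 0.86),
    }
    return {"24-well": w24, "96-well": w96}


@dataclass(frozen=True)
class FluorScenario:
    """Generative parameters of per-ROI GCaMP fluorescence traces.

    Baselines are drawn per ROI around ``baseline_mean`` with CV
    ``baseline_cv``; calcium transients arrive at ``transient_rate`` events
    per 10 min with an instantaneous rise of ``transient_amplitude_rel`` x
    baseline and exponential decay ``transient_decay_s``; Gaussian noise has
    SD ``noise_sd_rel`` x baseline.
    """

    region: str
    baseline_mean: float
    baseline_cv: float = 0.2
    transient_rate: float = 2.0  # events per 10 min per ROI
    transient_amplitude_rel: float = 1.5
    transient_decay_s: float = 2.0
    noise_sd_rel: float = 0.05
    rate_hz: float = 1.0
    duration_s: float = 600.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.region not in ("telencephalon", "diencephalon", "tectum", "cerebellum"):
            raise ValueError(f"unknown region: {self.region!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate_hz * self.duration_s))


def default_fluor_scenarios() -> dict[str, dict[str, FluorScenario]]:
    """Calcium-imaging scenario table keyed by region then group.

    Diencephalic baselines encode the ~4-fold sibling:mutant difference
    (400 vs 100 a.u.); telencephalic baselines are equal across genotypes;
    tectal transient rates are 2 (sibling) vs 3 (mutant) events per 10 min.
    """
    return {
        "diencephalon": {
            "sibling": FluorScenario("diencephalon", baseline_mean=400.0),
            "mutant": FluorScenario("diencephalon", baseline_mean=100.0),
        },
        "telencephalon": {
            "sibling": FluorScenario("telencephalon", baseline_mean=400.0),
            "mutant": FluorScenario("telencephalon", baseline_mean=400.0),
        },
        "tectum": {
            "sibling": FluorScenario("tectum", baseline_mean=300.0, transient_rate=2.0),
            "mutant": FluorScenario("tectum", baseline_mean=300.0, transient_rate=3.0),
        },
    }


@dataclass(frozen=True)
class CellFieldSpec:
    """Parameters of a synthetic labelled-cell field (e.g. neutrophils in an ROI).

    ``depletion_fraction`` scales the Poisson mean cell count down
    (0 = control, 0.9 = 90 % depletion).
    """

    roi: tuple[int, int, int, int] = (10, 10, 110, 110)  # (row0, col0, row1, col1)
    mean_cell_count: float = 30.0
    cell_radius_px: int = 3
    depletion_fraction: float = 0.0
    image_shape: tuple[int, int] = (128, 128)
    cell_intensity: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.depletion_fraction <= 1:
            raise ValueError("depletion_fraction must be in [0, 1]")
        if self.cell_radius_px < 1:
            raise ValueError("cell_radius_px must be >= 1")
        r0, c0, r1, c1 = self.roi
        if not (0 <= r0 < r1 <= self.image_shape[0] and 0 <= c0 < c1 <= self.image_shape[1]):
            raise ValueError("roi must be a non-degenerate rectangle inside the image")


def default_cell_field_specs() -> dict[str, CellFieldSpec]:
    """Neutrophil-field specs: control vs 90 %-depleted morphant."""
    return {
        "control": CellFieldSpec(),
        "morphant": CellFieldSpec(depletion_fraction=0.9),
    }
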