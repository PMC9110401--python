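import dataclasses

import numpy as np
import pytest

from swimquant.scenarios import CellFieldSpec, FluorScenario, Scenario
from swimquant.simulate import (
    Trajectory,
    make_pattern_trajectory,
    render_trace_image,
    simulate_cell_field,
    simulate_fluorescence_traces,
    simulate_swim_session,
)


class TestSwimSession:
    def test_seeded_determinism_byte_identical(self, simple_scenario, short_spec):
        _, t1 = simulate_swim_session({"wt": simple_scenario}, short_spec, 3, seed=7)
        _, t2 = simulate_swim_session({"wt": simple_scenario}, short_spec, 3, seed=7)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self, simple_scenario, short_spec):
        _, t1 = simulate_swim_session({"wt": simple_scenario}, short_spec, 3, seed=7)
        _, t2 = simulate_swim_session({"wt": simple_scenario}, short_spec, 3, seed=8)
        assert not t1["bout_count"].equals(t2["bout_count"])

    def test_zero_night_rate_gives_zero_dark_bouts(self, short_spec):
        scn = Scenario("wt", day_bout_rate=6.0, night_rate_multiplier=0.0,
                       dark_switch_boost=0.0)
        _, table = simulate_swim_session({"wt": scn}, short_spec, 4, seed=3)
        dark = table[table["light_state"] == "dark"]
        assert (dark["bout_count"] == 0).all()
        assert (dark["distance_cm"] == 0).all()

    def test_zero_distance_iff_zero_bouts(self, simple_scenario, short_spec):
        _, table = simulate_swim_session({"wt": simple_scenario}, short_spec, 5, seed=11)
        zero_count = table["bout_count"] == 0
        assert (table.loc[zero_count, "distance_cm"] == 0).all()
        assert (table.loc[~zero_count, "distance_cm"] > 0).all()

    def test_group_mean_matches_compound_process_expectation(self, short_spec):
        # E[distance per bin] = rate x bin_min x mean displacement for daytime
        scn = Scenario("wt", day_bout_rate=7.12, bout_displacement_mean_cm=0.5)
        n = 100
        _, table = simulate_swim_session({"wt": scn}, short_spec, n, seed=5)
        day = table[(table["light_state"] == "light")]
        per_fish = day.groupby("fish_id")["distance_cm"].mean()
        expected = 7.12 * 10 * 0.5  # 35.6 cm per 10-min
        se = expected * scn.fish_rate_cv / np.sqrt(n)
        assert abs(per_fish.mean() - expected) < 3 * se

    def test_unknown_group_label_rejected(self, simple_scenario, short_spec):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_swim_session({"wt": simple_scenario}, short_spec,
                                  {"mut": 3}, seed=1)

    def test_dark_switch_boost_raises_early_night_rate(self, short_spec):
        quiet = Scenario("wt", day_bout_rate=6.0, night_rate_multiplier=0.05,
                         dark_switch_boost=0.0, fish_rate_cv=0.0)
        boosted = dataclasses.replace(quiet, dark_switch_boost=3.0)
        _, tq = simulate_swim_session({"wt": quiet}, short_spec, 20, seed=9)
        _, tb = simulate_swim_session({"wt": boosted}, short_spec, 20, seed=9)
        sched_dark_first = tq[tq["light_state"] == "dark"]["bin_index"].min()
        first_dark = lambda t: t[t["bin_index"] == sched_dark_first]["bout_count"].mean()
        assert first_dark(tb) > 2 * first_dark(tq)


class TestTraceRendering:
    def test_stationary_fish_single_pixel(self):
        traj = Trajectory("f", 0, np.array([[0.0, 0.7, 0.7]]))
        img = render_trace_image(traj, image_px=99, well_size_cm=1.55)
        assert (img > 0).sum() == 1
        assert img.sum() == 1

    def test_full_lap_touches_all_eight_outer_squares(self):
        from swimquant.pattern import OUTER_SQUARES, grid_pixel_values

        for seed in range(5):
            traj = make_pattern_trajectory("full-lap", seed)
            img = render_trace_image(traj, image_px=99, well_size_cm=1.55)
            vals = grid_pixel_values(img)
            assert all(vals[i] > 0 for i in OUTER_SQUARES)

    def test_pixel_sum_conserves_visit_count(self):
        # a straight horizontal line of k pixels traversed once sums to k
        traj = Trajectory("f", 0, np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 0.0]]))
        img = render_trace_image(traj, image_px=11, well_size_cm=1.0)
        assert img.sum() == 11
        assert (img[0, :] == 1).all()

    def test_small_image_rejected(self):
        traj = Trajectory("f", 0, np.array([[0.0, 0.5, 0.5]]))
        with pytest.raises(ValueError):
            render_trace_image(traj, image_px=2)

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            Trajectory("f", 0, np.array([[1.0, 0.1, 0.1], [0.0, 0.2, 0.2]]))


class TestFluorescence:
    def test_ten_minutes_at_1hz_gives_600_samples(self):
        fscn = FluorScenario("diencephalon", baseline_mean=400.0)
        traces = simulate_fluorescence_traces(fscn, 3, seed=1)
        assert all(len(tr.values) == 600 for tr in traces)

    def test_no_transients_no_noise_is_constant_baseline(self):
        fscn = FluorScenario("tectum", baseline_mean=300.0, baseline_cv=0.0,
                             transient_rate=0.0, noise_sd_rel=0.0)
        (tr,) = simulate_fluorescence_traces(fscn, 1, seed=2)
        assert np.allclose(tr.values, 300.0)

    def test_trace_mean_matches_transient_area_expectation(self):
        # E[mean] = b x (1 + rate x amplitude x decay / duration)
        fscn = FluorScenario("tectum", baseline_mean=200.0, baseline_cv=0.0,
                             transient_rate=30.0, transient_amplitude_rel=1.5,
                             transient_decay_s=2.0, noise_sd_rel=0.0)
        traces = simulate_fluorescence_traces(fscn, 60, seed=4)
        means = np.array([tr.values.mean() for tr in traces])
        expected = 200.0 * (1 + 30.0 * 1.5 * 2.0 / 600.0)
        assert abs(means.mean() - expected) / expected < 0.02

    def test_seeded_determinism(self):
        fscn = FluorScenario("tectum", baseline_mean=300.0)
        a = simulate_fluorescence_traces(fscn, 2, seed=5)
        b = simulate_fluorescence_traces(fscn, 2, seed=5)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b, strict=True))


def _flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 8-connected component count (independent oracle)."""
    mask = mask.copy()
    n = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0]:
                continue
            n += 1
            stack = [(r0, c0)]
            mask[r0, c0] = False
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]):
                            mask[rr, cc] = False
                            stack.append((rr, cc))
    return n


class TestCellField:
    def test_full_depletion_empty_roi(self):
        cfs = CellFieldSpec(depletion_fraction=1.0)
        img, truth = simulate_cell_field(cfs, seed=1)
        assert truth["count"] == 0
        assert img.sum() == 0

    def test_truth_count_matches_flood_fill_oracle(self):
        cfs = CellFieldSpec(mean_cell_count=25.0)
        for seed in range(4):
            img, truth = simulate_cell_field(cfs, seed=seed)
            assert _flood_fill_count(img > 0) == truth["count"]

    def test_truth_area_is_count_times_disk_size(self):
        from skimage.draw import disk

        cfs = CellFieldSpec(mean_cell_count=15.0, cell_radius_px=3)
        px_per_disk = len(disk((50, 50), 3.5)[0])
        img, truth = simulate_cell_field(cfs, seed=3)
        assert truth["area_px"] == truth["count"] * px_per_disk
        assert (img > 0).sum() == truth["area_px"]

    def test_impossible_density_rejected(self):
        cfs = CellFieldSpec(roi=(10, 10, 30, 30), mean_cell_count=400.0,
                            cell_radius_px=4)
        with pytest.raises(ValueError):
            simulate_cell_field(cfs, seed=1)
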