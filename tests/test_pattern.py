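import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from swimquant.pattern import (
    CENTER_SQUARE,
    OUTER_SQUARES,
    PatternConfig,
    center_class,
    cluster_score_matrix,
    daytime_pattern_fractions,
    grid_pixel_values,
    pattern_correlation,
    perimeter_score,
)


class TestGridPixelValues:
    def test_all_zero_image(self):
        assert (grid_pixel_values(np.zeros((9, 9))) == 0).all()

    def test_single_center_pixel(self):
        img = np.zeros((99, 99))
        img[49, 49] = 7
        vals = grid_pixel_values(img)
        assert vals[CENTER_SQUARE] == 7
        assert vals.sum() == 7

    def test_conservation_against_whole_image_sum(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            img = rng.integers(0, 50, size=(n, n))
            assert grid_pixel_values(img).sum() == img.sum()

    def test_remainder_goes_to_trailing_squares(self):
        img = np.zeros((10, 10))
        img[9, 9] = 3  # remainder row/col belongs to the last square
        assert grid_pixel_values(img)[8] == 3

    @pytest.mark.parametrize("shape", [(2, 2), (5, 7)])
    def test_tiny_or_nonsquare_rejected(self, shape):
        with pytest.raises(ValueError):
            grid_pixel_values(np.zeros(shape))


class TestPerimeterScore:
    def test_full_perimeter_scores_eight(self):
        vals = np.full(9, 500.0)
        assert perimeter_score(vals) == 8

    def test_empty_scores_zero(self):
        assert perimeter_score(np.zeros(9)) == 0

    def test_strict_threshold_rule(self):
        # alternating 10/9: only values strictly above 9 count
        vals = np.zeros(9)
        vals[list(OUTER_SQUARES)] = [10, 9, 10, 9, 10, 9, 10, 9]
        assert perimeter_score(vals) == 4

    @given(
        base=st.lists(st.floats(0, 1000), min_size=9, max_size=9),
        idx=st.integers(0, 8),
        bump=st.floats(0, 1000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_under_pixel_increase(self, base, idx, bump):
        v = np.asarray(base)
        w = v.copy()
        w[idx] += bump
        assert perimeter_score(w) >= perimeter_score(v)

    def test_rotation_invariance(self, rng):
        for _ in range(20):
            img = rng.integers(0, 30, size=(99, 99))
            rot = np.rot90(img)
            assert perimeter_score(grid_pixel_values(img)) == perimeter_score(
                grid_pixel_values(rot)
            )
            assert (
                grid_pixel_values(img)[CENTER_SQUARE]
                == grid_pixel_values(rot)[CENTER_SQUARE]
            )


class TestCenterClass:
    @pytest.mark.parametrize(
        "value,cls",
        [(50, "low"), (600, "high"), (300, "intermediate"),
         (100, "intermediate"), (550, "intermediate"), (99.9, "low")],
    )
    def test_threshold_rule(self, value, cls):
        assert center_class(value) == cls

    def test_config_thresholds_respected(self):
        cfg = PatternConfig(center_low_threshold=10, center_high_threshold=20)
        assert center_class(15, cfg) == "intermediate"
        assert center_class(5, cfg) == "low"


class TestPatternFractions:
    def test_fraction_arithmetic(self):
        scores = pd.DataFrame({
            "fish_id": ["f1"] * 4,
            "perimeter_score": [8, 8, 0, 8],
            "center_class": ["low", "high", "low", "intermediate"],
        })
        fr = daytime_pattern_fractions(scores)
        assert fr["frac_full"].iloc[0] == 0.75
        assert fr["frac_none"].iloc[0] == 0.25
        assert fr["frac_center_high"].iloc[0] == 0.25
        assert fr["frac_center_low"].iloc[0] == 0.5

    def test_all_intermediate_fish(self):
        scores = pd.DataFrame({
            "fish_id": ["f1"] * 3,
            "perimeter_score": [3, 4, 5],
            "center_class": ["intermediate"] * 3,
        })
        fr = daytime_pattern_fractions(scores)
        assert fr[["frac_full", "frac_none", "frac_center_high",
                   "frac_center_low"]].iloc[0].sum() == 0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            daytime_pattern_fractions(pd.DataFrame(
                columns=["fish_id", "perimeter_score", "center_class"]))


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        m = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        z, _ = cluster_score_matrix(m)
        assert z[0, 2] == 0.0

    def test_two_separated_groups_recovered_at_k2(self, rng):
        a = rng.normal(0, 0.5, size=(10, 20))
        b = rng.normal(8, 0.5, size=(10, 20))
        m = np.vstack([a, b])
        z, _ = cluster_score_matrix(m)
        labels = fcluster(z, t=2, criterion="maxclust")
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_closest_pair_merges_first(self, rng):
        # brute-force the smallest pairwise distance and check it merges first
        m = rng.normal(0, 5, size=(8, 6))
        d = np.full((8, 8), np.inf)
        for i in range(8):
            for j in range(i + 1, 8):
                d[i, j] = np.linalg.norm(m[i] - m[j])
        i0, j0 = np.unravel_index(np.argmin(d), d.shape)
        z, _ = cluster_score_matrix(m)
        assert {int(z[0, 0]), int(z[0, 1])} == {i0, j0}

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_score_matrix(np.ones((1, 4)))


class TestPatternCorrelation:
    def test_anti_monotone_gives_minus_one(self):
        fr = pd.DataFrame({"frac_full": [0.1, 0.2, 0.3, 0.4],
                           "frac_center_low": [0.9, 0.8, 0.7, 0.6]})
        assert pattern_correlation(fr) == pytest.approx(-1.0)

    def test_identical_vectors_give_plus_one(self):
        fr = pd.DataFrame({"frac_full": [0.1, 0.2, 0.3],
                           "frac_center_low": [0.1, 0.2, 0.3]})
        assert pattern_correlation(fr) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        fr = pd.DataFrame({"frac_full": [0.2, 0.2, 0.2],
                           "frac_center_low": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match="zero variance"):
            pattern_correlation(fr)

    def test_generated_scenario_shows_inverse_correlation(self):
        # full-lap bins also transit the center, so fish doing more full laps
        # have fewer low-center bins
        from swimquant.pattern import score_image
        from swimquant.scenarios import default_swim_scenarios
        from swimquant.schedule import SessionSpec
        from swimquant.simulate import render_trace_image, simulate_swim_session

        spec = SessionSpec(duration_s=12 * 3600, bin_s=600, plate_format="24-well",
                           start_clock="07:00")
        scn = default_swim_scenarios()["24-well"]["wt"]
        day_bins = np.arange(40)
        trajs, table = simulate_swim_session(
            {"wt": scn}, spec, 16, seed=21,
            with_trajectories=True, trajectory_bins=day_bins)
        rows = []
        for (fish_id, b), traj in trajs.items():
            rec = score_image(render_trace_image(traj, 99, 1.55), fish_id, b)
            rows.append({"fish_id": fish_id,
                         "perimeter_score": rec["perimeter_score"],
                         "center_class": rec["center_class"]})
        fr = daytime_pattern_fractions(pd.DataFrame(rows))
        assert pattern_correlation(fr) < 0
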