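"""3x3 grid swim-pattern scoring of trace images.

Each well's trace image is divided into nine near-equal squares.  The eight
outer squares are binarized (pixel sum > 9 counts as swum) and summed into a
perimeter score of 0 (no perimeter swimming) to 8 (a full perimeter lap);
the central square is classified directly by its pixel sum (< 100 low,
> 550 high center activity, intermediate otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr

__all__ = [
    "PatternConfig",
    "grid_pixel_values",
    "perimeter_score",
    "center_class",
    "score_image",
    "daytime_pattern_fractions",
    "cluster_score_matrix",
    "pattern_correlation",
    "OUTER_SQUARES",
    "CENTER_SQUARE",
]

# row-major 3x3 indices
OUTER_SQUARES = (0, 1, 2, 3, 5, 6, 7, 8)
CENTER_SQUARE = 4


@dataclass(frozen=True)
class PatternConfig:
    """Pixel-sum thresholds for grid scoring (visit-count scale)."""

    outer_binarize_threshold: float = 9.0
    center_low_threshold: float = 100.0
    center_high_threshold: float = 550.0

    def __post_init__(self) -> None:
        if self.outer_binarize_threshold < 0:
            raise ValueError("outer_binarize_threshold must be >= 0")
        if not 0 <= self.center_low_threshold < self.center_high_threshold:
            raise ValueError("need 0 <= center_low_threshold < center_high_threshold")


def grid_pixel_values(img: np.ndarray) -> np.ndarray:
    """Sum pixel values in each square of the 3x3 grid (row-major order).

    Remainder rows/columns when the side is not divisible by 3 are assigned
    to the last row/column of squares.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("trace image must be square")
    n = img.shape[0]
    if n < 3:
        raise ValueError("image must be at least 3x3")
    step = n // 3
    edges = [0, step, 2 * step, n]
    vals = np.empty(9, dtype=float)
    for i in range(3):
        for j in range(3):
            block = img[edges[i]:edges[i + 1], edges[j]:edges[j + 1]]
            vals[3 * i + j] = float(block.sum(dtype=np.float64))
    return vals


def perimeter_score(square_values, cfg: PatternConfig | None = None) -> int:
    """Count of outer squares whose pixel sum exceeds the binarize threshold (0-8)."""
    cfg = cfg or PatternConfig()
    v = np.asarray(square_values, dtype=float)
    if v.shape != (9,):
        raise ValueError("expected 9 square values")
    return int(np.sum(v[list(OUTER_SQUARES)] > cfg.outer_binarize_threshold))


def center_class(center_value: float, cfg: PatternConfig | None = None) -> str:
    """Classify the central square's pixel sum as low / intermediate / high."""
    cfg = cfg or PatternConfig()
    if center_value < 0:
        raise ValueError("center value must be >= 0")
    if center_value < cfg.center_low_threshold:
        return "low"
    if center_value > cfg.center_high_threshold:
        return "high"
    return "intermediate"


def score_image(
    img: np.ndarray,
    fish_id: str = "",
    bin_index: int = -1,
    cfg: PatternConfig | None = None,
) -> dict:
    """Full grid scoring of one trace image."""
    cfg = cfg or PatternConfig()
    vals = grid_pixel_values(img)
    center = float(vals[CENTER_SQUARE])
    return {
        "fish_id": fish_id,
        "bin_index": bin_index,
        "square_values": vals,
        "perimeter_score": perimeter_score(vals, cfg),
        "center_value": center,
        "center_class": center_class(center, cfg),
    }


def daytime_pattern_fractions(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-fish fractions of bins at the pattern extremes.

    ``scores`` must have columns fish_id, perimeter_score, center_class
    (already restricted to the daytime bins of interest).  Returns per fish:
    ``frac_full`` (perimeter score 8), ``frac_none`` (score 0),
    ``frac_center_high`` and ``frac_center_low``.
    """
    if scores.empty:
        raise ValueError("empty score selection")
    cols = {"fish_id", "perimeter_score", "center_class"}
    if not cols <= set(scores.columns):
        raise ValueError(f"scores must contain columns {sorted(cols)}")

    def _frac(sub: pd.DataFrame) -> pd.Series:
        n = len(sub)
        return pd.Series({
            "frac_full": float((sub["perimeter_score"] == 8).sum()) / n,
            "frac_none": float((sub["perimeter_score"] == 0).sum()) / n,
            "frac_center_high": float((sub["center_class"] == "high").sum()) / n,
            "frac_center_low": float((sub["center_class"] == "low").sum()) / n,
            "n_bins": n,
        })

    keys = ["fish_id"] + (["group_label"] if "group_label" in scores.columns else [])
    out = scores.groupby(keys, sort=True).apply(_frac, include_groups=False).reset_index()
    out["n_bins"] = out["n_bins"].astype(int)
    return out


def cluster_score_matrix(
    matrix: np.ndarray | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of per-fish score vectors.

    Returns (linkage matrix, leaf order).  Rows are fish, columns bins; ties
    are broken deterministically by row index (scipy's ordering).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    z = linkage(m, method=method, metric=metric)
    return z, leaves_list(z)


def pattern_correlation(fractions: pd.DataFrame) -> float:
    """Pearson correlation between per-fish full-perimeter and low-center fractions.

    Raises ``ValueError`` when fewer than 3 fish or either variable has zero
    variance (the coefficient is undefined there).
    """
    if len(fractions) < 3:
        raise ValueError("need at least 3 fish")
    x = fractions["frac_full"].to_numpy(float)
    y = fractions["frac_center_low"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a variable")
    return float(pearsonr(x, y).statistic)
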