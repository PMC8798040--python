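"""Volume-curve cleaning: outlier fences, smoothing, and detrending.

The cleaning pipeline mirrors how raw fluorescence-exclusion volume curves
are prepared before any growth-rate computation:

1. **Outlier filtering** — on a centered sliding window (default 11 frames),
   points outside the quartile fences ``[Q1 - k·IQR, Q3 + k·IQR]`` (default
   ``k = 0.9``) are flagged invalid. Quartiles use the linear-interpolation
   rule (type 7) so the hand-worked examples in the tests are reproducible.
2. **Smoothing** — a centered moving average over 3 kept frames; boundary
   points use the truncated (shrinking) window so early post-birth frames
   are retained.
3. **Detrending** (for fluctuation/autocovariance analyses) — subtraction of
   a centered 8-frame moving average, or of a robust (Theil–Sen) line for
   series too short for the moving average.

Filtering and smoothing never alter the raw volume column: filtering only
toggles the ``valid`` flag and smoothing writes a separate
``volume_smooth`` column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Window sizes and fence multiplier for curve cleaning.

    ``fence_mode`` selects the interpretation of the fence rule:
    ``"tukey"`` (default) uses ``[Q1 - k·IQR, Q3 + k·IQR]``; ``"q4"`` takes
    the literal fourth quantile (the window maximum) ± k·IQR.
    """

    outlier_window: int = 11
    fence_k: float = 0.9
    smooth_window: int = 3
    detrend_ma_window: int = 8
    detrend_min_length: int = 24
    fence_mode: str = "tukey"

    def __post_init__(self) -> None:
        if self.outlier_window % 2 == 0 or self.smooth_window % 2 == 0:
            raise PreprocessError("centered windows must be odd")
        if self.fence_k <= 0:
            raise PreprocessError("fence_k must be positive")
        if self.fence_mode not in ("tukey", "q4"):
            raise PreprocessError(f"unknown fence_mode {self.fence_mode!r}")


def filter_outliers(
    values: np.ndarray,
    config: PreprocessConfig | None = None,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Keep-mask from sliding quartile fences.

    For each point, quartiles are computed on the centered window (truncated
    at the series boundaries) and the point is kept iff it lies inside the
    fences. Series shorter than the window are returned unfiltered.
    """
    config = config or PreprocessConfig()
    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is not None:
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise PreprocessError("times must be strictly increasing")
    keep = np.ones(n, dtype=bool)
    if n < config.outlier_window:
        return keep
    half = config.outlier_window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        window = values[lo:hi]
        q1, q3 = np.quantile(window, [0.25, 0.75])
        iqr = q3 - q1
        if config.fence_mode == "tukey":
            lo_fence = q1 - config.fence_k * iqr
            hi_fence = q3 + config.fence_k * iqr
        else:
            q4 = window.max()
            lo_fence = q4 - config.fence_k * iqr
            hi_fence = q4 + config.fence_k * iqr
        if values[i] < lo_fence or values[i] > hi_fence:
            keep[i] = False
    return keep


def smooth(
    values: np.ndarray,
    keep: np.ndarray | None = None,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Centered moving average over kept points.

    Removed points are excluded from every window and stay NaN in the
    output; boundary points average over the truncated window.
    """
    config = config or PreprocessConfig()
    values = np.asarray(values, dtype=float)
    n = len(values)
    if keep is None:
        keep = np.ones(n, dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    half = config.smooth_window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if not keep[i]:
            continue
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        sel = keep[lo:hi]
        out[i] = values[lo:hi][sel].mean()
    return out


def detrend(
    values: np.ndarray,
    times: np.ndarray | None = None,
    config: PreprocessConfig | None = None,
    mode: str = "auto",
) -> np.ndarray:
    """Residuals after removing the slow growth trend.

    ``mode="ma"`` subtracts a centered ``detrend_ma_window``-frame moving
    average; ``mode="linear"`` subtracts a Theil–Sen robust line;
    ``mode="ols"`` subtracts an ordinary-least-squares line — on clean
    series the two lines agree closely, but only the OLS projection has an
    exactly computable effect on the autocovariance, so the
    autocovariance-decay analysis uses it (see
    :func:`volgrowth.noise.fit_autocov_tau`). ``mode="auto"`` picks MA for
    series of at least ``detrend_min_length`` frames and the robust line
    otherwise (short tracks cannot support the 80-min moving average).
    """
    config = config or PreprocessConfig()
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise PreprocessError("detrend needs at least 3 points")
    if times is None:
        times = np.arange(n, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    if mode == "auto":
        mode = "ma" if n >= config.detrend_min_length else "linear"
    if mode == "ma":
        trend = (
            pd.Series(values)
            .rolling(config.detrend_ma_window, center=True, min_periods=2)
            .mean()
            .to_numpy()
        )
        return values - trend
    if mode in ("linear", "ols"):
        if np.ptp(times) == 0:
            raise PreprocessError("times have no spread for the linear detrend")
        if mode == "linear":
            slope, intercept, _, _ = stats.theilslopes(values, times)
        else:
            slope, intercept = np.polyfit(times, values, 1)
        return values - (intercept + slope * times)
    raise PreprocessError(f"unknown detrend mode {mode!r}")


def preprocess_dataset(
    dataset: Dataset, config: PreprocessConfig | None = None
) -> tuple[Dataset, pd.DataFrame]:
    """Apply outlier filtering and smoothing to every cell of a dataset.

    Returns the cleaned dataset (``valid`` updated, ``volume_smooth`` column
    added) and a removals report with one row per removed point
    (``cell_id, frame, reason``).
    """
    config = config or PreprocessConfig()
    out = dataset.copy()
    traj = out.trajectories.sort_values(["cell_id", "frame"]).reset_index(drop=True)
    smooth_col = np.full(len(traj), np.nan)
    valid = traj["valid"].to_numpy(copy=True)
    removals: list[dict] = []
    for cell_id, grp in traj.groupby("cell_id", sort=False):
        idx = grp.index.to_numpy()
        vals = grp["volume_um3"].to_numpy()
        base_valid = grp["valid"].to_numpy()
        keep = filter_outliers(vals, config) & base_valid
        for j in np.nonzero(base_valid & ~keep)[0]:
            removals.append(
                {
                    "cell_id": cell_id,
                    "frame": int(grp["frame"].iloc[j]),
                    "reason": "outlier_fence",
                }
            )
        valid[idx] = keep
        smooth_col[idx] = smooth(vals, keep, config)
    traj["valid"] = valid
    traj["volume_smooth"] = smooth_col
    out.trajectories = traj
    out.provenance = {
        **out.provenance,
        "filters": (
            f"fence({config.fence_mode},k={config.fence_k},"
            f"w={config.outlier_window});smooth(w={config.smooth_window})"
        ),
    }
    report = pd.DataFrame(removals, columns=["cell_id", "frame", "reason"])
    return out, report
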