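"""Windowed growth-rate estimation from cleaned volume trajectories.

Three local estimators are provided, all sliding frame-by-frame along each
cell's track:

* :func:`growth_speed_estimates` — growth speed dV/dt from a robust
  (Theil–Sen) linear fit on short windows (default 5 frames = 50 min) of
  the smoothed curve, plus the specific rate dV/dt / V at the window
  center. Theil–Sen (the median of all pairwise slopes) is deterministic
  and well defined on 5 points; an ordinary-least-squares option exists for
  sensitivity checks.
* :func:`log_return_estimates` — the conditional log return
  ``dq = log V(t+dt) - log V(t)``, conditioned on the volume at the window
  start. To first order ``dq = specific rate × dt``; unlike the variance of
  the specific rate, the Fano factor of dq is predicted to be independent
  of dt under the growth model.
* :func:`discrete_rate_estimates` — the discrete-derivative specific rate
  ``(V(t+dt) - V(t)) / (dt · V(t))`` used for the variance-vs-timescale
  analysis.

Fluctuation estimators default to the outlier-filtered *unsmoothed* volume:
the 3-frame smoother correlates adjacent increments and would distort the
timescale scaling of the variance (see the methods note).

:func:`assign_phase` labels each window G1 / SG2 / excluded from per-cell
annotations, fills time-from-birth, and flags the early post-birth window
(< 1.3 h) so that mean-trend analyses can include it while fluctuation
analyses drop it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .io import Dataset


class RatesError(ValueError):
    pass


EXCLUDED = "excluded"


def theil_sen_slope(values: np.ndarray, times: np.ndarray) -> float:
    """Median of all pairwise slopes (deterministic robust line slope)."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    slopes = [
        (values[j] - values[i]) / (times[j] - times[i])
        for i, j in combinations(range(len(values)), 2)
    ]
    return float(np.median(slopes))


def _window_slopes(win: np.ndarray, t_rel: np.ndarray, method: str) -> np.ndarray:
    """Slopes for a stack of windows ``win`` of shape (n_windows, w)."""
    w = win.shape[1]
    if method == "theil-sen":
        cols = [
            (win[:, j] - win[:, i]) / (t_rel[j] - t_rel[i])
            for i, j in combinations(range(w), 2)
        ]
        return np.median(np.stack(cols, axis=1), axis=1)
    if method == "ols":
        tc = t_rel - t_rel.mean()
        return (win - win.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    raise RatesError(f"unknown slope method {method!r}")


def growth_speed_estimates(
    dataset: Dataset,
    window_frames: int = 5,
    method: str = "theil-sen",
    column: str = "volume_smooth",
) -> pd.DataFrame:
    """Sliding-window growth speed dV/dt and specific rate for every cell.

    Windows slide by one frame. Fully kept windows are fitted on the
    smoothed curve; a window containing fence-flagged frames is fitted on
    its *raw* values instead — the median of pairwise slopes is itself
    insensitive to isolated artifacts, whereas either skipping such
    windows or refitting them without the flagged points selects against
    (or deletes) genuine fluctuations and measurably tilts conditional
    mean speeds. Only windows containing a nonpositive or missing raw
    value are skipped (count in ``result.attrs["n_skipped_windows"]``).
    Columns: cell_id, frame_center, t_center, v_center, v_bin, dvdt,
    specific_rate, dt_window, window_start_h, window_end_h.

    ``v_center`` (the smoothed volume at the window center) divides the
    slope to give the specific rate; ``v_bin`` (the raw volume at the
    window *start*) is the conditioning volume for binned statistics.
    Selecting windows by their own mid-window value would admit a window
    into a volume bin exactly when its internal fluctuation is upward,
    biasing conditional rates near bin boundaries; the start-frame volume
    precedes the increments that enter the slope, so conditioning on it is
    selection-clean (the same convention a log return uses).
    """
    if window_frames < 2 or window_frames % 2 == 0:
        raise RatesError("window_frames must be an odd integer >= 3")
    if column not in dataset.trajectories.columns:
        raise RatesError(f"column {column!r} not in trajectories")
    w = window_frames
    dt = dataset.frame_interval
    t_rel = np.arange(w) * dt
    half = w // 2
    parts: list[pd.DataFrame] = []
    n_skipped = 0
    traj = dataset.trajectories.sort_values(["cell_id", "frame"])
    for cell_id, grp in traj.groupby("cell_id", sort=False):
        vals = grp[column].to_numpy(dtype=float)
        raw = grp["volume_um3"].to_numpy(dtype=float)
        ok = grp["valid"].to_numpy(dtype=bool) & np.isfinite(vals)
        if len(vals) < w:
            continue
        win = np.lib.stride_tricks.sliding_window_view(vals, w)
        raw_win = np.lib.stride_tricks.sliding_window_view(raw, w)
        ok_win = np.lib.stride_tricks.sliding_window_view(ok, w)
        raw_ok = np.lib.stride_tricks.sliding_window_view(
            np.isfinite(raw) & (raw > 0), w
        ).all(axis=1)
        full = ok_win.all(axis=1)
        partial = ~full & raw_ok
        n_skipped += int((~(full | partial)).sum())

        starts_list: list[int] = []
        slopes_list: list[float] = []
        if full.any():
            starts_list.extend(np.nonzero(full)[0].tolist())
            slopes_list.extend(_window_slopes(win[full], t_rel, method).tolist())
        for s in np.nonzero(partial)[0]:
            v_sub = raw_win[s]
            if method == "theil-sen":
                slope = theil_sen_slope(v_sub, t_rel)
            else:
                slope = float(np.polyfit(t_rel, v_sub, 1)[0])
            starts_list.append(int(s))
            slopes_list.append(slope)
        if not starts_list:
            continue
        order = np.argsort(starts_list)
        starts = np.asarray(starts_list)[order]
        slopes = np.asarray(slopes_list)[order]
        frames = grp["frame"].to_numpy()
        centers = starts + half
        v_center = np.where(
            np.isfinite(vals[centers]), vals[centers], raw[centers]
        )
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "frame_center": frames[centers],
                    "t_center": frames[centers] * dt,
                    "v_center": v_center,
                    "v_bin": raw[starts],
                    "dvdt": slopes,
                    "specific_rate": slopes / v_center,
                    "dt_window": w * dt,
                    "window_start_h": (frames[centers] - half) * dt,
                    "window_end_h": (frames[centers] + half) * dt,
                }
            )
        )
    out = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(
            columns=[
                "cell_id",
                "frame_center",
                "t_center",
                "v_center",
                "dvdt",
                "specific_rate",
                "dt_window",
                "window_start_h",
                "window_end_h",
            ]
        )
    )
    out.attrs["n_skipped_windows"] = n_skipped
    return out


def _endpoint_pairs(
    dataset: Dataset, dt: float, column: str
) -> tuple[pd.DataFrame, int]:
    """Per-cell (start, end) volume pairs separated by ``dt``; both endpoints
    must be kept and positive."""
    step = dt / dataset.frame_interval
    k = int(round(step))
    if k < 1 or abs(step - k) > 1e-9:
        raise RatesError(
            f"dt = {dt} h is not a positive integer multiple of the frame "
            f"interval {dataset.frame_interval} h"
        )
    traj = dataset.trajectories.sort_values(["cell_id", "frame"])
    rows: list[pd.DataFrame] = []
    n_skipped = 0
    for cell_id, grp in traj.groupby("cell_id", sort=False):
        vals = grp[column].to_numpy(dtype=float)
        ok = grp["valid"].to_numpy(dtype=bool) & np.isfinite(vals)
        if len(vals) <= k:
            continue
        v0, v1 = vals[:-k], vals[k:]
        pair_ok = ok[:-k] & ok[k:]
        pos = (v0 > 0) & (v1 > 0)
        n_skipped += int((pair_ok & ~pos).sum())
        use = pair_ok & pos
        if not use.any():
            continue
        frames = grp["frame"].to_numpy()[:-k][use]
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "frame_start": frames,
                    "t_start": frames * dataset.frame_interval,
                    "v_start": v0[use],
                    "v_end": v1[use],
                }
            )
        )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["cell_id", "frame_start", "t_start", "v_start", "v_end"]
        )
    )
    return out, n_skipped


def log_return_estimates(
    dataset: Dataset, dt: float, column: str = "volume_um3"
) -> pd.DataFrame:
    """Conditional log returns ``dq = log V(t+dt) - log V(t)``.

    The conditioning volume ``v_start`` is the volume at the interval start.
    ``dt`` must be an integer multiple of the frame interval. Points with a
    nonpositive endpoint are skipped (count in ``attrs["n_skipped"]``).
    """
    pairs, n_skipped = _endpoint_pairs(dataset, dt, column)
    out = pairs.assign(
        dq=np.log(pairs["v_end"].to_numpy() / pairs["v_start"].to_numpy())
        if len(pairs)
        else pd.Series(dtype=float),
        dt=dt,
        t_center=pairs["t_start"] + dt / 2.0,
        window_start_h=pairs["t_start"],
        window_end_h=pairs["t_start"] + dt,
    ).drop(columns=["v_end"])
    out.attrs["n_skipped"] = n_skipped
    return out


def discrete_rate_estimates(
    dataset: Dataset, dt: float, column: str = "volume_um3"
) -> pd.DataFrame:
    """Discrete-derivative specific rate ``(V(t+dt) - V(t)) / (dt V(t))``."""
    pairs, n_skipped = _endpoint_pairs(dataset, dt, column)
    v0 = pairs["v_start"].to_numpy()
    v1 = pairs["v_end"].to_numpy()
    out = pairs.assign(
        specific_rate=(v1 - v0) / (dt * v0) if len(pairs) else pd.Series(dtype=float),
        dt=dt,
        t_center=pairs["t_start"] + dt / 2.0,
        window_start_h=pairs["t_start"],
        window_end_h=pairs["t_start"] + dt,
    ).drop(columns=["v_end"])
    out.attrs["n_skipped"] = n_skipped
    return out


def assign_phase(
    estimates: pd.DataFrame,
    annotations: pd.DataFrame,
    transient_duration: float = 1.3,
    phase_boundary_margin_h: float = 1.0 / 6.0,
) -> pd.DataFrame:
    """Label windowed estimates with cell-cycle phase and time from birth.

    A window is G1 when its center lies in ``[t_birth, t_g1s)`` and SG2 when
    in ``[t_g1s, overshoot_start or t_mitosis)`` (half-open intervals: a
    center exactly at t_g1s is SG2). Windows intersecting the
    mitotic-overshoot interval, lying past the phase range, or belonging to
    cells with missing or inconsistently ordered annotations are
    ``excluded``. ``early_post_birth`` flags windows whose center is within
    ``transient_duration`` of birth; mean-trend analyses may include them,
    fluctuation analyses drop them.
    """
    ann = annotations.set_index("cell_id")
    out = estimates.copy()
    out = out.join(
        ann[["t_birth", "t_g1s", "t_mitosis", "overshoot_start", "overshoot_end"]],
        on="cell_id",
    )
    t = out["t_center"].to_numpy(dtype=float)
    tb = out["t_birth"].to_numpy(dtype=float)
    tg = out["t_g1s"].to_numpy(dtype=float)
    tm = out["t_mitosis"].to_numpy(dtype=float)
    os_, oe = (
        out["overshoot_start"].to_numpy(dtype=float),
        out["overshoot_end"].to_numpy(dtype=float),
    )
    bad_order = (tg < tb) | (tm < tg)  # NaN-safe: comparisons with NaN are False
    skipped_cells = sorted(set(out.loc[bad_order, "cell_id"]))

    end_sg2 = np.where(np.isfinite(os_), os_, np.where(np.isfinite(tm), tm, np.inf))
    phase = np.full(len(out), EXCLUDED, dtype=object)
    has_core = np.isfinite(tb) & np.isfinite(tg)
    g1 = has_core & (t >= tb) & (t < tg)
    sg2 = has_core & (t >= tg) & (t < end_sg2)
    phase[g1] = "G1"
    phase[sg2] = "SG2"
    if "window_start_h" in out.columns:
        ws = out["window_start_h"].to_numpy(dtype=float)
        we = out["window_end_h"].to_numpy(dtype=float)
        in_overshoot = np.isfinite(os_) & (we >= os_) & (ws <= np.where(np.isfinite(oe), oe, np.inf))
        phase[in_overshoot] = EXCLUDED
    phase[bad_order] = EXCLUDED
    out["phase"] = phase
    out["time_from_birth"] = t - tb
    out["early_post_birth"] = (t - tb) < transient_duration
    if "window_start_h" in out.columns:
        ws = out["window_start_h"].to_numpy(dtype=float)
        we = out["window_end_h"].to_numpy(dtype=float)
        # windows that straddle the G1/S transition mix the two phase
        # rates; the margin extends the window by the smoothing reach
        # (one frame) so smoothed edge values do not leak across phases
        m = phase_boundary_margin_h
        straddles = np.isfinite(tg) & (ws - m < tg) & (we + m > tg)
        out["phase_pure"] = ~straddles & (phase != EXCLUDED)
    else:
        out["phase_pure"] = phase != EXCLUDED
    out.attrs["skipped_cells"] = skipped_cells
    out.attrs.update(estimates.attrs)
    return out


def variance_vs_timescale(
    dataset: Dataset,
    dt_list: list[float],
    volume_bin_edges: np.ndarray | None = None,
    annotations: pd.DataFrame | None = None,
    min_cells: int = 100,
    column: str = "volume_um3",
) -> pd.DataFrame:
    """Variance of the discrete-derivative specific rate per volume group
    and derivative timescale.

    Groups are fixed bins of the conditioning volume V(t). When
    ``annotations`` are given, windows in the first 1.3 h after birth or
    outside the phase range are dropped (the fluctuation-analysis gates).
    Under-populated (group, dt) cells (< ``min_cells`` distinct cells) have
    variance NaN.
    """
    if not dt_list:
        raise RatesError("dt_list must not be empty")
    if volume_bin_edges is None:
        volume_bin_edges = np.array([1800.0, 2300.0, 2800.0, 3300.0])
    edges = np.asarray(volume_bin_edges, dtype=float)
    rows = []
    for dt in dt_list:
        est = discrete_rate_estimates(dataset, dt, column=column)
        if annotations is not None:
            est = assign_phase(est, annotations)
            est = est[(est["phase"] != EXCLUDED) & ~est["early_post_birth"]]
        grp_idx = np.digitize(est["v_start"].to_numpy(), edges) - 1
        for g in range(len(edges) - 1):
            sel = est[grp_idx == g]
            n_cells = sel["cell_id"].nunique()
            rows.append(
                {
                    "v_low": edges[g],
                    "v_high": edges[g + 1],
                    "dt": dt,
                    "var_specific_rate": (
                        float(sel["specific_rate"].var(ddof=1))
                        if n_cells >= min_cells
                        else np.nan
                    ),
                    "n_points": len(sel),
                    "n_cells": n_cells,
                }
            )
    return pd.DataFrame(rows)
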