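"""Population-level growth analyses: conditional binned statistics, the
growth-mode (exponential vs linear) test, the phase-resolved specific rate,
and the newborn transient.

The growth-mode test estimates the mean specific growth rate two ways and
compares them: (i) the slope α of the binned conditional average of growth
speed dV/dt against volume V, and (ii) the unconditional average
⟨(1/V) dV/dt⟩ over the same points. Under average exponential growth the two
agree; under linear growth (dV/dt constant) the slope is ~0 while the mean
specific rate stays positive, so the relative discrepancy
``|slope - mean rate| / mean rate`` discriminates the modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rates import EXCLUDED


class PopStatsError(ValueError):
    pass


def bin_conditional(
    estimates: pd.DataFrame,
    x_field: str,
    y_field: str,
    width: float,
    min_cells: int = 1,
    sliding: bool = False,
    step: float | None = None,
    x_range: tuple[float, float] | None = None,
    weighting: str = "points",
) -> pd.DataFrame:
    """Conditional mean/sd/sem of ``y_field`` in bins of ``x_field``.

    Fixed non-overlapping bins by default; ``sliding=True`` uses overlapping
    windows of the stated width advanced by ``step`` (default width/2).
    ``n_cells`` counts distinct cell ids and bins with fewer than
    ``min_cells`` are suppressed; ``sem = sd / sqrt(n_cells)`` so clustered
    within-cell windows are not over-counted. ``weighting="cells"`` averages
    per-cell means instead of pooling all windows.
    """
    if width <= 0:
        raise PopStatsError("bin width must be positive")
    if len(estimates) == 0:
        raise PopStatsError("no estimates to bin")
    if weighting not in ("points", "cells"):
        raise PopStatsError(f"unknown weighting {weighting!r}")
    x = estimates[x_field].to_numpy(dtype=float)
    lo, hi = x_range if x_range is not None else (np.nanmin(x), np.nanmax(x))
    if sliding:
        step = width / 2.0 if step is None else step
        centers = np.arange(lo + width / 2.0, hi - width / 2.0 + 1e-9, step)
        intervals = [(c - width / 2.0, c + width / 2.0) for c in centers]
    else:
        edges = np.arange(lo, hi + width, width)
        intervals = list(zip(edges[:-1], edges[1:]))
        centers = [0.5 * (a + b) for a, b in intervals]
    rows = []
    for center, (a, b) in zip(centers, intervals):
        sel = estimates[(x >= a) & (x < b)]
        n_cells = sel["cell_id"].nunique()
        if n_cells < min_cells or len(sel) == 0:
            continue
        if weighting == "cells":
            y = sel.groupby("cell_id")[y_field].mean().to_numpy()
        else:
            y = sel[y_field].to_numpy(dtype=float)
        sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
        rows.append(
            {
                "bin_center": float(center),
                "bin_width": width,
                "mean": float(np.mean(y)),
                "sd": sd,
                "sem": sd / np.sqrt(n_cells),
                "n_points": len(sel),
                "n_cells": n_cells,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bin_center", "bin_width", "mean", "sd", "sem", "n_points", "n_cells"],
    )


@dataclass
class AlphaFit:
    """Result of the growth-mode test (binned dV/dt vs V fit)."""

    slope_alpha: float
    intercept: float
    slope_se: float
    mean_specific_rate: float
    volume_range: tuple[float, float]
    n_cells: int
    n_bins: int
    exponentiality_diagnostic: float
    bins: pd.DataFrame = field(repr=False)


def fit_alpha(
    estimates: pd.DataFrame,
    volume_range: tuple[float, float] = (1800.0, 4000.0),
    bin_width: float = 250.0,
    min_cells: int = 25,
    weighting: str = "binned",
    exclude_early: bool = True,
) -> AlphaFit:
    """Estimate α from the conditional trend of growth speed vs volume.

    Least squares of binned mean dV/dt against bin-center volume inside
    ``volume_range``. The default weights each bin by its distinct-cell
    count, so sparsely populated extreme-volume bins do not dominate the
    slope noise; ``weighting="binned-equal"`` reproduces an equal-weight
    fit of the binned points and ``weighting="points"`` fits the raw
    windows. Also returns the unconditional ⟨(1/V) dV/dt⟩ over the same
    points and the exponentiality diagnostic
    ``|slope - mean rate| / mean rate``.

    Windows in the first 1.3 h after birth follow a distinct growth pattern
    and are excluded by default when phase labels are present.
    """
    est = estimates
    if exclude_early and "early_post_birth" in est.columns:
        est = est[~est["early_post_birth"]]
    if "phase" in est.columns:
        est = est[est["phase"] != EXCLUDED]
    vcol = "v_bin" if "v_bin" in est.columns else "v_center"
    lo, hi = volume_range
    est = est[(est[vcol] >= lo) & (est[vcol] < hi)]
    if len(est) == 0:
        raise PopStatsError("no estimates inside the volume range")
    if np.ptp(est[vcol].to_numpy()) <= 0:
        raise PopStatsError("degenerate volume spread")
    bins = bin_conditional(
        est, vcol, "dvdt", bin_width, min_cells=min_cells, x_range=volume_range
    )
    if len(bins) < 2:
        raise PopStatsError(
            f"need >= 2 populated bins in {volume_range}, got {len(bins)}"
        )
    if weighting == "binned":
        w = bins["n_cells"].to_numpy(dtype=float)
        x = np.stack([np.ones(len(bins)), bins["bin_center"].to_numpy()], axis=1)
        xtwx = x.T @ (w[:, None] * x)
        beta = np.linalg.solve(xtwx, x.T @ (w * bins["mean"].to_numpy()))
        resid = bins["mean"].to_numpy() - x @ beta
        dof = max(len(bins) - 2, 1)
        s2 = float((w * resid**2).sum() / w.sum()) * len(bins) / dof
        cov = np.linalg.inv(xtwx) * s2 * w.mean()
        slope, intercept = float(beta[1]), float(beta[0])
        slope_se = float(np.sqrt(cov[1, 1]))
    elif weighting == "binned-equal":
        fit = stats.linregress(bins["bin_center"], bins["mean"])
        slope, intercept, slope_se = fit.slope, fit.intercept, fit.stderr
    elif weighting == "points":
        fit = stats.linregress(est[vcol], est["dvdt"])
        slope, intercept, slope_se = fit.slope, fit.intercept, fit.stderr
    else:
        raise PopStatsError(f"unknown weighting {weighting!r}")
    mean_rate = float(est["specific_rate"].mean())
    return AlphaFit(
        slope_alpha=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        mean_specific_rate=mean_rate,
        volume_range=volume_range,
        n_cells=est["cell_id"].nunique(),
        n_bins=len(bins),
        exponentiality_diagnostic=abs(slope - mean_rate) / abs(mean_rate),
        bins=bins,
    )


@dataclass
class PhaseComparison:
    """Phase-resolved specific growth rate and the S-G2 / G1 ratio."""

    ratio: float
    ratio_se: float
    mean_g1: float
    mean_sg2: float
    common_support: tuple[float, float]
    bins_g1: pd.DataFrame = field(repr=False)
    bins_sg2: pd.DataFrame = field(repr=False)
    warning: str | None = None


def phase_rate_comparison(
    estimates: pd.DataFrame,
    bin_width: float = 200.0,
    min_cells: int = 100,
    exclude_early: bool = True,
    volume_range: tuple[float, float] = (1800.0, 3100.0),
) -> PhaseComparison:
    """Binned specific rate vs volume per phase and the ratio of phase means.

    The ratio mean(SG2)/mean(G1) is computed over points in the common
    volume support (bins populated in both phases, intersected with
    ``volume_range`` — the interval where the specific rate is flat in
    volume within each phase, so the ratio is insensitive to the phases'
    different volume composition), with a per-cell clustered standard
    error. The early post-birth window is excluded by default (distinct
    growth regime).
    """
    est = estimates
    if exclude_early and "early_post_birth" in est.columns:
        est = est[~est["early_post_birth"]]
    if "phase_pure" in est.columns:
        est = est[est["phase_pure"]]
    vgate = "v_bin" if "v_bin" in est.columns else "v_center"
    if volume_range is not None:
        est = est[(est[vgate] >= volume_range[0]) & (est[vgate] < volume_range[1])]
    g1 = est[est["phase"] == "G1"]
    sg2 = est[est["phase"] == "SG2"]
    warning = None
    if len(g1) == 0 or len(sg2) == 0:
        raise PopStatsError("both phases must be populated")
    vcol = "v_bin" if "v_bin" in est.columns else "v_center"
    # shared bin grid so the per-phase bin centers align
    vmin = float(min(g1[vcol].min(), sg2[vcol].min()))
    vmax = float(max(g1[vcol].max(), sg2[vcol].max()))
    grid = (np.floor(vmin / bin_width) * bin_width,
            np.ceil(vmax / bin_width) * bin_width)
    bins_g1 = bin_conditional(g1, vcol, "specific_rate", bin_width, min_cells,
                              x_range=grid)
    bins_sg2 = bin_conditional(sg2, vcol, "specific_rate", bin_width, min_cells,
                               x_range=grid)
    merged = bins_g1.merge(
        bins_sg2, on="bin_center", suffixes=("_g1", "_sg2")
    )
    if len(merged) == 0:
        raise PopStatsError(
            "no common volume support at the cell-count threshold"
        )
    lo = merged["bin_center"].min() - bin_width / 2.0
    hi = merged["bin_center"].max() + bin_width / 2.0
    # identical per-bin weights for both phases, so the ratio compares the
    # phases at matched volumes and is immune to their different volume
    # composition; inverse-variance weights of the per-bin pair difference
    # keep sparse, noisy bins from dominating
    w = 1.0 / (merged["sem_g1"] ** 2 + merged["sem_sg2"] ** 2)
    mean_g1 = float(np.average(merged["mean_g1"], weights=w))
    mean_sg2 = float(np.average(merged["mean_sg2"], weights=w))
    ratio = mean_sg2 / mean_g1
    wsum = float(w.sum())
    se_g1 = float(np.sqrt((w**2 * merged["sem_g1"] ** 2).sum()) / wsum)
    se_sg2 = float(np.sqrt((w**2 * merged["sem_sg2"] ** 2).sum()) / wsum)
    ratio_se = abs(ratio) * np.sqrt(
        (se_g1 / mean_g1) ** 2 + (se_sg2 / mean_sg2) ** 2
    )
    return PhaseComparison(
        ratio=ratio,
        ratio_se=float(ratio_se),
        mean_g1=mean_g1,
        mean_sg2=mean_sg2,
        common_support=(float(lo), float(hi)),
        bins_g1=bins_g1,
        bins_sg2=bins_sg2,
        warning=warning,
    )


@dataclass
class NewbornTransient:
    """Growth speed vs time from birth per birth-volume group."""

    curves: pd.DataFrame = field(repr=False)
    group_sizes: dict = field(default_factory=dict)
    birth_cutoffs: tuple[float, float] = (np.nan, np.nan)
    first_hour_mean: dict = field(default_factory=dict)
    alpha_ref: float = np.nan
    early_spread: float = np.nan
    late_spread: float = np.nan
    convergence_ratio: float = np.nan


def newborn_transient(
    estimates: pd.DataFrame,
    annotations: pd.DataFrame,
    birth_groups: tuple[float, float, float] = (0.2, 0.6, 0.2),
    transient_duration: float = 1.3,
    max_time: float = 4.0,
    window_h: float = 1.0 / 3.0,
    step_h: float = 1.0 / 6.0,
    min_cells: int = 25,
    min_birth_cells: int = 50,
) -> NewbornTransient:
    """Sliding-average growth speed vs time from birth, split by birth volume.

    Cells are split into smallest / middle / largest birth-volume groups by
    the empirical quantiles implied by ``birth_groups``. The early
    (< ``transient_duration``) region is deliberately included.

    Convergence is measured on the *excess* growth speed
    ``dvdt - α_ref · V`` (α_ref: the median specific rate of
    post-transient windows), because raw speeds retain a structural α·ΔV
    offset between groups that persists after the transient has died out.
    ``convergence_ratio = late_spread / early_spread`` contrasts the
    max-minus-min of group mean excess speeds averaged over
    ``[transient_duration, transient_duration + 1 h]`` against the first
    hour; a small ratio means the groups have collapsed onto the common
    exponential baseline by the end of the transient.
    """
    ann = annotations.dropna(subset=["t_birth", "birth_volume"])
    if len(ann) < min_birth_cells:
        raise PopStatsError(
            f"only {len(ann)} annotated births; need >= {min_birth_cells}"
        )
    q_lo = float(ann["birth_volume"].quantile(birth_groups[0]))
    q_hi = float(ann["birth_volume"].quantile(1.0 - birth_groups[2]))
    group_of = pd.Series(
        np.where(
            ann["birth_volume"] < q_lo,
            "smallest",
            np.where(ann["birth_volume"] >= q_hi, "largest", "middle"),
        ),
        index=ann["cell_id"],
    )
    est = estimates[estimates["time_from_birth"].notna()].copy()
    est = est[(est["time_from_birth"] >= 0) & (est["time_from_birth"] <= max_time)]
    est["birth_group"] = est["cell_id"].map(group_of)
    est = est[est["birth_group"].notna()]

    post = est[est["time_from_birth"] >= transient_duration + 0.2]
    alpha_ref = (
        float(post["specific_rate"].median()) if len(post) else np.nan
    )
    est["excess"] = est["dvdt"] - alpha_ref * est["v_center"]

    centers = np.arange(window_h / 2.0, max_time - window_h / 2.0 + 1e-9, step_h)
    rows = []
    for group, gdf in est.groupby("birth_group"):
        tfb = gdf["time_from_birth"].to_numpy()
        for c in centers:
            sel = gdf[(tfb >= c - window_h / 2.0) & (tfb < c + window_h / 2.0)]
            n_cells = sel["cell_id"].nunique()
            if n_cells < min_cells:
                continue
            sd = float(sel["dvdt"].std(ddof=1))
            rows.append(
                {
                    "birth_group": group,
                    "t_center": float(c),
                    "mean_dvdt": float(sel["dvdt"].mean()),
                    "mean_excess": float(sel["excess"].mean()),
                    "sem": sd / np.sqrt(n_cells),
                    "n_points": len(sel),
                    "n_cells": n_cells,
                }
            )
    curves = pd.DataFrame(rows)

    def _band_mean(col: str, group: str, lo: float, hi: float) -> float:
        sel = curves[
            (curves["birth_group"] == group)
            & (curves["t_center"] >= lo)
            & (curves["t_center"] < hi)
        ]
        return float(sel[col].mean()) if len(sel) else np.nan

    groups = ["smallest", "middle", "largest"]
    first_hour = {g: _band_mean("mean_dvdt", g, 0.0, 1.0) for g in groups}
    early = [
        v
        for v in (_band_mean("mean_excess", g, 0.0, 1.0) for g in groups)
        if np.isfinite(v)
    ]
    late = [
        v
        for v in (
            _band_mean(
                "mean_excess", g, transient_duration, transient_duration + 1.0
            )
            for g in groups
        )
        if np.isfinite(v)
    ]
    early_spread = max(early) - min(early) if len(early) >= 2 else np.nan
    late_spread = max(late) - min(late) if len(late) >= 2 else np.nan
    return NewbornTransient(
        curves=curves,
        group_sizes=group_of.value_counts().to_dict(),
        birth_cutoffs=(q_lo, q_hi),
        first_hour_mean=first_hour,
        alpha_ref=alpha_ref,
        early_spread=early_spread,
        late_spread=late_spread,
        convergence_ratio=(
            late_spread / early_spread
            if np.isfinite(early_spread) and early_spread > 0
            else np.nan
        ),
    )
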