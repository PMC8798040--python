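"""Stochastic model of single-cell volume growth.

The generative model treats cell volume :math:`V(t)` (µm³) as a Langevin
process

.. math::

    \\frac{dV}{dt} = \\alpha V + \\nu_\\alpha V^{\\gamma},

where :math:`\\alpha` is the mean specific growth rate (h⁻¹),
:math:`\\nu_\\alpha` is Gaussian white noise of amplitude ``sigma``, and the
exponent :math:`\\gamma \\in [0, 1]` interpolates between two limiting noise
geometries:

* ``gamma = 0`` — *additive* noise: fluctuations of constant amplitude act
  directly on the growth speed dV/dt, independent of cell size.
* ``gamma = 1`` — *multiplicative* noise: the specific growth rate itself
  fluctuates, so the fluctuation amplitude scales with volume (geometric
  Brownian motion).

Trajectories are integrated with an Euler–Maruyama scheme (Itô convention)
on a sub-frame grid and sampled at the imaging frame interval. On top of the
single-cell dynamics, :func:`simulate_population` adds the cell-cycle
structure seen in proliferating HeLa-like cultures: lognormal birth volumes,
a G1 → S-G2 switch with a higher specific rate in S-G2, division into two
near-equal daughters, asynchronous founders, a post-birth transient during
which the largest-born cells transiently lose volume, and additive Gaussian
measurement noise per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PHASE_G1 = "G1"
PHASE_SG2 = "SG2"

TRAJECTORY_COLUMNS = ["cell_id", "frame", "time_h", "volume_um3", "valid"]
ANNOTATION_COLUMNS = [
    "cell_id",
    "parent_id",
    "t_birth",
    "t_g1s",
    "t_mitosis",
    "overshoot_start",
    "overshoot_end",
    "birth_volume",
]


class SimulationError(ValueError):
    """Raised for invalid model parameters or simulation inputs."""


@dataclass
class GrowthModelParams:
    """Parameters of the stochastic growth model and cell-cycle structure.

    Attributes
    ----------
    alpha_g1, alpha_sg2:
        Specific growth rates in G1 and S-G2 (h⁻¹). The ~15% higher S-G2
        rate observed in the data corresponds to ``alpha_sg2/alpha_g1 = 1.15``.
    gamma:
        Noise-interpolation exponent in [0, 1].
    sigma:
        Noise amplitude, units µm^{3(1-gamma)}·h^{-1/2}.
    frame_interval:
        Sampling (imaging) interval in hours; default 10 min.
    sim_substeps:
        Euler–Maruyama substeps per frame; default 10 (1-min steps), which
        makes the frame-sampled process insensitive to the step size.
    meas_noise_sd:
        Additive Gaussian measurement noise per frame (µm³), applied after
        the dynamics.
    birth_volume_mean, birth_volume_cv:
        Lognormal distribution of birth volumes (µm³, dimensionless).
    g1_duration_mean, g1_duration_cv, sg2_duration_mean, sg2_duration_cv:
        Independent lognormal phase durations (h, dimensionless). Defaults
        give ~15.5 h cycles so that e^{∫α dt} ≈ 2 and the birth-volume
        distribution stays near-stationary across generations (no explicit
        size-homeostasis mechanism is modelled).
    division_cv:
        CV of the daughter volume fraction around 0.5.
    transient_duration, transient_enabled:
        Post-birth transient: for ``transient_duration`` hours after birth
        (default 1.3 h) the deterministic drift ramps linearly from a
        birth-volume-dependent starting speed s0 to the steady drift α·V.
    transient_slope_large, transient_slope_other:
        s0 = coefficient × α_G1 × birth volume; the "large" coefficient
        (negative) applies to cells above the ``large_birth_quantile`` of
        the birth-volume distribution, the "other" (small positive) to the
        rest.
    growth_mode:
        "exponential" (drift α·V) or "linear" (drift = ``linear_speed``,
        a constant growth speed; used to test growth-mode discrimination).
    linear_speed:
        Constant growth speed (µm³/h) for ``growth_mode="linear"``; when
        None, defaults to ``alpha_g1 * birth_volume_mean``.
    volume_floor:
        Reflecting floor (µm³) guarding against the rare negative
        excursions of additive noise; floor hits are counted.
    seed:
        RNG seed for :func:`simulate_population`.
    """

    alpha_g1: float = 0.040
    alpha_sg2: float = 0.046
    gamma: float = 0.0
    sigma: float = 85.0
    frame_interval: float = 1.0 / 6.0
    sim_substeps: int = 10
    meas_noise_sd: float = 10.0
    birth_volume_mean: float = 1600.0
    birth_volume_cv: float = 0.15
    g1_duration_mean: float = 8.0
    g1_duration_cv: float = 0.3
    sg2_duration_mean: float = 7.5
    sg2_duration_cv: float = 0.2
    division_cv: float = 0.04
    transient_duration: float = 1.3
    transient_enabled: bool = True
    transient_slope_large: float = -2.0
    transient_slope_other: float = 0.25
    large_birth_quantile: float = 0.8
    growth_mode: str = "exponential"
    linear_speed: float | None = None
    volume_floor: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise SimulationError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.frame_interval <= 0:
            raise SimulationError("frame_interval must be positive")
        if self.sim_substeps < 1:
            raise SimulationError("sim_substeps must be >= 1")
        if self.growth_mode not in ("exponential", "linear"):
            raise SimulationError(f"unknown growth_mode {self.growth_mode!r}")
        nonneg = dict(
            alpha_g1=self.alpha_g1,
            alpha_sg2=self.alpha_sg2,
            sigma=self.sigma,
            meas_noise_sd=self.meas_noise_sd,
            birth_volume_mean=self.birth_volume_mean,
            birth_volume_cv=self.birth_volume_cv,
            g1_duration_mean=self.g1_duration_mean,
            g1_duration_cv=self.g1_duration_cv,
            sg2_duration_mean=self.sg2_duration_mean,
            sg2_duration_cv=self.sg2_duration_cv,
            division_cv=self.division_cv,
            transient_duration=self.transient_duration,
            volume_floor=self.volume_floor,
        )
        for name, value in nonneg.items():
            if value < 0:
                raise SimulationError(f"{name} must be >= 0, got {value}")

    @property
    def substep(self) -> float:
        """Integration step Δ in hours."""
        return self.frame_interval / self.sim_substeps

    def drift_speed(self, alpha: float, v: float) -> float:
        """Deterministic drift (µm³/h) at volume ``v`` for phase rate ``alpha``."""
        if self.growth_mode == "linear":
            s = self.linear_speed
            return self.alpha_g1 * self.birth_volume_mean if s is None else s
        return alpha * v

    def birth_volume_ppf(self, q: float) -> float:
        """Quantile of the lognormal birth-volume distribution."""
        mu, s = _lognormal_mu_sigma(self.birth_volume_mean, self.birth_volume_cv)
        return float(stats.lognorm.ppf(q, s, scale=math.exp(mu)))


def _lognormal_mu_sigma(mean: float, cv: float) -> tuple[float, float]:
    s2 = math.log1p(cv * cv)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _sample_lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    mu, s = _lognormal_mu_sigma(mean, cv)
    return float(rng.lognormal(mu, s))


def _integrate_cell(
    params: GrowthModelParams,
    v_birth: float,
    i_birth: int,
    i_stop: int,
    alpha_steps: Sequence[float],
    s0: float | None,
    rng: np.random.Generator,
    include_end: bool,
) -> tuple[list[tuple[int, float]], float, int]:
    """Euler–Maruyama integration on the substep grid.

    Integrates from absolute substep index ``i_birth`` to ``i_stop`` and
    samples the volume at every frame boundary (substep index divisible by
    ``sim_substeps``) lying in ``[max(i_birth, 0), i_stop]``; the endpoint is
    sampled only when ``include_end`` is true (a cell that divides is not
    observed at the division instant).

    Returns ``(samples, v_end, n_clip)`` where ``samples`` is a list of
    ``(frame_index, volume)`` pairs and ``v_end`` the volume at ``i_stop``.
    """
    n_steps = i_stop - i_birth
    if n_steps < 0:
        raise SimulationError("i_stop must be >= i_birth")
    delta = params.substep
    sqrt_delta = math.sqrt(delta)
    sigma = params.sigma
    gamma = params.gamma
    floor = params.volume_floor
    sub = params.sim_substeps
    ramp_steps = (
        int(round(params.transient_duration / delta))
        if (params.transient_enabled and s0 is not None)
        else 0
    )
    xi = rng.standard_normal(n_steps).tolist()
    alphas = list(alpha_steps)
    if len(alphas) != n_steps:
        raise SimulationError("alpha_steps length must equal the number of steps")

    samples: list[tuple[int, float]] = []
    v = float(v_birth)
    n_clip = 0
    for k in range(n_steps + 1):
        i = i_birth + k
        if i >= 0 and i % sub == 0:
            if k < n_steps or include_end:
                samples.append((i // sub, v))
        if k == n_steps:
            break
        base = params.drift_speed(alphas[k], v)
        if k < ramp_steps:
            frac = k / ramp_steps
            drift = s0 + (base - s0) * frac
        else:
            drift = base
        v = v + drift * delta + sigma * (v ** gamma) * sqrt_delta * xi[k]
        if v < floor:
            v = floor
            n_clip += 1
    return samples, v, n_clip


def simulate_trajectory(
    params: GrowthModelParams,
    v0: float,
    duration: float,
    phase_schedule: Sequence[tuple[str, float]] | None = None,
    rng: np.random.Generator | None = None,
    s0: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a single cell's volume trajectory (pre-measurement-noise).

    Parameters
    ----------
    v0:
        Initial volume (µm³), > 0.
    duration:
        Track length in hours, > 0.
    phase_schedule:
        Ordered ``(phase_label, start_h)`` pairs with labels "G1"/"SG2"
        selecting the phase-specific rate; defaults to G1 throughout.
    s0:
        Optional post-birth transient starting speed (µm³/h); when given and
        ``params.transient_enabled``, the drift ramps linearly from ``s0``
        to the steady drift over ``params.transient_duration``.

    Returns
    -------
    (table, info):
        ``table`` has columns cell_id, frame, time_h, volume_um3, valid;
        ``info`` reports ``n_clip`` (volume-floor hits), ``n_steps`` and
        ``clip_warning`` (true when more than 1% of steps were clipped).
    """
    if v0 <= 0:
        raise SimulationError(f"initial volume must be positive, got {v0}")
    if duration <= 0:
        raise SimulationError(f"duration must be positive, got {duration}")
    if params.alpha_g1 * params.substep >= 0.05:
        raise SimulationError("substep too coarse: alpha * substep must be < 0.05")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if phase_schedule is None:
        phase_schedule = [(PHASE_G1, 0.0)]
    delta = params.substep
    n_steps = int(round(duration / delta))
    alpha_of = {PHASE_G1: params.alpha_g1, PHASE_SG2: params.alpha_sg2}
    starts = [s for _, s in phase_schedule]
    if starts != sorted(starts):
        raise SimulationError("phase_schedule must be ordered by start time")
    labels = [lab for lab, _ in phase_schedule]
    step_times = np.arange(n_steps) * delta
    idx = np.searchsorted(np.asarray(starts), step_times, side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    try:
        alpha_steps = [alpha_of[labels[j]] for j in idx]
    except KeyError as exc:  # pragma: no cover - defensive
        raise SimulationError(f"unknown phase label {exc}") from exc

    samples, _, n_clip = _integrate_cell(
        params, v0, 0, n_steps, alpha_steps, s0, rng, include_end=True
    )
    frames = np.array([f for f, _ in samples], dtype=int)
    vols = np.array([v for _, v in samples], dtype=float)
    table = pd.DataFrame(
        {
            "cell_id": "cell0000",
            "frame": frames,
            "time_h": frames * params.frame_interval,
            "volume_um3": vols,
            "valid": True,
        }
    )[TRAJECTORY_COLUMNS]
    info = {
        "n_clip": n_clip,
        "n_steps": n_steps,
        "clip_warning": n_clip > 0.01 * max(n_steps, 1),
    }
    return table, info


def analytic_moments(
    alpha: float, gamma: float, sigma: float, v0: float, t: float
) -> tuple[float, float]:
    """Closed-form ensemble mean and variance in the two noise limits.

    For additive noise (``gamma = 0``)::

        mean = v0 * exp(alpha t)
        var  = sigma^2 * (exp(2 alpha t) - 1) / (2 alpha)

    For multiplicative noise (``gamma = 1``, geometric Brownian motion)::

        mean = v0 * exp(alpha t)
        var  = v0^2 * exp(2 alpha t) * (exp(sigma^2 t) - 1)

    Only the two limits admit closed forms; other values of gamma are
    rejected.
    """
    if gamma not in (0, 1):
        raise SimulationError("analytic moments exist only for gamma in {0, 1}")
    mean = v0 * math.exp(alpha * t)
    if gamma == 0:
        if alpha == 0:
            var = sigma * sigma * t
        else:
            var = sigma * sigma * (math.exp(2 * alpha * t) - 1.0) / (2 * alpha)
    else:
        var = v0 * v0 * math.exp(2 * alpha * t) * math.expm1(sigma * sigma * t)
    return mean, var


def simulate_ensemble(
    alpha: float,
    gamma: float,
    sigma: float,
    v0: float,
    t: float,
    n_rep: int,
    n_steps: int = 300,
    rng: np.random.Generator | None = None,
    floor: float = 1.0,
) -> np.ndarray:
    """Vectorized Euler–Maruyama ensemble: volume of ``n_rep`` replicates at time ``t``.

    Used to cross-check :func:`analytic_moments` and the per-cell integrator.
    """
    if rng is None:
        rng = np.random.default_rng()
    dt = t / n_steps
    sq = math.sqrt(dt)
    v = np.full(n_rep, float(v0))
    for _ in range(n_steps):
        v = v + alpha * v * dt + sigma * (v ** gamma) * sq * rng.standard_normal(n_rep)
        np.clip(v, floor, None, out=v)
    return v


def ou_series(
    n: int,
    dt: float,
    tau: float,
    sd: float,
    rng: np.random.Generator,
    n_tracks: int = 1,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise, exact discretization.

    Returns an ``(n_tracks, n)`` array with autocovariance
    ``sd² · exp(-lag/tau)``; emulates temporally correlated measurement
    noise for autocovariance-recovery checks.
    """
    a = math.exp(-dt / tau)
    b = sd * math.sqrt(1.0 - a * a)
    x = np.empty((n_tracks, n))
    x[:, 0] = sd * rng.standard_normal(n_tracks)
    for k in range(1, n):
        x[:, k] = a * x[:, k - 1] + b * rng.standard_normal(n_tracks)
    return x


def simulate_population(
    params: GrowthModelParams,
    n_founders: int,
    duration: float,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate an asynchronously growing population for ``duration`` hours.

    Founders are drawn from the birth-volume distribution with a uniformly
    random cell-cycle age (their birth therefore precedes the observation
    window); cells switch from ``alpha_g1`` to ``alpha_sg2`` at their
    sampled G1/S time and divide at their sampled mitosis time into two
    daughters whose volumes sum exactly to the mother's pre-division volume.
    During the first ``transient_duration`` after birth the drift ramps from
    a starting speed s0 — negative for cells born in the top
    ``1 - large_birth_quantile`` fraction of birth volumes, small positive
    otherwise — up to the steady drift. Measurement noise is added
    independently per frame after the dynamics.

    Returns ``(trajectories, annotations, info)``; annotations record the
    sampled event times exactly (including events beyond the observation
    window, as synthetic ground truth).
    """
    if n_founders < 1:
        raise SimulationError("n_founders must be >= 1")
    if duration < params.frame_interval:
        raise SimulationError("duration must cover at least one frame interval")
    rng = np.random.default_rng(params.seed)
    delta = params.substep
    sub = params.sim_substeps
    n_sub_total = int(round(duration / delta))
    q_large = params.birth_volume_ppf(params.large_birth_quantile)

    queue: list[tuple[float, int, str | None]] = []
    for _ in range(n_founders):
        vb = _sample_lognormal(rng, params.birth_volume_mean, params.birth_volume_cv)
        d_g1 = _sample_lognormal(rng, params.g1_duration_mean, params.g1_duration_cv)
        d_sg2 = _sample_lognormal(rng, params.sg2_duration_mean, params.sg2_duration_cv)
        age = rng.uniform(0.0, d_g1 + d_sg2)
        i_birth = -int(round(age / delta))
        queue.append((vb, i_birth, None, d_g1, d_sg2))  # type: ignore[arg-type]

    traj_parts: list[pd.DataFrame] = []
    ann_rows: list[dict] = []
    n_clip_total = 0
    n_steps_total = 0
    counter = 0
    head = 0
    while head < len(queue):
        vb, i_birth, parent_id, d_g1, d_sg2 = queue[head]  # type: ignore[misc]
        head += 1
        cell_id = f"c{counter:04d}"
        counter += 1
        i_g1s = i_birth + int(round(d_g1 / delta))
        i_div = i_g1s + int(round(d_sg2 / delta))
        i_stop = min(i_div, n_sub_total)
        divides = i_div <= n_sub_total
        if params.transient_enabled:
            coef = (
                params.transient_slope_large
                if vb >= q_large
                else params.transient_slope_other
            )
            s0 = coef * params.alpha_g1 * vb
        else:
            s0 = None
        n_steps = i_stop - i_birth
        n_g1_steps = min(max(i_g1s - i_birth, 0), n_steps)
        alpha_steps = [params.alpha_g1] * n_g1_steps + [params.alpha_sg2] * (
            n_steps - n_g1_steps
        )
        samples, v_end, n_clip = _integrate_cell(
            params,
            vb,
            i_birth,
            i_stop,
            alpha_steps,
            s0,
            rng,
            include_end=not divides,
        )
        n_clip_total += n_clip
        n_steps_total += n_steps
        if samples:
            frames = np.array([f for f, _ in samples], dtype=int)
            vols = np.array([v for _, v in samples], dtype=float)
            traj_parts.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_id,
                        "frame": frames,
                        "time_h": frames * params.frame_interval,
                        "volume_um3": vols,
                        "valid": True,
                    }
                )
            )
            ann_rows.append(
                {
                    "cell_id": cell_id,
                    "parent_id": parent_id,
                    "t_birth": i_birth * delta,
                    "t_g1s": i_g1s * delta,
                    "t_mitosis": i_div * delta,
                    "overshoot_start": np.nan,
                    "overshoot_end": np.nan,
                    "birth_volume": vb,
                }
            )
        if divides:
            f = 0.5 + rng.normal(0.0, 0.5 * params.division_cv)
            f = min(max(f, 0.01), 0.99)
            for frac in (f, 1.0 - f):
                dg1 = _sample_lognormal(
                    rng, params.g1_duration_mean, params.g1_duration_cv
                )
                dsg2 = _sample_lognormal(
                    rng, params.sg2_duration_mean, params.sg2_duration_cv
                )
                if i_div < n_sub_total:
                    queue.append((frac * v_end, i_div, cell_id, dg1, dsg2))  # type: ignore[arg-type]

    trajectories = (
        pd.concat(traj_parts, ignore_index=True)
        if traj_parts
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    if params.meas_noise_sd > 0 and len(trajectories):
        trajectories["volume_um3"] = trajectories[
            "volume_um3"
        ] + params.meas_noise_sd * rng.standard_normal(len(trajectories))
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    info = {
        "n_cells": len(ann_rows),
        "n_founders": n_founders,
        "n_clip": n_clip_total,
        "n_steps": n_steps_total,
        "clip_warning": n_clip_total > 0.01 * max(n_steps_total, 1),
        "large_birth_cutoff": q_large,
    }
    return trajectories[TRAJECTORY_COLUMNS], annotations, info
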