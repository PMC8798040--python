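# volgrowth

Analysis of single-cell **volume growth trajectories** from live-cell
imaging: what is the mean growth mode of proliferating animal cells
(exponential vs linear), how does the volume-specific growth rate change
across the cell cycle, and — the central question — what is the *geometry*
of the growth fluctuations: do cells add noisy volume increments of
constant amplitude (additive noise), or does the specific growth rate
itself fluctuate (multiplicative noise)?

The package is aimed at quantitative cell biologists working with
fluorescence-exclusion (FXm) or similar volume time series: one record per
cell per frame (~10-min intervals over ~24 h, volumes ~1200–4500 µm³),
plus per-cell annotations of birth (cytokinesis onset), the G1/S
transition, and mitosis onset.

## The model and the statistic

Volume follows a Langevin equation interpolating the two noise limits,

$$\frac{dV}{dt} = \alpha V + \nu_\alpha V^{\gamma},$$

with mean specific growth rate α (h⁻¹, phase-dependent: ~15% higher in
S-G2 than G1), white noise ν_α of amplitude σ, and exponent γ ∈ [0, 1]
(γ=0 additive, γ=1 multiplicative / geometric Brownian motion).

Because the variance, SD, and CV of the specific rate all depend on the
timescale *dt* of the discrete derivative (Var ∝ 1/dt), they cannot
separate the two scenarios. The discriminating statistic is the **Fano
factor of the conditional log return** dq|V = log V(t+dt) − log V(t):

$$\mathrm{Fano}(dq)\,|\,V = \frac{\sigma^2 V^{2(\gamma-1)}}{\alpha_q(V)},$$

which is independent of dt and scales as 1/V² for additive noise but is
flat in V for multiplicative noise. Linearizing this relation
(log(Fano·α_q) vs log V) yields estimates of γ and σ.

Around that core the package provides the full trajectory pipeline:
quartile-fence outlier filtering and 3-frame smoothing, robust (Theil–Sen)
sliding-window growth speeds, conditional binned statistics, the
exponential-vs-linear growth-mode test, the newborn-transient analysis,
and autocovariance-based estimation of the fluctuation decay time — all
exercised end-to-end on a bundled stochastic simulator with cell-cycle
structure (asynchronous founders, lognormal birth sizes and phase
durations, division, post-birth transient, measurement noise).

## Worked example

```python
import volgrowth as vg

params = vg.GrowthModelParams(alpha_g1=0.042, alpha_sg2=0.042,
                              gamma=0.0, sigma=85.0, seed=101)
traj, ann, info = vg.simulate_population(params, n_founders=300,
                                         duration=24.0)
ds = vg.make_dataset(traj, ann, params.frame_interval)
clean, removed = vg.preprocess_dataset(ds)

speeds = vg.assign_phase(vg.growth_speed_estimates(clean), ann)
fit = vg.fit_alpha(speeds)
print(f"alpha slope {fit.slope_alpha:.4f} /h, "
      f"mean (1/V)dV/dt {fit.mean_specific_rate:.4f} /h, "
      f"diagnostic {fit.exponentiality_diagnostic:.3f}")

dq = vg.assign_phase(vg.log_return_estimates(clean, dt=5/6), ann)
g = vg.estimate_gamma_sigma(vg.fano_curve(dq))
print(f"gamma_hat {g.gamma_hat:+.3f} +/- {g.gamma_se:.3f}, "
      f"sigma_hat {g.sigma_hat:.3g}")
```

prints (additive-noise cohort, ~1600 cells):

```
alpha slope 0.0401 /h, mean (1/V)dV/dt 0.0411 /h, diagnostic 0.025
gamma_hat -0.110 +/- 0.013, sigma_hat 83.1
```

The slope of dV/dt vs V agrees with the unconditional mean specific rate
(growth is exponential on average, α ≈ 0.042 h⁻¹), and the Fano-curve fit
places the noise exponent at γ ≈ 0 with σ recovered within a few percent
of the generative value 85 µm³·h⁻¹ᐟ².

The numbered scripts under `analysis/` run the complete study on four
simulated cohorts (additive, multiplicative, linear-growth, and
phase-effect) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_clean_trajectories.py
python analysis/03_growth_mode.py
python analysis/04_phase_and_newborn.py
python analysis/05_noise_inference.py
python analysis/06_fluctuation_timescale.py
```

A `volgrowth` command-line interface exposes the same stages
(`simulate`, `validate`, `preprocess`, `growth`, `popstats`, `fano`,
`autocov`) over plain-CSV dataset directories.

## Documentation

`docs/methods.md` describes the model, the estimators and their
numerical choices, what the synthetic cohorts do and do not emulate, and
known limitations.
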