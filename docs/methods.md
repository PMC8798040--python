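# Methods

## Generative model

Cell volume V(t) (µm³) follows the Itô Langevin equation

    dV/dt = α V + ν_α V^γ,

integrated by Euler–Maruyama on a sub-frame grid (default 10 substeps per
10-min frame, i.e. 1-min steps, which makes the frame-sampled process
insensitive to the step size) and sampled at the imaging interval. ν_α is
Gaussian white noise of amplitude σ (units µm^{3(1−γ)}·h^{−1/2}); γ ∈ [0,1]
interpolates additive (γ=0) and multiplicative (γ=1) fluctuations. A
reflecting floor at 1 µm³ guards the rare negative excursions of additive
noise; floor hits are counted and a warning is raised when they exceed 1%
of steps. For the two limits, closed-form ensemble moments
(`analytic_moments`) serve as simulation oracles: mean v0·e^{αt} in both
limits; variance σ²(e^{2αt}−1)/2α for γ=0 and v0²e^{2αt}(e^{σ²t}−1) for
γ=1.

### Cell-cycle structure

`simulate_population` emulates an asynchronously proliferating culture
observed for 24 h at 10-min frames:

* **Birth volumes** — lognormal, mean 1600 µm³, CV 0.15.
* **Phase durations** — independent lognormals, G1 8 h (CV 0.3), S-G2
  7.5 h (CV 0.2). The total of ~15.5 h is deliberately matched to the
  volume doubling time ln2/α so that e^{∫α dt} ≈ 2 and the birth-volume
  distribution stays near-stationary across generations: no explicit
  size-homeostasis mechanism is modelled, so a longer cycle would make
  birth sizes drift geometrically. A consequence of the *absence* of size
  control is that duration-lottery lineages can shrink over generations;
  a handful of cells per run decay to the volume floor. All analyses gate
  on volume ranges ≥ 1800 µm³, which excludes them.
* **Specific rates** — α_G1 = 0.040, α_SG2 = 0.046 h⁻¹ by default (the
  ~15% S-G2 excess); the switch occurs at the sampled G1/S time.
* **Division** — at the sampled mitosis time the track ends (the mitotic
  overshoot is not simulated; overshoot annotation fields exist but stay
  empty) and two daughters receive fractions f and 1−f of the mother's
  exact pre-division volume, f ~ N(0.5, 0.5·division_cv), default CV 0.04.
* **Founders** — drawn at a uniformly random cell-cycle age; their birth
  precedes the observation window, and the dynamics are integrated from
  birth so the transient and phase structure are correct at t = 0.
* **Post-birth transient** — for 1.3 h after birth the deterministic
  drift ramps linearly from a starting speed s0 to the steady drift αV.
  s0 = −2·α·V_birth for cells above the 80th percentile of the
  birth-volume distribution (they lose volume at first) and
  +0.25·α·V_birth otherwise. The ramp constrains only the mean speed; the
  noise term is unchanged.
* **Measurement noise** — additive Gaussian, default SD 10 µm³ per frame,
  applied after the dynamics. At this level technical variance is ~3% of
  the growth-noise variance of a 50-min log return, so it does not
  confound the noise-geometry inference.
* **Annotations** record the sampled event times exactly, including
  events beyond the observation window (synthetic ground truth; this
  avoids censoring ambiguity in phase assignment).
* A **linear growth mode** (drift = constant speed, default
  α_G1·mean birth volume) provides the control population for the
  growth-mode discrimination test.

Identical parameters and seed give bit-identical outputs.

## Trajectory cleaning

1. **Outlier fences** — for each point, quartiles of the centred 11-frame
   window (truncated at track ends; linear-interpolation/type-7 rule so
   hand examples reproduce); the point is flagged when outside
   [Q1 − 0.9·IQR, Q3 + 0.9·IQR]. A literal "fourth-quantile" variant
   (window maximum ± 0.9·IQR) is available as `fence_mode="q4"` but
   removes a large fraction of well-behaved points. Flagging never alters
   the raw volumes; it toggles the `valid` flag, and a removals report is
   produced.
2. **Smoothing** — centred 3-frame average over kept points, truncated at
   boundaries; flagged points are excluded from windows and remain absent
   from the smoothed curve.
3. **Detrending** (fluctuation/autocovariance analyses) — centred 8-frame
   moving average for long tracks, a fitted line for short ones
   (Theil–Sen by default; an OLS mode exists because only a linear
   projection has an exactly computable effect on the autocovariance —
   see below).

### Interaction of the fences with strong growth noise

At the study's fluctuation scale (~4% volume change per 50 min) the fence
filter flags ~3% of *genuine* process points, preferentially
down-deviations (the upward trend fills the top of each window's value
distribution, so the lower fence is effectively closer). Deleting those
points — or skipping derivative windows that contain them — selects
against real fluctuations and measurably tilts conditional growth speeds
(up to ~10% at low volumes, attenuating the α slope). The windowed
derivative estimator therefore does **not** delete flagged frames: fully
kept windows are fitted on the smoothed curve, and windows containing
flagged frames are fitted on their raw values, relying on the robust
estimator itself (below) to reject isolated artifacts. Only windows with
nonpositive/missing raw values are skipped. Two-point statistics (log
returns) cannot be made robust this way and do require both endpoints
kept.

## Growth-rate estimators

* **Growth speed** — Theil–Sen slope (median of all pairwise slopes;
  deterministic and well defined on 5 points, insensitive to one corrupt
  point in five) over 5-frame (50-min) sliding windows; an OLS option
  exists for sensitivity checks. Exact on affine input for any window
  size; on noiseless exponential input the specific rate is recovered to
  0.5% (interior windows).
* **Conditioning volume** — windows are *binned* by the raw volume at the
  window start (`v_bin`). Conditioning on the window's own mid-value
  would admit a window into a volume bin exactly when its internal
  fluctuation is upward — a threshold-selection bias that inflates
  conditional rates near bin edges by several percent. The start volume
  precedes every increment entering the slope, so conditioning on it is
  selection-clean, at the cost of reading the slope a deterministic
  factor e^{2αΔ} ≈ 1.4% high (speed measured two frames later). The
  *divisor* for the specific rate remains the smoothed window-centre
  volume.
* **Log returns** — dq = log V(t+dt) − log V(t) on the filtered,
  *unsmoothed* curve, conditioned on V(t); dt must be an integer number
  of frames. The 3-frame smoother correlates adjacent increments and
  would flatten the Var ∝ 1/dt law to ≈ dt^{−0.6}, so fluctuation
  statistics avoid it. dq telescopes exactly over consecutive intervals.
* **Phase labels** — G1 for window centres in [t_birth, t_g1s), SG2 in
  [t_g1s, overshoot start or mitosis) (half-open; a centre exactly at
  t_g1s is SG2). Windows intersecting the overshoot interval or with
  missing/inconsistent annotations are excluded. `early_post_birth` flags
  centres within 1.3 h of birth: mean-trend analyses may include them,
  fluctuation analyses and steady-state rate comparisons drop them.
  `phase_pure` additionally marks windows that do not straddle the G1/S
  time (± one frame for the smoothing reach); straddling windows mix the
  two phase rates and attenuate the phase contrast by ~2–4%.

## Population statistics

* **Growth-mode test** (`fit_alpha`) — bin mean dV/dt vs v_bin (250-µm³
  bins, ≥25 distinct cells per bin) over 1800–4000 µm³ and fit a line
  weighted by per-bin cell counts (sparse extreme-volume bins are 10×
  noisier than the bulk and would otherwise dominate the slope noise;
  equal-weight and point-weighted fits remain as options). The
  exponentiality diagnostic |slope − ⟨(1/V)dV/dt⟩| / ⟨(1/V)dV/dt⟩ is ≈0
  for exponential growth and ≈1 for linear growth.
* **Phase comparison** — per-phase binned specific rates on a *shared*
  200-µm³ grid, restricted to 1800–3100 µm³ (where the rate is flat in V
  within each phase), paired per bin with identical inverse-variance
  weights. Pairing at matched volumes makes the S-G2/G1 ratio immune to
  the phases' different volume composition; per-bin SEMs use distinct-cell
  counts (windows within a cell are strongly correlated). On simulations
  the ratio recovers a 15% effect to within its reported SE (~0.02 at
  ~2500 cells) and is consistent with 1.0 under equal rates.
* **Newborn transient** — sliding-average growth speed vs time from
  birth, cells split 20/60/20% by birth volume. Convergence is assessed
  on the *excess* speed dV/dt − α_ref·V (α_ref = median post-transient
  specific rate): raw speeds retain a structural α·ΔV offset between
  birth-volume groups even after the transient has died, so the
  meaningful statistic is the contraction of the between-group excess
  spread (first hour vs after 1.3 h); transient-enabled simulations give
  contraction ratios ≈ 0.05–0.15.

## Noise inference

* **Fano curve** — sliding 200-µm³ volume bins (step 100 µm³) over
  1800–3100 µm³, windows ≥1.3 h after birth, ≥100 distinct cells per bin;
  per bin the mean and variance of dq, Fano = var/mean, α_q = mean/dt,
  and a leave-one-cell-out jackknife SE of the Fano factor (computed from
  per-cell sufficient statistics).
* **γ̂** — weighted least squares of log(Fano·α_q) on log V (weights =
  per-bin cell counts); slope = 2(γ−1).
* **σ̂** — σ carries γ-dependent units, and reading it off the regression
  intercept (log V = 0) would extrapolate ~8 log-units below the data,
  where a within-noise slope error becomes a severalfold σ error. σ̂ is
  instead evaluated with the exponent pinned at the noise limit nearest
  γ̂: the cell-weighted mean of Fano·α_q·V^{2(1−γ_lim)} across bins, with
  a between-bin weighted SE. Recovery on simulations: within ~3% (γ=0,
  σ=85) and ~2% (γ=1, σ=0.044).
* **Timescale invariance** — Fano per fixed volume group across dt =
  20–60 min is flat (max |log–log slope| ≲ 0.1; a small residue comes
  from the measurement-noise term ∝ 1/dt), while Var, SD, CV of the
  specific rate scale as dt^{−1}, dt^{−1/2}, dt^{−1/2}.
* **Autocovariance** — pooled biased-normalized sample autocovariance of
  detrended residuals across cells (divide by total points; stable at
  large lags; series shorter than 3× the maximum lag are skipped). The
  decay time is fitted as A·g_τ, where g_τ is the *expected* sample
  autocovariance of an exponentially correlated process of the same
  series length after the detrending operation — computed exactly via the
  OLS projection matrix. This matters: subtracting a fitted line from a
  1-h track removes low-frequency power and reshapes the whole
  autocovariance, so a naive exponential fit of linearly detrended
  10-min-correlated noise reports ~3–5 min; the detrending-aware fit
  recovers ~10 min within a few percent, and is exact on idealized
  exponential input. White noise (no resolvable correlation) yields a
  missing decay time rather than a number.

## Problem sizes and tolerances

Recovery analyses use 24-h, 10-min-frame populations of 300–1200 founders
(≈600–5000 cells), sized so that estimator sampling noise is several
times smaller than the effect being recovered (e.g. phase-ratio SE
≈ 0.015 at 1200 founders, α-slope SE ≈ 0.001 at 800). The Monte-Carlo
moment checks use 10⁴ replicates and 3-SE bands. Numerical tie-breaks:
type-7 quantiles everywhere; np.median (mean of central pair) for the
even pairwise-slope count of Theil–Sen windows; division fractions
clipped to (0.01, 0.99); τ optimisation on a log grid with bounded scalar
minimisation.

## What the simulator does not emulate

Measurement artifacts (segmentation spikes) are absent, so the fence
filter mostly flags genuine fluctuation extremes here; mitotic-overshoot
dynamics, size homeostasis (adder/sizer correlations between birth size
and phase durations), mass/density co-dynamics, and temporally correlated
*growth* noise (the white-noise model makes volume fluctuations
persistent, whereas the OU helper models correlated measurement noise
only) are likewise not modelled. Passing recovery tests therefore shows
the pipeline is faithful to the stated stochastic model at realistic
scales — not that real data satisfy that model.
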