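"""Decay timescale of volume fluctuations from fast time-lapse tracks.

Emulates the fast-imaging control: 1-h tracks sampled every 20 s whose
fluctuations are exponentially correlated with a 10-min decay time
(Ornstein–Uhlenbeck), riding on a linear growth trend. Each track is
detrended with an OLS line and the pooled autocovariance is fitted with the
detrending-aware estimator.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import volgrowth as vg

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(106)
    dt = 20.0 / 3600.0
    n_frames, n_tracks = 180, 120
    tau_true, sd = 10.0 / 60.0, 30.0
    t = np.arange(n_frames) * dt
    trend = 2000.0 + 0.042 * 2000.0 * t  # exponential ~ linear over 1 h
    tracks = trend + vg.ou_series(n_frames, dt, tau_true, sd, rng, n_tracks)
    resid = [vg.detrend(row, t, mode="ols") for row in tracks]
    res = vg.autocovariance(resid, dt, max_lag=60, detrend="linear")
    pd.DataFrame({"lag_h": res.lags_h, "autocov": res.autocov}).to_csv(
        OUT / "autocovariance.csv", index=False)
    (OUT / "autocov_fit.json").write_text(json.dumps({
        "fitted_tau_min": res.fitted_tau * 60.0,
        "true_tau_min": tau_true * 60.0,
        "c0": res.c0, "n_tracks": res.n_series,
    }, indent=2))
    print(f"fitted fluctuation decay time: {res.fitted_tau * 60:.1f} min "
          f"(generator truth {tau_true * 60:.0f} min, {res.n_series} tracks)")
    print("note: naive exponential fitting of the detrended autocovariance "
          "would report ~3-5 min; the fit inverts the detrending distortion.")


if __name__ == "__main__":
    main()
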