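"""Windowed derivative estimators, log returns, and phase assignment."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import volgrowth as vg
from volgrowth.rates import RatesError

from conftest import synthetic_annotation, trajectories_from_array


def _dataset(vols, frame_interval=1 / 6, ann=None, smooth=False):
    traj = trajectories_from_array(vols, frame_interval)
    if ann is None:
        ann = synthetic_annotation(["c0000"])
    ds = vg.make_dataset(traj, ann, frame_interval)
    if smooth:
        ds, _ = vg.preprocess_dataset(ds)
    else:
        ds.trajectories["volume_smooth"] = ds.trajectories["volume_um3"]
    return ds


class TestGrowthSpeed:
    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_exact_on_affine_input(self, window):
        t = np.arange(40) / 6
        ds = _dataset(1000.0 + 60.0 * t)
        est = vg.growth_speed_estimates(ds, window_frames=window)
        np.testing.assert_allclose(est["dvdt"], 60.0, rtol=1e-10)

    def test_theil_sen_is_median_of_pairwise_slopes(self):
        """On a 5-point window with one outlier, the slope equals the median
        of the 10 pairwise slopes enumerated by brute force."""
        vols = np.array([1000.0, 1010.0, 1500.0, 1030.0, 1040.0])
        t = np.arange(5) / 6
        ds = _dataset(vols)
        est = vg.growth_speed_estimates(ds, window_frames=5)
        brute = np.median([
            (vols[j] - vols[i]) / (t[j] - t[i])
            for i, j in combinations(range(5), 2)
        ])
        assert est["dvdt"].iloc[0] == pytest.approx(brute, rel=1e-12)
        assert vg.theil_sen_slope(vols, t) == pytest.approx(brute, rel=1e-12)

    def test_exponential_specific_rate(self):
        """On noiseless exponential input the specific rate matches alpha to
        0.5% (curvature bound for a 50-min window)."""
        t = np.arange(60) / 6
        ds = _dataset(2000.0 * np.exp(0.042 * t), smooth=True)
        est = vg.growth_speed_estimates(ds, window_frames=5)
        interior = est[(est["frame_center"] >= 3) & (est["frame_center"] <= 55)]
        np.testing.assert_allclose(interior["specific_rate"], 0.042, rtol=5e-3)
        # boundary windows touch truncated smoothing windows; still within 1%
        np.testing.assert_allclose(est["specific_rate"], 0.042, rtol=1e-2)

    def test_flagged_frame_windows_fall_back_to_raw(self):
        """Windows containing a fence-flagged frame are fitted on the raw
        values; the robust slope survives even a large artifact spike."""
        t = np.arange(20) / 6
        vols = 1000.0 + 60.0 * t
        vols[9] += 5000.0  # artifact
        ds = _dataset(vols)
        ds.trajectories.loc[9, "valid"] = False
        ds.trajectories.loc[9, "volume_smooth"] = np.nan
        est = vg.growth_speed_estimates(ds, window_frames=5)
        assert est.attrs["n_skipped_windows"] == 0
        # every window present, and the Theil-Sen median shrugs off the spike
        assert set(est["frame_center"]) == set(range(2, 18))
        np.testing.assert_allclose(est["dvdt"], 60.0, rtol=1e-10)

    def test_nonpositive_raw_skips_window(self):
        ds = _dataset(np.full(20, 2000.0))
        ds.trajectories.loc[9, "volume_um3"] = -1.0
        ds.trajectories.loc[9, "valid"] = False
        est = vg.growth_speed_estimates(ds, window_frames=5)
        assert est.attrs["n_skipped_windows"] == 5
        for fc in (7, 8, 9, 10, 11):
            assert fc not in set(est["frame_center"])

    def test_even_window_rejected(self):
        ds = _dataset(np.full(12, 1.0))
        with pytest.raises(RatesError):
            vg.growth_speed_estimates(ds, window_frames=4)

    def test_ols_option_exact_on_line(self):
        t = np.arange(20) / 6
        ds = _dataset(500.0 + 30.0 * t)
        est = vg.growth_speed_estimates(ds, method="ols")
        np.testing.assert_allclose(est["dvdt"], 30.0, rtol=1e-10)


class TestLogReturn:
    def test_constant_volume_zero(self):
        ds = _dataset(np.full(20, 2000.0))
        est = vg.log_return_estimates(ds, 5 / 6)
        np.testing.assert_allclose(est["dq"], 0.0, atol=1e-14)

    def test_doubling_gives_ln2(self):
        vols = np.array([1000.0] * 6 + [2000.0] * 6)
        ds = _dataset(vols)
        est = vg.log_return_estimates(ds, 1.0)
        row = est[est["frame_start"] == 5].iloc[0]
        assert row["dq"] == pytest.approx(math.log(2.0))
        assert row["v_start"] == pytest.approx(1000.0)

    def test_small_increment_matches_specific_rate(self):
        """For exponential input, dq/dt equals the specific rate up to the
        quadratic Taylor remainder."""
        t = np.arange(60) / 6
        ds = _dataset(2000.0 * np.exp(0.042 * t))
        est = vg.log_return_estimates(ds, 5 / 6)
        np.testing.assert_allclose(est["dq"] / (5 / 6), 0.042, rtol=1e-10)

    def test_telescoping_over_consecutive_steps(self):
        """dq summed over k consecutive dt-intervals equals the dq over
        k*dt exactly."""
        rng = np.random.default_rng(4)
        vols = 2000.0 + np.cumsum(rng.normal(10, 30, 30))
        ds = _dataset(vols)
        one = vg.log_return_estimates(ds, 1 / 6).set_index("frame_start")["dq"]
        three = vg.log_return_estimates(ds, 0.5).set_index("frame_start")["dq"]
        for f in range(0, 20):
            assert three.loc[f] == pytest.approx(
                one.loc[f] + one.loc[f + 1] + one.loc[f + 2], rel=1e-12)

    def test_non_multiple_dt_rejected(self):
        ds = _dataset(np.full(20, 1.0))
        with pytest.raises(RatesError):
            vg.log_return_estimates(ds, 0.25)

    def test_nonpositive_endpoint_skipped(self):
        vols = np.full(20, 2000.0)
        vols[8] = -1.0
        ds = _dataset(vols)
        est = vg.log_return_estimates(ds, 1 / 6)
        assert 8 not in set(est["frame_start"])
        assert 7 not in set(est["frame_start"])


class TestAssignPhase:
    def _estimates(self, centers):
        return pd.DataFrame({
            "cell_id": "c0000",
            "t_center": centers,
            "window_start_h": np.asarray(centers) - 0.4,
            "window_end_h": np.asarray(centers) + 0.4,
        })

    def test_boundary_convention_half_open(self):
        ann = synthetic_annotation(["c0000"], t_birth=0.0, t_g1s=10.0,
                                   t_mitosis=20.0)
        out = vg.assign_phase(self._estimates([9.9, 10.0, 10.1]), ann)
        assert out["phase"].tolist() == ["G1", "SG2", "SG2"]

    def test_overshoot_straddle_excluded(self):
        ann = synthetic_annotation(["c0000"], t_birth=0.0, t_g1s=5.0,
                                   t_mitosis=22.0)
        ann.loc[0, "overshoot_start"] = 20.0
        ann.loc[0, "overshoot_end"] = 21.0
        out = vg.assign_phase(self._estimates([19.0, 19.8, 20.5]), ann)
        assert out["phase"].tolist() == ["SG2", "excluded", "excluded"]

    def test_inconsistent_annotation_skips_cell(self):
        ann = synthetic_annotation(["c0000"], t_birth=5.0, t_g1s=2.0,
                                   t_mitosis=20.0)
        out = vg.assign_phase(self._estimates([6.0]), ann)
        assert (out["phase"] == "excluded").all()
        assert out.attrs["skipped_cells"] == ["c0000"]

    def test_early_post_birth_flag(self):
        ann = synthetic_annotation(["c0000"], t_birth=1.0, t_g1s=10.0)
        out = vg.assign_phase(self._estimates([1.5, 2.2, 3.0]), ann)
        assert out["early_post_birth"].tolist() == [True, True, False]
        np.testing.assert_allclose(out["time_from_birth"], [0.5, 1.2, 2.0])

    def test_phase_occupancy_matches_generator(self, small_clean,
                                               small_population):
        """The fraction of G1-labelled windows matches the generator's true
        phase occupancy within 2%."""
        params, _, ann, _ = small_population
        clean, _ = small_clean
        est = vg.growth_speed_estimates(clean)
        est = vg.assign_phase(est, ann)
        labelled = est[est["phase"].isin(["G1", "SG2"])]
        frac_g1 = (labelled["phase"] == "G1").mean()
        a = ann.set_index("cell_id")
        truth_g1 = truth_tot = 0.0
        for cid, grp in labelled.groupby("cell_id"):
            tb, tg = a.loc[cid, "t_birth"], a.loc[cid, "t_g1s"]
            t = grp["t_center"].to_numpy()
            truth_g1 += ((t >= tb) & (t < tg)).sum()
            truth_tot += len(t)
        assert frac_g1 == pytest.approx(truth_g1 / truth_tot, abs=0.02)


class TestVarianceVsTimescale:
    def test_zero_noise_zero_variance(self):
        params = vg.GrowthModelParams(sigma=0.0, meas_noise_sd=0.0,
                                      transient_enabled=False, seed=6,
                                      alpha_g1=0.042, alpha_sg2=0.042)
        traj, ann, _ = vg.simulate_population(params, 60, 24.0)
        ds = vg.make_dataset(traj, ann, params.frame_interval)
        out = vg.variance_vs_timescale(ds, [2 / 6, 5 / 6], annotations=ann,
                                       min_cells=10)
        ok = out.dropna(subset=["var_specific_rate"])
        assert len(ok) > 0
        assert (ok["var_specific_rate"] < 1e-8).all()

    def test_empty_dt_list_rejected(self, small_dataset):
        with pytest.raises(RatesError):
            vg.variance_vs_timescale(small_dataset, [])
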