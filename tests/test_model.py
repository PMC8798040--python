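"""Simulator correctness: deterministic limits, analytic moments, cell-cycle
bookkeeping, and reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest

import volgrowth as vg
from volgrowth.model import GrowthModelParams, SimulationError


class TestSimulateTrajectory:
    def test_zero_noise_is_compound_growth(self):
        """With sigma = 0 and one substep per frame, the trajectory is the
        deterministic compounding recursion V_n = v0 (1 + alpha*dt)^n."""
        params = GrowthModelParams(alpha_g1=0.0416, sigma=0.0, meas_noise_sd=0.0,
                                   sim_substeps=1, transient_enabled=False)
        table, info = vg.simulate_trajectory(params, 2000.0, 5.0,
                                             rng=np.random.default_rng(0))
        n = np.arange(len(table))
        expected = 2000.0 * (1.0 + 0.0416 / 6.0) ** n
        np.testing.assert_allclose(table["volume_um3"].to_numpy(), expected,
                                   rtol=1e-12)
        assert info["n_clip"] == 0

    def test_multiplicative_update_identity(self):
        """At gamma = 1 the recursion is a per-step multiplicative factor:
        V_{n+1} = V_n (1 + alpha dt + sigma sqrt(dt) xi)."""
        params = GrowthModelParams(alpha_g1=0.042, gamma=1.0, sigma=0.05,
                                   sim_substeps=1, meas_noise_sd=0.0,
                                   transient_enabled=False)
        seed = 7
        table, _ = vg.simulate_trajectory(params, 2000.0, 3.0,
                                          rng=np.random.default_rng(seed))
        xi = np.random.default_rng(seed).standard_normal(18)
        dt = 1.0 / 6.0
        factors = 1.0 + 0.042 * dt + 0.05 * math.sqrt(dt) * xi
        expected = 2000.0 * np.concatenate([[1.0], np.cumprod(factors)])
        np.testing.assert_allclose(table["volume_um3"].to_numpy(), expected,
                                   rtol=1e-12)

    def test_phase_schedule_switches_rate(self):
        params = GrowthModelParams(alpha_g1=0.03, alpha_sg2=0.06, sigma=0.0,
                                   meas_noise_sd=0.0, sim_substeps=1,
                                   transient_enabled=False)
        table, _ = vg.simulate_trajectory(
            params, 1000.0, 2.0, phase_schedule=[("G1", 0.0), ("SG2", 1.0)],
            rng=np.random.default_rng(0))
        v = table["volume_um3"].to_numpy()
        early = v[1:7] / v[:6]
        late = v[7:] / v[6:-1]
        np.testing.assert_allclose(early, 1.0 + 0.03 / 6.0, rtol=1e-12)
        np.testing.assert_allclose(late, 1.0 + 0.06 / 6.0, rtol=1e-12)

    @pytest.mark.parametrize("v0,duration", [(-5.0, 1.0), (0.0, 1.0), (100.0, -1.0)])
    def test_rejects_nonpositive_inputs(self, v0, duration):
        params = GrowthModelParams()
        with pytest.raises(SimulationError):
            vg.simulate_trajectory(params, v0, duration)


class TestAnalyticMoments:
    def test_initial_condition(self):
        for gamma in (0, 1):
            mean, var = vg.analytic_moments(0.042, gamma, 30.0, 2000.0, 0.0)
            assert mean == pytest.approx(2000.0)
            assert var == pytest.approx(0.0)

    def test_deterministic_limit(self):
        mean, var = vg.analytic_moments(0.042, 0, 0.0, 2000.0, 5.0)
        assert mean == pytest.approx(2000.0 * math.exp(0.21))
        assert var == 0.0

    def test_additive_closed_form(self):
        _, var = vg.analytic_moments(0.042, 0, 30.0, 2000.0, 5.0)
        assert var == pytest.approx(30.0 ** 2 * (math.exp(0.42) - 1.0) / 0.084)

    def test_rejects_intermediate_gamma(self):
        with pytest.raises(SimulationError):
            vg.analytic_moments(0.042, 0.5, 30.0, 2000.0, 1.0)

    @pytest.mark.parametrize("gamma,sigma", [(0, 30.0), (1, 0.05)])
    def test_ensemble_moments_match(self, gamma, sigma):
        """Euler–Maruyama ensembles agree with the closed-form moments
        within 3 standard errors at 10^4 replicates."""
        alpha, v0, t, n_rep = 0.042, 2000.0, 5.0, 10_000
        rng = np.random.default_rng(42 + gamma)
        v = vg.simulate_ensemble(alpha, gamma, sigma, v0, t, n_rep, rng=rng)
        mean_th, var_th = vg.analytic_moments(alpha, gamma, sigma, v0, t)
        se_mean = v.std(ddof=1) / math.sqrt(n_rep)
        assert abs(v.mean() - mean_th) < 3 * se_mean
        m4 = ((v - v.mean()) ** 4).mean()
        se_var = math.sqrt((m4 - v.var() ** 2) / n_rep)
        assert abs(v.var(ddof=1) - var_th) < 3 * se_var


class TestSimulatePopulation:
    def test_seed_determinism(self):
        params = GrowthModelParams(seed=5)
        t1, a1, _ = vg.simulate_population(params, 20, 12.0)
        t2, a2, _ = vg.simulate_population(params, 20, 12.0)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_division_conserves_volume(self):
        """With a symmetric noiseless split, both daughters carry exactly
        half the mother's pre-division volume."""
        params = GrowthModelParams(sigma=0.0, meas_noise_sd=0.0, division_cv=0.0,
                                   transient_enabled=False, seed=3)
        traj, ann, _ = vg.simulate_population(params, 30, 24.0)
        daughters = ann[ann["parent_id"].notna()]
        assert len(daughters) > 0
        for parent_id, grp in daughters.groupby("parent_id"):
            mother = traj[traj["cell_id"] == parent_id]
            if len(grp) != 2 or len(mother) == 0:
                continue
            vb = grp["birth_volume"].to_numpy()
            assert vb[0] == pytest.approx(vb[1], rel=1e-12)
            # mother's volume one frame before division, compounded forward
            t_div = ann.set_index("cell_id").loc[parent_id, "t_mitosis"]
            last = mother.iloc[-1]
            steps = round((t_div - last["time_h"]) / params.substep)
            v_div = last["volume_um3"] * (1 + params.alpha_sg2 * params.substep) ** steps
            assert vb.sum() == pytest.approx(v_div, rel=1e-6)

    def test_annotations_cover_all_cells(self, small_population):
        _, traj, ann, info = small_population
        assert set(traj["cell_id"]) == set(ann["cell_id"])
        assert info["n_cells"] == ann["cell_id"].nunique()
        # event ordering holds for every cell
        assert (ann["t_g1s"] >= ann["t_birth"]).all()
        assert (ann["t_mitosis"] >= ann["t_g1s"]).all()

    def test_phase_effect_in_drift(self):
        """With no noise, the specific rate over S-G2 frames is alpha_sg2."""
        params = GrowthModelParams(alpha_g1=0.040, alpha_sg2=0.046, sigma=0.0,
                                   meas_noise_sd=0.0, transient_enabled=False,
                                   seed=9)
        traj, ann, _ = vg.simulate_population(params, 10, 20.0)
        a = ann.set_index("cell_id")
        for cid, grp in traj.groupby("cell_id"):
            tg = a.loc[cid, "t_g1s"]
            sg2 = grp[grp["time_h"] >= tg + params.frame_interval]
            if len(sg2) < 3:
                continue
            ratios = sg2["volume_um3"].to_numpy()[1:] / sg2["volume_um3"].to_numpy()[:-1]
            rate = (ratios ** (1.0 / params.sim_substeps) - 1).mean() / params.substep
            assert rate == pytest.approx(0.046, rel=1e-9)

    def test_frames_on_uniform_grid(self, small_population):
        params, traj, _, _ = small_population
        np.testing.assert_allclose(traj["time_h"],
                                   traj["frame"] * params.frame_interval)

    def test_duration_too_short_rejected(self):
        with pytest.raises(SimulationError):
            vg.simulate_population(GrowthModelParams(seed=1), 5, 0.05)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"gamma": 1.5}, {"gamma": -0.1}, {"frame_interval": 0.0},
        {"sim_substeps": 0}, {"sigma": -1.0}, {"growth_mode": "cubic"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            GrowthModelParams(**kwargs)


def test_ou_series_autocovariance():
    """The OU generator has autocovariance sd^2 exp(-lag/tau)."""
    rng = np.random.default_rng(12)
    dt, tau, sd = 1 / 180, 1 / 6, 20.0
    x = vg.ou_series(400, dt, tau, sd, rng, n_tracks=400)
    var = x.var()
    assert var == pytest.approx(sd ** 2, rel=0.05)
    lag9 = (x[:, :-9] * x[:, 9:]).mean()
    assert lag9 == pytest.approx(sd ** 2 * math.exp(-9 * dt / tau), rel=0.1)
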