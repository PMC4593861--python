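import numpy as np
import pytest
from hypothesis import given, strategies as st

import myosyn as ms
from myosyn.control import _PIDLoop
from myosyn.errors import ContractError, DomainError


class TestPIDStep:
    def test_zero_everything(self):
        assert ms.pid_step(ms.PIDConfig(), 0.0, 0.0, 0.0) == 0.0

    def test_default_proportional_gain(self):
        # Kp = 10 on a 0.05 rad error gives half activation
        assert ms.pid_step(ms.PIDConfig(), 0.05, 0.0, 0.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert ms.pid_step(ms.PIDConfig(), 1.0, 0.0, 0.0) == 1.0
        assert ms.pid_step(ms.PIDConfig(), -1.0, 0.0, 0.0) == -1.0

    def test_negative_gains_rejected(self):
        with pytest.raises(ContractError):
            ms.PIDConfig(kp=-1.0)

    def test_antiwindup_freezes_integral(self):
        loop = _PIDLoop(ms.PIDConfig(), dt=1e-3)
        for _ in range(200):
            u = loop.step(1.0)  # persistently saturating error
        assert u == 1.0
        assert loop.integral == 0.0  # never accumulated while saturated


class TestSplit:
    def test_positive(self):
        assert ms.split_signed_activation(0.3) == (0.3, 0.0)

    def test_negative(self):
        assert ms.split_signed_activation(-0.2) == (0.0, 0.2)

    def test_zero(self):
        assert ms.split_signed_activation(0.0) == (0.0, 0.0)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_split_reconstructs_and_is_one_sided(self, u):
        a_pos, a_neg = ms.split_signed_activation(u)
        assert a_pos >= 0 and a_neg >= 0
        assert a_pos - a_neg == pytest.approx(u)
        assert a_pos == 0 or a_neg == 0 or u == 0


class TestTrajectory:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_stays_in_range(self, seed):
        rng = (0.0, 2.6)
        traj = ms.TrajectorySpec.sum_of_sines(seed, rng, duration=10.0)
        t = np.linspace(0, traj.duration, 5000)
        th = traj.theta(t)
        assert th.min() >= rng[0] and th.max() <= rng[1]

    def test_derivatives_consistent(self):
        traj = ms.TrajectorySpec.sum_of_sines(4, (0.0, 2.6))
        t = np.linspace(0.5, 5.0, 200)
        eps = 1e-6
        fd_vel = (traj.theta(t + eps) - traj.theta(t - eps)) / (2 * eps)
        fd_acc = (traj.theta_dot(t + eps) - traj.theta_dot(t - eps)) / (2 * eps)
        np.testing.assert_allclose(traj.theta_dot(t), fd_vel, atol=1e-5)
        np.testing.assert_allclose(traj.theta_ddot(t), fd_acc, atol=1e-5)

    def test_deterministic(self):
        t1 = ms.TrajectorySpec.sum_of_sines(5, (0.0, 2.6))
        t2 = ms.TrajectorySpec.sum_of_sines(5, (0.0, 2.6))
        np.testing.assert_array_equal(t1.amplitudes, t2.amplitudes)
        np.testing.assert_array_equal(t1.frequencies, t2.frequencies)


class TestFSOStep:
    def test_near_zero_at_equilibrium(self, simple_model):
        # on target, at rest, no gravity: effort term keeps muscles silent
        a = ms.fso_step(simple_model, 1.0, 0.0, 1.0, 0.0, ms.FSOConfig(), 1e-3)
        assert np.all(a >= 0)
        assert np.max(a) < 1e-6

    def test_high_weights_approach_sharing_optimum(self, forearm):
        # with tracking dominating, FSO's torque is shared like the closed form
        cfg = ms.FSOConfig(w1=1.0, w2=1e12, w3=1e8)
        th, thd = 1.3, 0.0
        a = ms.fso_step(forearm, th, thd, 1.32, 0.0, cfg, 1e-3)
        tau = float(ms.h_vector(forearm, th) @ a)
        a_opt = ms.optimal_activations(
            ms.SharingProblem(ms.h_vector(forearm, th), tau)
        )
        np.testing.assert_allclose(a, a_opt, rtol=1e-4, atol=1e-9)

    def test_default_weights_are_shipped(self):
        cfg = ms.FSOConfig()
        assert (cfg.w1, cfg.w2, cfg.w3) == (1.0, 3.0e6, 5.0e2)

    def test_bad_dt(self, simple_model):
        with pytest.raises(ContractError):
            ms.fso_step(simple_model, 1.0, 0.0, 1.0, 0.0, ms.FSOConfig(), -1e-3)


def make_result(activations, dt=0.01):
    n = activations.shape[1]
    t = np.arange(n) * dt
    z = np.zeros(n)
    return ms.SimulationResult(
        time=t, theta=z, theta_dot=z, activations=activations,
        torque_demand=z, torque_produced=z,
        muscle_names=[f"m{i}" for i in range(activations.shape[0])],
    )


class TestEffort:
    def test_zero_activations(self):
        assert ms.effort(make_result(np.zeros((3, 100)))) == 0.0

    def test_single_constant_half(self):
        assert ms.effort(make_result(np.full((1, 200), 0.5))) == pytest.approx(0.25)

    def test_two_constant_muscles(self):
        a = np.vstack([np.full(200, 0.3), np.full(200, 0.4)])
        assert ms.effort(make_result(a)) == pytest.approx(0.25)

    def test_duration_independent(self):
        assert ms.effort(make_result(np.full((1, 50), 0.5))) == pytest.approx(
            ms.effort(make_result(np.full((1, 5000), 0.5)))
        )

    def test_zero_duration_rejected(self):
        with pytest.raises(DomainError):
            ms.effort(make_result(np.zeros((1, 1))))


@pytest.fixture(scope="module")
def short_task():
    forearm = ms.forearm_model()
    table = ms.build_synergy_table(forearm)
    traj = ms.TrajectorySpec.sum_of_sines(2, forearm.theta_range, duration=2.0)
    return forearm, table, traj


class TestClosedLoop:
    def test_pid_tracks(self, short_task):
        forearm, table, traj = short_task
        res = ms.simulate_tracking(
            forearm, ms.SynergyPIDController(table, traj), traj
        )
        assert ms.rms_tracking_error(res) < 0.05
        assert np.all(res.activations >= 0)
        assert res.activations.max() <= 1.0

    def test_fso_tracks(self, short_task):
        forearm, _, traj = short_task
        res = ms.simulate_tracking(forearm, ms.FSOController(forearm, traj), traj)
        assert ms.rms_tracking_error(res) < 0.05

    def test_comparison_deterministic(self, short_task):
        forearm, table, traj = short_task

        def run():
            ctrls = {
                "fso": ms.FSOController(forearm, traj),
                "pid_posture": ms.SynergyPIDController(table, traj),
            }
            return ms.run_comparison(forearm, traj, ctrls, dt=2e-3).to_json()

        assert run() == run()

    def test_report_writes_files(self, short_task, tmp_path):
        forearm, table, traj = short_task
        report = ms.run_comparison(
            forearm, traj,
            {"pid_posture": ms.SynergyPIDController(table, traj)},
            dt=2e-3,
        )
        report.write(tmp_path)
        assert (tmp_path / "comparison.json").exists()
        assert (tmp_path / "comparison.csv").exists()
        assert (tmp_path / "run_pid_posture.csv").exists()

    def test_static_controller_requires_assigned_roles(self, short_task):
        forearm, _, traj = short_task
        syn = ms.StaticSynergies(
            S=np.ones((7, 2)), C=np.ones((2, 3)), vaf=1.0,
            muscle_names=forearm.muscle_names,
        )
        with pytest.raises(ContractError):
            ms.StaticSynergyPIDController(syn, traj)
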