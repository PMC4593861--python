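import numpy as np
import pytest

import myosyn as ms
from myosyn.errors import ContractError, InvalidRepresentativeError, RangeError
from myosyn.muscle_mechanics import MuscleParams
from myosyn.plant import OneDoFModel


class TestProbeH:
    def test_matches_analytic_on_grid(self, forearm):
        grid = np.linspace(*forearm.theta_range, 50)
        for i, mu in enumerate(forearm.muscles):
            for th in grid:
                assert ms.probe_h(forearm, i, th) == pytest.approx(
                    ms.h_analytic(mu, th, 0.0), abs=1e-8
                )

    def test_zero_at_zero_moment_arm(self):
        # switching muscle with arm k*(theta - 0.5): probe vanishes at 0.5
        k, th0 = 0.03, 0.5
        mu = MuscleParams("sw", 100.0, 0.0, [0.3, k * th0, -k / 2], 0.1, 0.2)
        other = MuscleParams("flex", 100.0, 0.0, [0.35, -0.02], 0.1, 0.23)
        model = OneDoFModel(muscles=[mu, other], inertia=0.05, theta_range=(0.0, 2.0))
        assert ms.probe_h(model, 0, th0) == pytest.approx(0.0, abs=1e-12)

    def test_crank_switching_muscle_changes_sign(self, crank):
        idx = crank.meta["switching"][0]
        lo, hi = crank.theta_range
        vals = [ms.probe_h(crank, idx, th) for th in np.linspace(lo, hi, 51)]
        assert min(vals) < 0 < max(vals)

    def test_out_of_range(self, forearm):
        with pytest.raises(RangeError):
            ms.probe_h(forearm, 0, 9.0)

    def test_bad_probe_activation(self, forearm):
        with pytest.raises(ContractError):
            ms.probe_h(forearm, 0, 1.0, a_probe=0.0)

    def test_probe_independent_of_probe_level(self, forearm):
        # torque is linear in activation, so the ratio is probe-invariant
        for a in (0.1, 0.5, 1.0):
            assert ms.probe_h(forearm, 2, 1.3, a_probe=a) == pytest.approx(
                ms.probe_h(forearm, 2, 1.3, a_probe=0.5), rel=1e-12
            )


class TestValidateRepresentatives:
    def test_forearm_default_pair_valid(self, forearm):
        grid = np.linspace(*forearm.theta_range, 60)
        report = ms.validate_representatives(
            forearm, grid, forearm.meta["rep_pos"], forearm.meta["rep_neg"]
        )
        assert report.as_dict()["biceps_long"] == "positive"
        assert report.as_dict()["triceps_long"] == "negative"
        assert not report.switches_sign.any()

    def test_crank_switching_rep_invalid(self, crank):
        grid = np.linspace(*crank.theta_range, 60)
        idx = crank.meta["switching"][0]
        with pytest.raises(InvalidRepresentativeError, match="theta"):
            ms.validate_representatives(crank, grid, idx, crank.meta["rep_neg"])

    def test_empty_grid_rejected(self, forearm):
        with pytest.raises(ContractError):
            ms.validate_representatives(forearm, [], 2, 4)


class TestBuildTable:
    def test_representative_ratio_is_one(self, forearm_table):
        np.testing.assert_allclose(forearm_table.S_pos[forearm_table.rep_pos], 1.0)
        np.testing.assert_allclose(forearm_table.S_neg[forearm_table.rep_neg], 1.0)

    def test_triceps_purely_extensor(self, forearm, forearm_table):
        for i, name in enumerate(forearm.muscle_names):
            if name.startswith("triceps"):
                assert np.all(forearm_table.S_pos[i] == 0)
                assert np.all(forearm_table.S_neg[i] > 0)

    def test_one_synergy_per_posture(self, crank_table):
        assert np.all(crank_table.S_pos * crank_table.S_neg == 0)

    def test_crank_switching_muscle_changes_synergy(self, crank, crank_table):
        idx = crank.meta["switching"][0]
        assert (crank_table.S_pos[idx] > 0).any()
        assert (crank_table.S_neg[idx] > 0).any()

    def test_requires_representatives(self, forearm):
        model = OneDoFModel(
            muscles=forearm.muscles, inertia=0.06, theta_range=forearm.theta_range
        )
        with pytest.raises(ContractError):
            ms.build_synergy_table(model)

    def test_grid_is_strictly_increasing_contract(self, forearm_table):
        with pytest.raises(ContractError):
            ms.SynergyTable(
                muscle_names=forearm_table.muscle_names,
                theta_grid=np.array([0.0, 0.0, 1.0]),
                S_pos=np.zeros((7, 3)),
                S_neg=np.zeros((7, 3)),
                rep_pos=2,
                rep_neg=4,
                h_rep_pos=np.ones(3),
                h_rep_neg=-np.ones(3),
            )


class TestReconstruct:
    def test_zero_commands(self, forearm_table):
        a = ms.reconstruct_activations(forearm_table, 0.0, 0.0, 1.3)
        np.testing.assert_array_equal(a, np.zeros(7))

    def test_identity_readout_at_grid_point(self, forearm_table):
        th = forearm_table.theta_grid[37]
        a = ms.reconstruct_activations(forearm_table, 1.0, 0.0, th)
        np.testing.assert_allclose(a, forearm_table.S_pos[:, 37], atol=1e-12)

    def test_negative_command_rejected(self, forearm_table):
        with pytest.raises(ContractError):
            ms.reconstruct_activations(forearm_table, -0.1, 0.0, 1.3)

    def test_outside_span_rejected(self, forearm_table):
        with pytest.raises(RangeError):
            ms.reconstruct_activations(forearm_table, 0.1, 0.0, 99.0)

    def test_reproduces_closed_form_optimum(self, forearm, forearm_table):
        rng = np.random.default_rng(2)
        for _ in range(25):
            th = rng.uniform(0.05, 2.55)
            T = rng.uniform(-1.5, 1.5)
            if abs(T) < 0.1:
                continue
            a_table = forearm_table.activations_for_torque(th, T)
            a_opt = ms.optimal_activations(
                ms.SharingProblem(ms.h_vector(forearm, th), T)
            )
            np.testing.assert_allclose(a_table, a_opt, rtol=0.02, atol=1e-6)

    def test_exact_at_grid_points(self, forearm, forearm_table):
        th = forearm_table.theta_grid[50]
        for T in (0.8, -0.6):
            a_table = forearm_table.activations_for_torque(th, T)
            a_opt = ms.optimal_activations(
                ms.SharingProblem(ms.h_vector(forearm, th), T)
            )
            np.testing.assert_allclose(a_table, a_opt, rtol=1e-9, atol=1e-12)


class TestSymmetry:
    def test_mirrored_model_swaps_synergies(self, forearm):
        # reflect the posture axis (theta -> -theta): flexors become extensors
        mirrored = []
        for mu in forearm.muscles:
            poly = mu.length_poly.copy()
            poly[1::2] *= -1
            mirrored.append(
                MuscleParams(mu.name, mu.f0max, mu.pennation, poly, mu.l_opt,
                             mu.l_slack, mu.v_max)
            )
        # mirror the posture axis too so fiber kinematics match point-to-point
        model = OneDoFModel(
            muscles=mirrored, inertia=forearm.inertia, damping=forearm.damping,
            theta_range=(-forearm.theta_range[1], -forearm.theta_range[0]),
            meta={"rep_pos": forearm.meta["rep_neg"], "rep_neg": forearm.meta["rep_pos"]},
        )
        table_m = ms.build_synergy_table(model)
        table_f = ms.build_synergy_table(forearm)
        np.testing.assert_allclose(
            table_m.S_pos[:, ::-1], table_f.S_neg, rtol=1e-9, atol=1e-12
        )
        np.testing.assert_allclose(
            table_m.S_neg[:, ::-1], table_f.S_pos, rtol=1e-9, atol=1e-12
        )


class TestSerialization:
    def test_json_roundtrip(self, forearm_table, tmp_path):
        path = tmp_path / "table.json"
        forearm_table.save(path)
        loaded = ms.SynergyTable.load(path)
        np.testing.assert_allclose(loaded.S_pos, forearm_table.S_pos)
        np.testing.assert_allclose(loaded.S_neg, forearm_table.S_neg)
        np.testing.assert_allclose(loaded.theta_grid, forearm_table.theta_grid)
        assert loaded.rep_pos == forearm_table.rep_pos

    def test_csv_export(self, forearm_table, tmp_path):
        import pandas as pd

        path = tmp_path / "table.csv"
        forearm_table.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == len(forearm_table.theta_grid)
        assert "S_pos_biceps_long" in df.columns
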