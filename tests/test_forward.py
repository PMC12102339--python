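import numpy as np
import pytest

import tumortwin as tt
from tumortwin.forward import (
    ParamVector,
    assign_auc_maps,
    masked_laplacian,
    simulate_fom,
    stable_dt,
    treatment_field,
)
from tumortwin.regimen import TreatmentRegimen, build_protocol, canonicalize

EMPTY = TreatmentRegimen()


def _params(D=0.0, alpha=0.0, k=None):
    return ParamVector(D=D, alpha=alpha, beta={"A": 0.6, "C": 3.25}, k=k)


class TestLaplacian:
    def test_constant_field_annihilated(self, toy_grid, rng):
        L = masked_laplacian(toy_grid)
        np.testing.assert_allclose(L @ np.ones(toy_grid.n_masked), 0.0, atol=1e-12)

    def test_zero_flux_mass_conservation(self, rng):
        mask = rng.random((5, 5, 3)) > 0.3
        grid = tt.VoxelGrid(spacing=(1.0, 2.0, 3.0), breast_mask=mask)
        L = masked_laplacian(grid)
        f = rng.random(grid.n_masked)
        assert abs((L @ f).sum()) < 1e-10 * np.abs(L @ f).max()

    def test_linear_in_diffusivity(self, toy_grid, rng):
        L = masked_laplacian(toy_grid)
        f = rng.random(toy_grid.n_masked)
        np.testing.assert_allclose(2.0 * (0.5 * L @ f), L @ f)

    def test_empty_mask_rejected(self):
        grid = tt.VoxelGrid(spacing=(1, 1, 1), breast_mask=np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            masked_laplacian(grid)


class TestTreatmentField:
    def setup_method(self):
        self.reg = canonicalize(build_protocol(2, 2.0))
        self.assign = {j: np.zeros(2, int) for j in ("A", "C")}

    def test_zero_efficacy(self):
        auc = [np.ones(4)]
        g = treatment_field(_params(alpha=0.0, k=np.zeros(4)), self.reg, auc, self.assign, t=0.0)
        np.testing.assert_array_equal(g, 0.0)

    def test_unit_dose_at_delivery_instant(self):
        auc = [np.ones(4)]
        g = treatment_field(_params(alpha=0.3, k=np.zeros(4)), self.reg, auc, self.assign, t=0.0)
        # both drugs active with weight alpha each at t = tau
        np.testing.assert_allclose(g, 2 * 0.3)

    def test_sub_threshold_dose_contributes_nothing(self):
        reg = canonicalize(
            TreatmentRegimen(times={"A": np.array([0.0])}, doses={"A": np.array([0.05])})
        )
        g = treatment_field(
            _params(alpha=0.5, k=np.zeros(3)), reg, [np.ones(3)], {"A": np.zeros(1, int)}, t=0.0
        )
        np.testing.assert_array_equal(g, 0.0)

    def test_auc_map_assignment_most_recent_visit(self):
        reg = build_protocol(4, 2.0)  # days 0, 14, 28, 42
        assign = assign_auc_maps(reg, {"V1": 0.0, "V2": 28.0, "V3": 56.0})
        np.testing.assert_array_equal(assign["A"], [0, 0, 1, 1])


class TestSimulateFOM:
    def test_logistic_closed_form(self):
        grid = tt.VoxelGrid(spacing=(1, 1, 1), breast_mask=np.ones((1, 1, 1), bool))
        k, n0, t_end = 0.05, 0.3, 30.0
        res = simulate_fom(
            grid, 1e6, _params(k=np.array([k])), EMPTY, [np.zeros(1)], None,
            np.array([n0]), (0, t_end), dt=0.05,
        )
        exact = n0 / (n0 + (1 - n0) * np.exp(-k * t_end))
        assert res.total_cells[-1] / 1e6 == pytest.approx(exact, rel=1e-3)

    def test_pure_diffusion_conserves_mass(self, rng):
        mask = np.ones((8, 8, 2), bool)
        grid = tt.VoxelGrid(spacing=(1.0, 1.0, 2.0), breast_mask=mask)
        n0 = rng.uniform(0, 1, grid.n_masked)
        res = simulate_fom(
            grid, 1e6, _params(D=1e-3, k=np.zeros(grid.n_masked)), EMPTY,
            [np.zeros(grid.n_masked)], None, n0, (0, 10), dt=0.1,
        )
        drift = abs(res.total_cells[-1] - res.total_cells[0]) / res.total_cells[0]
        assert drift < 1e-10

    def test_strong_treatment_shrinks_tumor(self, rng):
        grid = tt.VoxelGrid(spacing=(1, 1, 1), breast_mask=np.ones((4, 4, 1), bool))
        n = grid.n_masked
        reg = canonicalize(build_protocol(1, 2.0))
        p = ParamVector(D=0.0, alpha=0.9, beta={"A": 0.6, "C": 3.25}, k=np.full(n, 0.01))
        res = simulate_fom(
            grid, 1e6, p, reg, [np.ones(n)], {j: np.zeros(1, int) for j in ("A", "C")},
            np.full(n, 0.5), (0, 1.0), dt=0.05,
        )
        assert res.total_cells[-1] < res.total_cells[0]

    def test_state_stays_within_bounds(self, rng):
        grid = tt.VoxelGrid(spacing=(1, 1, 1), breast_mask=np.ones((4, 4, 2), bool))
        n = grid.n_masked
        p = ParamVector(D=5e-4, alpha=0.8, beta={"A": 0.6, "C": 3.25}, k=rng.uniform(0.01, 0.1, n))
        reg = canonicalize(build_protocol(2, 1.0))
        res = simulate_fom(
            grid, 1e6, p, reg, [rng.uniform(0, 1, n)], {j: np.zeros(2, int) for j in ("A", "C")},
            rng.uniform(0, 1, n), (0, 20),
        )
        for f in res.fields.values():
            assert np.all((f >= 0) & (f <= 1))
        assert np.all(res.total_cells >= 0)

    def test_invalid_initial_condition_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            simulate_fom(
                toy_grid, 1e6, _params(k=np.zeros(toy_grid.n_masked)), EMPTY,
                [np.zeros(toy_grid.n_masked)], None,
                np.full(toy_grid.n_masked, 1.5), (0, 1),
            )

    def test_stable_dt_bounds(self, toy_grid):
        dt = stable_dt(toy_grid, D=1e-3, k_max=0.1, alpha=1.0)
        assert 0 < dt <= 0.1
        assert dt <= 0.5 / 1.1 + 1e-12


class TestTimestepConsistency:
    def test_halving_dt_changes_bulk_below_half_percent(self, responder, responder_fields):
        n_v1, _ = responder_fields
        g = responder.grid
        coarse = simulate_fom(
            g, responder.theta_cap, responder.truth, responder.regimen,
            responder.auc_list(), responder.auc_assign(), n_v1, (0, 56), dt=0.025,
            store_times=np.array([56.0]),
        )
        fine = simulate_fom(
            g, responder.theta_cap, responder.truth, responder.regimen,
            responder.auc_list(), responder.auc_assign(), n_v1, (0, 56), dt=0.0125,
            store_times=np.array([56.0]),
        )
        rel = abs(coarse.total_cells[-1] - fine.total_cells[-1]) / fine.total_cells[-1]
        assert rel < 0.005
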