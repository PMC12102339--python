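import numpy as np
import pytest

import tumortwin as tt
from tumortwin.forward import ParamVector, simulate_fom
from tumortwin.regimen import build_protocol, canonicalize
from tumortwin.rom import (
    SnapshotMatrix,
    build_snapshots,
    pod_basis,
    project_operators,
    reduce_proliferation,
    simulate_rom,
    simulate_rom_batch,
)


@pytest.fixture()
def toy_setup(toy_grid, rng):
    """Random full-rank basis, operators and fields on the 6x6x1 grid."""
    n = toy_grid.n_masked
    S = SnapshotMatrix(columns=rng.standard_normal((n, n)), pseudo_times=np.arange(n, dtype=float))
    basis = pod_basis(S, energy=1.0)
    k_map = reduce_proliferation(basis, seed=1)
    auc = [rng.uniform(0, 1, n)]
    rom = project_operators(toy_grid, basis, auc, theta_cap=1e5, k_map=k_map)
    return rom, auc


class TestSnapshots:
    def test_two_pseudo_times_no_smoothing_are_the_visits(self, toy_grid, rng):
        n = toy_grid.n_masked
        v1, v2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        S = build_snapshots(v1, v2, toy_grid, (0, 28), n_pseudo=2, smoothing_widths=())
        np.testing.assert_allclose(S.columns[:, 0], v1)
        np.testing.assert_allclose(S.columns[:, 1], v2)

    def test_midpoint_is_average(self, toy_grid, rng):
        n = toy_grid.n_masked
        v1, v2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        S = build_snapshots(v1, v2, toy_grid, (0, 28), n_pseudo=3, smoothing_widths=())
        np.testing.assert_allclose(S.columns[:, 1], 0.5 * (v1 + v2))

    def test_identical_visits_rank_one(self, toy_grid, rng):
        v = rng.uniform(0, 1, toy_grid.n_masked)
        S = build_snapshots(v, v, toy_grid, (0, 28), n_pseudo=5, smoothing_widths=())
        assert np.linalg.matrix_rank(S.columns, tol=1e-10) == 1

    def test_all_zero_rejected(self, toy_grid):
        z = np.zeros(toy_grid.n_masked)
        with pytest.raises(ValueError):
            build_snapshots(z, z, toy_grid, (0, 28))


class TestPODBasis:
    def test_orthonormality(self, toy_setup):
        rom, _ = toy_setup
        V = rom.basis.modes
        gram_err = np.abs(V.T @ V - np.eye(rom.rank)).max()
        assert gram_err < 1e-10

    def test_rank_one_exact(self, rng):
        u = rng.standard_normal(20)
        S = SnapshotMatrix(columns=np.outer(u, [1.0, 2.0, 3.0]), pseudo_times=np.arange(3.0))
        basis = pod_basis(S, energy=0.995)
        assert basis.rank == 1
        recon = basis.modes @ (basis.modes.T @ S.columns)
        np.testing.assert_allclose(recon, S.columns, atol=1e-10)

    def test_known_rank_recovered_exactly(self, rng):
        A = rng.standard_normal((30, 3)) @ rng.standard_normal((3, 7))
        basis = pod_basis(SnapshotMatrix(columns=A, pseudo_times=np.arange(7.0)), energy=1.0)
        assert basis.rank <= 3
        recon = basis.modes @ (basis.modes.T @ A)
        assert np.abs(recon - A).max() < 1e-10

    def test_energy_truncation_error_bound(self, rng):
        A = rng.standard_normal((40, 10))
        energy = 0.9
        basis = pod_basis(SnapshotMatrix(columns=A, pseudo_times=np.arange(10.0)), energy=energy)
        resid = A - basis.modes @ (basis.modes.T @ A)
        assert np.linalg.norm(resid) <= np.sqrt(1 - energy) * np.linalg.norm(A) + 1e-9


class TestKLReduction:
    def test_in_span_round_trip(self, toy_setup):
        rom, _ = toy_setup  # full-rank basis: every field is in span
        k = np.random.default_rng(5).uniform(1e-6, 0.1, rom.basis.modes.shape[0])
        np.testing.assert_allclose(rom.k_map.lift(rom.k_map.reduce(k)), k, atol=1e-10)

    def test_constant_extremes_within_bounds(self, toy_setup):
        rom, _ = toy_setup
        for c in (1e-6, 0.1):
            kr = rom.k_map.reduce(np.full(rom.basis.modes.shape[0], c))
            assert np.all(kr >= rom.k_map.lower - 1e-12)
            assert np.all(kr <= rom.k_map.upper + 1e-12)

    def test_bounds_monotone_in_samples(self, toy_grid, rng):
        basis = pod_basis(
            SnapshotMatrix(columns=rng.standard_normal((toy_grid.n_masked, 4)), pseudo_times=np.arange(4.0)),
            energy=1.0,
        )
        small = reduce_proliferation(basis, n_mc=16, seed=3)
        large = reduce_proliferation(basis, n_mc=256, seed=3)
        assert np.all(large.lower <= small.lower + 1e-15)
        assert np.all(large.upper >= small.upper - 1e-15)


class TestProjection:
    def test_diffusion_operator_affine_in_D(self, toy_setup):
        rom, _ = toy_setup
        np.testing.assert_allclose(2.0 * (0.5 * rom.A_unit), rom.A_unit)

    def test_uniform_auc_projects_to_identity(self, toy_grid, rng):
        n = toy_grid.n_masked
        basis = pod_basis(
            SnapshotMatrix(columns=rng.standard_normal((n, 5)), pseudo_times=np.arange(5.0)), energy=1.0
        )
        rom = project_operators(toy_grid, basis, [np.ones(n)], theta_cap=1.0)
        np.testing.assert_allclose(rom.T_units[0], np.eye(rom.rank), atol=1e-12)

    def test_full_rank_spectrum_matches_full_operator(self, toy_grid, toy_setup):
        from tumortwin.forward import masked_laplacian

        rom, _ = toy_setup
        L = masked_laplacian(toy_grid).toarray()
        ev_full = np.sort(np.linalg.eigvalsh(L))
        ev_red = np.sort(np.linalg.eigvalsh(0.5 * (rom.A_unit + rom.A_unit.T)))
        np.testing.assert_allclose(ev_red, ev_full, atol=1e-8)


class TestReducedSimulation:
    def test_full_rank_rom_equals_fom(self, toy_grid, toy_setup, rng):
        rom, auc = toy_setup
        n = toy_grid.n_masked
        k_field = rng.uniform(0.01, 0.08, n)
        n0 = rng.uniform(0, 0.5, n)
        reg = canonicalize(build_protocol(2, 1.0))
        assign = {j: np.zeros(2, int) for j in ("A", "C")}
        p_full = ParamVector(D=5e-4, alpha=0.4, beta={"A": 0.6, "C": 3.25}, k=k_field)
        fom = simulate_fom(toy_grid, 1e5, p_full, reg, auc, assign, n0, (0, 14), dt=0.05)
        p_red = ParamVector(D=5e-4, alpha=0.4, beta={"A": 0.6, "C": 3.25}, k=rom.k_map.reduce(k_field))
        red = simulate_rom(rom, p_red, reg, assign, rom.reduce(n0), (0, 14), dt=0.05)
        np.testing.assert_allclose(red.total_cells, fom.total_cells, rtol=1e-6)

    def test_zero_state_stays_zero(self, toy_setup):
        rom, _ = toy_setup
        p = ParamVector(D=1e-4, alpha=0.0, beta={"A": 0.6, "C": 3.25}, k=np.zeros(rom.rank))
        from tumortwin.regimen import TreatmentRegimen

        res = simulate_rom(rom, p, TreatmentRegimen(), {}, np.zeros(rom.rank), (0, 10))
        np.testing.assert_array_equal(res.total_cells, 0.0)

    def test_batch_matches_single_runs(self, toy_setup, rng):
        rom, _ = toy_setup
        r = rom.rank
        reg = canonicalize(build_protocol(2, 1.0))
        assign = {j: np.zeros(2, int) for j in ("A", "C")}
        u0 = rng.standard_normal(r) * 0.05
        D = np.array([1e-4, 5e-4])
        alpha = np.array([0.2, 0.7])
        beta = {"A": np.array([0.5, 0.7]), "C": np.array([2.0, 4.0])}
        Kr = rng.standard_normal((2, r)) * 0.01
        _, U = simulate_rom_batch(rom, D, alpha, beta, Kr, reg, assign, u0, (0, 14), dt=0.05)
        for s in range(2):
            p = ParamVector(D=D[s], alpha=alpha[s], beta={"A": beta["A"][s], "C": beta["C"][s]}, k=Kr[s])
            _, Us = simulate_rom_batch(
                rom, np.array([p.D]), np.array([p.alpha]),
                {j: np.array([p.beta[j]]) for j in p.beta}, p.k[None, :],
                reg, assign, u0, (0, 14), dt=0.05,
            )
            np.testing.assert_allclose(U[s], Us[0], rtol=1e-12)
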