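"""Proper-orthogonal-decomposition / Galerkin reduced-order model.

The reduced model is built from imaging snapshots: the two calibration
visits are linearly interpolated in pseudo-time and enriched with
Gaussian-smoothed copies, the SVD of the snapshot matrix gives an
orthonormal basis V truncated at a cumulative-energy threshold, and the
full-order operators are Galerkin-projected onto span(V).  The spatial
proliferation field k(x) is reduced with a Karhunen-Loeve expansion on
the same basis, k ~ V k_r, so the calibration works with a handful of
coefficients instead of one rate per voxel.

Every operator in the model depends affinely on its parameter (the
diffusion operator is linear in D, the proliferation operators linear in
each k_r coefficient, and the treatment term factors into a scalar dose
weight times a fixed projected AUC operator), so unit operators are
projected once and recombined exactly at simulation time; no operator
interpolation over a parameter grid is needed.

Reduced dynamics (forward Euler, same step rule as the full solver)::

    du/dt = D A u + B(k_r) u - G(k_r)(u, u) - sum_{j,k} w_{j,k}(t) T_{m(k)} u

where u = N_r is the reduced state, A = V' L V the projected Laplacian,
B(k_r) = sum_i k_ri V' diag(phi_i) V, G the projected quadratic logistic
term, T_m = V' diag(AUC_m) V the projected drug-delivery maps and
w_{j,k}(t) the scalar kill weights of each delivery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import SimulationResult, delivery_weights, masked_laplacian, stable_dt
from .grids import VoxelGrid
from .regimen import TreatmentRegimen

try:  # compiled Euler kernel; the pure-numpy loop below is the fallback
    import numba

    @numba.njit(cache=False)
    def _euler_kernel(M, G, T, W, u, step_sizes, rec_after, U_out):  # pragma: no cover
        n_steps = step_sizes.size
        S, r = u.shape
        n_maps = T.shape[0]
        n_rec = rec_after.size
        k = 0
        while k < n_rec and rec_after[k] == 0:
            U_out[:, k, :] = u
            k += 1
        rhs = np.empty(r)
        for n in range(n_steps):
            h = step_sizes[n]
            for s in range(S):
                for a in range(r):
                    acc = 0.0
                    for b in range(r):
                        mab = M[s, a, b]
                        for mm in range(n_maps):
                            mab -= W[n, s, mm] * T[mm, a, b]
                        acc += mab * u[s, b]
                    for b in range(r):
                        ub = u[s, b]
                        for c in range(r):
                            acc -= G[s, a, b, c] * ub * u[s, c]
                    rhs[a] = acc
                for a in range(r):
                    u[s, a] += h * rhs[a]
            while k < n_rec and rec_after[k] == n + 1:
                U_out[:, k, :] = u
                k += 1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class SnapshotMatrix:
    """Vectorized masked cellularity fields at pseudo-times (columns)."""

    columns: np.ndarray  # (n_masked, n_cols)
    pseudo_times: np.ndarray


@dataclass
class PODBasis:
    modes: np.ndarray  # (n_masked, r), orthonormal columns
    singular_values: np.ndarray  # full spectrum of the snapshot matrix
    energy: float  # cumulative squared-singular-value fraction retained

    @property
    def rank(self) -> int:
        return self.modes.shape[1]


@dataclass
class KLMap:
    """Karhunen-Loeve reduction of the proliferation field on basis V."""

    basis: np.ndarray  # (n_masked, r)
    lower: np.ndarray  # per-coefficient bounds (r,)
    upper: np.ndarray

    def reduce(self, k_field: np.ndarray) -> np.ndarray:
        return self.basis.T @ k_field

    def lift(self, k_r: np.ndarray) -> np.ndarray:
        return self.basis @ k_r


@dataclass
class ReducedModel:
    """Projected operators plus the maps between full and reduced space."""

    grid: VoxelGrid
    theta_cap: float
    basis: PODBasis
    A_unit: np.ndarray  # (r, r); A_r(D) = D * A_unit
    B_units: np.ndarray  # (r, r, r); B_r(k_r) = einsum('i,iab->ab', k_r, B_units)
    G_units: np.ndarray  # (r, r, r, r); quadratic logistic term per k_r coefficient
    T_units: np.ndarray  # (n_maps, r, r); projected AUC delivery maps
    k_map: KLMap
    cells_weights: np.ndarray  # (r,); total cells = theta * cells_weights @ u

    @property
    def rank(self) -> int:
        return self.basis.rank

    def reduce(self, field: np.ndarray) -> np.ndarray:
        return self.basis.modes.T @ field

    def lift(self, u: np.ndarray, clip: bool = True) -> np.ndarray:
        n = self.basis.modes @ u
        return np.clip(n, 0.0, 1.0) if clip else n


def build_snapshots(
    n_v1: np.ndarray,
    n_v2: np.ndarray,
    grid: VoxelGrid,
    visit_days: tuple[float, float] = (0.0, 28.0),
    n_pseudo: int = 8,
    smoothing_widths: tuple[float, ...] = (1.0, 2.0),
) -> SnapshotMatrix:
    """Snapshot matrix bridging the time gap between the two visits.

    Columns are linear pseudo-time interpolations between the V1 and V2
    normalized cellularity fields, each augmented with Gaussian-smoothed
    copies at the given widths (in voxels).  Smoothing is mask-aware
    (normalized convolution), so the breast boundary does not bleed
    zeros into the fields.
    """
    if n_v1.size != grid.n_masked or n_v2.size != grid.n_masked:
        raise ValueError("snapshot fields must live on the masked voxels")
    if n_pseudo < 2:
        raise ValueError("need at least two pseudo-times")
    if not (np.any(n_v1) or np.any(n_v2)):
        raise ValueError("both visit fields are identically zero")
    w = np.linspace(0.0, 1.0, n_pseudo)
    base = n_v1[:, None] * (1 - w)[None, :] + n_v2[:, None] * w[None, :]
    cols = [base]

    mask = grid.breast_mask
    mask_f = mask.astype(float)
    for sigma in smoothing_widths:
        norm = gaussian_filter(mask_f, sigma)
        smoothed = np.empty_like(base)
        for c in range(n_pseudo):
            vol = grid.unflatten(base[:, c])
            sm = gaussian_filter(vol, sigma)
            smoothed[:, c] = (sm / np.maximum(norm, 1e-12))[mask]
        cols.append(smoothed)

    t0, t1 = visit_days
    pseudo = np.concatenate([t0 + w * (t1 - t0)] * len(cols))
    return SnapshotMatrix(columns=np.concatenate(cols, axis=1), pseudo_times=pseudo)


def pod_basis(snapshots: SnapshotMatrix, energy: float = 0.995) -> PODBasis:
    """Truncated SVD basis retaining the requested cumulative energy.

    The rank is the smallest r whose cumulative squared-singular-value
    fraction reaches ``energy`` (conventionally 99.5%).
    """
    if not 0 < energy <= 1:
        raise ValueError("energy must lie in (0, 1]")
    S = snapshots.columns
    if not np.any(S):
        raise ValueError("all-zero snapshot matrix")
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    e = np.cumsum(s**2) / np.sum(s**2)
    r = int(np.searchsorted(e, energy - 1e-12) + 1)
    r = min(r, np.count_nonzero(s > s[0] * 1e-12))
    return PODBasis(modes=U[:, :r], singular_values=s, energy=float(e[r - 1]))


def reduce_proliferation(
    basis: PODBasis,
    k_min: float = 1e-6,
    k_max: float = 0.1,
    n_mc: int = 200,
    seed: int | np.random.Generator = 0,
) -> KLMap:
    """KL map for k(x) with per-coefficient prior bounds.

    The per-voxel prior box [k_min, k_max] has no direct image in the
    reduced space, so per-coefficient bounds are estimated by projecting
    ``n_mc`` uniform random fields plus the two constant extreme fields
    and taking the running min/max of each coefficient.
    """
    if k_min >= k_max:
        raise ValueError("k_min must be below k_max")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    V = basis.modes
    n, r = V.shape
    lo = np.full(r, np.inf)
    hi = np.full(r, -np.inf)
    for field in (np.full(n, k_min), np.full(n, k_max)):
        c = V.T @ field
        lo, hi = np.minimum(lo, c), np.maximum(hi, c)
    batch = 64
    done = 0
    while done < n_mc:
        m = min(batch, n_mc - done)
        C = V.T @ rng.uniform(k_min, k_max, size=(n, m))
        lo = np.minimum(lo, C.min(axis=1))
        hi = np.maximum(hi, C.max(axis=1))
        done += m
    return KLMap(basis=V, lower=lo, upper=hi)


def project_operators(
    grid: VoxelGrid,
    basis: PODBasis,
    auc_maps: list[np.ndarray],
    theta_cap: float,
    k_map: KLMap | None = None,
) -> ReducedModel:
    """Galerkin projection of all model operators onto the POD basis."""
    V = basis.modes
    n, r = V.shape
    if n != grid.n_masked:
        raise ValueError("basis does not match grid")
    L = masked_laplacian(grid)
    A_unit = V.T @ (L @ V)

    B_units = np.empty((r, r, r))
    G_units = np.empty((r, r, r, r))
    # Z[x, b*r+c] = V[x,b] V[x,c]; one pass gives the projected quadratic term
    Z = (V[:, :, None] * V[:, None, :]).reshape(n, r * r)
    for i in range(r):
        Wi = V * V[:, i : i + 1]  # diag(phi_i) applied columnwise
        B_units[i] = V.T @ Wi
        G_units[i] = (Wi.T @ Z).reshape(r, r, r)

    T_units = np.empty((len(auc_maps), r, r))
    for m, auc in enumerate(auc_maps):
        if auc.size != n:
            raise ValueError("AUC map does not match grid")
        T_units[m] = V.T @ (V * auc[:, None])

    if k_map is None:
        k_map = reduce_proliferation(basis)
    return ReducedModel(
        grid=grid,
        theta_cap=theta_cap,
        basis=basis,
        A_unit=A_unit,
        B_units=B_units,
        G_units=G_units,
        T_units=T_units,
        k_map=k_map,
        cells_weights=V.sum(axis=0),
    )


def simulate_rom_batch(
    rom: ReducedModel,
    D: np.ndarray,
    alpha: np.ndarray,
    beta: dict[str, np.ndarray],
    Kr: np.ndarray,
    regimen: TreatmentRegimen,
    auc_assign: dict[str, np.ndarray],
    u0: np.ndarray,
    t_span: tuple[float, float],
    dt: float | None = None,
    store_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the reduced dynamics for a batch of parameter samples.

    Parameters are arrays over samples: ``D, alpha`` shape (S,), ``beta``
    per drug (S,), ``Kr`` shape (S, r).  ``u0`` may be a single reduced
    state (r,) shared by all samples or a per-sample (S, r) array.

    Returns ``(store_times, U)`` with ``U`` of shape (S, n_store, r).
    Bulk cell counts follow as ``theta * U @ cells_weights``.
    """
    D = np.atleast_1d(np.asarray(D, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    Kr = np.atleast_2d(np.asarray(Kr, dtype=float))
    S, r = Kr.shape
    if r != rom.rank:
        raise ValueError("k_r dimension does not match the basis rank")
    beta = {j: np.atleast_1d(np.asarray(b, dtype=float)) for j, b in beta.items()}

    u = np.broadcast_to(np.asarray(u0, dtype=float), (S, r)).copy()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if dt is None:
        k_lift_max = float(np.abs(rom.k_map.lift(Kr.T)).max()) if Kr.size else 0.0
        dt = stable_dt(rom.grid, float(D.max()), k_lift_max, float(alpha.max()))
    n_steps = int(np.ceil((t1 - t0) / dt - 1e-12))

    # per-sample affine recombination, done once
    M = D[:, None, None] * rom.A_unit + np.einsum("si,iab->sab", Kr, rom.B_units)
    G = np.einsum("si,iabc->sabc", Kr, rom.G_units)

    # scalar treatment weights per step, drug and delivery, precomputed
    step_sizes = np.full(n_steps, dt)
    overshoot = t0 + n_steps * dt - t1
    if overshoot > 1e-12:
        step_sizes[-1] -= overshoot
    t_steps = t0 + np.concatenate([[0.0], np.cumsum(step_sizes[:-1])])
    # W[n, s, m]: total weight multiplying T_units[m] at step n for sample s
    n_maps = rom.T_units.shape[0]
    W = np.zeros((n_steps, S, n_maps))
    for j in regimen.drugs:
        tau, dose = regimen.times[j], regimen.doses[j]
        active = dose > 0
        if not np.any(active):
            continue
        tau_a, dose_a, map_a = tau[active], dose[active], auc_assign[j][active]
        # step-averaged decay weight over [t_n, t_n + h_n] (exact for the
        # exponential; left-endpoint sampling over-integrates fast decays)
        lower = np.maximum(t_steps[:, None] - tau_a[None, :], 0.0)  # (n_steps, K)
        upper = (t_steps + step_sizes)[:, None] - tau_a[None, :]
        on = upper > 0
        b = beta[j][None, :, None]  # (1, S, 1)
        e_lo = np.exp(-b * lower[:, None, :])
        e_hi = np.exp(-b * np.where(on, upper, 1.0)[:, None, :])
        decay = np.where(on[:, None, :], (e_lo - e_hi) / (b * step_sizes[:, None, None]), 0.0)
        contrib = alpha[None, :, None] * dose_a[None, None, :] * decay  # (n, S, K)
        for m in range(n_maps):
            sel = map_a == m
            if np.any(sel):
                W[:, :, m] += contrib[:, :, sel].sum(axis=2)

    if store_times is None:
        store_times = np.array([t0, t1])
    store_times = np.asarray(store_times, dtype=float)
    U_out = np.empty((S, store_times.size, r))
    # number of completed steps after which each store time is reached
    t_after = np.concatenate([[t0], t0 + np.cumsum(step_sizes)])
    rec_after = np.searchsorted(t_after, store_times - 1e-9)

    if _HAVE_NUMBA:
        _euler_kernel(
            np.ascontiguousarray(M), np.ascontiguousarray(G),
            np.ascontiguousarray(rom.T_units), np.ascontiguousarray(W),
            u, step_sizes, rec_after.astype(np.int64), U_out,
        )
    else:
        next_store = 0
        for k in np.flatnonzero(rec_after == 0):
            U_out[:, k, :] = u
            next_store = k + 1
        for step_idx in range(n_steps):
            rhs = np.einsum("sab,sb->sa", M, u)
            rhs -= np.einsum("sabc,sb,sc->sa", G, u, u)
            w = W[step_idx]
            if w.any():
                rhs -= np.einsum("sm,mab,sb->sa", w, rom.T_units, u)
            u = u + step_sizes[step_idx] * rhs
            while next_store < store_times.size and rec_after[next_store] == step_idx + 1:
                U_out[:, next_store, :] = u
                next_store += 1
    if not np.all(np.isfinite(U_out)):
        raise FloatingPointError("non-finite reduced state (dt too large?)")
    return store_times, U_out


def simulate_rom(
    rom: ReducedModel,
    params,
    regimen: TreatmentRegimen,
    auc_assign: dict[str, np.ndarray],
    u0: np.ndarray,
    t_span: tuple[float, float],
    dt: float | None = None,
    store_times: np.ndarray | None = None,
    store_every: float = 0.5,
    volume_fraction_threshold: float = 0.01,
    lift_fields: bool = False,
) -> SimulationResult:
    """Single-sample reduced simulation with bulk summaries.

    ``params.k`` holds the reduced coefficients k_r.  Volumes require
    lifting to the voxel grid, done only at the stored times.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if store_times is None:
        store_times = np.arange(t0, t1 + 1e-9, store_every)
        if store_times[-1] < t1 - 1e-9:
            store_times = np.append(store_times, t1)
    _, U = simulate_rom_batch(
        rom,
        np.array([params.D]),
        np.array([params.alpha]),
        {j: np.array([params.beta[j]]) for j in params.beta},
        params.k[None, :],
        regimen,
        auc_assign,
        u0,
        (t0, t1),
        dt=dt,
        store_times=store_times,
    )
    traj = U[0]
    voxvol = rom.grid.voxel_volume
    cells = np.empty(store_times.size)
    vols = np.empty(store_times.size)
    fields = {}
    for i, ts in enumerate(store_times):
        n_full = rom.lift(traj[i])
        cells[i] = rom.theta_cap * n_full.sum()
        vols[i] = np.count_nonzero(n_full >= volume_fraction_threshold) * voxvol / 1000.0
        if lift_fields:
            fields[float(ts)] = n_full
    return SimulationResult(times=store_times, total_cells=cells, volumes=vols, fields=fields)
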