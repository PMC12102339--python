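"""Full-order reaction-diffusion model of tumor growth and chemo response.

The model couples Fisher-Kolmogorov invasion/growth with an exponential-
decay chemotherapy kill term, on the voxel grid restricted to the breast
mask::

    dN/dt = D lap(N) + k(x) N (1 - N) - N sum_j gamma_j(x, t)

with N the cellularity normalized by the carrying capacity (N in [0,1]),
D the diffusivity (mm^2/day), k(x) a spatially resolved proliferation
rate (1/day), and gamma_j the kill rate of drug j: drug efficacy alpha
times the local delivery surrogate (the AUC map of the most recent
contrast-enhanced session) times the decaying dose concentration.

Discretization: 2nd-order central differences with zero-flux boundaries
at the breast-mask edge (out-of-mask fluxes dropped), explicit forward
Euler in time with a stability-bounded step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .grids import VoxelGrid
from .regimen import TreatmentRegimen


@dataclass
class ParamVector:
    """Calibration unknowns: (D, k, alpha, beta_A, beta_C).

    ``k`` is either the full-order per-voxel proliferation vector (on the
    masked voxels) or the reduced Karhunen-Loeve coefficients, depending
    on which solver consumes it.
    """

    D: float
    alpha: float
    beta: dict[str, float]
    k: np.ndarray

    # prior support (per-voxel k bounds; reduced-space bounds are derived)
    BOUNDS = {
        "D": (1e-6, 1e-3),
        "alpha": (1e-6, 1.0),
        "beta_A": (0.35, 0.85),
        "beta_C": (1.0, 5.5),
        "k": (1e-6, 0.1),
    }

    def __post_init__(self):
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))


@dataclass
class SimulationResult:
    """Stored bulk time courses (and optionally full fields) of one run."""

    times: np.ndarray
    total_cells: np.ndarray  # cells
    volumes: np.ndarray  # mL
    fields: dict[float, np.ndarray] = field(default_factory=dict)  # time -> masked vector (normalized)

    def at(self, t: float) -> np.ndarray:
        key = min(self.fields, key=lambda s: abs(s - t))
        if abs(key - t) > 1e-6:
            raise KeyError(f"no stored field near t={t}")
        return self.fields[key]


def masked_laplacian(grid: VoxelGrid) -> sp.csr_matrix:
    """Unit-diffusivity 7-point Laplacian on the masked voxels.

    Only neighbor pairs with both voxels inside the breast mask
    contribute; fluxes through missing neighbors are dropped, which is
    the finite-volume statement of a homogeneous Neumann (zero-flux)
    boundary.  Row sums are identically zero, so the operator conserves
    total mass.
    """
    mask = grid.breast_mask
    if not mask.any():
        raise ValueError("breast mask is empty")
    n = grid.n_masked
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(n)

    rows, cols, vals = [], [], []
    for axis, h in enumerate(grid.spacing):
        w = 1.0 / h**2
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        i = index[tuple(sl_lo)][pair]
        j = index[tuple(sl_hi)][pair]
        # symmetric exchange term: +w off-diagonal, -w on both diagonals
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([np.full(i.size, w), np.full(i.size, w), np.full(i.size, -w), np.full(i.size, -w)])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def assemble_operators(grid: VoxelGrid, params: ParamVector) -> dict:
    """Operator form of the model: A = D*L, B = diag(k), H = k N^2 handle."""
    L = masked_laplacian(grid)
    if params.k.size != grid.n_masked:
        raise ValueError("full-order k must have one entry per masked voxel")
    return {"L": L, "A": params.D * L, "k": params.k}


def assign_auc_maps(regimen: TreatmentRegimen, visit_days: dict[str, float]) -> dict[str, np.ndarray]:
    """Index of the AUC map feeding each delivery: the most recent visit.

    Each delivery at day tau uses the map from the latest imaging visit
    acquired on or before tau (deliveries preceding all visits fall back
    to the first visit's map).  Returns, per drug, an integer array over
    deliveries indexing the visits in chronological order.
    """
    order = sorted(visit_days, key=visit_days.get)
    days = np.array([visit_days[v] for v in order])
    out = {}
    for j in regimen.drugs:
        idx = np.searchsorted(days, regimen.times[j], side="right") - 1
        out[j] = np.clip(idx, 0, len(order) - 1)
    return out


def delivery_weights(
    regimen: TreatmentRegimen,
    alpha: float | np.ndarray,
    beta: dict[str, float | np.ndarray],
    t: float,
    step: float | None = None,
) -> dict[str, np.ndarray]:
    """Scalar kill-rate weight of each delivery at time t (per drug).

    ``w_{j,k}(t) = alpha * C_{j,k} * 1[C_{j,k} >= 0.1 via canonicalization]
    * 1[t >= tau_{j,k}] * exp(-beta_j (t - tau_{j,k}))``.  With array
    ``alpha``/``beta`` (posterior samples, shape (S,)) the result is
    (S, K) per drug.

    With ``step`` given, the instantaneous decay factor is replaced by
    its exact average over ``[t, t + step]``: the cyclophosphamide decay
    (beta up to 5.5/day) is fast on the explicit-Euler step, and
    sampling it at the left endpoint would over-integrate every kill
    pulse by O(beta*dt/2).
    """
    out = {}
    for j in regimen.drugs:
        tau = regimen.times[j]
        b = np.asarray(beta[j], dtype=float)
        if step is None:
            dt = t - tau
            gate = dt >= 0
            decay = np.where(gate, np.exp(-np.multiply.outer(b, np.where(gate, dt, 0.0))), 0.0)
        else:
            lower = np.maximum(t - tau, 0.0)
            upper = (t + step) - tau
            active = upper > 0
            up = np.where(active, upper, 1.0)
            e_lo = np.exp(-np.multiply.outer(b, lower))
            e_hi = np.exp(-np.multiply.outer(b, up))
            decay = np.where(active, (e_lo - e_hi) / np.multiply.outer(b, np.full_like(lower, step)), 0.0)
        out[j] = np.multiply.outer(np.asarray(alpha, dtype=float), regimen.doses[j]) * decay
    return out


def treatment_field(
    params: ParamVector,
    regimen: TreatmentRegimen,
    auc_maps: list[np.ndarray],
    auc_assign: dict[str, np.ndarray],
    t: float,
    step: float | None = None,
) -> np.ndarray:
    """Total kill-rate field gamma(x, t) = sum_j gamma_j(x, t), 1/day.

    ``auc_maps`` are masked vectors in visit order; ``auc_assign`` maps
    each delivery to its AUC map (see :func:`assign_auc_maps`); ``step``
    requests step-averaged decay weights (see :func:`delivery_weights`).
    """
    w = delivery_weights(regimen, params.alpha, params.beta, t, step=step)
    gamma = np.zeros_like(auc_maps[0])
    for j in regimen.drugs:
        for k, wk in enumerate(np.atleast_1d(w[j].squeeze())):
            if wk > 0:
                gamma += wk * auc_maps[auc_assign[j][k]]
    return gamma


def stable_dt(
    grid: VoxelGrid,
    D: float,
    k_max: float,
    alpha: float,
    dt_max: float = 0.025,
) -> float:
    """Explicit-Euler step bound: diffusive CFL plus a reaction-rate guard.

    The cap of 0.025 day is accuracy-motivated rather than a stability
    limit: halving it moves the reference bulk-cell trajectory by about
    0.3%, so the first-order scheme is inside its convergent regime even
    during the fast chemotherapy kill pulses.
    """
    inv_h2 = sum(1.0 / h**2 for h in grid.spacing)
    cfl = 1.0 / (2.0 * max(D, 1e-12) * inv_h2)
    reaction = 0.5 / max(k_max + alpha, 1e-12)
    return min(dt_max, cfl, reaction)


def simulate_fom(
    grid: VoxelGrid,
    theta_cap: float,
    params: ParamVector,
    regimen: TreatmentRegimen,
    auc_maps: list[np.ndarray],
    auc_assign: dict[str, np.ndarray] | None,
    n0: np.ndarray,
    t_span: tuple[float, float],
    dt: float | None = None,
    store_times: np.ndarray | None = None,
    store_every: float = 0.5,
    volume_fraction_threshold: float = 0.01,
) -> SimulationResult:
    """Explicit-Euler integration of the full-order model.

    ``n0`` is the initial normalized cellularity on the masked voxels
    (N/theta in [0,1]); bulk outputs are converted back to cells using
    ``theta_cap``.  The state is clipped to [0, 1] after each step
    (explicit schemes can overshoot near the capacity).
    """
    n = np.asarray(n0, dtype=float).copy()
    if n.size != grid.n_masked:
        raise ValueError("initial condition must live on the masked voxels")
    if np.any((n < -1e-12) | (n > 1 + 1e-12)):
        raise ValueError("initial cellularity outside [0, theta]")
    t0, t1 = float(t_span[0]), float(t_span[1])
    kvec = params.k
    if kvec.size != grid.n_masked:
        raise ValueError("full-order k must have one entry per masked voxel")
    if dt is None:
        dt = stable_dt(grid, params.D, float(kvec.max(initial=0.0)), params.alpha)
    L = masked_laplacian(grid)
    if auc_assign is None:
        auc_assign = {j: np.zeros(regimen.n_deliveries(j), dtype=int) for j in regimen.drugs}

    if store_times is None:
        store_times = np.arange(t0, t1 + 1e-9, store_every)
        if store_times[-1] < t1 - 1e-9:
            store_times = np.append(store_times, t1)
    store_times = np.asarray(store_times, dtype=float)

    n_steps = int(np.ceil((t1 - t0) / dt - 1e-12))
    voxvol = grid.voxel_volume
    times_out, cells_out, vols_out = [], [], []
    fields: dict[float, np.ndarray] = {}
    next_store = 0

    def record(t_now):
        nonlocal next_store
        while next_store < store_times.size and store_times[next_store] <= t_now + 1e-9:
            ts = store_times[next_store]
            times_out.append(ts)
            cells_out.append(theta_cap * n.sum())
            vols_out.append(np.count_nonzero(n >= volume_fraction_threshold) * voxvol / 1000.0)
            fields[float(ts)] = n.copy()
            next_store += 1

    t = t0
    record(t)
    for _ in range(n_steps):
        step = min(dt, t1 - t)
        gamma = (
            treatment_field(params, regimen, auc_maps, auc_assign, t, step=step)
            if regimen.drugs
            else 0.0
        )
        rhs = params.D * (L @ n) + kvec * n * (1.0 - n) - n * gamma
        n += step * rhs
        if not np.all(np.isfinite(n)):
            raise FloatingPointError(f"non-finite state at t={t + step:.3f} (dt too large?)")
        np.clip(n, 0.0, 1.0, out=n)
        t += step
        record(t)

    return SimulationResult(
        times=np.asarray(times_out),
        total_cells=np.asarray(cells_out),
        volumes=np.asarray(vols_out),
        fields=fields,
    )
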