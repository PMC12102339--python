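"""Likelihood-free calibration of the patient-specific digital state.

The unknowns are theta = (D, k_r, alpha, beta_A, beta_C).  Priors encode
parameter identifiability: diffusivity and the drug decay rates are not
identifiable from two imaging visits and get informative truncated
normals from the literature, while drug efficacy and the reduced
proliferation coefficients are identifiable and get uniform priors.

Calibration is rejection approximate Bayesian computation (ABC): draw
theta from the priors, run the reduced model from the first visit to the
second, and accept when the mean squared error between the simulated and
measured reduced states falls below a tolerance epsilon.  Epsilon is set
patient-specifically to the MSE achieved by a deterministic
Levenberg-Marquardt point fit, so the accepted set spans parameter
vectors that explain the data about as well as the best least-squares
solution.  The 500 accepted samples are the calibrated digital state.

Because the parameter vector has four more degrees of freedom than the
reduced V2 residual, the box-constrained point fit can interpolate the
data essentially exactly, collapsing the tolerance toward the solver
floor; the acceptance region then has vanishing prior measure and plain
rejection aborts by its rate-floor contract.  Two safeguards make the
calibration well-posed: the tolerance is floored at a small fraction of
the mean squared reduced data (a numerical regularization — the
posterior is insensitive to the floor over several decades), and a
sequential (population Monte Carlo) sampler anneals epsilon down to the
target through intermediate populations, reaching tolerances plain
rejection cannot.  The pipeline uses the sequential mode by default;
rejection remains available for permissive tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit
from scipy.stats import truncnorm, uniform

from .forward import ParamVector
from .regimen import TreatmentRegimen
from .rom import KLMap, ReducedModel, simulate_rom_batch


def _truncnorm(mu, sigma, a, b):
    return truncnorm((a - mu) / sigma, (b - mu) / sigma, loc=mu, scale=sigma)


@dataclass
class PriorSet:
    """Frozen prior distributions for every component of theta."""

    D: object
    alpha: object
    beta: dict[str, object]
    k_r: list[object]
    bounds: dict[str, tuple[float, float]]
    k_bounds: tuple[np.ndarray, np.ndarray]

    @property
    def n_k(self) -> int:
        return len(self.k_r)

    @property
    def n_params(self) -> int:
        return 4 + self.n_k

    def sample(self, rng: np.random.Generator, size: int) -> dict[str, np.ndarray]:
        out = {
            "D": self.D.rvs(size=size, random_state=rng),
            "alpha": self.alpha.rvs(size=size, random_state=rng),
            "beta_A": self.beta["A"].rvs(size=size, random_state=rng),
            "beta_C": self.beta["C"].rvs(size=size, random_state=rng),
            "Kr": np.column_stack([d.rvs(size=size, random_state=rng) for d in self.k_r])
            if self.n_k
            else np.empty((size, 0)),
        }
        return out

    def logpdf(self, flat: np.ndarray) -> float:
        d, a, bA, bC = flat[:4]
        lp = (
            self.D.logpdf(d)
            + self.alpha.logpdf(a)
            + self.beta["A"].logpdf(bA)
            + self.beta["C"].logpdf(bC)
        )
        for i, dist in enumerate(self.k_r):
            lp += dist.logpdf(flat[4 + i])
        return float(lp)


def default_priors(k_map: KLMap) -> PriorSet:
    """Literature priors for (D, alpha, beta) plus uniform k_r priors.

    D ~ TN(0.5e-4, 2.5e-4; 1e-6, 1e-3) mm^2/day, alpha ~ U(1e-6, 1) 1/day,
    beta_A ~ TN(0.60, 0.06; 0.35, 0.85) 1/day,
    beta_C ~ TN(3.25, 0.56; 1.00, 5.50) 1/day,
    k_r,i ~ U(lower_i, upper_i) from the Karhunen-Loeve bound estimate.
    """
    bounds = dict(ParamVector.BOUNDS)
    return PriorSet(
        D=_truncnorm(0.5e-4, 2.5e-4, *bounds["D"]),
        alpha=uniform(bounds["alpha"][0], bounds["alpha"][1] - bounds["alpha"][0]),
        beta={
            "A": _truncnorm(0.60, 0.06, *bounds["beta_A"]),
            "C": _truncnorm(3.25, 0.56, *bounds["beta_C"]),
        },
        k_r=[uniform(lo, hi - lo) for lo, hi in zip(k_map.lower, k_map.upper)],
        bounds={k: bounds[k] for k in ("D", "alpha", "beta_A", "beta_C")},
        k_bounds=(k_map.lower.copy(), k_map.upper.copy()),
    )


@dataclass
class PosteriorEnsemble:
    """Accepted parameter samples: the calibrated digital state."""

    D: np.ndarray
    alpha: np.ndarray
    beta_A: np.ndarray
    beta_C: np.ndarray
    Kr: np.ndarray  # (n, r)
    distances: np.ndarray
    epsilon: float
    attempts: int

    def __len__(self) -> int:
        return self.D.size

    @property
    def beta(self) -> dict[str, np.ndarray]:
        return {"A": self.beta_A, "C": self.beta_C}

    def param_vector(self, i: int) -> ParamVector:
        return ParamVector(
            D=float(self.D[i]),
            alpha=float(self.alpha[i]),
            beta={"A": float(self.beta_A[i]), "C": float(self.beta_C[i])},
            k=self.Kr[i],
        )

    @classmethod
    def from_samples(cls, samples: dict[str, np.ndarray], distances, epsilon, attempts):
        return cls(
            D=np.asarray(samples["D"], dtype=float),
            alpha=np.asarray(samples["alpha"], dtype=float),
            beta_A=np.asarray(samples["beta_A"], dtype=float),
            beta_C=np.asarray(samples["beta_C"], dtype=float),
            Kr=np.asarray(samples["Kr"], dtype=float),
            distances=np.asarray(distances, dtype=float),
            epsilon=float(epsilon),
            attempts=int(attempts),
        )


@dataclass
class PatientData:
    """Reduced-space view of one patient's calibration inputs."""

    u0: np.ndarray  # reduced V1 state (initial condition)
    data_v2: np.ndarray  # reduced V2 state (calibration target)
    visit_days: tuple[float, float]  # (V1, V2) in days
    regimen: TreatmentRegimen  # canonicalized delivered regimen
    auc_assign: dict[str, np.ndarray]


def _simulate_batch_v2(rom: ReducedModel, data: PatientData, samples: dict[str, np.ndarray]) -> np.ndarray:
    """Reduced state at V2 for a batch of parameter samples, shape (S, r)."""
    _, U = simulate_rom_batch(
        rom,
        samples["D"],
        samples["alpha"],
        {"A": samples["beta_A"], "C": samples["beta_C"]},
        samples["Kr"],
        data.regimen,
        data.auc_assign,
        data.u0,
        data.visit_days,
        store_times=np.array([data.visit_days[1]]),
    )
    return U[:, -1, :]


def reduced_mse(rom: ReducedModel, data: PatientData, samples: dict[str, np.ndarray]) -> np.ndarray:
    """Distance rho: MSE between simulated and measured reduced V2 states."""
    u_v2 = _simulate_batch_v2(rom, data, samples)
    return np.mean((u_v2 - data.data_v2[None, :]) ** 2, axis=1)


def _flat_bounds(priors: PriorSet) -> tuple[np.ndarray, np.ndarray]:
    lo = np.concatenate([
        [priors.bounds["D"][0], priors.bounds["alpha"][0], priors.bounds["beta_A"][0], priors.bounds["beta_C"][0]],
        priors.k_bounds[0],
    ])
    hi = np.concatenate([
        [priors.bounds["D"][1], priors.bounds["alpha"][1], priors.bounds["beta_A"][1], priors.bounds["beta_C"][1]],
        priors.k_bounds[1],
    ])
    return lo, hi


def _flat_to_samples(flat: np.ndarray) -> dict[str, np.ndarray]:
    flat = np.atleast_2d(flat)
    return {
        "D": flat[:, 0],
        "alpha": flat[:, 1],
        "beta_A": flat[:, 2],
        "beta_C": flat[:, 3],
        "Kr": flat[:, 4:],
    }


def _samples_to_flat(samples: dict[str, np.ndarray]) -> np.ndarray:
    return np.column_stack([samples["D"], samples["alpha"], samples["beta_A"], samples["beta_C"], samples["Kr"]])


def epsilon_floor(data: PatientData, frac: float = 1e-3) -> float:
    """Tolerance floor: ``frac`` times the mean squared reduced data.

    Guards against the degenerate case where the point fit interpolates
    the data exactly and the raw tolerance collapses to the solver
    floor, leaving an acceptance region of vanishing prior measure.
    """
    return frac * float(np.mean(data.data_v2**2))


def lm_fit(
    rom: ReducedModel,
    data: PatientData,
    priors: PriorSet,
    n_starts: int = 4,
    seed: int = 0,
    max_nfev: int = 150,
) -> tuple[ParamVector, float, bool]:
    """Box-constrained least-squares point fit defining the ABC tolerance.

    The Levenberg-Marquardt iteration runs in a sigmoid-transformed
    unconstrained space so every iterate respects the prior box.
    Multiple seeded starts guard against local minima; the best final
    cost sets epsilon (the reduced-space MSE of the fit).  Returns
    ``(theta_LM, epsilon, converged)``.
    """
    lo, hi = _flat_bounds(priors)
    span = hi - lo

    def to_box(z):
        return lo + span * expit(z)

    def to_z(x):
        frac = np.clip((x - lo) / span, 1e-9, 1 - 1e-9)
        return logit(frac)

    def residual(z):
        samples = _flat_to_samples(to_box(z))
        u_v2 = _simulate_batch_v2(rom, data, samples)
        return (u_v2[0] - data.data_v2).ravel()

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    for _ in range(n_starts - 1):
        s = priors.sample(rng, 1)
        starts.append(_samples_to_flat(s)[0])

    # MINPACK's LM needs at least as many residuals as unknowns; the
    # reduced residual has r components against 4 + r parameters, so the
    # trust-region reflective variant (same damped Gauss-Newton family)
    # handles the underdetermined case.
    n_params = 4 + priors.n_k
    method = "lm" if data.data_v2.size >= n_params else "trf"

    best = None
    converged = False
    for x0 in starts:
        try:
            res = least_squares(residual, to_z(x0), method=method, max_nfev=max_nfev)
        except Exception:
            continue
        cost = np.mean(res.fun**2)
        if best is None or cost < best[1]:
            best = (to_box(res.x), cost)
            converged = converged or res.status > 0
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    flat, eps = best
    theta = ParamVector(D=flat[0], alpha=flat[1], beta={"A": flat[2], "C": flat[3]}, k=flat[4:])
    return theta, float(eps), converged


def abc_rejection(
    rom: ReducedModel,
    data: PatientData,
    priors: PriorSet,
    epsilon: float,
    n_accept: int = 500,
    max_attempts: int = 5_000_000,
    batch_size: int = 2000,
    rate_floor: float = 1e-4,
    seed: int = 0,
) -> PosteriorEnsemble:
    """Plain rejection ABC: accept theta ~ prior iff rho(theta) <= epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    n_found = 0
    attempts = 0
    while n_found < n_accept:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"ABC accepted only {n_found}/{n_accept} in {attempts} attempts; epsilon={epsilon:.3g} too tight"
            )
        m = min(batch_size, max_attempts - attempts)
        samples = priors.sample(rng, m)
        d = reduced_mse(rom, data, samples)
        keep = d <= epsilon
        attempts += m
        if np.any(keep):
            accepted.append(_samples_to_flat(samples)[keep])
            dists.append(d[keep])
            n_found += int(keep.sum())
        if attempts >= max(10 * batch_size, 50_000) and n_found / attempts < rate_floor and n_found < n_accept:
            raise RuntimeError(
                f"ABC acceptance rate {n_found / attempts:.2e} below floor {rate_floor:.0e}; epsilon too tight"
            )
    flat = np.concatenate(accepted)[:n_accept]
    d = np.concatenate(dists)[:n_accept]
    return PosteriorEnsemble.from_samples(_flat_to_samples(flat), d, epsilon, attempts)


def abc_smc(
    rom: ReducedModel,
    data: PatientData,
    priors: PriorSet,
    epsilon: float,
    n_accept: int = 500,
    max_generations: int = 30,
    quantile: float = 0.5,
    max_attempts: int = 2_000_000,
    seed: int = 0,
) -> PosteriorEnsemble:
    """Sequential ABC (population Monte Carlo) annealing down to epsilon.

    The first generation samples the priors with an all-accepting
    tolerance; each later generation resamples the previous population
    with importance weights, perturbs with a Gaussian kernel (twice the
    weighted population variance, the usual PMC choice), and lowers the
    tolerance to the ``quantile`` of the previous accepted distances
    until the target epsilon is reached.
    """
    rng = np.random.default_rng(seed)
    lo, hi = _flat_bounds(priors)
    attempts = 0

    # generation 0: draw from the prior
    samples = priors.sample(rng, n_accept)
    flat = _samples_to_flat(samples)
    d = reduced_mse(rom, data, samples)
    attempts += n_accept
    weights = np.full(n_accept, 1.0 / n_accept)

    n_dim = flat.shape[1]
    generation = 0
    while True:
        eps_t = max(float(np.quantile(d, quantile)), epsilon)
        generation += 1
        if generation > max_generations:
            raise RuntimeError(
                f"sequential ABC did not reach epsilon={epsilon:.3g} in {max_generations} generations"
            )
        # full-covariance kernel (twice the weighted population covariance):
        # the acceptance region collapses onto a thin curved manifold, and a
        # diagonal kernel steps off it almost surely once eps is small
        cov = 2.0 * np.atleast_2d(np.cov(flat.T, aweights=weights))
        cov += np.eye(n_dim) * (1e-12 * max(np.trace(cov) / n_dim, 1e-30))
        chol = np.linalg.cholesky(cov)
        cov_inv = np.linalg.inv(cov)
        new_flat = np.empty_like(flat)
        new_d = np.empty(n_accept)
        n_found = 0
        while n_found < n_accept:
            if attempts >= max_attempts:
                raise RuntimeError(f"sequential ABC exhausted {max_attempts} attempts at eps={eps_t:.3g}")
            m = min(2000, max_attempts - attempts)
            idx = rng.choice(n_accept, size=m, p=weights)
            cand = flat[idx] + rng.standard_normal((m, n_dim)) @ chol.T
            inb = np.all((cand >= lo) & (cand <= hi), axis=1)
            attempts += m
            cand = cand[inb]
            if cand.size == 0:
                continue
            dc = reduced_mse(rom, data, _flat_to_samples(cand))
            keep = dc <= eps_t
            cand, dc = cand[keep], dc[keep]
            take = min(cand.shape[0], n_accept - n_found)
            new_flat[n_found : n_found + take] = cand[:take]
            new_d[n_found : n_found + take] = dc[:take]
            n_found += take
        # importance weights, vectorized over the new population
        diff = new_flat[:, None, :] - flat[None, :, :]  # (new, old, p)
        maha = np.einsum("nop,pq,noq->no", diff, cov_inv, diff)
        denom = (np.exp(-0.5 * maha) * weights[None, :]).sum(axis=1)
        prior_pdf = np.array([np.exp(priors.logpdf(c)) for c in new_flat])
        new_w = prior_pdf / np.maximum(denom, 1e-300)
        flat, d = new_flat, new_d
        weights = new_w / new_w.sum()
        if eps_t <= epsilon:
            break

    # resample to equal weights for the final ensemble
    idx = rng.choice(n_accept, size=n_accept, p=weights)
    return PosteriorEnsemble.from_samples(_flat_to_samples(flat[idx]), d[idx], epsilon, attempts)


@dataclass
class PredictiveSummary:
    times: np.ndarray
    cells: np.ndarray  # (S, T) per-sample total cells
    volumes: np.ndarray  # (S, T) per-sample tumor volume, mL
    cells_median: np.ndarray
    cells_iqr: tuple[np.ndarray, np.ndarray]
    volumes_median: np.ndarray
    volumes_iqr: tuple[np.ndarray, np.ndarray]


def posterior_predict(
    rom: ReducedModel,
    ensemble: PosteriorEnsemble,
    regimen: TreatmentRegimen,
    auc_assign: dict[str, np.ndarray],
    u0: np.ndarray,
    t_span: tuple[float, float],
    store_every: float = 1.0,
    volume_fraction_threshold: float = 0.01,
) -> PredictiveSummary:
    """Simulate every accepted sample and summarize the bulk time courses.

    Cell counts and volumes are computed from the lifted (voxel-space,
    clipped) states at the stored times; the median and interquartile
    range are taken pointwise in time across the ensemble.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    t0, t1 = float(t_span[0]), float(t_span[1])
    store = np.arange(t0, t1 + 1e-9, store_every)
    if store[-1] < t1 - 1e-9:
        store = np.append(store, t1)
    _, U = simulate_rom_batch(
        rom,
        ensemble.D,
        ensemble.alpha,
        ensemble.beta,
        ensemble.Kr,
        regimen,
        auc_assign,
        u0,
        (t0, t1),
        store_times=store,
    )
    S, T, _ = U.shape
    V = rom.basis.modes
    cells = np.empty((S, T))
    vols = np.empty((S, T))
    voxvol = rom.grid.voxel_volume
    for ti in range(T):
        lifted = np.clip(U[:, ti, :] @ V.T, 0.0, 1.0)  # (S, n_vox)
        cells[:, ti] = rom.theta_cap * lifted.sum(axis=1)
        vols[:, ti] = (lifted >= volume_fraction_threshold).sum(axis=1) * voxvol / 1000.0
    q1c, medc, q3c = np.percentile(cells, [25, 50, 75], axis=0)
    q1v, medv, q3v = np.percentile(vols, [25, 50, 75], axis=0)
    return PredictiveSummary(
        times=store,
        cells=cells,
        volumes=vols,
        cells_median=medc,
        cells_iqr=(q1c, q3c),
        volumes_median=medv,
        volumes_iqr=(q1v, q3v),
    )
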