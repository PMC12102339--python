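"""Chemotherapy regimens: schedules, dose bookkeeping, concentration decay.

A regimen is, per drug, a list of delivery days and normalized doses
(NU; 1 NU = the drug's maximum tolerated dose).  Doses below 10% of the
MTD are not recognized as deliveries and are zeroed at canonicalization,
so that dose accounting, concentration curves and the treatment term of
the growth model all see the same effective schedule.  Each delivered
dose decays exponentially at the drug-specific rate ``beta`` (1/day);
contributions are gated on ``t >= tau`` (a dose is active from its
delivery instant onward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: doses below this fraction of the MTD are not recognized as deliveries
DOSE_THRESHOLD = 0.1

#: maximum tolerated doses, mg/m^2 (metadata only; all arithmetic is in NU)
MTD_MG_PER_M2 = {"A": 60.0, "C": 600.0}

DRUG_NAMES = {"A": "Adriamycin", "C": "Cyclophosphamide"}


@dataclass(frozen=True)
class DrugSpec:
    name: str
    mtd_mg_per_m2: float


@dataclass
class TreatmentRegimen:
    """Per-drug delivery days and normalized doses."""

    times: dict[str, np.ndarray] = field(default_factory=dict)
    doses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for j in self.times:
            t = np.atleast_1d(np.asarray(self.times[j], dtype=float))
            d = np.atleast_1d(np.asarray(self.doses[j], dtype=float))
            if t.shape != d.shape:
                raise ValueError(f"times/doses length mismatch for drug {j!r}")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"delivery times must be non-decreasing for {j!r}")
            if np.any(t < 0):
                raise ValueError("delivery times must be non-negative")
            if np.any((d < 0) | (d > 1)):
                raise ValueError("normalized doses must lie in [0, 1]")
            self.times[j], self.doses[j] = t, d

    @property
    def drugs(self) -> list[str]:
        return list(self.times)

    def n_deliveries(self, drug: str) -> int:
        return int(self.times[drug].size)

    def last_delivery(self) -> float:
        days = [t[d > 0].max() for t, d in zip(self.times.values(), self.doses.values()) if np.any(d > 0)]
        return float(max(days)) if days else 0.0

    def to_json(self) -> str:
        payload = {
            j: [{"day": float(t), "dose": float(d)} for t, d in zip(self.times[j], self.doses[j])]
            for j in self.drugs
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TreatmentRegimen":
        payload = json.loads(text)
        times = {j: np.array([e["day"] for e in entries], dtype=float) for j, entries in payload.items()}
        doses = {j: np.array([e["dose"] for e in entries], dtype=float) for j, entries in payload.items()}
        return cls(times=times, doses=doses)


@dataclass(frozen=True)
class RegimenWindow:
    """Optimization window derived from the delivered cycle-3/4 days.

    ``delta_tau`` is the inter-cycle interval and the simulation horizon
    is ``t_f = tau4 + delta_tau`` (end of treatment).
    """

    tau3: float
    tau4: float

    def __post_init__(self):
        if self.tau4 <= self.tau3:
            raise ValueError("tau4 must follow tau3")

    @property
    def delta_tau(self) -> float:
        return self.tau4 - self.tau3

    @property
    def t_f(self) -> float:
        return self.tau4 + self.delta_tau


def build_protocol(
    n_cycles: int,
    interval_weeks: float,
    dose_per_cycle: float = 1.0,
    start_day: float = 0.0,
    drugs: tuple[str, ...] = ("A", "C"),
) -> TreatmentRegimen:
    """Build an ``n``-cycle protocol with both drugs delivered together.

    Protocols are conventionally named ``(cycles)-(drugs)-(weeks between
    cycles)``, e.g. ``4-AC-2`` = four A/C cycles, 14 days apart, one full
    (1 NU) dose per cycle.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if interval_weeks <= 0:
        raise ValueError("cycle interval must be positive")
    days = start_day + np.arange(n_cycles) * interval_weeks * 7.0
    doses = np.full(n_cycles, float(dose_per_cycle))
    return TreatmentRegimen(
        times={j: days.copy() for j in drugs},
        doses={j: doses.copy() for j in drugs},
    )


def parse_protocol(shorthand: str, start_day: float = 0.0) -> TreatmentRegimen:
    """Parse a shorthand like ``"4-AC-2"`` into a regimen."""
    try:
        n, drugs, weeks = shorthand.split("-")
        return build_protocol(int(n), float(weeks), start_day=start_day, drugs=tuple(drugs))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"cannot parse protocol shorthand {shorthand!r}") from exc


def canonicalize(regimen: TreatmentRegimen) -> TreatmentRegimen:
    """Zero every dose below the 10%-of-MTD recognition threshold.

    A dose of exactly 0.1 NU is retained (the threshold step is taken as
    active at zero argument).
    """
    doses = {j: np.where(d >= DOSE_THRESHOLD, d, 0.0) for j, d in regimen.doses.items()}
    return TreatmentRegimen(times={j: t.copy() for j, t in regimen.times.items()}, doses=doses)


def total_dose(regimen: TreatmentRegimen, drug: str) -> float:
    """Total delivered dose of a drug, in NU (the l1 norm of the dose vector)."""
    return float(np.abs(regimen.doses[drug]).sum())


def concentration_timecourse(
    regimen: TreatmentRegimen,
    drug: str,
    beta: float | np.ndarray,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Normalized plasma-like concentration c(t) for one drug.

    ``c(t) = sum_k C_k * 1[t >= tau_k] * exp(-beta (t - tau_k))``.
    ``beta`` may be a scalar (returns shape ``(T,)``) or an array of
    posterior samples with shape ``(S,)`` (returns ``(S, T)``).
    """
    beta_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any(beta_arr <= 0):
        raise ValueError("decay rate beta must be positive")
    t = np.asarray(time_grid, dtype=float)
    tau = regimen.times[drug]
    dose = regimen.doses[drug]
    # (S, T, K) broadcasting collapsed over deliveries
    dt_mat = t[:, None] - tau[None, :]  # (T, K)
    gate = dt_mat >= 0
    c = np.einsum(
        "stk,k->st",
        np.where(gate[None, :, :], np.exp(-beta_arr[:, None, None] * np.where(gate, dt_mat, 0.0)[None, :, :]), 0.0),
        dose,
    )
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return c[0]
    return c


def default_time_grid(
    regimen: TreatmentRegimen,
    beta_min: float,
    dt: float = 0.01,
    start: float = 0.0,
    tail_factor: float = 8.0,
) -> np.ndarray:
    """Uniform grid from ``start`` to ``last delivery + tail_factor/beta_min``.

    The tail captures the post-last-dose decay; the toxicity functional
    integrates over it, and a horizon of 8/beta truncates less than 0.04%
    of the single-dose exposure integral.
    """
    end = regimen.last_delivery() + tail_factor / beta_min
    n = int(np.ceil((end - start) / dt)) + 1
    return start + np.arange(n) * dt
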