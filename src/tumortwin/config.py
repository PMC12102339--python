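"""Run configuration: one YAML-serializable record of every knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

VERSION = "0.1.0"


@dataclass
class RunConfig:
    patient_dir: str = "patient"
    output_dir: str = "twin_output"
    seed: int = 0
    # ROM construction
    pod_energy: float = 0.995
    n_pseudo: int = 8
    smoothing_widths: tuple[float, ...] = (1.0, 2.0)
    kl_n_mc: int = 200
    # calibration
    ensemble_size: int = 500
    abc_mode: str = "smc"  # or "rejection"
    epsilon_floor_frac: float = 1e-3  # tolerance floor as fraction of data power
    abc_max_attempts: int = 5_000_000
    abc_rate_floor: float = 1e-4
    lm_starts: int = 4
    # risk functionals
    risk_dt: float = 0.01
    n_lambda: int = 101
    # optimization
    problems: tuple[str, ...] = ("P1", "P2")
    n_hops: int = 10
    subsample: int = 100
    cobyla_maxiter: int = 400
    constraint_tol: float = 1e-6
    # bookkeeping
    version: str = VERSION
    extras: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["smoothing_widths"] = list(self.smoothing_widths)
        d["problems"] = list(self.problems)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("smoothing_widths", "problems"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
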