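"""Virtual breast-cancer patients with known ground truth.

Clinical multi-visit MRI data of this kind is confidential, so the rest
of the package is exercised on synthetic patients: an ellipsoidal
breast mask on a coarse voxel grid, an ellipsoidal tumor seeded with a
Gaussian cellularity bump, a smooth random proliferation field, and
per-visit drug-delivery (AUC) maps.  Tumor evolution through three
imaging visits under a delivered A/C schedule is produced by the
full-order reaction-diffusion solver with the ground-truth parameters;
ADC maps are obtained by inverting the linear ADC-cellularity relation,
optionally corrupted with additive Gaussian noise (clipped back to the
physical ADC range).

Two stock phenotypes mirror the clinical response split: a responder
(high drug efficacy, shrinking tumor) and a non-responder (negligible
efficacy, growth throughout).

The default reference patient is a 32 x 32 x 16 grid at 2 x 2 x 4 mm —
a sub-sampled breast region sized so that a full calibrate-and-optimize
run takes minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import ParamVector, assign_auc_maps, simulate_fom
from .grids import (
    DEFAULT_ADC_W,
    VoxelGrid,
    adc_to_cellularity,
    cellularity_to_adc,
    compute_carrying_capacity,
)
from .regimen import TreatmentRegimen, build_protocol, canonicalize

VISITS = ("V1", "V2", "V3")


@dataclass
class VirtualPatientSpec:
    """Everything needed to generate one virtual patient."""

    seed: int = 0
    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)  # mm
    tumor_radii: tuple[float, float, float] = (8.0, 8.0, 8.0)  # mm
    tumor_center: tuple[float, float, float] | None = None  # mm; grid center if None
    visit_days: tuple[float, float, float] = (0.0, 28.0, 56.0)
    # ground-truth model parameters
    D: float = 1.0e-4  # mm^2/day
    alpha: float = 0.5  # 1/day; high efficacy = responder
    beta_A: float = 0.60  # 1/day
    beta_C: float = 3.25  # 1/day
    k_range: tuple[float, float] = (0.01, 0.06)  # 1/day, smooth field limits
    initial_peak: float = 0.75  # peak normalized cellularity of the seed bump
    # imaging model
    adc_w: float = DEFAULT_ADC_W  # mm^2/s
    adc_min: float = 0.8e-3  # mm^2/s
    noise_sd_frac: float = 0.05  # ADC noise SD as fraction of (adc_w - adc_min)
    tumor_mask_fraction: float = 0.01  # segmentation threshold on N/theta
    regimen: TreatmentRegimen = field(default_factory=lambda: build_protocol(4, 2.0))

    def __post_init__(self):
        if not (self.visit_days[0] < self.visit_days[1] < self.visit_days[2]):
            raise ValueError("visit days must be increasing")


def responder_spec(seed: int = 0, **overrides) -> VirtualPatientSpec:
    """High-efficacy phenotype: cell count falls below baseline by V3."""
    return VirtualPatientSpec(seed=seed, alpha=overrides.pop("alpha", 0.5), **overrides)


def nonresponder_spec(seed: int = 0, **overrides) -> VirtualPatientSpec:
    """Negligible-efficacy phenotype: growth dominates throughout."""
    return VirtualPatientSpec(seed=seed, alpha=overrides.pop("alpha", 1e-5), **overrides)


@dataclass
class VirtualPatient:
    """In-memory generated patient: grid, fields per visit, truth."""

    spec: VirtualPatientSpec
    grid: VoxelGrid
    theta_cap: float
    k_field: np.ndarray  # masked vector, 1/day
    auc_maps: dict[str, np.ndarray]  # visit -> masked vector in [0,1]
    cellularity: dict[str, np.ndarray]  # visit -> 3-D cells/voxel (exact)
    adc: dict[str, np.ndarray]  # visit -> 3-D ADC (noise applied if configured)
    adc_exact: dict[str, np.ndarray]
    regimen: TreatmentRegimen
    truth: ParamVector

    @property
    def visit_days(self) -> dict[str, float]:
        return dict(zip(VISITS, self.spec.visit_days))

    def auc_list(self) -> list[np.ndarray]:
        return [self.auc_maps[v] for v in VISITS]

    def auc_assign(self, regimen: TreatmentRegimen | None = None) -> dict[str, np.ndarray]:
        return assign_auc_maps(regimen if regimen is not None else self.regimen, self.visit_days)


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = [(np.arange(n) + 0.5) * h for n, h in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0


def _smooth_unit_field(rng, shape, mask, sigma_vox=2.0) -> np.ndarray:
    """Gaussian-smoothed noise min-max rescaled to [0, 1] over the mask."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma_vox)
    vals = raw[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(shape)
    out[mask] = (raw[mask] - lo) / max(hi - lo, 1e-12)
    return out


def generate_ground_truth_fields(spec: VirtualPatientSpec):
    """Grid, masks, proliferation field and per-visit AUC maps.

    The AUC maps are tumor-correlated: a smooth random component blended
    with a kernel centered on the tumor, so perfused tumor regions see
    more drug — then min-max normalized over the breast mask.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    extent = [n * h for n, h in zip(shape, spacing)]
    center = spec.tumor_center or tuple(e / 2 for e in extent)
    breast = _ellipsoid_mask(shape, spacing, tuple(e / 2 for e in extent), tuple(0.48 * e for e in extent))
    tumor_geom = _ellipsoid_mask(shape, spacing, center, spec.tumor_radii)
    if np.any(tumor_geom & ~breast):
        raise ValueError("tumor geometry extends outside the breast mask")
    grid = VoxelGrid(spacing=spacing, breast_mask=breast)

    k_lo, k_hi = spec.k_range
    k_field = k_lo + (k_hi - k_lo) * _smooth_unit_field(rng, shape, breast)[breast]

    coords = [(np.arange(n) + 0.5) * h for n, h in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    d2 = sum(((c - cc) / r) ** 2 for c, cc, r in zip((X, Y, Z), center, spec.tumor_radii))
    tumor_kernel = np.exp(-d2)

    auc_maps = {}
    for v in VISITS:
        base = 0.5 * _smooth_unit_field(rng, shape, breast) + 1.5 * tumor_kernel
        vals = base[breast]
        lo, hi = vals.min(), vals.max()
        auc_maps[v] = (vals - lo) / max(hi - lo, 1e-12)
    return grid, tumor_geom, k_field, auc_maps


def generate_virtual_patient(spec: VirtualPatientSpec) -> VirtualPatient:
    """Simulate the ground-truth trajectory and derive the imaging data."""
    rng = np.random.default_rng(spec.seed + 1)  # independent of the field stream
    grid, tumor_geom, k_field, auc_maps = generate_ground_truth_fields(spec)
    theta = compute_carrying_capacity(spec.spacing)

    # Gaussian seed bump centered in the tumor geometry
    shape, spacing = spec.shape, spec.spacing
    extent = [n * h for n, h in zip(shape, spacing)]
    center = spec.tumor_center or tuple(e / 2 for e in extent)
    coords = [(np.arange(n) + 0.5) * h for n, h in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    d2 = sum(((c - cc) / (r / 2.0)) ** 2 for c, cc, r in zip((X, Y, Z), center, spec.tumor_radii))
    bump = spec.initial_peak * np.exp(-0.5 * d2)
    bump[~tumor_geom] = 0.0
    n0 = bump[grid.breast_mask]

    truth = ParamVector(
        D=spec.D, alpha=spec.alpha, beta={"A": spec.beta_A, "C": spec.beta_C}, k=k_field
    )
    reg = canonicalize(spec.regimen)
    visit_days = dict(zip(VISITS, spec.visit_days))
    assign = assign_auc_maps(reg, visit_days)
    auc_list = [auc_maps[v] for v in VISITS]
    result = simulate_fom(
        grid, theta, truth, reg, auc_list, assign, n0,
        (spec.visit_days[0], spec.visit_days[2]),
        store_times=np.asarray(spec.visit_days),
    )

    cellularity, adc_exact, adc_noisy = {}, {}, {}
    tumor_masks = {}
    noise_sd = spec.noise_sd_frac * (spec.adc_w - spec.adc_min)
    for v, day in visit_days.items():
        n_vec = result.at(day)
        vol = grid.unflatten(n_vec)
        mask = vol >= spec.tumor_mask_fraction
        tumor_masks[v] = mask
        cells = np.where(mask, vol * theta, 0.0)
        cellularity[v] = cells
        adc = cellularity_to_adc(cells, mask, spec.adc_w, spec.adc_min, theta)
        adc_exact[v] = adc
        if noise_sd > 0:
            noisy = adc + rng.normal(0.0, noise_sd, size=adc.shape)
            adc_noisy[v] = np.clip(noisy, spec.adc_min, spec.adc_w)
        else:
            adc_noisy[v] = adc.copy()

    grid_with_masks = VoxelGrid(spacing=spacing, breast_mask=grid.breast_mask, tumor_masks=tumor_masks)
    return VirtualPatient(
        spec=spec,
        grid=grid_with_masks,
        theta_cap=theta,
        k_field=k_field,
        auc_maps=auc_maps,
        cellularity=cellularity,
        adc=adc_noisy,
        adc_exact=adc_exact,
        regimen=reg,
        truth=truth,
    )


def measured_cellularity(patient: VirtualPatient, visit: str) -> np.ndarray:
    """Cellularity recovered from the (possibly noisy) stored ADC map.

    This is the observation path every downstream consumer should use;
    with zero noise it reproduces the stored cellularity exactly.
    """
    spec = patient.spec
    return adc_to_cellularity(
        patient.adc[visit],
        patient.grid.tumor_masks[visit],
        spec.adc_w,
        spec.adc_min,
        patient.theta_cap,
    )


def write_patient(patient: VirtualPatient, directory: str | Path) -> Path:
    """Write the patient directory (NIfTI volumes + JSON sidecars)."""
    from . import io

    return io.write_patient_dir(patient, directory)


def ground_truth_dict(patient: VirtualPatient) -> dict:
    spec = patient.spec
    d = asdict(spec)
    d.pop("regimen")
    d["theta_cap"] = patient.theta_cap
    return d
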