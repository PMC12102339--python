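"""Persistence: NIfTI volumes, JSON sidecars, HDF5 digital states.

Patient directory layout (consumed by `calibrate`/`optimize`)::

    patient/
      meta.json                 spacing, visit days, imaging constants
      breast_mask.nii.gz        uint8
      tumor_mask_V{1,2,3}.nii.gz
      adc_V{1,2,3}.nii.gz
      cellularity_V{1,2,3}.nii.gz
      auc_V{1,2,3}.nii.gz
      regimen.json
      ground_truth.json         (synthetic patients only)
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .calibrate import PosteriorEnsemble
from .grids import VoxelGrid
from .regimen import TreatmentRegimen
from .rom import KLMap, PODBasis, ReducedModel

SCHEMA_VERSION = 1


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_nifti(path: Path, volume: np.ndarray, spacing, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=dtype), _affine(spacing))
    nib.save(img, str(path))


def read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def write_patient_dir(patient, directory: str | Path) -> Path:
    from .synth import VISITS, ground_truth_dict

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    spec = patient.spec
    spacing = spec.spacing
    meta = {
        "schema_version": SCHEMA_VERSION,
        "spacing": list(spacing),
        "visit_days": {v: d for v, d in zip(VISITS, spec.visit_days)},
        "adc_w": spec.adc_w,
        "adc_min": spec.adc_min,
        "theta_cap": patient.theta_cap,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    write_nifti(out / "breast_mask.nii.gz", patient.grid.breast_mask, spacing, np.uint8)
    for v in VISITS:
        write_nifti(out / f"tumor_mask_{v}.nii.gz", patient.grid.tumor_masks[v], spacing, np.uint8)
        write_nifti(out / f"adc_{v}.nii.gz", patient.adc[v], spacing)
        write_nifti(out / f"cellularity_{v}.nii.gz", patient.cellularity[v], spacing)
        write_nifti(out / f"auc_{v}.nii.gz", patient.grid.unflatten(patient.auc_maps[v]), spacing)
    (out / "regimen.json").write_text(patient.regimen.to_json())
    (out / "ground_truth.json").write_text(json.dumps(ground_truth_dict(patient), indent=2, default=float))
    return out


class PatientDir:
    """Lazy reader for a patient directory."""

    def __init__(self, directory: str | Path):
        self.path = Path(directory)
        meta_path = self.path / "meta.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"not a patient directory (missing {meta_path})")
        self.meta = json.loads(meta_path.read_text())
        if self.meta.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported patient schema version {self.meta.get('schema_version')} (expected {SCHEMA_VERSION})"
            )
        self.spacing = tuple(self.meta["spacing"])
        self.visit_days = {v: float(d) for v, d in self.meta["visit_days"].items()}
        self.theta_cap = float(self.meta["theta_cap"])

    def _vol(self, name: str) -> np.ndarray:
        p = self.path / name
        if not p.exists():
            raise FileNotFoundError(f"missing {p}")
        vol, spacing = read_nifti(p)
        if not np.allclose(spacing, self.spacing, atol=1e-6):
            raise ValueError(f"{p} spacing {spacing} mismatches meta {self.spacing}")
        return vol

    def grid(self) -> VoxelGrid:
        breast = self._vol("breast_mask.nii.gz").astype(bool)
        masks = {}
        for v in self.visit_days:
            p = self.path / f"tumor_mask_{v}.nii.gz"
            if p.exists():
                masks[v] = self._vol(p.name).astype(bool)
        return VoxelGrid(spacing=self.spacing, breast_mask=breast, tumor_masks=masks)

    def adc(self, visit: str) -> np.ndarray:
        return self._vol(f"adc_{visit}.nii.gz")

    def cellularity(self, visit: str) -> np.ndarray:
        return self._vol(f"cellularity_{visit}.nii.gz")

    def auc(self, visit: str) -> np.ndarray:
        return self._vol(f"auc_{visit}.nii.gz")

    def regimen(self) -> TreatmentRegimen:
        return TreatmentRegimen.from_json((self.path / "regimen.json").read_text())

    def ground_truth(self) -> dict | None:
        p = self.path / "ground_truth.json"
        return json.loads(p.read_text()) if p.exists() else None


def save_ensemble(path: str | Path, ensemble: PosteriorEnsemble) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["epsilon"] = ensemble.epsilon
        f.attrs["attempts"] = ensemble.attempts
        for name in ("D", "alpha", "beta_A", "beta_C", "Kr", "distances"):
            f.create_dataset(name, data=getattr(ensemble, name))


def load_ensemble(path: str | Path) -> PosteriorEnsemble:
    with h5py.File(path, "r") as f:
        return PosteriorEnsemble(
            D=f["D"][:], alpha=f["alpha"][:], beta_A=f["beta_A"][:], beta_C=f["beta_C"][:],
            Kr=f["Kr"][:], distances=f["distances"][:],
            epsilon=float(f.attrs["epsilon"]), attempts=int(f.attrs["attempts"]),
        )


def save_rom(path: str | Path, rom: ReducedModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["theta_cap"] = rom.theta_cap
        f.attrs["spacing"] = rom.grid.spacing
        f.attrs["energy"] = rom.basis.energy
        f.create_dataset("breast_mask", data=rom.grid.breast_mask.astype(np.uint8))
        f.create_dataset("modes", data=rom.basis.modes)
        f.create_dataset("singular_values", data=rom.basis.singular_values)
        for name in ("A_unit", "B_units", "G_units", "T_units", "cells_weights"):
            f.create_dataset(name, data=getattr(rom, name))
        f.create_dataset("k_lower", data=rom.k_map.lower)
        f.create_dataset("k_upper", data=rom.k_map.upper)


def load_rom(path: str | Path) -> ReducedModel:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(
            spacing=tuple(float(s) for s in f.attrs["spacing"]),
            breast_mask=f["breast_mask"][:].astype(bool),
        )
        basis = PODBasis(
            modes=f["modes"][:],
            singular_values=f["singular_values"][:],
            energy=float(f.attrs["energy"]),
        )
        return ReducedModel(
            grid=grid,
            theta_cap=float(f.attrs["theta_cap"]),
            basis=basis,
            A_unit=f["A_unit"][:],
            B_units=f["B_units"][:],
            G_units=f["G_units"][:],
            T_units=f["T_units"][:],
            k_map=KLMap(basis=basis.modes, lower=f["k_lower"][:], upper=f["k_upper"][:]),
            cells_weights=f["cells_weights"][:],
        )
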