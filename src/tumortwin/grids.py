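"""Voxel grids and imaging-derived scalar fields.

The computational domain is a regular voxel grid restricted to a breast
mask; tumor segmentations (one per imaging visit) live inside it.  Tumor
cell density is expressed in cells per voxel, bounded above by a physical
carrying capacity derived from voxel volume, cell size and sphere-packing
density.  Cellularity is estimated from apparent-diffusion-coefficient
(ADC) maps through a linear inverse relationship with water mobility, and
local drug delivery is summarized by a normalized area-under-the-curve
(AUC) map of contrast enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: free-water ADC at body temperature, mm^2/s
DEFAULT_ADC_W = 3.0e-3
#: densest sphere packing fraction
DEFAULT_PACKING = 0.7405
#: tumor cell diameter, micrometres
DEFAULT_CELL_DIAMETER_UM = 10.0
#: a voxel counts toward tumor volume when N >= this fraction of capacity
DEFAULT_VOLUME_FRACTION = 0.01


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid with a breast mask and per-visit tumor masks.

    Fields are stored as 3-D arrays with shape ``dims``; the breast mask
    defines the computational domain (zero-flux boundary at its edge).
    """

    spacing: tuple[float, float, float]  # mm per voxel along each axis
    breast_mask: np.ndarray  # bool, shape = dims
    tumor_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        bm = np.asarray(self.breast_mask, dtype=bool)
        object.__setattr__(self, "breast_mask", bm)
        if bm.ndim != 3:
            raise ValueError("breast_mask must be a 3-D boolean array")
        for visit, tm in self.tumor_masks.items():
            tm = np.asarray(tm, dtype=bool)
            if tm.shape != bm.shape:
                raise ValueError(f"tumor mask {visit!r} shape differs from grid")
            if np.any(tm & ~bm):
                raise ValueError(f"tumor mask {visit!r} extends outside breast mask")
            self.tumor_masks[visit] = tm

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.breast_mask.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_masked(self) -> int:
        return int(self.breast_mask.sum())

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract the masked voxels of a 3-D volume as a 1-D vector."""
        return np.asarray(volume)[self.breast_mask]

    def unflatten(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector back to a full 3-D volume."""
        out = np.full(self.dims, fill, dtype=float)
        out[self.breast_mask] = vector
        return out


@dataclass(frozen=True)
class ScalarField:
    """A scalar field defined on a grid, tagged with its visit label."""

    values: np.ndarray
    visit: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


class ADCField(ScalarField):
    """Apparent diffusion coefficient map, mm^2/s."""


class CellularityField(ScalarField):
    """Tumor cell count per voxel."""


class AUCField(ScalarField):
    """Normalized contrast-enhancement AUC map in [0, 1]."""


def compute_carrying_capacity(
    spacing: tuple[float, float, float],
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM,
    packing: float = DEFAULT_PACKING,
) -> float:
    """Physical carrying capacity (cells per voxel).

    ``theta = voxel_volume * packing / sphere_volume(cell_diameter)``:
    the number of spherical cells of the given diameter that fit in one
    voxel at the given packing density.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if cell_diameter_um <= 0:
        raise ValueError("cell diameter must be positive")
    if not 0 < packing <= 1:
        raise ValueError("packing fraction must be in (0, 1]")
    voxel_volume_mm3 = float(np.prod(spacing))
    d_mm = cell_diameter_um * 1e-3
    cell_volume_mm3 = np.pi / 6.0 * d_mm**3
    return voxel_volume_mm3 * packing / cell_volume_mm3


def adc_to_cellularity(
    adc: np.ndarray,
    tumor_mask: np.ndarray,
    adc_w: float,
    adc_min: float,
    theta_cap: float,
) -> np.ndarray:
    """Convert an ADC map to a cellularity map (cells/voxel).

    Cellularity scales linearly with the ADC deficit relative to free
    water: ``N = theta * (adc_w - adc) / (adc_w - adc_min)`` inside the
    tumor mask, clipped to ``[0, theta]`` as a noise guard, and zero
    outside the segmentation.
    """
    if adc_w <= adc_min:
        raise ValueError("adc_w must exceed adc_min")
    adc = np.asarray(adc, dtype=float)
    n = theta_cap * (adc_w - adc) / (adc_w - adc_min)
    n = np.clip(n, 0.0, theta_cap)
    n = np.where(np.asarray(tumor_mask, dtype=bool), n, 0.0)
    return n


def cellularity_to_adc(
    cells: np.ndarray,
    tumor_mask: np.ndarray,
    adc_w: float,
    adc_min: float,
    theta_cap: float,
    background_adc: float | None = None,
) -> np.ndarray:
    """Exact right-inverse of :func:`adc_to_cellularity` on the tumor mask.

    Outside the mask the map is filled with a configurable tissue ADC
    (default ``adc_w``).
    """
    if adc_w <= adc_min:
        raise ValueError("adc_w must exceed adc_min")
    if background_adc is None:
        background_adc = adc_w
    cells = np.asarray(cells, dtype=float)
    adc = adc_w - (cells / theta_cap) * (adc_w - adc_min)
    return np.where(np.asarray(tumor_mask, dtype=bool), adc, background_adc)


def estimate_adc_min(adc_maps: dict[str, np.ndarray], tumor_masks: dict[str, np.ndarray]) -> float:
    """Minimum ADC within the union of tumor segmentations across visits."""
    vals = []
    for visit, adc in adc_maps.items():
        mask = tumor_masks[visit]
        if mask.any():
            vals.append(np.asarray(adc)[mask].min())
    if not vals:
        raise ValueError("no tumor voxels found in any visit")
    return float(min(vals))


def compute_auc_map(
    series: np.ndarray,
    times: np.ndarray,
    breast_mask: np.ndarray,
) -> tuple[np.ndarray, bool]:
    """Per-voxel trapezoidal AUC of an enhancement time series, min-max
    normalized to [0, 1] over the breast mask.

    ``series`` has shape ``dims + (n_timepoints,)``.  Returns the
    normalized map and a flag that is True when the series carried signal
    (False for an all-constant series, in which case the map is all zero).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape[-1] < 2 or times.size < 2:
        raise ValueError("need at least two time points")
    auc = np.trapezoid(series, times, axis=-1)
    mask = np.asarray(breast_mask, dtype=bool)
    lo, hi = auc[mask].min(), auc[mask].max()
    if hi - lo <= 0:
        return np.zeros_like(auc), False
    out = np.clip((auc - lo) / (hi - lo), 0.0, 1.0)
    out[~mask] = 0.0
    return out, True


def summarize(
    cells: np.ndarray,
    theta_cap: float,
    voxel_volume_mm3: float,
    volume_fraction_threshold: float = DEFAULT_VOLUME_FRACTION,
) -> tuple[float, float]:
    """Bulk summaries of a cellularity field: (total cells, tumor volume in mL).

    Total cells is the plain sum over voxels.  Tumor volume counts voxels
    whose cellularity reaches ``volume_fraction_threshold * theta_cap``
    (excludes the numerical-diffusion halo) times the voxel volume,
    converted from mm^3 to mL.
    """
    cells = np.asarray(cells, dtype=float)
    total = float(cells.sum())
    n_occupied = int(np.count_nonzero(cells >= volume_fraction_threshold * theta_cap))
    volume_ml = n_occupied * voxel_volume_mm3 / 1000.0  # 1 mL = 1000 mm^3
    return total, volume_ml


def block_downsample(volume: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Block-average downsampling (in-plane factor 4 is the typical use).

    Trailing voxels that do not fill a complete block are dropped.
    """
    v = np.asarray(volume, dtype=float)
    fx, fy, fz = factors
    nx, ny, nz = (v.shape[0] // fx) * fx, (v.shape[1] // fy) * fy, (v.shape[2] // fz) * fz
    v = v[:nx, :ny, :nz]
    v = v.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz)
    return v.mean(axis=(1, 3, 5))
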