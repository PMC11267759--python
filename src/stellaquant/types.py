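"""Shared data containers for volumes, scans, masks and derived records.

Coordinate convention: voxel indices are 0-based ``(z, y, x)``; the physical
position of voxel ``(i, j, k)`` is its center, ``((i + 0.5) * dz,
(j + 0.5) * dy, (k + 0.5) * dx)`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all requested objects."""


@dataclass
class VoxelVolume:
    """A 3D scalar image (refractive index or fluorescence intensity).

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values; refractive index is dimensionless, fluorescence is a.u.
    voxel_size : tuple of float
        Physical voxel dimensions ``(dz, dy, dx)`` in µm; all positive.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class CellMask:
    """Boolean cell-vs-background mask sharing a volume's geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def cell_volume(self) -> float:
        """µm³: count of foreground voxels times the physical voxel volume."""
        dz, dy, dx = self.voxel_size
        return float(self.data.sum()) * dz * dy * dx


@dataclass
class RamanScan:
    """A spatial grid of spectra sharing one wavenumber axis.

    ``cube`` is ``(lines, points, channels)``; ``wavenumbers`` is strictly
    increasing, in cm⁻¹. ``state`` tracks the preprocessing stages applied
    (``despiked``, ``baselined``, ``normalized``). ``valid`` marks pixels
    whose spectra remain usable downstream (normalization excludes pixels
    with non-positive integral).
    """

    cube: np.ndarray
    wavenumbers: np.ndarray
    state: set = field(default_factory=set)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("scan cube must be (lines, points, channels)")
        if self.wavenumbers.ndim != 1 or self.cube.shape[2] != self.wavenumbers.size:
            raise ValueError("channel axis does not match wavenumber axis length")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.cube.shape[:2], dtype=bool)

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]


@dataclass
class GroundTruth:
    """Sidecar record of every planted object/parameter of a generator call.

    ``objects`` holds the planted entities (droplet centers and radii in µm,
    per-component voxel lists, per-pixel band amplitudes, masks, outlier
    indices, group parameters); ``params`` is the full parameter record so a
    call can be reproduced exactly from (params, seed).
    """

    kind: str
    objects: dict[str, Any]
    seed: int
    params: dict[str, Any]


@dataclass
class DropletSet:
    """Detected lipid droplets: centers (z, y, x) in µm, radii in µm, and
    the scale-normalized LoG peak response of each detection."""

    centers: np.ndarray          # (n, 3) µm
    radii: np.ndarray            # (n,) µm
    responses: np.ndarray        # (n,)
    boundary_flags: np.ndarray   # (n,) bool — detection touches the mask edge
    source_volume_id: str | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float).reshape(-1, 3))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.responses = np.asarray(self.responses, dtype=float).ravel()
        self.boundary_flags = np.asarray(self.boundary_flags, dtype=bool).ravel()
        if np.any(self.radii <= 0):
            raise ValueError("droplet radii must be positive")

    def __len__(self) -> int:
        return self.radii.size


@dataclass
class LipidFraction:
    """Total droplet (sphere-model) volume relative to segmented cell volume."""

    lipid_volume: float   # µm³
    cell_volume: float    # µm³
    fraction: float


@dataclass
class MitoStats:
    """Mitochondrial-network morphometry for one stack."""

    mito_volume: float                     # µm³ above-threshold volume
    n_segments: int
    mean_segment_size: float | None       # voxels; None when no segments
    mito_volume_per_cell_volume: float
    segments_per_cell_volume: float       # µm⁻³
    segment_sizes: list[int] = field(default_factory=list)
    otsu_threshold: float | None = None


@dataclass
class BandWindow:
    """A closed wavenumber interval [lo, hi] in cm⁻¹."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band window requires lo < hi, got [{self.lo}, {self.hi}]")


#: Retinoid (vitamin A) band, dominated by the conjugated C=C stretch near 1590 cm⁻¹.
VA_WINDOW = BandWindow(1554.0, 1615.0)
#: Lipid CH-stretch region.
LIPID_WINDOW = BandWindow(2800.0, 3000.0)


@dataclass
class BandMaps:
    """Per-pixel band integrals and their spatial Pearson correlation."""

    va_map: np.ndarray
    lipid_map: np.ndarray
    pearson_r: float | None
    n_pixels: int
    windows: tuple[BandWindow, BandWindow] = (VA_WINDOW, LIPID_WINDOW)


@dataclass
class UVQuant:
    """Triangle-threshold quantification of a UV autofluorescence image."""

    threshold: float
    positive_area_fraction: float
    integrated_positive_signal: float


@dataclass
class ActinScore:
    """α-SMA intensity restricted to the PDGFR-β-positive area of one field."""

    mask_area: int
    asma_integral: float | None
    mean_intensity_in_mask: float | None


@dataclass
class OxidationRecord:
    """Radiotracer substrate oxidation: uptake = CO₂ + cell-associated (CA)
    counts; fractional oxidation = CO₂ / uptake."""

    co2: float
    ca: float
    uptake: float
    fractional_oxidation: float | None


@dataclass
class SeahorseTrace:
    """Extracellular-flux time series for one well/condition.

    ``injection_marks`` maps injection names (``oligomycin``, ``fccp``,
    ``rot_aa``, optionally ``2dg``) to the 0-based index of the first
    measurement cycle after that injection.
    """

    timepoints: np.ndarray       # minutes
    ocr: np.ndarray              # pmol/min (or % of baseline)
    ecar: np.ndarray             # mpH/min (or % of baseline)
    injection_marks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        if not (self.timepoints.size == self.ocr.size == self.ecar.size):
            raise ValueError("timepoints, ocr and ecar must have equal length")
        marks = [self.injection_marks[k] for k in self.injection_marks]
        if marks != sorted(marks):
            raise ValueError("injection indices must be increasing")


@dataclass
class StatResult:
    """Welch two-sample comparison with group summaries."""

    t: float
    df: float
    p: float
    group_summaries: dict[str, dict[str, Any]]
    five_number: tuple[float, float, float, float, float]
    outliers_removed: list[int] = field(default_factory=list)
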