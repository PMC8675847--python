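"""Core containers for dual-energy CT gold quantification.

Two acquisitions at different tube potentials (typically 80 and 140 kVp)
give each voxel a pair of CT numbers whose energy dependence separates a
high-Z contrast material (gold, k-edge 80.7 keV) from soft tissue.  The
per-voxel two-material model is linear::

    CT'_E = intercept_E + e_w,E * C_w + e_Au,E * C_Au

with concentrations in mg/ml and sensitivities e in HU' per (mg/ml).

All internal arithmetic uses *shifted* CT numbers CT' = HU + 1000, so that
air maps to 0 and water to 1000.  In true Hounsfield units water is 0 HU at
every energy, which would force the water sensitivity to zero and make the
two-material matrix singular; the shift makes e_w = 1 HU'·ml/mg exactly for
water at 1000 mg/ml and keeps the system invertible whenever the gold
sensitivities differ between the two energies.  The shift is stored on each
image and applied/removed only at I/O boundaries.

Units convention: external interfaces (CSV, NIfTI maps, configs) use μg/ml,
the common reporting unit; internal math is mg/ml.  The factor of 1000 is
applied exactly once at ingestion/egress.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import GeometryError, SingularSystemError

#: HU -> CT' shift: CT' = HU + HU_OFFSET (air 0, water 1000).
HU_OFFSET = 1000.0

#: Water concentration of pure water, mg/ml.
WATER_MG_ML = 1000.0

#: Water sensitivity under the shifted-CT convention, HU' per (mg/ml).
E_WATER = 1.0

#: μg per mg: the single external<->internal unit conversion factor.
UG_PER_MG = 1000.0


@dataclass(frozen=True)
class Grid:
    """A regular 3-D voxel grid.

    Coordinates are voxel centres in mm, origin at the grid centre,
    axes aligned with the array axes (x, y, z).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 0.625)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise GeometryError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise GeometryError(f"voxel dimensions must be > 0, got {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coords(self, axis: int) -> np.ndarray:
        """Physical voxel-centre coordinates along one axis, centred at 0."""
        n, d = self.shape[axis], self.voxel_size[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(self.coords(0), self.coords(1), self.coords(2), indexing="ij")

    @property
    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to mm (grid-centred)."""
        aff = np.diag([*self.voxel_size, 1.0])
        aff[:3, 3] = [self.coords(i)[0] for i in range(3)]
        return aff


@dataclass(frozen=True)
class ScanProtocol:
    """Dual-energy acquisition settings.

    ``pitch`` and ``mas`` are recorded as acquisition metadata only: the
    simulator operates on reconstructed voxels, so dose enters the forward
    model solely through ``noise_sd`` (per-energy HU standard deviation).
    """

    energy_low: float = 80.0
    energy_high: float = 140.0
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 0.625)
    noise_sd: tuple[float, float] = (5.0, 5.0)
    seed: int = 0
    pitch: float = 1.0
    mas: float = 250.0

    def __post_init__(self) -> None:
        if np.isscalar(self.noise_sd):
            object.__setattr__(self, "noise_sd", (float(self.noise_sd),) * 2)
        else:
            object.__setattr__(self, "noise_sd", tuple(float(s) for s in self.noise_sd))
        if not self.energy_low < self.energy_high:
            raise ValueError(
                f"energy_low ({self.energy_low}) must be < energy_high ({self.energy_high})"
            )
        if any(s < 0 for s in self.noise_sd):
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if any(d <= 0 for d in self.voxel_size):
            raise ValueError(f"voxel dimensions must be > 0, got {self.voxel_size}")

    def with_seed(self, seed: int) -> "ScanProtocol":
        return replace(self, seed=int(seed))

    def noiseless(self) -> "ScanProtocol":
        return replace(self, noise_sd=(0.0, 0.0))


@dataclass
class MaterialMaps:
    """Per-voxel water and gold concentration maps (mg/ml) plus a body mask.

    Ground-truth maps are non-negative by construction; maps *recovered* by
    decomposition may carry negative gold values (noise), which are retained
    unless clipping is requested.
    """

    c_water: np.ndarray
    c_au: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.c_water = np.asarray(self.c_water, dtype=float)
        self.c_au = np.asarray(self.c_au, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.c_water.shape == self.c_au.shape == self.mask.shape):
            raise GeometryError(
                f"field shapes differ: {self.c_water.shape}, {self.c_au.shape}, {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.c_water.shape


@dataclass
class DualEnergyImage:
    """Paired co-registered CT' volumes at the low and high tube potential."""

    ct_low: np.ndarray
    ct_high: np.ndarray
    offset: float = HU_OFFSET
    protocol: ScanProtocol | None = None

    def __post_init__(self) -> None:
        self.ct_low = np.asarray(self.ct_low, dtype=float)
        self.ct_high = np.asarray(self.ct_high, dtype=float)
        if self.ct_low.shape != self.ct_high.shape:
            raise GeometryError(
                f"energy volumes differ in shape: {self.ct_low.shape} vs {self.ct_high.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ct_low.shape

    @property
    def hu_low(self) -> np.ndarray:
        """Low-energy volume in true Hounsfield units."""
        return self.ct_low - self.offset

    @property
    def hu_high(self) -> np.ndarray:
        return self.ct_high - self.offset


@dataclass
class SensitivityMatrix:
    """The 2×2 two-material sensitivity system plus fit diagnostics.

    Rows are ordered low energy first; columns are (water, gold).  Units
    are HU' per (mg/ml); intercepts are HU'.  The water sensitivities
    default to the shifted-CT convention value ``E_WATER`` = 1.
    """

    e_au_low: float
    e_au_high: float
    e_w_low: float = E_WATER
    e_w_high: float = E_WATER
    intercept_low: float = 0.0
    intercept_high: float = 0.0
    fit_r2_low: float = float("nan")
    fit_r2_high: float = float("nan")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.e_w_low, self.e_au_low], [self.e_w_high, self.e_au_high]], dtype=float
        )

    @property
    def intercepts(self) -> np.ndarray:
        return np.array([self.intercept_low, self.intercept_high], dtype=float)

    @property
    def determinant(self) -> float:
        return self.e_w_low * self.e_au_high - self.e_au_low * self.e_w_high

    @property
    def condition_number(self) -> float:
        """2-norm condition number of the 2×2 matrix (inf when singular)."""
        return float(np.linalg.cond(self.matrix))

    def inverse(self, condition_cap: float = 1e8) -> np.ndarray:
        """Closed-form 2×2 inverse; errors above the condition cap."""
        cond = self.condition_number
        if not np.isfinite(cond) or cond > condition_cap:
            raise SingularSystemError(
                f"sensitivity matrix condition number {cond:.3g} exceeds cap {condition_cap:.3g}"
            )
        det = self.determinant
        return (
            np.array(
                [[self.e_au_high, -self.e_au_low], [-self.e_w_high, self.e_w_low]], dtype=float
            )
            / det
        )

    def to_dict(self) -> dict:
        return {
            "e_w_low": self.e_w_low,
            "e_au_low": self.e_au_low,
            "e_w_high": self.e_w_high,
            "e_au_high": self.e_au_high,
            "intercept_low": self.intercept_low,
            "intercept_high": self.intercept_high,
            "fit_r2_low": self.fit_r2_low,
            "fit_r2_high": self.fit_r2_high,
            "condition_number": self.condition_number,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityMatrix":
        keys = (
            "e_au_low",
            "e_au_high",
            "e_w_low",
            "e_w_high",
            "intercept_low",
            "intercept_high",
            "fit_r2_low",
            "fit_r2_high",
        )
        return cls(**{k: float(d[k]) for k in keys if k in d})


#: Default gold sensitivities, HU' per (mg/ml).  Reported in-vivo HU
#: elevations for hepatic gold at 80 and 140 kVp (≈22 and ≈27 HU per unit
#: concentration) anchor the defaults; the high-energy sensitivity exceeds
#: the low-energy one because much of the 140 kVp spectrum lies above
#: gold's 80.7 keV k-edge.  These are configuration values, not constants
#: baked into any algorithm.
DEFAULT_SENSITIVITY = SensitivityMatrix(e_au_low=22.0, e_au_high=27.0)


def ug_to_mg(values) -> np.ndarray | float:
    """μg/ml -> mg/ml (the single ingestion-side unit conversion)."""
    return np.asarray(values, dtype=float) / UG_PER_MG if np.ndim(values) else float(values) / UG_PER_MG


def mg_to_ug(values) -> np.ndarray | float:
    """mg/ml -> μg/ml (the single egress-side unit conversion)."""
    return np.asarray(values, dtype=float) * UG_PER_MG if np.ndim(values) else float(values) * UG_PER_MG
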