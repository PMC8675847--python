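"""Synthetic dual-energy volumes with known ground truth.

Two digital objects are provided:

* a PMMA calibration phantom — a cylinder with five vial cavities filled
  with gold-nanoparticle suspensions at known concentrations, used to fit
  per-energy sensitivity coefficients;
* a mouse-like volume — an ellipsoidal body with ellipsoidal organ
  compartments (tumour, kidneys, lungs, spleen, heart, liver) carrying gold
  concentrations, emulating a biodistribution scan 3 h after tail-vein
  injection.  A folate-targeted probe roughly doubles tumour uptake
  relative to the untargeted particle, which is the scenario's default
  targeting ratio.

The forward model is the same linear two-material response the
decomposition assumes — shifted CT number CT'_E = e_w,E·C_w + e_Au,E·C_Au
per voxel per energy — plus additive, independent, per-energy Gaussian
noise on reconstructed voxels.  No projection-domain physics (beam
hardening, scatter, spectra) is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_SENSITIVITY,
    Grid,
    DualEnergyImage,
    MaterialMaps,
    ScanProtocol,
    SensitivityMatrix,
    WATER_MG_ML,
    ug_to_mg,
)
from .exceptions import ConfigurationError, GeometryError

#: Water-equivalent concentrations (mg/ml) of the phantom background
#: materials.  PMMA sits near +120 HU, i.e. 1120 on the shifted scale.
BACKGROUND_WATER_EQUIV = {"water": 1000.0, "pmma": 1120.0}

#: The five vial concentrations of the calibration phantom, μg/ml.
DEFAULT_VIAL_CONCENTRATIONS_UG_ML = (250.0, 500.0, 1000.0, 1500.0, 2000.0)

DEFAULT_PHANTOM_GRID = Grid(shape=(72, 72, 8), voxel_size=(1.0, 1.0, 0.625))
DEFAULT_MOUSE_GRID = Grid(shape=(80, 60, 72), voxel_size=(0.4, 0.4, 0.625))

#: The organ set reported in the biodistribution comparison.
MOUSE_ORGANS = (
    "tumour",
    "kidney_right",
    "kidney_left",
    "lungs",
    "spleen",
    "heart",
    "liver",
)

#: Default organ gold concentrations, μg/ml, for the *non-targeted* probe:
#: reticuloendothelial organs (liver, spleen) dominate 3 h post-injection,
#: kidneys carry circulating/clearing particle, tumour retains EPR-level
#: uptake.  The targeted scenario multiplies the tumour by targeting_ratio.
DEFAULT_ORGAN_CONCENTRATIONS_UG_ML = {
    "liver": 3000.0,
    "spleen": 2500.0,
    "kidney_right": 1000.0,
    "kidney_left": 1000.0,
    "lungs": 600.0,
    "heart": 500.0,
    "tumour": 1500.0,
}

#: Water-equivalent concentration (mg/ml) per tissue; lungs are air-filled.
ORGAN_WATER_MG_ML = {
    "liver": 1055.0,
    "spleen": 1055.0,
    "kidney_right": 1045.0,
    "kidney_left": 1045.0,
    "lungs": 300.0,
    "heart": 1050.0,
    "tumour": 1040.0,
}
BODY_WATER_MG_ML = 1030.0


def _ring_centres(n: int, ring_radius: float, phase_deg: float = 90.0) -> list[tuple[float, float]]:
    angles = np.deg2rad(phase_deg + 360.0 * np.arange(n) / n)
    return [(ring_radius * math.cos(a), ring_radius * math.sin(a)) for a in angles]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contents of the five-vial calibration phantom.

    Vials are axis-aligned cylinders running the full z extent of the
    body cylinder.  Concentrations are external units (μg/ml).
    """

    body_radius: float = 30.0
    vial_radius: float = 4.0
    vial_concentrations: tuple[float, ...] = DEFAULT_VIAL_CONCENTRATIONS_UG_ML
    vial_centres: tuple[tuple[float, float], ...] | None = None
    background_material: str = "pmma"

    def __post_init__(self) -> None:
        if self.body_radius <= 0 or self.vial_radius <= 0:
            raise GeometryError("body and vial radii must be positive")
        if any(c < 0 for c in self.vial_concentrations):
            raise GeometryError("vial concentrations must be non-negative")
        if self.background_material not in BACKGROUND_WATER_EQUIV:
            raise ConfigurationError(
                f"unknown background material {self.background_material!r}; "
                f"choose from {sorted(BACKGROUND_WATER_EQUIV)}"
            )
        if self.vial_centres is not None and len(self.vial_centres) != len(
            self.vial_concentrations
        ):
            raise GeometryError("vial_centres and vial_concentrations length mismatch")

    def centres(self) -> list[tuple[float, float]]:
        if self.vial_centres is not None:
            return [tuple(c) for c in self.vial_centres]
        ring = 0.55 * self.body_radius
        return _ring_centres(len(self.vial_concentrations), ring)

    def validate_geometry(self) -> None:
        centres = self.centres()
        for i, (x, y) in enumerate(centres):
            if math.hypot(x, y) + self.vial_radius >= self.body_radius:
                raise GeometryError(f"vial {i} extends outside the phantom body")
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                d = math.dist(centres[i], centres[j])
                if d < 2.0 * self.vial_radius:
                    raise GeometryError(f"vials {i} and {j} overlap (centre distance {d:.2f} mm)")


def vial_label_volume(spec: PhantomSpec, grid: Grid = DEFAULT_PHANTOM_GRID) -> np.ndarray:
    """Integer label volume: 0 = background, 1..n = vials in spec order."""
    spec.validate_geometry()
    x, y, _ = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.int16)
    for k, (cx, cy) in enumerate(spec.centres(), start=1):
        vial = (x - cx) ** 2 + (y - cy) ** 2 <= spec.vial_radius**2
        if not vial.any():
            raise GeometryError(f"vial {k} contains no voxels on this grid")
        labels[vial] = k
    return labels


def build_phantom(spec: PhantomSpec, grid: Grid = DEFAULT_PHANTOM_GRID) -> MaterialMaps:
    """Voxelize the calibration phantom into ground-truth material maps.

    Vial voxels carry their vial's gold concentration (converted to mg/ml)
    in a water diluent; background body voxels carry the background
    material's water-equivalent concentration; outside the body is air.
    """
    spec.validate_geometry()
    x, y, _ = grid.meshgrid()
    body = x**2 + y**2 <= spec.body_radius**2
    if not body.any():
        raise GeometryError("phantom body does not intersect the grid")
    c_water = np.where(body, BACKGROUND_WATER_EQUIV[spec.background_material], 0.0)
    c_au = np.zeros(grid.shape)
    labels = vial_label_volume(spec, grid)
    for k, conc_ug in enumerate(spec.vial_concentrations, start=1):
        vial = labels == k
        c_au[vial] = ug_to_mg(conc_ug)
        c_water[vial] = WATER_MG_ML
    return MaterialMaps(c_water=c_water, c_au=c_au, mask=body)


@dataclass(frozen=True)
class OrganGeometry:
    """A label volume assigning voxels to named organs."""

    label_map: np.ndarray
    label_ids: dict[str, int]
    grid: Grid

    def mask(self, organ: str) -> np.ndarray:
        if organ not in self.label_ids:
            raise ConfigurationError(f"organ {organ!r} not in geometry {sorted(self.label_ids)}")
        return self.label_map == self.label_ids[organ]

    @property
    def body_mask(self) -> np.ndarray:
        return self.label_map > 0


# (centre mm, semi-axes mm) for each organ ellipsoid; painted in order so a
# later organ claims any contested voxel.  The tumour is a 0.1 cm^3 sphere
# on the right flank, matching the imaging time point's mean tumour volume.
_TUMOUR_RADIUS = (3.0 * 100.0 / (4.0 * math.pi)) ** (1.0 / 3.0)  # ~2.879 mm
_MOUSE_LAYOUT: tuple[tuple[str, tuple[float, float, float], tuple[float, float, float]], ...] = (
    ("lungs", (0.0, 0.0, 14.5), (5.5, 4.5, 4.0)),
    ("heart", (0.0, 0.0, 11.0), (3.0, 3.0, 3.2)),
    ("liver", (0.5, 1.0, -3.0), (7.0, 5.0, 4.5)),
    ("spleen", (-7.5, -1.0, -8.0), (2.5, 2.0, 3.0)),
    ("kidney_right", (5.0, -3.5, -10.0), (2.0, 2.0, 3.0)),
    ("kidney_left", (-4.5, -3.5, -12.5), (2.0, 2.0, 3.0)),
    ("tumour", (8.5, 0.0, -13.5), (_TUMOUR_RADIUS,) * 3),
)
_BODY_SEMI_AXES = (14.0, 10.0, 20.0)


def default_mouse_geometry(grid: Grid = DEFAULT_MOUSE_GRID) -> OrganGeometry:
    """Ellipsoid-organ mouse atlas on the given grid.

    Label 0 is outside the animal; label 1 is unlabelled body tissue;
    organs take labels 2..8.  The body mask is the union of the trunk
    ellipsoid and every organ, so the flank tumour is fully inside it.
    """
    x, y, z = grid.meshgrid()
    ax, ay, az = _BODY_SEMI_AXES
    body = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0
    labels = np.where(body, 1, 0).astype(np.int16)
    ids: dict[str, int] = {}
    for k, (name, (cx, cy, cz), (sx, sy, sz)) in enumerate(_MOUSE_LAYOUT, start=2):
        organ = ((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2 <= 1.0
        if not organ.any():
            raise GeometryError(f"organ {name!r} contains no voxels on this grid")
        labels[organ] = k
        ids[name] = k
    return OrganGeometry(label_map=labels, label_ids=ids, grid=grid)


@dataclass(frozen=True)
class MouseScenario:
    """Gold biodistribution scenario for the mouse-like volume.

    ``organ_concentrations`` are non-targeted values in μg/ml; building
    with ``targeted=True`` multiplies the tumour by ``targeting_ratio``.
    """

    organ_concentrations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_CONCENTRATIONS_UG_ML)
    )
    targeting_ratio: float = 2.0
    tumour_label: str = "tumour"
    geometry: OrganGeometry | None = None

    def __post_init__(self) -> None:
        if self.targeting_ratio <= 0:
            raise ConfigurationError("targeting_ratio must be > 0")
        if any(c < 0 for c in self.organ_concentrations.values()):
            raise ConfigurationError("organ concentrations must be non-negative")


def build_mouse(
    scenario: MouseScenario,
    grid: Grid = DEFAULT_MOUSE_GRID,
    targeted: bool = False,
) -> tuple[MaterialMaps, OrganGeometry]:
    """Ground-truth material maps for a mouse scenario.

    Returns the maps together with the organ geometry used, so that the
    same labels drive ROI quantification downstream.
    """
    geometry = scenario.geometry or default_mouse_geometry(grid)
    missing = set(scenario.organ_concentrations) - set(geometry.label_ids)
    if missing:
        raise ConfigurationError(f"organs not present in geometry: {sorted(missing)}")
    c_water = np.where(geometry.label_map > 0, BODY_WATER_MG_ML, 0.0)
    c_au = np.zeros(geometry.label_map.shape)
    for organ, conc_ug in scenario.organ_concentrations.items():
        m = geometry.mask(organ)
        conc = float(conc_ug)
        if targeted and organ == scenario.tumour_label:
            conc *= scenario.targeting_ratio
        c_au[m] = ug_to_mg(conc)
        c_water[m] = ORGAN_WATER_MG_ML.get(organ, BODY_WATER_MG_ML)
    return MaterialMaps(c_water=c_water, c_au=c_au, mask=geometry.body_mask), geometry


def forward_project(
    maps: MaterialMaps,
    coeffs: SensitivityMatrix = DEFAULT_SENSITIVITY,
    protocol: ScanProtocol = ScanProtocol(),
) -> DualEnergyImage:
    """Simulate the paired CT' volumes from ground-truth material maps.

    Each energy's volume is the linear response
    ``CT'_E = intercept_E + e_w,E·C_w + e_Au,E·C_Au`` with independent
    Gaussian noise of the protocol's per-energy sd added voxelwise.  The
    low-energy volume's noise is drawn first from a generator seeded by
    ``protocol.seed``, so identical inputs give bit-identical output.
    """
    ct = []
    rng = np.random.default_rng(protocol.seed)
    rows = coeffs.matrix
    intercepts = coeffs.intercepts
    for e, (row, icpt, sd) in enumerate(zip(rows, intercepts, protocol.noise_sd)):
        vol = icpt + row[0] * maps.c_water + row[1] * maps.c_au
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, size=maps.shape)
        ct.append(vol)
    return DualEnergyImage(ct_low=ct[0], ct_high=ct[1], protocol=protocol)
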