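"""Sensitivity-coefficient calibration from vial phantom measurements.

At each tube potential the mean CT' of every vial ROI is regressed on the
vial's nominal gold concentration; the fitted slope is that energy's gold
sensitivity e_Au,E (HU' per mg/ml) and the intercept absorbs the diluent
baseline.  The water sensitivity is fixed at the shifted-CT convention
value (1 HU'·ml/mg) unless a caller overrides it from a water-dilution
series.  The resulting 2×2 matrix — rows (low, high) energy, columns
(water, gold) — is what the per-voxel decomposition inverts.

``DualEnergyCalibration`` is the model object (built from an image plus
vial masks, or from a tidy measurement table); ``fit`` returns
``CalibrationResults`` carrying the sensitivity matrix, fit diagnostics
and a round-trip validation against reference concentrations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    E_WATER,
    DualEnergyImage,
    SensitivityMatrix,
    mg_to_ug,
    ug_to_mg,
)
from .exceptions import (
    CalibrationError,
    DegenerateDesignError,
    GeometryError,
    InputError,
    MeasurementError,
)


@dataclass
class CalibrationSeries:
    """Per-energy vial measurements: (concentration, mean CT', sd, n)."""

    energy: float
    concentrations: np.ndarray  # mg/ml
    means: np.ndarray  # CT', HU'
    sds: np.ndarray  # HU'
    ns: np.ndarray  # voxels per vial

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.ns = np.asarray(self.ns, dtype=int)
        k = len(self.concentrations)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise InputError("calibration series fields differ in length")
        if (self.ns < 1).any():
            raise MeasurementError("every calibration point needs n >= 1 voxels")
        if (self.sds < 0).any():
            raise InputError("sd must be non-negative")

    def __len__(self) -> int:
        return len(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "energy_kvp": self.energy,
                "concentration_ug_ml": mg_to_ug(self.concentrations),
                "mean_ct_prime": self.means,
                "sd_hu": self.sds,
                "n_voxels": self.ns,
            }
        )


def measure_vials(
    image: DualEnergyImage,
    vial_labels: np.ndarray,
    concentrations_ug_ml,
) -> tuple[CalibrationSeries, CalibrationSeries]:
    """Mean/sd CT' per vial per energy, paired with nominal concentrations.

    ``vial_labels`` is an integer volume where label k (1-based) marks the
    k-th vial of ``concentrations_ug_ml``.
    """
    vial_labels = np.asarray(vial_labels)
    if vial_labels.shape != image.shape:
        raise GeometryError(
            f"label volume shape {vial_labels.shape} != image shape {image.shape}"
        )
    concs_mg = np.atleast_1d(ug_to_mg(concentrations_ug_ml))
    series = []
    energies = (
        (image.protocol.energy_low, image.protocol.energy_high)
        if image.protocol is not None
        else (float("nan"), float("nan"))
    )
    for vol, energy in zip((image.ct_low, image.ct_high), energies):
        means, sds, ns = [], [], []
        for k in range(1, len(concs_mg) + 1):
            m = vial_labels == k
            n = int(m.sum())
            if n == 0:
                raise MeasurementError(f"vial {k} mask is empty")
            vals = vol[m]
            means.append(float(vals.mean()))
            sds.append(float(vals.std(ddof=1)) if n > 1 else 0.0)
            ns.append(n)
        series.append(
            CalibrationSeries(
                energy=energy, concentrations=concs_mg, means=means, sds=sds, ns=ns
            )
        )
    return series[0], series[1]


def _ols_line(c: np.ndarray, y: np.ndarray, weights: np.ndarray | None):
    """Slope, intercept, r^2 of y on c; optionally weighted least squares."""
    if weights is None:
        res = stats.linregress(c, y)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)
    w = np.asarray(weights, dtype=float)
    W = np.diag(w)
    X = np.column_stack([np.ones_like(c), c])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    yhat = X @ beta
    ybar = np.average(y, weights=w)
    ss_res = float(w @ (y - yhat) ** 2)
    ss_tot = float(w @ (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(beta[1]), float(beta[0]), r2


def fit_sensitivity(
    series_low: CalibrationSeries,
    series_high: CalibrationSeries,
    weighted: bool = False,
    e_water: tuple[float, float] = (E_WATER, E_WATER),
) -> SensitivityMatrix:
    """Per-energy OLS of mean CT' on concentration -> sensitivity matrix.

    ``weighted`` switches to 1/sd² inverse-variance weighting (points with
    zero sd fall back to unweighted).  The water column is fixed at
    ``e_water`` rather than fitted, per the shifted-CT convention.
    """
    out = {}
    for tag, s in (("low", series_low), ("high", series_high)):
        c = s.concentrations
        if len(np.unique(c)) < 2:
            raise DegenerateDesignError(
                f"{tag}-energy series needs >=2 distinct concentrations"
            )
        weights = None
        if weighted and (s.sds > 0).all():
            weights = 1.0 / s.sds**2
        slope, intercept, r2 = _ols_line(c, s.means, weights)
        if slope < 0:
            warnings.warn(
                f"negative fitted gold sensitivity at {tag} energy ({slope:.3g}); "
                "check vial concentrations/ROIs",
                stacklevel=2,
            )
        out[tag] = (slope, intercept, r2)
    return SensitivityMatrix(
        e_au_low=out["low"][0],
        e_au_high=out["high"][0],
        e_w_low=e_water[0],
        e_w_high=e_water[1],
        intercept_low=out["low"][1],
        intercept_high=out["high"][1],
        fit_r2_low=out["low"][2],
        fit_r2_high=out["high"][2],
    )


def validate_calibration(
    fit: SensitivityMatrix,
    series_low: CalibrationSeries,
    series_high: CalibrationSeries,
    reference_concentrations_ug_ml,
    condition_cap: float = 1e8,
) -> pd.DataFrame:
    """Back-predict each vial's concentration through the fitted system.

    Solves the 2×2 system on each vial's mean CT' pair and reports
    per-vial recovered concentration, relative error against the reference
    list (ICP-MS-style truth), and the DECT-vs-reference Pearson
    correlation (as a frame attribute ``correlation``).
    """
    ref = np.atleast_1d(np.asarray(reference_concentrations_ug_ml, dtype=float))
    if len(ref) != len(series_low) or len(series_low) != len(series_high):
        raise InputError(
            f"reference list length {len(ref)} does not match series length {len(series_low)}"
        )
    try:
        inv = fit.inverse(condition_cap)
    except Exception as exc:
        raise CalibrationError(f"calibration not invertible: {exc}") from exc
    ct = np.vstack([series_low.means, series_high.means]) - fit.intercepts[:, None]
    sol = inv @ ct  # rows: (c_water, c_au) in mg/ml
    recovered_ug = mg_to_ug(sol[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(ref > 0, (recovered_ug - ref) / ref, np.nan)
    df = pd.DataFrame(
        {
            "reference_ug_ml": ref,
            "recovered_ug_ml": recovered_ug,
            "relative_error": rel_err,
        }
    )
    if len(ref) >= 2 and np.std(ref) > 0 and np.std(recovered_ug) > 0:
        corr = float(np.corrcoef(ref, recovered_ug)[0, 1])
    else:
        corr = float("nan")
    df.attrs["correlation"] = corr
    df.attrs["mean_abs_relative_error"] = float(np.nanmean(np.abs(rel_err)))
    return df


class DualEnergyCalibration:
    """Calibration model: vial measurements at two energies.

    Construct from a measured ``DualEnergyImage`` plus vial labels
    (``from_image``), from a tidy table (``from_dataframe`` /
    ``from_csv``, columns energy_kvp, concentration_ug_ml, mean_hu,
    sd_hu, n_voxels — mean_hu in true HU), or directly from two
    ``CalibrationSeries``.  ``fit`` performs the per-energy regressions.
    """

    def __init__(self, series_low: CalibrationSeries, series_high: CalibrationSeries):
        self.series_low = series_low
        self.series_high = series_high

    @classmethod
    def from_image(
        cls,
        image: DualEnergyImage,
        vial_labels: np.ndarray,
        concentrations_ug_ml,
    ) -> "DualEnergyCalibration":
        low, high = measure_vials(image, vial_labels, concentrations_ug_ml)
        return cls(low, high)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, hu_offset: float = 1000.0) -> "DualEnergyCalibration":
        required = {"energy_kvp", "concentration_ug_ml", "mean_hu", "sd_hu", "n_voxels"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"calibration table missing columns: {sorted(missing)}")
        energies = np.sort(df["energy_kvp"].unique())
        if len(energies) != 2:
            raise InputError(f"expected exactly 2 energies, got {list(energies)}")
        series = []
        for e in energies:
            sub = df[df["energy_kvp"] == e].sort_values("concentration_ug_ml")
            series.append(
                CalibrationSeries(
                    energy=float(e),
                    concentrations=ug_to_mg(sub["concentration_ug_ml"].to_numpy()),
                    means=sub["mean_hu"].to_numpy(dtype=float) + hu_offset,
                    sds=sub["sd_hu"].to_numpy(dtype=float),
                    ns=sub["n_voxels"].to_numpy(dtype=int),
                )
            )
        return cls(*series)

    @classmethod
    def from_csv(cls, path, hu_offset: float = 1000.0) -> "DualEnergyCalibration":
        return cls.from_dataframe(pd.read_csv(path), hu_offset=hu_offset)

    def fit(self, weighted: bool = False) -> "CalibrationResults":
        sens = fit_sensitivity(self.series_low, self.series_high, weighted=weighted)
        return CalibrationResults(self, sens)


class CalibrationResults:
    """Fitted sensitivity coefficients plus diagnostics."""

    def __init__(self, model: DualEnergyCalibration, sensitivity: SensitivityMatrix):
        self.model = model
        self.sensitivity = sensitivity

    @property
    def condition_number(self) -> float:
        return self.sensitivity.condition_number

    def predict_ct(self, c_water_mg_ml, c_au_mg_ml) -> np.ndarray:
        """Forward-predict (CT'_low, CT'_high) for given concentrations."""
        s = self.sensitivity
        cw = np.asarray(c_water_mg_ml, dtype=float)
        ca = np.asarray(c_au_mg_ml, dtype=float)
        return np.stack(
            [
                s.intercept_low + s.e_w_low * cw + s.e_au_low * ca,
                s.intercept_high + s.e_w_high * cw + s.e_au_high * ca,
            ]
        )

    def validate(self, reference_concentrations_ug_ml=None, condition_cap: float = 1e8):
        ref = (
            reference_concentrations_ug_ml
            if reference_concentrations_ug_ml is not None
            else mg_to_ug(self.model.series_low.concentrations)
        )
        return validate_calibration(
            self.sensitivity, self.model.series_low, self.model.series_high, ref, condition_cap
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.sensitivity.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def summary(self) -> str:
        s = self.sensitivity
        lines = [
            "Dual-energy sensitivity calibration",
            "===================================",
            f"{'energy':>8} {'e_w':>8} {'e_Au':>8} {'intercept':>10} {'r^2':>8}",
            f"{'low':>8} {s.e_w_low:8.4f} {s.e_au_low:8.4f} {s.intercept_low:10.2f} {s.fit_r2_low:8.5f}",
            f"{'high':>8} {s.e_w_high:8.4f} {s.e_au_high:8.4f} {s.intercept_high:10.2f} {s.fit_r2_high:8.5f}",
            f"condition number: {s.condition_number:.3f}",
            "units: sensitivities HU'/(mg/ml); intercepts HU' (CT = HU + 1000)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        s = self.sensitivity
        return (
            f"<CalibrationResults e_Au=({s.e_au_low:.3f}, {s.e_au_high:.3f}) "
            f"cond={s.condition_number:.2f}>"
        )
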