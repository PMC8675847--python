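"""Haemolysis assay statistic.

Free haemoglobin released by ruptured red blood cells is read as 540 nm
absorbance; a sample's haemolysis fraction is its absorbance normalised
between the negative control (buffer-incubated cells, no lysis) and the
positive control (fully lysed cells)::

    hemolysis = (abs_sample - abs_negative) / (abs_positive - abs_negative)

The fraction is dimensionless (percentage at report boundaries) and by
construction invariant to adding a constant to all three absorbances or
scaling all three by a positive factor.  Values below 0 (sample reading
under the negative control) are reported as computed, flagged rather than
clipped.  Replicate spread is summarised by the sd across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AssayInvalidError, InputError

#: Default assay concentration grid, μM Au.
DEFAULT_CONCENTRATIONS_UM = (200.0, 300.0, 400.0, 500.0, 600.0)

_ROLES = {"sample", "negative", "positive"}
_COLUMNS = ("label", "concentration_uM", "replicate", "absorbance", "role")


@dataclass
class HemolysisAssay:
    """Replicate-level 540 nm absorbance readings.

    ``data`` is a tidy table with columns label, concentration_uM,
    replicate, absorbance, role (sample / negative / positive).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.data.columns)
        if missing:
            raise InputError(f"assay table missing columns: {sorted(missing)}")
        bad = set(self.data["role"]) - _ROLES
        if bad:
            raise InputError(f"unknown roles {sorted(bad)}; expected {sorted(_ROLES)}")
        if (self.data["absorbance"] < 0).any():
            raise InputError("absorbances must be non-negative")
        for role in ("negative", "positive"):
            if not (self.data["role"] == role).any():
                raise AssayInvalidError(f"assay has no {role} control readings")

    @classmethod
    def from_records(
        cls,
        samples: dict[str, list[float]],
        negative: list[float],
        positive: list[float],
        concentrations_uM: dict[str, float] | None = None,
    ) -> "HemolysisAssay":
        """Build an assay from per-label replicate absorbance lists."""
        rows = []
        conc = concentrations_uM or {}
        for label, reps in samples.items():
            for i, a in enumerate(reps):
                rows.append((label, conc.get(label, np.nan), i, a, "sample"))
        for role, reps in (("negative", negative), ("positive", positive)):
            for i, a in enumerate(reps):
                rows.append((role, np.nan, i, a, role))
        return cls(pd.DataFrame(rows, columns=_COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "HemolysisAssay":
        return cls(pd.read_csv(path))

    @property
    def abs_negative(self) -> float:
        return float(self.data.loc[self.data["role"] == "negative", "absorbance"].mean())

    @property
    def abs_positive(self) -> float:
        return float(self.data.loc[self.data["role"] == "positive", "absorbance"].mean())


def hemolysis_ratio(abs_sample: float, abs_negative: float, abs_positive: float) -> float:
    """The scalar haemolysis fraction for one absorbance triple."""
    denom = abs_positive - abs_negative
    if denom <= 0:
        raise AssayInvalidError(
            f"positive control ({abs_positive}) must exceed negative control ({abs_negative})"
        )
    return (abs_sample - abs_negative) / denom


def hemolysis_fraction(assay: HemolysisAssay) -> pd.DataFrame:
    """Per-sample haemolysis fraction with replicate sd.

    The fraction is computed per replicate against the mean controls and
    summarised by mean and sd across replicates; ``percent`` is the
    report-boundary scale, ``below_zero`` flags samples reading under the
    negative control.
    """
    neg, pos = assay.abs_negative, assay.abs_positive
    if pos <= neg:
        raise AssayInvalidError(
            f"positive control ({pos}) must exceed negative control ({neg})"
        )
    rows = []
    samples = assay.data[assay.data["role"] == "sample"]
    for (label,), grp in samples.groupby(["label"], sort=False):
        fr = (grp["absorbance"].to_numpy(dtype=float) - neg) / (pos - neg)
        rows.append(
            {
                "label": label,
                "concentration_uM": float(grp["concentration_uM"].iloc[0]),
                "n_replicates": len(fr),
                "fraction": float(fr.mean()),
                "sd": float(fr.std(ddof=1)) if len(fr) > 1 else 0.0,
                "percent": float(100.0 * fr.mean()),
                "below_zero": bool(fr.mean() < 0),
            }
        )
    return pd.DataFrame(rows)
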