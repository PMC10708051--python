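"""ICH-style validation statistics for microwell spectrophotometric assays.

Covers the calibration workflow of a 96-well plate method: least-squares
calibration with intercept standard error, LOD/LOQ from the intercept SE
(3.3 and 10 x SDa/slope), precision/accuracy summaries (recovery, error,
RSD), unknown quantitation with linear-range flags, label-claim reporting,
robustness summaries and batch-throughput arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFit",
    "PlateLayout",
    "fit_calibration",
    "lod_loq",
    "precision_accuracy",
    "quantify_unknowns",
    "label_claim",
    "robustness_summary",
    "throughput",
    "read_plate_csv",
    "write_plate_csv",
    "read_layout_csv",
    "plate_to_series",
    "blank_correct",
    "fit_calibration_from_plate",
]

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")
_ROLES = {"standard", "unknown", "blank"}


@dataclass
class CalibrationFit:
    """OLS calibration line absorbance = intercept + slope * concentration.

    ``slope`` in AU per ug/mL, ``intercept`` and its standard error
    ``intercept_se`` in AU, ``n`` points, ``conc_range`` the fitted
    concentration span (ug/mL).
    """

    slope: float
    intercept: float
    r_squared: float
    intercept_se: float
    n: int
    conc_range: tuple[float, float]


@dataclass
class PlateLayout:
    """Mapping of wells (A1-H12) to sample id, nominal concentration and role."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "sample_id", "nominal_ug_ml", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        wells = self.table["well"].astype(str)
        bad = [w for w in wells if not _WELL_RE.match(w)]
        if bad:
            raise ValueError(f"invalid well ids: {bad[:5]}")
        if wells.duplicated().any():
            dup = wells[wells.duplicated()].iloc[0]
            raise ValueError(f"duplicate well in layout: {dup}")
        bad_roles = set(self.table["role"]) - _ROLES
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")

    def subset(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role]


def fit_calibration(concs, absorbances) -> CalibrationFit:
    """Least-squares calibration line with intercept standard error.

    Requires at least 5 distinct concentration levels (ICH linearity
    practice); replicate wells at a level are individual points.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.size != y.size:
        raise ValueError("concs and absorbances must have equal length")
    if np.unique(x).size < 5:
        raise ValueError("calibration requires at least 5 unique concentration levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")
    fit = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        intercept_se=float(fit.intercept_stderr),
        n=int(x.size),
        conc_range=(float(np.min(x)), float(np.max(x))),
    )


def lod_loq(fit: CalibrationFit) -> tuple[float, float]:
    """Detection and quantitation limits from the calibration fit.

    ``LOD = 3.3 * SDa / b`` and ``LOQ = 10 * SDa / b`` where SDa is the
    standard error of the intercept and b the slope (ICH Q2 signal-to-noise
    surrogate).  Their ratio is 10/3.3 by construction.
    """
    if fit.slope <= 0:
        raise ValueError("slope must be positive for LOD/LOQ")
    lod = 3.3 * fit.intercept_se / fit.slope
    loq = 10.0 * fit.intercept_se / fit.slope
    return lod, loq


def precision_accuracy(found, nominal: float) -> dict[str, float]:
    """Recovery, error and RSD of replicate found concentrations.

    ``recovery = 100 * mean(found)/nominal`` (%), ``error = recovery - 100``
    (%), ``rsd = 100 * sd(found, ddof=1)/mean(found)`` (%).  Sample standard
    deviation is used because replicate counts are small (n = 3-6).
    """
    found = np.asarray(found, dtype=float)
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    if found.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(np.mean(found))
    recovery = 100.0 * mean / nominal
    rsd = 100.0 * float(np.std(found, ddof=1)) / mean
    return {"recovery": recovery, "error": recovery - 100.0, "rsd": rsd}


def quantify_unknowns(
    fit: CalibrationFit,
    plate: pd.DataFrame,
    layout: PlateLayout,
) -> pd.DataFrame:
    """Invert the calibration line for every non-blank well in the layout.

    ``C = (A - intercept)/slope``; concentrations outside the calibration
    range are reported with ``in_range=False`` (never clipped).  A layout
    well missing from the plate readings raises ``KeyError``.
    """
    readings = plate_to_series(plate)
    rows = []
    for _, entry in layout.table.iterrows():
        well = entry["well"]
        if well not in readings.index or pd.isna(readings[well]):
            raise KeyError(f"no reading for well {well}")
        if entry["role"] == "blank":
            continue
        a = float(readings[well])
        conc = (a - fit.intercept) / fit.slope
        lo, hi = fit.conc_range
        rows.append(
            {
                "well": well,
                "sample_id": entry["sample_id"],
                "role": entry["role"],
                "absorbance": a,
                "conc_ug_ml": conc,
                "in_range": bool(lo <= conc <= hi),
            }
        )
    return pd.DataFrame(
        rows, columns=["well", "sample_id", "role", "absorbance", "conc_ug_ml", "in_range"]
    )


def label_claim(found: float, nominal: float) -> float:
    """Label-claim percentage, ``100 * found / nominal``."""
    if nominal <= 0:
        raise ValueError("nominal content must be positive")
    return 100.0 * found / nominal


def robustness_summary(
    groups: Mapping[str, tuple[Sequence[float], float]]
) -> pd.DataFrame:
    """Per-condition recovery +/- RSD table.

    ``groups`` maps a condition label to ``(found replicates, nominal)``;
    the result has one row per condition with recovery (%), error (%) and
    RSD (%), mirroring a robustness/ruggedness report.
    """
    rows = []
    for condition, (found, nominal) in groups.items():
        summary = precision_accuracy(found, nominal)
        rows.append({"condition": condition, **summary})
    return pd.DataFrame(rows, columns=["condition", "recovery", "error", "rsd"])


def throughput(plates_per_batch: int, wells: int, rounds_per_hour: float) -> float:
    """Samples processed per hour: plates x wells x rounds/hour."""
    if plates_per_batch <= 0 or wells <= 0 or rounds_per_hour <= 0:
        raise ValueError("all throughput arguments must be positive")
    return plates_per_batch * wells * rounds_per_hour


# --------------------------------------------------------------------------
# plate I/O
# --------------------------------------------------------------------------

def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read an 8x12 plate-reading CSV (rows A-H, columns 1-12)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: plate file is empty") from exc
    df.index = df.index.astype(str)
    if list(df.index) != list("ABCDEFGH"):
        raise ValueError(f"{path}: plate rows must be A-H, got {list(df.index)[:9]}")
    try:
        df.columns = [int(c) for c in df.columns]
    except ValueError as exc:
        raise ValueError(f"{path}: plate columns must be 1-12") from exc
    if list(df.columns) != list(range(1, 13)):
        raise ValueError(f"{path}: plate columns must be 1-12")
    return df.astype(float)


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, float_format="%.6g")


def read_layout_csv(path: str | Path) -> PlateLayout:
    """Read a ``well,sample_id,nominal_ug_ml,role`` layout CSV."""
    df = pd.read_csv(path, comment="#")
    return PlateLayout(df)


def plate_to_series(plate: pd.DataFrame) -> pd.Series:
    """Flatten an 8x12 plate to a Series indexed by well id (A1..H12)."""
    data = {}
    for row in plate.index:
        for col in plate.columns:
            data[f"{row}{int(col)}"] = plate.loc[row, col]
    return pd.Series(data)


def blank_correct(plate: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Subtract the mean blank absorbance from every well.

    With no blank wells in the layout the plate is returned unchanged;
    blanking is optional in this workflow, and when applied it must precede
    both calibration fitting and unknown quantitation so the two stay
    consistent.
    """
    blanks = layout.subset("blank")
    if blanks.empty:
        return plate.copy()
    readings = plate_to_series(plate)
    blank_mean = float(np.mean([readings[w] for w in blanks["well"]]))
    return plate - blank_mean


def fit_calibration_from_plate(
    plate: pd.DataFrame, layout: PlateLayout, blanked: bool = True
) -> CalibrationFit:
    """Calibration fit from the standard wells of a plate.

    When ``blanked`` (default) and blank wells are present, the mean blank
    absorbance is subtracted from every reading before fitting.
    """
    if blanked:
        plate = blank_correct(plate, layout)
    readings = plate_to_series(plate)
    std = layout.subset("standard")
    if std.empty:
        raise ValueError("layout contains no standard wells")
    concs = std["nominal_ug_ml"].to_numpy(dtype=float)
    absorb = np.array([readings[w] for w in std["well"]], dtype=float)
    return fit_calibration(concs, absorb)
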