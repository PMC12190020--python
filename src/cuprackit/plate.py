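"""Reading, validating and writing the assay's tabular formats.

Canonical dialects (UTF-8, comma-separated, ``.`` decimal):

* plate CSV — long ("tidy") kinetic reads:
  ``well,time_min,wavelength_nm,absorbance``
* design CSV — solvent-screen replicates:
  ``frac_methanol,frac_ethanol,frac_water,replicate,absorbance``
* calibration CSV — ``conc_uM,replicate,absorbance``
* groups CSV — either raw replicates ``label,replicate,teac`` or
  summaries ``label,n,mean,sd``
* reports — JSON with a ``"schema": "cuprackit/1"`` field.

Plate geometry is fixed at 8 rows x 12 columns (96-well); well IDs are
case-insensitive on input and stored uppercase.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError, FormatError

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = range(1, 13)
REPORT_SCHEMA = "cuprackit/1"

_WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")
_NUMBER_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def validate_well_id(well: str) -> str:
    """Normalise a well ID to uppercase and check it is on the 96-well grid."""
    w = str(well).strip().upper()
    if not _WELL_RE.match(w):
        raise DataValidationError(
            f"well ID {well!r} is not a valid 96-well coordinate (A1..H12)"
        )
    return w


@dataclass
class KineticSeries:
    """Absorbance of one well monitored over time at a single wavelength.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A1"``.
    timepoints : array-like
        Minutes since the start of the read; strictly increasing, >= 0.
    absorbances : array-like
        Absorbance units (AU), same length as ``timepoints``.
    wavelength : float
        Detection wavelength in nm (the assay reads the Cu(I)-neocuproine
        complex at 450 nm).
    """

    well_id: str
    timepoints: np.ndarray
    absorbances: np.ndarray
    wavelength: float = 450.0

    def __post_init__(self) -> None:
        self.well_id = validate_well_id(self.well_id)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.timepoints.shape != self.absorbances.shape:
            raise DataValidationError(
                f"well {self.well_id}: {self.timepoints.size} timepoints but "
                f"{self.absorbances.size} absorbances"
            )
        if self.timepoints.size == 0:
            raise DataValidationError(f"well {self.well_id}: empty series")
        if np.any(self.timepoints < 0):
            raise DataValidationError(f"well {self.well_id}: negative timepoint")
        if np.any(np.diff(self.timepoints) <= 0):
            raise DataValidationError(
                f"well {self.well_id}: timepoints are not strictly increasing"
            )
        if not np.all(np.isfinite(self.absorbances)):
            raise DataValidationError(
                f"well {self.well_id}: non-finite absorbance"
            )

    def endpoint(self, last_n: int = 1) -> float:
        """Endpoint absorbance: the final reading, or the mean of the last
        ``last_n`` readings when the tail of the kinetic trace is to be
        averaged."""
        if last_n < 1:
            raise ValueError("last_n must be >= 1")
        n = min(last_n, self.absorbances.size)
        return float(self.absorbances[-n:].mean())


@dataclass
class PlateTable:
    """A collection of :class:`KineticSeries` with free-form metadata."""

    series: list[KineticSeries] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.well_id for s in self.series]
        dup = {w for w in ids if ids.count(w) > 1}
        if dup:
            raise DataValidationError(f"duplicate well IDs: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.series)

    def well(self, well_id: str) -> KineticSeries:
        wid = validate_well_id(well_id)
        for s in self.series:
            if s.well_id == wid:
                return s
        raise KeyError(wid)

    @property
    def well_ids(self) -> list[str]:
        return [s.well_id for s in self.series]


def _read_csv_strict(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    """Strict numeric conversion; rejects comma decimals explicitly."""
    raw = df[col].astype(str).str.strip()
    bad = raw[~raw.map(lambda s: bool(_NUMBER_RE.match(s)))]
    if len(bad):
        example = bad.iloc[0]
        if "," in example:
            raise FormatError(
                f"{path}: column '{col}' contains comma-decimal value "
                f"{example!r}; use '.' as the decimal separator"
            )
        raise FormatError(
            f"{path}: column '{col}' contains non-numeric value {example!r}"
        )
    return raw.astype(float).to_numpy()


def read_plate(path: str | Path, metadata: Mapping[str, Any] | None = None) -> PlateTable:
    """Read a long-format plate CSV into a :class:`PlateTable`.

    Row order in the file does not affect the result: rows are grouped by
    well and sorted by time before validation.
    """
    df = _read_csv_strict(path, ["well", "time_min", "absorbance"])
    if len(df) == 0:
        return PlateTable(series=[], metadata=dict(metadata or {}))
    wells = df["well"].map(validate_well_id)
    time = _numeric(df, "time_min", path)
    absorb = _numeric(df, "absorbance", path)
    if "wavelength_nm" in df.columns:
        wl = _numeric(df, "wavelength_nm", path)
    else:
        wl = np.full(len(df), 450.0)

    tidy = pd.DataFrame(
        {"well": wells, "time_min": time, "wavelength_nm": wl, "absorbance": absorb}
    )
    if tidy.duplicated(["well", "time_min"]).any():
        dup = tidy[tidy.duplicated(["well", "time_min"])].iloc[0]
        raise DataValidationError(
            f"{path}: duplicated (well, time) row: well {dup['well']} at "
            f"t={dup['time_min']} min"
        )
    series = []
    for wid, grp in tidy.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        wls = grp["wavelength_nm"].unique()
        if len(wls) > 1:
            raise DataValidationError(
                f"{path}: well {wid} mixes wavelengths {sorted(wls)}"
            )
        series.append(
            KineticSeries(
                well_id=str(wid),
                timepoints=grp["time_min"].to_numpy(),
                absorbances=grp["absorbance"].to_numpy(),
                wavelength=float(wls[0]),
            )
        )
    return PlateTable(series=series, metadata=dict(metadata or {}))


def write_plate(table: PlateTable, path: str | Path) -> None:
    rows = []
    for s in table.series:
        for t, a in zip(s.timepoints, s.absorbances):
            rows.append((s.well_id, t, s.wavelength, a))
    pd.DataFrame(
        rows, columns=["well", "time_min", "wavelength_nm", "absorbance"]
    ).to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a solvent-screen design CSV (fractions + replicate signals)."""
    df = _read_csv_strict(
        path, ["frac_methanol", "frac_ethanol", "frac_water", "replicate", "absorbance"]
    )
    out = pd.DataFrame(
        {
            "frac_methanol": _numeric(df, "frac_methanol", path),
            "frac_ethanol": _numeric(df, "frac_ethanol", path),
            "frac_water": _numeric(df, "frac_water", path),
            "replicate": _numeric(df, "replicate", path).astype(int),
            "absorbance": _numeric(df, "absorbance", path),
        }
    )
    if (out["absorbance"] < 0).any():
        raise DataValidationError(f"{path}: negative absorbance in design table")
    return out


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["frac_methanol", "frac_ethanol", "frac_water", "replicate", "absorbance"]
    df[cols].to_csv(path, index=False)


def read_calibration(path: str | Path) -> pd.DataFrame:
    """Read a calibration CSV (Trolox concentration in uM vs absorbance)."""
    df = _read_csv_strict(path, ["conc_uM", "replicate", "absorbance"])
    out = pd.DataFrame(
        {
            "conc_uM": _numeric(df, "conc_uM", path),
            "replicate": _numeric(df, "replicate", path).astype(int),
            "absorbance": _numeric(df, "absorbance", path),
        }
    )
    if (out["conc_uM"] < 0).any():
        raise DataValidationError(f"{path}: negative concentration")
    return out


def write_calibration(df: pd.DataFrame, path: str | Path) -> None:
    df[["conc_uM", "replicate", "absorbance"]].to_csv(path, index=False)


def read_groups(path: str | Path) -> pd.DataFrame:
    """Read a groups CSV in either raw (label,replicate,teac) or summary
    (label,n,mean,sd) form; the returned frame carries a ``kind`` attr."""
    df = _read_csv_strict(path, ["label"])
    if {"replicate", "teac"}.issubset(df.columns):
        out = pd.DataFrame(
            {
                "label": df["label"].astype(str),
                "replicate": _numeric(df, "replicate", path).astype(int),
                "teac": _numeric(df, "teac", path),
            }
        )
        out.attrs["kind"] = "raw"
        return out
    if {"n", "mean", "sd"}.issubset(df.columns):
        out = pd.DataFrame(
            {
                "label": df["label"].astype(str),
                "n": _numeric(df, "n", path).astype(int),
                "mean": _numeric(df, "mean", path),
                "sd": _numeric(df, "sd", path),
            }
        )
        out.attrs["kind"] = "summary"
        return out
    raise FormatError(
        f"{path}: groups CSV must have columns (label,replicate,teac) or "
        f"(label,n,mean,sd); found {list(df.columns)}"
    )


def read_layout(path: str | Path) -> dict[str, str]:
    """Read a plate-layout CSV mapping wells to sample labels.

    The physical arrangement of standards and samples is user-supplied
    metadata; it is never inferred from the plate read itself.
    """
    df = _read_csv_strict(path, ["well", "label"])
    layout: dict[str, str] = {}
    for _, row in df.iterrows():
        wid = validate_well_id(row["well"])
        if wid in layout:
            raise DataValidationError(f"{path}: well {wid} assigned twice")
        layout[wid] = str(row["label"]).strip()
    return layout


def write_layout(layout: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(layout.items()), columns=["well", "label"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON reports


def _jsonable(obj: Any, _path: str = "report") -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name), f"{_path}.{f.name}")
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v, f"{_path}.{k}") for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v, _path) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, f"{_path}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        if not math.isfinite(obj):
            raise DataValidationError(
                f"report field {_path} is non-finite ({obj!r}); refusing to write"
            )
        return obj
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    raise TypeError(f"cannot serialise report field {_path} of type {type(obj)}")


def write_report(report: Any, path: str | Path) -> None:
    """Serialise any result object (dataclass / dict / nested) as JSON.

    Values round-trip through :func:`read_report` at full double precision.
    Non-finite numbers are refused with an error naming the field.
    """
    payload = _jsonable(report)
    if isinstance(payload, dict):
        payload.setdefault("schema", REPORT_SCHEMA)
    else:
        payload = {"schema": REPORT_SCHEMA, "report": payload}
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, allow_nan=False)
            fh.write("\n")
    except OSError as exc:
        raise FormatError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "schema" not in payload:
        raise FormatError(f"{path}: not a cuprackit report (no schema field)")
    return payload
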