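"""Trolox-equivalent antioxidant capacity (TEAC) of sample extracts.

The blank-corrected endpoint absorbance dA of an extract is converted to
mol Trolox equivalents per gram of sample:

    TEAC = dA * V_f * V_i / (epsilon * V_s * W_s * h)

with V_f the final well volume, V_i the initial extract volume, V_s the
extract volume added to the well, W_s the sample mass, h the optical path
length and epsilon the Trolox molar absorptivity in the assay reagent.
TEAC is computed and stored in mol/g (the formula's natural unit);
reports default to mmol/g.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataValidationError
from .plate import KineticSeries, PlateTable

#: exact decimal factors between supported display units and mol/g
UNIT_FACTORS = {"mol/g": 1.0, "mmol/g": 1e3, "umol/g": 1e6}


@dataclass(frozen=True)
class AssayGeometry:
    """Volumes, mass and path length entering the TEAC formula.

    Defaults are the standard microplate protocol: 0.25 mL final well
    volume, 10 mL extraction volume, 0.10 mL extract per well, 0.080 g
    sample, 0.50 cm solution height.
    """

    v_f: float = 0.25   # mL, final well volume
    v_i: float = 10.0   # mL, initial extract volume
    v_s: float = 0.10   # mL, extract volume added to the well
    w_s: float = 0.080  # g, sample mass extracted
    h: float = 0.50     # cm, optical path length

    def __post_init__(self) -> None:
        for name in ("v_f", "v_i", "v_s", "w_s", "h"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"geometry field {name} must be > 0")
        if self.v_s > self.v_f:
            raise DataValidationError("sample volume v_s cannot exceed well volume v_f")


@dataclass
class DeltaAbsorbance:
    """Blank-corrected absorbance; negative values are allowed but flagged."""

    value: float
    wavelength: float
    negative: bool = field(init=False)

    def __post_init__(self) -> None:
        self.negative = self.value < 0


def delta_absorbance(sample: KineticSeries, blank: KineticSeries, last_n: int = 1) -> DeltaAbsorbance:
    """dA between a sample well and a blank well at matching wavelength."""
    if sample.wavelength != blank.wavelength:
        raise DataValidationError(
            f"wavelength mismatch: sample {sample.wavelength} nm vs blank "
            f"{blank.wavelength} nm"
        )
    d = DeltaAbsorbance(sample.endpoint(last_n) - blank.endpoint(last_n), sample.wavelength)
    if d.negative:
        warnings.warn(
            f"negative delta-absorbance ({d.value:.4f} AU) for well {sample.well_id}",
            stacklevel=2,
        )
    return d


def teac(delta_a: float, geom: AssayGeometry, epsilon: float) -> float:
    """Evaluate the TEAC formula; result in mol Trolox equivalents per g."""
    if epsilon <= 0:
        raise DataValidationError(f"epsilon must be > 0, got {epsilon}")
    if not math.isfinite(delta_a):
        raise DataValidationError("delta_a must be finite")
    return delta_a * geom.v_f * geom.v_i / (epsilon * geom.v_s * geom.w_s * geom.h)


def convert_teac(value_mol_per_g: float, unit: str = "mmol/g") -> float:
    if unit not in UNIT_FACTORS:
        raise DataValidationError(f"unknown TEAC unit {unit!r}; use {sorted(UNIT_FACTORS)}")
    return value_mol_per_g * UNIT_FACTORS[unit]


def summarize_sample(replicate_teacs: Sequence[float]) -> tuple[float, float | None]:
    """Mean and sample (n-1) SD over replicate TEAC values; SD is absent
    for a single replicate."""
    vals = np.asarray(list(replicate_teacs), dtype=float)
    if vals.size == 0:
        raise DataValidationError("no replicate TEAC values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else None
    return mean, sd


@dataclass
class TEACResult:
    """Per-sample TEAC with replicate values and summary statistics."""

    sample_id: str
    delta_a: list[float]            # per-replicate dA (AU)
    replicates: list[float]         # per-replicate TEAC (mol/g)
    mean: float                     # mol/g
    sd: float | None                # mol/g, sample SD (n-1); None if n < 2
    unit: str = "mol/g"
    warnings: list[str] = field(default_factory=list)

    def in_unit(self, unit: str = "mmol/g") -> tuple[float, float | None]:
        f = UNIT_FACTORS[unit] if unit in UNIT_FACTORS else None
        if f is None:
            raise DataValidationError(f"unknown TEAC unit {unit!r}")
        return self.mean * f, None if self.sd is None else self.sd * f


def quantify_plate(
    plate: PlateTable,
    layout: Mapping[str, str],
    geom: AssayGeometry,
    epsilon: float,
    blank_label: str = "blank",
    last_n: int = 1,
    calibrated_max_delta_a: float | None = 0.70,
) -> list[TEACResult]:
    """TEAC per sample from a plate read and a well-to-sample layout.

    Blank wells (layout label ``blank_label``) are averaged into a single
    blank endpoint; each sample replicate well is blank-corrected and run
    through the TEAC formula. A dA beyond ``calibrated_max_delta_a`` (the
    top of the validated linear range, in AU) is flagged with a warning on
    the result — the value is still reported, but it was obtained outside
    the range the calibration validates.
    """
    unknown = sorted(set(layout) - set(plate.well_ids))
    if unknown:
        raise DataValidationError(f"layout names wells absent from the plate: {unknown}")
    blanks = [plate.well(w) for w, lab in layout.items() if lab == blank_label]
    if not blanks:
        raise DataValidationError(f"no wells labelled {blank_label!r} in the layout")
    wl = {b.wavelength for b in blanks}
    if len(wl) > 1:
        raise DataValidationError(f"blank wells mix wavelengths: {sorted(wl)}")
    blank_endpoint = float(np.mean([b.endpoint(last_n) for b in blanks]))

    by_sample: dict[str, list[KineticSeries]] = {}
    for well, label in sorted(layout.items()):
        if label == blank_label:
            continue
        by_sample.setdefault(label, []).append(plate.well(well))

    results = []
    for label, wells in by_sample.items():
        das, teacs, warns = [], [], []
        for w in wells:
            if w.wavelength not in wl:
                raise DataValidationError(
                    f"well {w.well_id}: wavelength differs from blanks"
                )
            da = w.endpoint(last_n) - blank_endpoint
            if da < 0:
                warns.append(f"well {w.well_id}: negative dA {da:.4f} AU")
            if calibrated_max_delta_a is not None and da > calibrated_max_delta_a:
                warns.append(
                    f"well {w.well_id}: dA {da:.3f} AU exceeds the calibrated "
                    f"range (max {calibrated_max_delta_a} AU)"
                )
            das.append(da)
            teacs.append(teac(da, geom, epsilon))
        mean, sd = summarize_sample(teacs)
        results.append(
            TEACResult(
                sample_id=label, delta_a=das, replicates=teacs,
                mean=mean, sd=sd, warnings=warns,
            )
        )
    return results
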