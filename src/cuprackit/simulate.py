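"""Synthetic data generators for every pipeline input.

Each generator draws Gaussian, homoscedastic-within-class noise around a
known truth so that every downstream stage can be exercised and its
estimators checked by round-trip recovery. Defaults reproduce the
statistical structure of the reference datasets bundled with the package:
the seven-point simplex design (three vertices, three edge midpoints,
centroid) with per-class replicate SDs of 0.039/0.046/0.060 AU, a
calibration line y = 0.013 x + 0.039 with 0.004 AU residual noise over
0-50 uM, and plate reads whose blank sits at the calibration intercept.

All generators are deterministic given ``GeneratorConfig.seed`` and emit
objects (or CSV files via :mod:`cuprackit.plate`) that pass the
corresponding reader's validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import CalibrationPoint
from .errors import DataValidationError
from .mixture import (
    MixtureDesignTable,
    MixtureObservation,
    ScheffeCoefficients,
    SolventComposition,
    predict_phi,
)
from .plate import PLATE_ROWS, KineticSeries, PlateTable
from .quantify import AssayGeometry

#: the seven-point simplex-lattice design used by the reference screen
DESIGN_POINTS = [
    SolventComposition(1, 0, 0),
    SolventComposition(0, 1, 0),
    SolventComposition(0, 0, 1),
    SolventComposition(0.5, 0.5, 0),
    SolventComposition(0.5, 0, 0.5),
    SolventComposition(0, 0.5, 0.5),
    SolventComposition(1 / 3, 1 / 3, 1 / 3),
]


def _default_scheffe() -> ScheffeCoefficients:
    return ScheffeCoefficients(0.046, 0.038, 0.015, 0.063, 0.112, 0.066)


def _default_sigma() -> dict[str, float]:
    return {"pure": 0.039, "binary": 0.046, "ternary": 0.060}


def _default_teac_targets() -> dict[str, float]:
    # Three samples with means in the ratio 68.6 : 62.2 : 71.7, scaled so
    # the largest implied dA sits at 0.65 AU, inside the validated linear
    # range (see gen_samples).
    geom, eps = AssayGeometry(), 2.62e4
    per_da = geom.v_f * geom.v_i / (eps * geom.v_s * geom.w_s * geom.h)
    scale = 0.65 * per_da / 71.7
    return {"A": 68.6 * scale, "B": 62.2 * scale, "C": 71.7 * scale}


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic generators, with assay-realistic defaults."""

    seed: int
    scheffe_coeffs: ScheffeCoefficients = field(default_factory=_default_scheffe)
    sigma_by_class: dict[str, float] = field(default_factory=_default_sigma)
    mixture_noise_scale: float = 1.0  # replicate noise sd = scale * sigma(class)
    cal_slope: float = 0.013        # AU per uM
    cal_intercept: float = 0.039    # AU
    cal_sigma: float = 0.004        # AU, photometric replicate noise
    kinetic_drift: float = 0.0      # AU per min
    teac_targets: dict[str, float] = field(default_factory=_default_teac_targets)
    sample_sigma: float | None = None  # AU noise on dA; defaults to cal_sigma
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    epsilon: float = 2.62e4         # L mol^-1 cm^-1
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataValidationError("GeneratorConfig.seed is mandatory")
        for c, s in self.sigma_by_class.items():
            if s < 0:
                raise DataValidationError(f"sigma for class {c!r} must be >= 0")
        for p in ("cal_sigma",):
            if getattr(self, p) < 0:
                raise DataValidationError(f"{p} must be >= 0")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def gen_mixture_table(cfg: GeneratorConfig) -> MixtureDesignTable:
    """Simulate the solvent screen: for each design point the true signal
    is psi = Phi(z)/sigma(class), observed with N(0, sigma(class)) replicate
    noise (scaled by ``cfg.mixture_noise_scale``; 0 gives noise-free data)."""
    rng = np.random.default_rng(cfg.seed)
    obs = []
    for z in DESIGN_POINTS:
        sigma = cfg.sigma_by_class[z.mixture_class]
        if sigma <= 0:
            raise DataValidationError(
                f"sigma for class {z.mixture_class!r} must be > 0 to place signals"
            )
        psi_true = predict_phi(cfg.scheffe_coeffs, z) / sigma
        for rep in range(1, cfg.replicates + 1):
            psi = psi_true + rng.normal(0.0, sigma * cfg.mixture_noise_scale)
            obs.append(MixtureObservation(z, max(psi, 0.0), rep))
    table = MixtureDesignTable(observations=obs)
    if cfg.replicates < 2:
        table.metadata["degenerate"] = "single replicate; sigma estimation impossible"
    return table


def gen_calibration(
    cfg: GeneratorConfig, levels: Sequence[float] = (0, 10, 20, 30, 40, 50)
) -> list[CalibrationPoint]:
    """Simulate a Trolox calibration: y = slope*x + intercept + N(0, cal_sigma),
    ``cfg.replicates`` replicates per level."""
    if len(levels) < 3:
        raise DataValidationError("calibration generator needs >= 3 levels")
    rng = np.random.default_rng(cfg.seed)
    pts = []
    for x in levels:
        for rep in range(1, cfg.replicates + 1):
            y = cfg.cal_slope * x + cfg.cal_intercept + rng.normal(0.0, cfg.cal_sigma)
            pts.append(CalibrationPoint(float(x), float(y), rep))
    return pts


def _well_name(i: int) -> str:
    return f"{PLATE_ROWS[i // 12]}{i % 12 + 1}"


def gen_kinetic(
    cfg: GeneratorConfig,
    base: float,
    n_timepoints: int = 31,
    n_replicates: int | None = None,
    well_offset: int = 0,
) -> list[KineticSeries]:
    """Simulate kinetic reads: absorbance(t) = base + drift*t + N(0, cal_sigma)."""
    if n_timepoints < 2:
        raise DataValidationError("need >= 2 timepoints")
    rng = np.random.default_rng(cfg.seed)
    reps = cfg.replicates if n_replicates is None else n_replicates
    t = np.arange(n_timepoints, dtype=float)
    out = []
    for rep in range(reps):
        a = base + cfg.kinetic_drift * t + rng.normal(0.0, cfg.cal_sigma, n_timepoints)
        out.append(KineticSeries(_well_name(well_offset + rep), t, a))
    return out


def gen_samples(
    cfg: GeneratorConfig, n_timepoints: int = 31
) -> tuple[PlateTable, dict[str, str]]:
    """Simulate sample wells from target TEAC values by inverting the TEAC
    formula: dA = teac * eps * V_s * W_s * h / (V_f * V_i), plus
    N(0, sample_sigma) per replicate well (sample_sigma defaults to the
    photometric cal_sigma). Blank wells at the calibration intercept are
    included. Implied dA outside [0, 3] AU is recorded as a warning in the
    plate metadata."""
    rng = np.random.default_rng(cfg.seed)
    g = cfg.geometry
    per_teac = cfg.epsilon * g.v_s * g.w_s * g.h / (g.v_f * g.v_i)
    sigma = cfg.cal_sigma if cfg.sample_sigma is None else cfg.sample_sigma
    series: list[KineticSeries] = []
    layout: dict[str, str] = {}
    t = np.arange(n_timepoints, dtype=float)
    warnings_: list[str] = []
    idx = 0
    for rep in range(cfg.replicates):
        w = _well_name(idx)
        idx += 1
        series.append(KineticSeries(w, t, np.full(n_timepoints, cfg.cal_intercept)))
        layout[w] = "blank"
    for label, target in sorted(cfg.teac_targets.items()):
        if target < 0:
            raise DataValidationError(f"negative TEAC target for sample {label!r}")
        da_true = target * per_teac
        if not (0.0 <= da_true <= 3.0):
            warnings_.append(
                f"sample {label!r}: implied dA {da_true:.3f} AU outside [0, 3]"
            )
        for rep in range(cfg.replicates):
            w = _well_name(idx)
            idx += 1
            da = da_true + rng.normal(0.0, sigma)
            series.append(
                KineticSeries(w, t, np.full(n_timepoints, cfg.cal_intercept + da))
            )
            layout[w] = label
    plate = PlateTable(series=series, metadata={"warnings": warnings_} if warnings_ else {})
    return plate, layout
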