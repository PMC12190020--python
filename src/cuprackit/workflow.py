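"""End-to-end orchestration of the assay pipeline.

A single JSON config drives up to four stages in order — solvent
optimization, calibration validation, TEAC quantification, group
comparison — and a consolidated JSON report (schema ``cuprackit/1``)
records every numerical decision (sigma-blank mode, endpoint rule,
assumed n for summary input) alongside the results, so reported numbers
are auditable. A failure in any stage halts the run with a diagnostic
naming the stage.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import calibration as cal
from . import groupstats, plate, quantify
from .errors import ConfigurationError, CuprackitError, PipelineError
from .mixture import ScheffeMixtureModel

log = logging.getLogger("cuprackit")


class MixtureStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    design_path: str
    grid_step: float = 0.005
    sigma_mode: str = "empirical"  # or "fixed"
    sigma_by_class: Optional[dict[str, float]] = None


class CalibrationStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    calibration_path: str
    path_length_cm: float = 0.50
    alpha: float = 0.05
    r_min: float = 0.990
    sigma_blank_mode: str = "replicates"
    endpoint_last_n: int = 1


class QuantifyStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    plate_path: str
    layout_path: str
    epsilon: Optional[float] = None  # None -> take from calibration stage
    v_f: float = 0.25
    v_i: float = 10.0
    v_s: float = 0.10
    w_s: float = 0.080
    path_length_cm: float = 0.50
    display_unit: str = "mmol/g"
    endpoint_last_n: int = 1


class CompareStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    groups_path: Optional[str] = None  # None -> use quantify-stage results
    alpha: float = 0.05
    method: str = "lsd"
    default_n: int = 3


class RunConfig(BaseModel):
    """Validated pipeline configuration (JSON-serialisable)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    mixture: Optional[MixtureStage] = None
    calibration: Optional[CalibrationStage] = None
    quantify: Optional[QuantifyStage] = None
    compare: Optional[CompareStage] = None
    report_path: Optional[str] = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        import json

        try:
            with open(path, encoding="utf-8") as fh:
                return cls.model_validate(json.load(fh))
        except ValidationError as exc:
            raise ConfigurationError(f"invalid run config {path}: {exc}") from exc

    def input_paths(self) -> list[str]:
        out = []
        if self.mixture:
            out.append(self.mixture.design_path)
        if self.calibration:
            out.append(self.calibration.calibration_path)
        if self.quantify:
            out += [self.quantify.plate_path, self.quantify.layout_path]
        if self.compare and self.compare.groups_path:
            out.append(self.compare.groups_path)
        return out


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run the configured stages in order and return the consolidated report."""
    for p in cfg.input_paths():
        if not Path(p).exists():
            raise ConfigurationError(f"input file does not exist: {p}")

    report: dict[str, Any] = {"schema": plate.REPORT_SCHEMA, "seed": cfg.seed, "stages": []}
    epsilon_from_cal: float | None = None
    teac_results: list[quantify.TEACResult] = []

    if cfg.mixture:
        st = cfg.mixture
        try:
            df = plate.read_design(st.design_path)
            sigma = st.sigma_by_class if st.sigma_mode == "fixed" else None
            if st.sigma_mode == "fixed" and sigma is None:
                raise ConfigurationError("sigma_mode 'fixed' needs sigma_by_class")
            model = ScheffeMixtureModel.from_dataframe(df, sigma_by_class=sigma)
            res = model.fit()
            opt = res.optimize(st.grid_step)
            log.info(
                "mixture: sigma_mode=%s sigma=%s grid_step=%g",
                st.sigma_mode, model.sigma_by_class, st.grid_step,
            )
            report["mixture"] = {
                "sigma_mode": st.sigma_mode,
                "sigma_by_class": model.sigma_by_class,
                "coefficients": _asdict(res.coefficients),
                "coefficients_rounded": _asdict(res.coefficients.rounded(3)),
                "standard_errors": [float(v) for v in res.bse],
                "optimum": {
                    "z_methanol": opt.composition.z1,
                    "z_ethanol": opt.composition.z2,
                    "z_water": opt.composition.z3,
                    "phi_pred": opt.phi_pred,
                    "psi_pred_AU": opt.psi_pred,
                    "grid_step": opt.grid_step,
                },
            }
            report["stages"].append("mixture")
        except CuprackitError as exc:
            raise PipelineError("mixture", str(exc)) from exc

    if cfg.calibration:
        st = cfg.calibration
        try:
            df = plate.read_calibration(st.calibration_path)
            results = cal.TroloxCalibration.from_dataframe(df).fit()
            vr = results.validate(
                path_length_cm=st.path_length_cm,
                alpha=st.alpha,
                r_min=st.r_min,
                sigma_blank_mode=st.sigma_blank_mode,
            )
            log.info(
                "calibration: sigma_blank_mode=%s endpoint=last_%d alpha=%g",
                st.sigma_blank_mode, st.endpoint_last_n, st.alpha,
            )
            epsilon_from_cal = vr.epsilon
            report["calibration"] = _asdict(vr)
            report["calibration"]["settings"] = st.model_dump()
            report["stages"].append("calibration")
        except CuprackitError as exc:
            raise PipelineError("calibration", str(exc)) from exc

    if cfg.quantify:
        st = cfg.quantify
        try:
            eps = st.epsilon if st.epsilon is not None else epsilon_from_cal
            if eps is None:
                raise ConfigurationError(
                    "quantify stage needs epsilon (explicit or from a calibration stage)"
                )
            table = plate.read_plate(st.plate_path)
            layout = plate.read_layout(st.layout_path)
            geom = quantify.AssayGeometry(
                v_f=st.v_f, v_i=st.v_i, v_s=st.v_s, w_s=st.w_s, h=st.path_length_cm
            )
            teac_results = quantify.quantify_plate(
                table, layout, geom, eps, last_n=st.endpoint_last_n
            )
            log.info("quantify: epsilon=%g geometry=%s unit=%s", eps, geom, st.display_unit)
            report["quantify"] = {
                "epsilon": eps,
                "geometry": _asdict(geom),
                "display_unit": st.display_unit,
                "samples": [
                    {
                        "sample_id": r.sample_id,
                        "mean": quantify.convert_teac(r.mean, st.display_unit),
                        "sd": None if r.sd is None
                        else quantify.convert_teac(r.sd, st.display_unit),
                        "n": len(r.replicates),
                        "unit": st.display_unit,
                        "delta_a": r.delta_a,
                        "warnings": r.warnings,
                    }
                    for r in teac_results
                ],
            }
            report["stages"].append("quantify")
        except CuprackitError as exc:
            raise PipelineError("quantify", str(exc)) from exc

    if cfg.compare:
        st = cfg.compare
        try:
            if st.groups_path:
                df = plate.read_groups(st.groups_path)
                comp = groupstats.AntioxidantComparison.from_dataframe(
                    df, default_n=st.default_n
                )
                if df.attrs.get("kind") == "summary" and "n" not in df.columns:
                    log.info("compare: replicate count assumed n=%d", st.default_n)
            elif teac_results:
                raw = {r.sample_id: r.replicates for r in teac_results}
                comp = groupstats.AntioxidantComparison(raw)
            else:
                raise ConfigurationError(
                    "compare stage needs groups_path or a preceding quantify stage"
                )
            res = comp.fit(alpha=st.alpha, method=st.method)
            log.info("compare: method=%s alpha=%g", st.method, st.alpha)
            report["compare"] = _asdict(res.report)
            report["stages"].append("compare")
        except CuprackitError as exc:
            raise PipelineError("compare", str(exc)) from exc

    if cfg.report_path:
        plate.write_report(report, cfg.report_path)
    return report
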