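"""Trolox calibration fitting and ICH-style validation.

A straight line y = phi*x + beta is fitted to replicate absorbances at a
handful of Trolox concentration levels (uM). Linearity is judged by the
joint condition r > r_min and F_experimental < F_critical, where the F
ratio compares lack-of-fit variance (systematic departure of level means
from the line, L-2 df) to pure-error variance (replicate scatter about the
level means, n-L df). The validation report further carries LOD/LOQ
(3.3 and 10 x sigma_blank/phi), per-point back-calculated accuracy,
kinetic precision (CV) and the molar absorptivity from Beer-Lambert
(epsilon = slope / path length, after converting uM to mol/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .errors import ConfigurationError, DataValidationError
from .plate import KineticSeries


@dataclass(frozen=True)
class CalibrationPoint:
    """One replicate absorbance at one nominal Trolox concentration."""

    x: float  # uM
    y: float  # AU
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.x < 0:
            raise DataValidationError(f"negative concentration {self.x}")
        if not math.isfinite(self.y):
            raise DataValidationError("non-finite absorbance")


@dataclass
class CalibrationFit:
    """OLS calibration line y = phi*x + beta with Pearson r."""

    phi: float          # slope, AU per uM
    beta: float         # intercept, AU
    r: float            # Pearson correlation (signed)
    n: int
    phi_se: float = float("nan")
    beta_se: float = float("nan")
    resid_sd: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return self.phi * np.asarray(x, dtype=float) + self.beta

    def invert(self, y) -> np.ndarray:
        """Back-calculate concentration from signal: x = (y - beta)/phi."""
        return (np.asarray(y, dtype=float) - self.beta) / self.phi


@dataclass
class LackOfFitANOVA:
    ss_pure: float
    ss_lof: float
    df_pure: int
    df_lof: int
    ms_pure: float
    ms_lof: float
    f_exp: float
    f_crit: float
    alpha: float

    @property
    def lack_of_fit_significant(self) -> bool:
        return self.f_exp >= self.f_crit


@dataclass
class ValidationReport:
    """Bundle of ICH-style validation outputs for one calibration."""

    fit: CalibrationFit
    anova: LackOfFitANOVA
    linear: bool
    r_condition: bool
    f_condition: bool
    r_min: float
    lod: float
    loq: float
    sigma_blank: float
    sigma_blank_mode: str
    accuracy: list[dict]
    cv: dict[str, float] | None
    epsilon: float | None
    epsilon_se: float | None
    path_length_cm: float | None


def _as_points(points: Iterable) -> list[CalibrationPoint]:
    out = []
    for p in points:
        if isinstance(p, CalibrationPoint):
            out.append(p)
        else:
            out.append(CalibrationPoint(float(p[0]), float(p[1])))
    return out


def fit_line(points: Iterable[CalibrationPoint]) -> CalibrationFit:
    """Ordinary least squares line with intercept; r is the Pearson
    correlation of (x, y)."""
    pts = _as_points(points)
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    if len(np.unique(x)) < 2:
        raise DataValidationError("calibration needs >= 2 distinct concentration levels")
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated 2-point fit
        res = sm.OLS(y, sm.add_constant(x)).fit()
        beta, phi = res.params
        saturated = res.df_resid <= 0
        resid_sd = 0.0 if saturated else float(np.sqrt(res.ssr / res.df_resid))
        phi_se = 0.0 if saturated else float(res.bse[1])
        beta_se = 0.0 if saturated else float(res.bse[0])
    if len(x) == 2:
        r = 1.0 if (phi >= 0) else -1.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return CalibrationFit(
        phi=float(phi),
        beta=float(beta),
        r=r,
        n=len(x),
        phi_se=phi_se,
        beta_se=beta_se,
        resid_sd=resid_sd,
    )


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail (1 - alpha) quantile of the F(df1, df2) distribution,
    computed through the inverse regularized incomplete beta function."""
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ConfigurationError("degrees of freedom must be >= 1")
    # If X ~ F(d1, d2) then W = d1 X/(d1 X + d2) ~ Beta(d1/2, d2/2).
    w = special.betaincinv(df1 / 2.0, df2 / 2.0, 1.0 - alpha)
    return float(df2 * w / (df1 * (1.0 - w)))


def lack_of_fit(
    points: Iterable[CalibrationPoint],
    fit: CalibrationFit,
    alpha: float = 0.05,
) -> LackOfFitANOVA:
    """Lack-of-fit vs pure-error decomposition of the residuals about the
    fitted line, with a one-sided F test (lack-of-fit mean square in the
    numerator)."""
    pts = _as_points(points)
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    levels = np.unique(x)
    if len(levels) < 3:
        raise DataValidationError("lack-of-fit test needs >= 3 concentration levels")
    ss_pure = 0.0
    ss_lof = 0.0
    for lv in levels:
        yy = y[x == lv]
        if len(yy) < 2:
            raise DataValidationError(
                f"concentration level {lv} has no replication; pure error undefined"
            )
        ss_pure += float(((yy - yy.mean()) ** 2).sum())
        ss_lof += len(yy) * float((yy.mean() - fit.predict(lv)) ** 2)
    df_pure = len(x) - len(levels)
    df_lof = len(levels) - 2
    ms_pure = ss_pure / df_pure
    ms_lof = ss_lof / df_lof
    f_exp = ms_lof / ms_pure
    return LackOfFitANOVA(
        ss_pure=ss_pure,
        ss_lof=ss_lof,
        df_pure=df_pure,
        df_lof=df_lof,
        ms_pure=ms_pure,
        ms_lof=ms_lof,
        f_exp=f_exp,
        f_crit=f_critical(alpha, df_lof, df_pure),
        alpha=alpha,
    )


def assess_linearity(
    fit: CalibrationFit, anova: LackOfFitANOVA, r_min: float = 0.990
) -> tuple[bool, bool, bool]:
    """Joint linearity decision: (linear, r_condition, f_condition)."""
    r_ok = fit.r > r_min
    f_ok = anova.f_exp < anova.f_crit
    return (r_ok and f_ok, r_ok, f_ok)


def lod_loq(sigma_blank: float, phi: float) -> tuple[float, float]:
    """LOD = 3.3 sigma_blank/phi, LOQ = 10 sigma_blank/phi (uM)."""
    if phi <= 0:
        raise DataValidationError(f"slope must be positive, got {phi}")
    if sigma_blank < 0:
        raise DataValidationError("sigma_blank must be >= 0")
    return 3.3 * sigma_blank / phi, 10.0 * sigma_blank / phi


def back_calc_accuracy(
    points: Iterable[CalibrationPoint], fit: CalibrationFit
) -> list[dict]:
    """Per-point accuracy from back-calculated concentrations.

    For x > 0 the accuracy is 100*(x_hat - x)/x (%). At the blank level
    x = 0 a percent deviation is undefined, so the absolute deviation in uM
    is reported instead (``kind`` distinguishes the two).
    """
    out = []
    for p in _as_points(points):
        xhat = float(fit.invert(p.y))
        if p.x > 0:
            out.append(
                {"x": p.x, "y": p.y, "x_back": xhat, "kind": "percent",
                 "accuracy": 100.0 * (xhat - p.x) / p.x}
            )
        else:
            out.append(
                {"x": p.x, "y": p.y, "x_back": xhat, "kind": "abs_uM",
                 "accuracy": abs(xhat)}
            )
    return out


def precision_cv(
    series_by_level: Mapping[str, Sequence[KineticSeries] | np.ndarray]
) -> dict[str, float]:
    """Coefficient of variation per level, CV = 100*sigma/mu, pooled over
    all replicate x timepoint readings of that level. A zero mean leaves
    the CV undefined (NaN)."""
    out: dict[str, float] = {}
    for level, group in series_by_level.items():
        if len(group) and isinstance(group[0], KineticSeries):
            readings = np.concatenate([s.absorbances for s in group])
        else:
            readings = np.asarray(group, dtype=float)
        if readings.size < 2:
            raise DataValidationError(f"level {level}: CV needs >= 2 readings")
        mu = readings.mean()
        out[str(level)] = float("nan") if mu == 0 else float(
            100.0 * readings.std(ddof=1) / mu
        )
    return out


def molar_absorptivity(
    phi: float, path_length_cm: float, phi_se: float = 0.0
) -> tuple[float, float]:
    """Molar absorptivity from the calibration slope via Beer-Lambert.

    The slope is AU per uM; converting uM to mol/L multiplies by 1e6, and
    dividing by the optical path length h gives epsilon in L mol^-1 cm^-1.
    The standard error is propagated linearly from the slope's SE.
    """
    if path_length_cm <= 0:
        raise DataValidationError(f"path length must be > 0, got {path_length_cm}")
    scale = 1e6 / path_length_cm
    return phi * scale, phi_se * scale


# ---------------------------------------------------------------------------
# Model / Results surface


class TroloxCalibration:
    """Calibration model for replicate (concentration, absorbance) data.

    Construct from points, arrays or a dataframe with columns
    ``conc_uM``/``absorbance``, then :meth:`fit`.
    """

    def __init__(self, points: Iterable[CalibrationPoint]):
        self.points = _as_points(points)
        if len(self.points) < 3:
            raise DataValidationError("calibration needs >= 3 points")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TroloxCalibration":
        return cls(
            CalibrationPoint(
                float(r["conc_uM"]), float(r["absorbance"]),
                int(r.get("replicate", i + 1)),
            )
            for i, (_, r) in enumerate(df.iterrows())
        )

    @classmethod
    def from_arrays(cls, x, y) -> "TroloxCalibration":
        return cls(CalibrationPoint(float(a), float(b)) for a, b in zip(x, y))

    def fit(self) -> "CalibrationResults":
        return CalibrationResults(self, fit_line(self.points))


class CalibrationResults:
    """Fitted calibration line plus the validation battery."""

    def __init__(self, model: TroloxCalibration, fit: CalibrationFit):
        self.model = model
        self.fit_ = fit

    @property
    def slope(self) -> float:
        return self.fit_.phi

    @property
    def intercept(self) -> float:
        return self.fit_.beta

    @property
    def r(self) -> float:
        return self.fit_.r

    def lack_of_fit(self, alpha: float = 0.05) -> LackOfFitANOVA:
        return lack_of_fit(self.model.points, self.fit_, alpha)

    def sigma_blank(self, mode: str = "replicates") -> float:
        """Blank-noise estimate: sample SD of the blank (x = 0) replicates,
        or the regression residual SD (``mode='residual'``)."""
        if mode == "residual":
            return self.fit_.resid_sd
        if mode != "replicates":
            raise ConfigurationError(f"unknown sigma_blank mode {mode!r}")
        blanks = [p.y for p in self.model.points if p.x == 0]
        if len(blanks) < 2:
            raise DataValidationError(
                "sigma_blank from replicates needs >= 2 blank (0 uM) points"
            )
        return float(np.std(blanks, ddof=1))

    def lod_loq(self, sigma_blank_mode: str = "replicates") -> tuple[float, float]:
        return lod_loq(self.sigma_blank(sigma_blank_mode), self.fit_.phi)

    def accuracy(self) -> list[dict]:
        return back_calc_accuracy(self.model.points, self.fit_)

    def molar_absorptivity(self, path_length_cm: float) -> tuple[float, float]:
        return molar_absorptivity(self.fit_.phi, path_length_cm, self.fit_.phi_se)

    def validate(
        self,
        path_length_cm: float | None = None,
        alpha: float = 0.05,
        r_min: float = 0.990,
        sigma_blank_mode: str = "replicates",
        cv_series: Mapping[str, Sequence[KineticSeries]] | None = None,
    ) -> ValidationReport:
        anova = self.lack_of_fit(alpha)
        linear, r_ok, f_ok = assess_linearity(self.fit_, anova, r_min)
        sb = self.sigma_blank(sigma_blank_mode)
        lod, loq = lod_loq(sb, self.fit_.phi)
        eps = eps_se = None
        if path_length_cm is not None:
            eps, eps_se = self.molar_absorptivity(path_length_cm)
        return ValidationReport(
            fit=self.fit_,
            anova=anova,
            linear=linear,
            r_condition=r_ok,
            f_condition=f_ok,
            r_min=r_min,
            lod=lod,
            loq=loq,
            sigma_blank=sb,
            sigma_blank_mode=sigma_blank_mode,
            accuracy=self.accuracy(),
            cv=precision_cv(cv_series) if cv_series is not None else None,
            epsilon=eps,
            epsilon_se=eps_se,
            path_length_cm=path_length_cm,
        )

    def summary(self, alpha: float = 0.05, r_min: float = 0.990) -> str:
        f = self.fit_
        anova = self.lack_of_fit(alpha)
        linear, r_ok, f_ok = assess_linearity(f, anova, r_min)
        lines = [
            "Trolox calibration (OLS)",
            f"  y = {f.phi:.3f} x + {f.beta:.3f}   (n = {f.n}, r = {f.r:.3f})",
            f"  slope SE {f.phi_se:.2e}   intercept SE {f.beta_se:.2e}",
            "  lack-of-fit ANOVA:",
            f"    pure error  SS {anova.ss_pure:.3e}  df {anova.df_pure}",
            f"    lack-of-fit SS {anova.ss_lof:.3e}  df {anova.df_lof}",
            f"    F_exp {anova.f_exp:.4f}  vs  F_crit({anova.alpha:g}) {anova.f_crit:.4f}",
            f"  linear: {linear} (r > {r_min}: {r_ok}; F_exp < F_crit: {f_ok})",
        ]
        return "\n".join(lines)
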