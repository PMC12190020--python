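"""Scheffé mixture modelling of the Trolox solvent screen.

The solvent system is a ternary mixture of methanol (z1), ethanol (z2) and
water (z3) with z1 + z2 + z3 = 1. Replicate absorbance signals psi (AU) are
recorded for each candidate composition. Compositions fall into three
classes — pure (one nonzero fraction), binary (two) and ternary (three) —
and each class gets an average replicate standard deviation sigma_average.
The raw signal is transformed as

    Phi = psi * sigma_average(class)

and the six-term quadratic Scheffé canonical polynomial

    Phi = k1*z1 + k2*z2 + k3*z3 + k12*z1*z2 + k13*z1*z3 + k23*z2*z3

is fitted to the transformed replicates by ordinary least squares (no
intercept; the linear terms absorb it on the simplex). Prediction
back-transforms to the absorbance scale by dividing by the sigma_average of
the *candidate* composition's own class, which makes the predicted psi
surface discontinuous across class boundaries; the optimizer therefore
scans the simplex interior, the three edges and the three vertices
separately (lattice plus closed-form stationary points) so the
discontinuity cannot hide a maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError, SingularDesignError

CLASSES = ("pure", "binary", "ternary")

#: sum tolerance within which an input composition is renormalised to 1
SUM_TOLERANCE = 0.02
#: fractions below this (after normalisation) count as absent components
ZERO_TOL = 1e-6


@dataclass(frozen=True)
class SolventComposition:
    """A point on the methanol/ethanol/water simplex (volume fractions).

    Inputs whose fractions sum to 1 within :data:`SUM_TOLERANCE` are
    renormalised to sum exactly 1 (printed designs often use 0.33/0.33/0.33
    for the centroid); larger deviations are rejected.
    """

    z1: float  # methanol
    z2: float  # ethanol
    z3: float  # water

    def __post_init__(self) -> None:
        z = np.array([self.z1, self.z2, self.z3], dtype=float)
        if np.any(z < -ZERO_TOL) or np.any(z > 1 + ZERO_TOL):
            raise DataValidationError(f"fractions out of [0,1]: {tuple(z)}")
        total = z.sum()
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise DataValidationError(
                f"fractions {tuple(z)} sum to {total:.4f}, outside 1 +/- {SUM_TOLERANCE}"
            )
        z = np.clip(z, 0.0, None) / np.clip(z, 0.0, None).sum()
        object.__setattr__(self, "z1", float(z[0]))
        object.__setattr__(self, "z2", float(z[1]))
        object.__setattr__(self, "z3", float(z[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.z1, self.z2, self.z3])

    @property
    def mixture_class(self) -> str:
        return classify_composition(self)

    def key(self, ndigits: int = 9) -> tuple[float, float, float]:
        """Hashable identity for grouping replicates of one composition."""
        return (round(self.z1, ndigits), round(self.z2, ndigits), round(self.z3, ndigits))


def classify_composition(z: SolventComposition, zero_tol: float = ZERO_TOL) -> str:
    """Classify a composition as pure, binary or ternary by counting
    components whose fraction exceeds ``zero_tol``."""
    n = int(np.sum(z.as_array() > zero_tol))
    if n == 0:
        raise DataValidationError("composition has no component above zero_tol")
    return {1: "pure", 2: "binary", 3: "ternary"}[n]


@dataclass(frozen=True)
class MixtureObservation:
    """One replicate signal psi (AU) at one composition."""

    composition: SolventComposition
    psi: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.psi) or self.psi < 0:
            raise DataValidationError(f"psi must be finite and >= 0, got {self.psi}")


@dataclass(frozen=True)
class ScheffeCoefficients:
    """The six coefficients of the quadratic Scheffé polynomial.

    Linear coefficients equal the (transformed) response at the pure-solvent
    vertices; interaction coefficients capture blending synergy or
    antagonism along each binary edge.
    """

    k1: float
    k2: float
    k3: float
    k12: float
    k13: float
    k23: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.as_array()):
            raise DataValidationError("non-finite Scheffé coefficient")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k12, self.k13, self.k23])

    @classmethod
    def from_array(cls, k: Sequence[float]) -> "ScheffeCoefficients":
        return cls(*[float(v) for v in k])

    def rounded(self, ndigits: int = 3) -> "ScheffeCoefficients":
        return ScheffeCoefficients.from_array(np.round(self.as_array(), ndigits))


@dataclass
class MixtureDesignTable:
    """Replicate signals per composition plus per-class sigma_average."""

    observations: list[MixtureObservation]
    sigma_by_class: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MixtureDesignTable":
        obs = [
            MixtureObservation(
                composition=SolventComposition(
                    row["frac_methanol"], row["frac_ethanol"], row["frac_water"]
                ),
                psi=float(row["absorbance"]),
                replicate=int(row.get("replicate", i + 1)),
            )
            for i, (_, row) in enumerate(df.iterrows())
        ]
        return cls(observations=obs, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frac_methanol": [o.composition.z1 for o in self.observations],
                "frac_ethanol": [o.composition.z2 for o in self.observations],
                "frac_water": [o.composition.z3 for o in self.observations],
                "replicate": [o.replicate for o in self.observations],
                "absorbance": [o.psi for o in self.observations],
            }
        )

    def grouped(self) -> dict[tuple, list[MixtureObservation]]:
        groups: dict[tuple, list[MixtureObservation]] = {}
        for o in self.observations:
            groups.setdefault(o.composition.key(), []).append(o)
        return groups

    def mean_psi(self) -> dict[tuple, float]:
        return {k: float(np.mean([o.psi for o in v])) for k, v in self.grouped().items()}


def compute_sigma_by_class(table: MixtureDesignTable) -> dict[str, float]:
    """Per-class average replicate standard deviation (sigma_average).

    The sample SD (n-1 denominator) of psi is computed per distinct
    composition, then averaged (unweighted) over the compositions within
    each class. Every distinct composition needs >= 2 replicates.
    """
    per_class: dict[str, list[float]] = {}
    singletons = []
    for key, obs in table.grouped().items():
        if len(obs) < 2:
            singletons.append(key)
            continue
        sd = float(np.std([o.psi for o in obs], ddof=1))
        per_class.setdefault(obs[0].composition.mixture_class, []).append(sd)
    if singletons:
        raise DataValidationError(
            f"compositions with a single replicate (cannot estimate sigma): {singletons}"
        )
    sigma = {c: float(np.mean(sds)) for c, sds in per_class.items()}
    for c, v in sigma.items():
        if v == 0.0:
            table.metadata.setdefault("degenerate_sigma_classes", []).append(c)
    return sigma


def transform_signals(
    table: MixtureDesignTable, sigma_by_class: Mapping[str, float] | None = None
) -> list[tuple[SolventComposition, float]]:
    """Transform each replicate signal as Phi = psi * sigma_average(class)."""
    sigma = dict(sigma_by_class) if sigma_by_class is not None else table.sigma_by_class
    if sigma is None:
        sigma = compute_sigma_by_class(table)
    out = []
    for o in table.observations:
        cls_ = o.composition.mixture_class
        if cls_ not in sigma:
            raise ConfigurationError(f"no sigma_average configured for class '{cls_}'")
        out.append((o.composition, o.psi * sigma[cls_]))
    return out


def _design_row(z: SolventComposition) -> np.ndarray:
    return np.array([z.z1, z.z2, z.z3, z.z1 * z.z2, z.z1 * z.z3, z.z2 * z.z3])


def fit_scheffe(
    transformed: Iterable[tuple[SolventComposition, float]]
) -> tuple[ScheffeCoefficients, np.ndarray, np.ndarray]:
    """Least-squares fit of the quadratic Scheffé model to (z, Phi) pairs.

    Returns (coefficients, residuals, standard errors). No intercept is
    added; with z summing to 1 the linear terms span the constant. All
    replicate observations enter individually.
    """
    pairs = list(transformed)
    X = np.array([_design_row(z) for z, _ in pairs])
    y = np.array([phi for _, phi in pairs])
    if X.shape[0] < 6 or np.linalg.matrix_rank(X) < 6:
        support = {z.key(3) for z, _ in pairs}
        needed = {
            (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
            (0.5, 0.5, 0.0), (0.5, 0.0, 0.5), (0.0, 0.5, 0.5),
        }
        missing = sorted(needed - support)
        raise SingularDesignError(
            "design matrix rank < 6; a saturated quadratic needs 6 independent "
            f"support points (e.g. vertices + edge midpoints); missing: {missing}"
        )
    k, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ k
    dof = X.shape[0] - 6
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
    else:
        bse = np.zeros(6)
    return ScheffeCoefficients.from_array(k), resid, bse


def predict_phi(coeffs: ScheffeCoefficients, z: SolventComposition) -> float:
    """Evaluate the Scheffé polynomial at a composition."""
    return float(_design_row(z) @ coeffs.as_array())


def back_transform(
    phi: float, z: SolventComposition, sigma_by_class: Mapping[str, float]
) -> float:
    """Back-transform Phi to the absorbance scale: psi = Phi / sigma(class)."""
    cls_ = z.mixture_class
    if cls_ not in sigma_by_class:
        raise ConfigurationError(f"no sigma_average for class '{cls_}'")
    sigma = sigma_by_class[cls_]
    if sigma <= 0:
        raise ZeroDivisionError(
            f"sigma_average for class '{cls_}' is {sigma}; cannot back-transform"
        )
    return phi / sigma


@dataclass
class OptimumResult:
    """Argmax of the back-transformed predicted signal over the simplex."""

    composition: SolventComposition
    phi_pred: float
    psi_pred: float
    grid_step: float

    def as_ratio(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round(self.composition.z1, ndigits),
            round(self.composition.z2, ndigits),
            round(self.composition.z3, ndigits),
        )


def _interior_stationary(k: ScheffeCoefficients) -> SolventComposition | None:
    # Stationary point of Phi on the plane z1+z2+z3=1, parametrised by (z1, z2).
    A = np.array(
        [
            [-2 * k.k13, k.k12 - k.k13 - k.k23],
            [k.k12 - k.k13 - k.k23, -2 * k.k23],
        ]
    )
    b = np.array([k.k3 - k.k1 - k.k13, k.k3 - k.k2 - k.k23])
    try:
        z12 = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    z1, z2 = float(z12[0]), float(z12[1])
    z3 = 1.0 - z1 - z2
    if min(z1, z2, z3) <= ZERO_TOL or max(z1, z2, z3) >= 1 - ZERO_TOL:
        return None
    return SolventComposition(z1, z2, z3)


def _edge_stationary(ki: float, kj: float, kij: float) -> float | None:
    # Phi(t) = ki*t + kj*(1-t) + kij*t*(1-t) along an edge; interior argmax.
    if kij == 0:
        return None
    t = (ki - kj + kij) / (2 * kij)
    if t <= 0 or t >= 1:
        return None
    return t


def _candidate_compositions(
    coeffs: ScheffeCoefficients, grid_step: float
) -> list[SolventComposition]:
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ConfigurationError(f"grid_step {grid_step} does not divide 1 evenly")
    cands = []
    for i in range(n + 1):
        for j in range(n - i + 1):
            z1 = i * grid_step
            z2 = j * grid_step
            cands.append(SolventComposition(z1, z2, 1.0 - z1 - z2))
    # closed-form stationary points (edges + interior) so the class-wise
    # back-transform discontinuity cannot hide the true optimum
    k = coeffs
    for (ki, kj, kij), place in [
        ((k.k1, k.k2, k.k12), lambda t: SolventComposition(t, 1 - t, 0.0)),
        ((k.k1, k.k3, k.k13), lambda t: SolventComposition(t, 0.0, 1 - t)),
        ((k.k2, k.k3, k.k23), lambda t: SolventComposition(0.0, t, 1 - t)),
    ]:
        t = _edge_stationary(ki, kj, kij)
        if t is not None:
            cands.append(place(t))
    interior = _interior_stationary(k)
    if interior is not None:
        cands.append(interior)
    return cands


def optimize_composition(
    coeffs: ScheffeCoefficients,
    sigma_by_class: Mapping[str, float],
    grid_step: float = 0.005,
) -> OptimumResult:
    """Locate the composition maximizing the back-transformed signal psi.

    Evaluates psi = Phi/sigma(class) at every simplex lattice point of pitch
    ``grid_step``, at the three vertices, at each edge's closed-form
    stationary point and at the interior stationary point, and returns the
    global argmax. Exact ties are broken toward larger methanol fraction
    (z1), then larger water fraction (z3).
    """
    for c in CLASSES:
        if c not in sigma_by_class:
            raise ConfigurationError(f"sigma_average missing for class '{c}'")
    best: tuple[float, float, float] | None = None
    best_z: SolventComposition | None = None
    best_phi = 0.0
    for z in _candidate_compositions(coeffs, grid_step):
        phi = predict_phi(coeffs, z)
        psi = back_transform(phi, z, sigma_by_class)
        rank = (psi, z.z1, z.z3)
        if best is None or rank > best:
            best, best_z, best_phi = rank, z, phi
    assert best_z is not None
    return OptimumResult(
        composition=best_z, phi_pred=best_phi, psi_pred=best[0], grid_step=grid_step
    )


def signal_ratios(
    table: MixtureDesignTable,
    reference: SolventComposition,
    ndigits: int | None = 2,
) -> dict[tuple, float]:
    """Mean raw signal of each composition relative to a reference
    composition (e.g. pure water), optionally rounded for reporting."""
    means = table.mean_psi()
    ref_key = reference.key()
    if ref_key not in means:
        raise DataValidationError(
            f"reference composition {ref_key} not present in the design table"
        )
    ref = means[ref_key]
    out = {}
    for key, m in means.items():
        if key == ref_key:
            continue
        r = m / ref
        out[key] = round(r, ndigits) if ndigits is not None else r
    return out


# ---------------------------------------------------------------------------
# Model / Results surface


class ScheffeMixtureModel:
    """Quadratic Scheffé mixture model for a solvent-screen design table.

    Parameters
    ----------
    table : MixtureDesignTable
        Replicate signals per composition.
    sigma_by_class : mapping, optional
        Fixed per-class sigma_average values; by default they are estimated
        from the replicate scatter in ``table`` ("empirical" mode).
    """

    def __init__(
        self,
        table: MixtureDesignTable,
        sigma_by_class: Mapping[str, float] | None = None,
    ):
        self.table = table
        if sigma_by_class is not None:
            self.sigma_by_class = dict(sigma_by_class)
        elif table.sigma_by_class is not None:
            self.sigma_by_class = dict(table.sigma_by_class)
        else:
            self.sigma_by_class = compute_sigma_by_class(table)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sigma_by_class: Mapping[str, float] | None = None
    ) -> "ScheffeMixtureModel":
        return cls(MixtureDesignTable.from_dataframe(df), sigma_by_class)

    def fit(self) -> "ScheffeMixtureResults":
        transformed = transform_signals(self.table, self.sigma_by_class)
        coeffs, resid, bse = fit_scheffe(transformed)
        return ScheffeMixtureResults(self, coeffs, resid, bse)


class ScheffeMixtureResults:
    """Fitted Scheffé model: coefficients, uncertainties, prediction and
    solvent optimization."""

    def __init__(
        self,
        model: ScheffeMixtureModel,
        coefficients: ScheffeCoefficients,
        resid: np.ndarray,
        bse: np.ndarray,
    ):
        self.model = model
        self.coefficients = coefficients
        self.resid = resid
        self.bse = bse
        self.nobs = len(model.table.observations)

    @property
    def params(self) -> np.ndarray:
        return self.coefficients.as_array()

    def predict_phi(self, z: SolventComposition) -> float:
        return predict_phi(self.coefficients, z)

    def predict_psi(self, z: SolventComposition) -> float:
        return back_transform(self.predict_phi(z), z, self.model.sigma_by_class)

    def optimize(self, grid_step: float = 0.005) -> OptimumResult:
        return optimize_composition(self.coefficients, self.model.sigma_by_class, grid_step)

    def prediction_grid(self, grid_step: float = 0.01) -> pd.DataFrame:
        """Delimited grid of (z1, z2, z3, phi_pred, psi_pred) for external
        ternary plotting."""
        rows = []
        n = round(1.0 / grid_step)
        for i in range(n + 1):
            for j in range(n - i + 1):
                z = SolventComposition(i * grid_step, j * grid_step, (n - i - j) * grid_step)
                phi = self.predict_phi(z)
                rows.append((z.z1, z.z2, z.z3, phi, back_transform(phi, z, self.model.sigma_by_class)))
        return pd.DataFrame(rows, columns=["z1", "z2", "z3", "phi_pred", "psi_pred"])

    def summary(self) -> str:
        names = ["k1 (methanol)", "k2 (ethanol)", "k3 (water)",
                 "k12 (MeOH:EtOH)", "k13 (MeOH:water)", "k23 (EtOH:water)"]
        lines = [
            "Quadratic Scheffé mixture model (transformed signal Phi)",
            f"  observations: {self.nobs}    residual SS: {float(self.resid @ self.resid):.3e}",
            f"  sigma_average: " + ", ".join(
                f"{c}={v:.3f}" for c, v in sorted(self.model.sigma_by_class.items())
            ),
            f"  {'term':<18}{'coef':>10}{'std err':>10}",
        ]
        for name, k, se in zip(names, self.params, self.bse):
            lines.append(f"  {name:<18}{k:>10.3f}{se:>10.3f}")
        return "\n".join(lines)
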