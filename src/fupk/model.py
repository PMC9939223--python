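"""Structural and statistical model of infusional fluorouracil kinetics.

One-compartment disposition with linear elimination and zero-order (infusion)
input; covariate effects act multiplicatively on clearance, centered at the
study medians, so that the population clearance parameter keeps its meaning
of "clearance of the median patient".  Between-subject variability is a
log-normal random effect on clearance; residual variability combines a
proportional and an optional additive component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dataset import SubjectRecord

__all__ = [
    "CovariateEffect",
    "ResidualErrorModel",
    "PopulationModel",
    "typical_clearance",
    "individual_clearance",
    "predict_concentration",
    "residual_variance",
    "omega_to_cv",
    "cv_to_omega",
    "load_model",
    "save_model",
    "final_model",
]

EFFECT_FORMS = ("linear_proportional", "power", "exponential",
                "piecewise_linear")


def omega_to_cv(omega: float) -> float:
    """Map a log-normal SD to the coefficient of variation in percent.

    %CV = 100·sqrt(exp(ω²) − 1), the exact CV of exp(η), η ~ N(0, ω²).
    """
    return 100.0 * math.sqrt(math.expm1(omega**2))


def cv_to_omega(cv_percent: float) -> float:
    """Inverse of :func:`omega_to_cv`."""
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


@dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative covariate effect on a PK parameter.

    ``theta`` is the effect coefficient; for the piecewise-linear form it is
    a pair (slope below center, slope above center).  ``center`` is the
    reference value (study median): at ``cov == center`` every form returns
    a multiplier of exactly 1.
    """

    covariate: str
    form: str
    theta: float | tuple[float, float]
    center: float

    def __post_init__(self) -> None:
        if self.form not in EFFECT_FORMS:
            raise ValueError(f"unknown covariate-effect form {self.form!r}")
        if not np.isfinite(self.center):
            raise ValueError("center must be finite")
        if self.form == "piecewise_linear":
            if np.ndim(self.theta) != 1 or len(self.theta) != 2:
                raise ValueError("piecewise_linear needs two slopes")

    @property
    def n_params(self) -> int:
        return 2 if self.form == "piecewise_linear" else 1

    def multiplier(self, value: float | np.ndarray) -> float | np.ndarray:
        value = np.asarray(value, dtype=float)
        if self.form == "linear_proportional":
            return 1.0 + self.theta * (value - self.center)
        if self.form == "exponential":
            return np.exp(self.theta * (value - self.center))
        if self.form == "power":
            if np.any(value <= 0):
                raise ValueError(
                    f"power form requires positive {self.covariate}")
            return (value / self.center) ** self.theta
        lo, hi = self.theta
        d = value - self.center
        return 1.0 + np.where(d < 0, lo, hi) * d


@dataclass(frozen=True)
class ResidualErrorModel:
    """Proportional (+ optional additive) residual error.

    ``sigma_prop`` is the proportional SD as a fraction of the prediction;
    ``sigma_add`` is the additive SD in ng/ml.  ``iiv_on_residual`` is the
    SD of a subject-level log-normal multiplier on the total residual SD —
    a feature of the legacy initial model, off (0) by default.
    """

    sigma_prop: float
    sigma_add: float = 0.0
    iiv_on_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_prop < 0 or self.sigma_add < 0 or self.iiv_on_residual < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError(
                "at least one of sigma_prop, sigma_add must be positive")


@dataclass(frozen=True)
class PopulationModel:
    """Population PK model: structure, covariates, random effects, error.

    Volume of distribution and its variability default to the literature
    values (46.1 L, 51.1 %CV) and are fixed: with steady-state observations
    only, neither is identifiable.
    """

    cl_pop: float  # L/h
    v: float = 46.1  # L
    covariate_effects: tuple[CovariateEffect, ...] = ()
    omega_cl: float = 0.0  # SD of eta_CL on the log scale
    omega_v: float = cv_to_omega(51.1)
    residual: ResidualErrorModel = ResidualErrorModel(sigma_prop=0.214)
    fixed: frozenset[str] = frozenset({"v", "omega_v"})

    def __post_init__(self) -> None:
        if self.cl_pop <= 0:
            raise ValueError("cl_pop must be positive")
        if self.v <= 0:
            raise ValueError("v must be positive")
        if self.omega_cl < 0 or self.omega_v < 0:
            raise ValueError("omega SDs must be non-negative")
        seen = set()
        for e in self.covariate_effects:
            if e.covariate in seen:
                raise ValueError(
                    f"duplicate covariate effect on {e.covariate!r}")
            seen.add(e.covariate)

    @property
    def iiv_cl_cv(self) -> float:
        """IIV of clearance expressed as %CV."""
        return omega_to_cv(self.omega_cl)

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        return replace(self,
                       covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, covariate: str) -> "PopulationModel":
        return replace(self, covariate_effects=tuple(
            e for e in self.covariate_effects if e.covariate != covariate))


def typical_clearance(model: PopulationModel,
                      covariates: SubjectRecord | dict) -> float:
    """Typical (η=0) clearance for a subject: CL_pop × Π f(covariate)."""
    cl = model.cl_pop
    for eff in model.covariate_effects:
        if isinstance(covariates, dict):
            value = covariates.get(eff.covariate, np.nan)
        else:
            value = covariates.covariate(eff.covariate)
        if value is None or not np.isfinite(value):
            sid = getattr(covariates, "subject_id", "?")
            raise ValueError(
                f"subject {sid}: missing covariate {eff.covariate!r}")
        m = float(eff.multiplier(value))
        if m <= 0:
            raise ValueError(
                f"covariate effect on {eff.covariate!r} drives the "
                f"clearance multiplier non-positive ({m:.4g})")
        cl *= m
    return cl


def individual_clearance(typical_cl: float, eta: float) -> float:
    """Individual clearance CL_i = typical CL × exp(η), η ~ N(0, ω²)."""
    if typical_cl <= 0:
        raise ValueError("typical_cl must be positive")
    return typical_cl * math.exp(eta)


def predict_concentration(cl: float, v: float, rate: float,
                          time_since_start: float,
                          steady_state: bool = True) -> float:
    """Plasma concentration (ng/ml) during a zero-order infusion.

    At steady state C = R0/CL; before steady state the one-compartment
    accumulation C(t) = (R0/CL)·(1 − exp(−(CL/V)·t)).  Input units: mg/h,
    L/h, L; the mg/L result is converted to ng/ml (×1000).
    """
    if cl <= 0 or v <= 0:
        raise ValueError("cl and v must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    css = rate / cl * 1000.0
    if steady_state:
        return css
    return css * -math.expm1(-(cl / v) * time_since_start)


def residual_variance(pred: float | np.ndarray,
                      residual: ResidualErrorModel) -> float | np.ndarray:
    """Residual variance σ_add² + (σ_prop·pred)² at a prediction (ng/ml)."""
    pred = np.asarray(pred, dtype=float)
    out = residual.sigma_add**2 + (residual.sigma_prop * pred) ** 2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Model (de)serialization and the published final model
# ---------------------------------------------------------------------------

def _effect_to_dict(e: CovariateEffect) -> dict:
    theta = list(e.theta) if e.form == "piecewise_linear" else float(e.theta)
    return {"covariate": e.covariate, "form": e.form, "theta": theta,
            "center": float(e.center)}


def save_model(model: PopulationModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "cl_pop": float(model.cl_pop),
        "v": float(model.v),
        "omega_cl": float(model.omega_cl),
        "omega_v": float(model.omega_v),
        "covariate_effects": [_effect_to_dict(e)
                              for e in model.covariate_effects],
        "residual": {
            "sigma_prop": float(model.residual.sigma_prop),
            "sigma_add": float(model.residual.sigma_add),
            "iiv_on_residual": float(model.residual.iiv_on_residual),
        },
        "fixed": sorted(model.fixed),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def load_model(path: str | Path) -> PopulationModel:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    effects = tuple(
        CovariateEffect(covariate=d["covariate"], form=d["form"],
                        theta=tuple(d["theta"])
                        if d["form"] == "piecewise_linear" else d["theta"],
                        center=d["center"])
        for d in doc.get("covariate_effects", []))
    res = doc.get("residual", {})
    return PopulationModel(
        cl_pop=doc["cl_pop"], v=doc.get("v", 46.1),
        covariate_effects=effects,
        omega_cl=doc.get("omega_cl", 0.0),
        omega_v=doc.get("omega_v", cv_to_omega(51.1)),
        residual=ResidualErrorModel(
            sigma_prop=res.get("sigma_prop", 0.214),
            sigma_add=res.get("sigma_add", 0.0),
            iiv_on_residual=res.get("iiv_on_residual", 0.0)),
        fixed=frozenset(doc.get("fixed", {"v", "omega_v"})),
    )


def final_model() -> PopulationModel:
    """The published final model of the study cohort.

    CL 223 L/h for the median patient (BSA 1.97 m², back-muscle SMI
    3.78 cm²/m²), a linear-proportional BSA effect (0.794 per m²), an
    exponential back-muscle-SMI effect (0.0570 per cm²/m²), 20.9 %CV
    between-subject variability on clearance and 21.4% proportional
    residual error; V fixed at 46.1 L (51.1 %CV, uninformed at steady
    state).
    """
    return PopulationModel(
        cl_pop=223.0,
        covariate_effects=(
            CovariateEffect("bsa", "linear_proportional", 0.794, 1.97),
            CovariateEffect("smi_back", "exponential", 0.0570, 3.78),
        ),
        omega_cl=cv_to_omega(20.9),
        residual=ResidualErrorModel(sigma_prop=0.214),
    )
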