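"""Virtual study cohorts: covariates, dosing, concentrations, adverse events.

The generator reproduces the covariate structure of the study population
(111 patients under 24-h infusional fluorouracil with TDM): medians and
ranges of BSA, age, the four skeletal-muscle-index measures, the 75:36
male:female ratio, BSA-based dosing (median 2283 mg/m²) and 1-5 observed
cycles with median 2.  Only medians and ranges are published, so covariates
are drawn from truncated log-normals matched to them; the four SMI measures
share one latent "muscularity" factor so they are positively correlated.

Concentrations are simulated under a :class:`~fupk.model.PopulationModel`
"truth" (log-normal between-subject variability on clearance, proportional
± additive residual error), adverse events under per-AE logistic models in
an SMI measure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import (AE_TYPES, AdverseEventRecord, AnalysisDataset,
                      ConcentrationObservation, DoseEvent, SubjectRecord,
                      LLOQ_NG_ML)
from .model import PopulationModel, final_model, predict_concentration, \
    typical_clearance

__all__ = ["CovariateDistribution", "CohortSpec", "LogisticTruth",
           "TruthParameters", "generate_cohort", "simulate_concentrations",
           "simulate_adverse_events", "default_truth"]


@dataclass(frozen=True)
class CovariateDistribution:
    """Truncated log-normal summarized by the published median and range.

    The log-scale SD is chosen so that the published range corresponds to
    roughly ±2.5 SD (the extremes of ~111 samples); draws outside
    [minimum, maximum] are redrawn (truncation).
    """

    median: float
    minimum: float
    maximum: float
    z_range: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.minimum <= self.median <= self.maximum):
            raise ValueError("need 0 < minimum <= median <= maximum")

    @property
    def sigma_log(self) -> float:
        if self.maximum == self.minimum:
            return 0.0
        return (math.log(self.maximum) - math.log(self.minimum)) / (
            2.0 * self.z_range)

    def sample(self, rng: np.random.Generator, size: int,
               z: np.ndarray | None = None) -> np.ndarray:
        """Draw ``size`` values; ``z`` supplies the standard-normal scores
        (for latent-factor correlation), otherwise they are drawn fresh."""
        mu, sd = math.log(self.median), self.sigma_log
        if z is None:
            z = rng.standard_normal(size)
        out = np.exp(mu + sd * z)
        bad = (out < self.minimum) | (out > self.maximum)
        for _ in range(100):
            if not bad.any():
                break
            out[bad] = np.exp(mu + sd * rng.standard_normal(bad.sum()))
            bad = (out < self.minimum) | (out > self.maximum)
        return np.clip(out, self.minimum, self.maximum)


# Table-1 structure of the study population
_DEFAULT_COVARIATES: dict[str, CovariateDistribution] = {
    "bsa": CovariateDistribution(1.97, 1.47, 2.85),
    "age": CovariateDistribution(64.0, 35.0, 84.0),
    "smi_psoas": CovariateDistribution(1.48, 0.46, 3.78),
    "smi_back": CovariateDistribution(3.78, 0.94, 8.41),
    "smi_total_hu": CovariateDistribution(9.58, 4.12, 18.82),
    "smi_total_seg": CovariateDistribution(50.26, 25.47, 92.67),
    # height is not tabulated; ~1.73 m with a plausible adult spread
    "height": CovariateDistribution(1.73, 1.50, 2.00),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a virtual cohort.

    ``cycle_probs`` give P(1..5 observed cycles) — median and mode 2, as in
    the study.  ``obs_per_cycle`` is the mean number of steady-state TDM
    draws per cycle (fractional means are realized as 1-or-2 draws); the
    default 1.55 together with the cycle distribution reproduces the
    ~395-observation scale of the study (395/111 ≈ 3.6 samples per
    patient).
    """

    n_subjects: int = 111
    cycle_probs: tuple[float, ...] = (0.30, 0.35, 0.18, 0.10, 0.07)
    obs_per_cycle: float = 1.55
    infusion_duration: float = 24.0  # h
    dose_per_bsa: CovariateDistribution = CovariateDistribution(
        2283.0, 1441.0, 3641.0)  # mg/m²
    covariates: Mapping[str, CovariateDistribution] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES))
    p_female: float = 36.0 / 111.0
    smi_latent_correlation: float = 0.8
    ct_offset_sd_days: float = 60.0
    ct_offset_max_days: float = 205.0
    obs_time: float = 18.0  # h after infusion start, within the infusion

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.cycle_probs) - 1.0) > 1e-9 or \
                any(p < 0 for p in self.cycle_probs):
            raise ValueError("cycle_probs must be a probability vector")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must be in [0, 1]")
        if not 1.0 <= self.obs_per_cycle <= 2.0:
            raise ValueError("obs_per_cycle must lie in [1, 2]")
        if not 0.0 <= self.smi_latent_correlation <= 1.0:
            raise ValueError("smi_latent_correlation must be in [0, 1]")


@dataclass(frozen=True)
class LogisticTruth:
    """Per-AE logistic simulation truth: logit P(severe) = β0 + β1·SMI."""

    ae_type: str
    covariate: str
    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if self.ae_type not in AE_TYPES:
            raise ValueError(f"unknown ae_type {self.ae_type!r}")


@dataclass(frozen=True)
class TruthParameters:
    """Simulation truth: a population PK model plus logistic AE models."""

    pk: PopulationModel
    ae: tuple[LogisticTruth, ...] = ()


def default_truth() -> TruthParameters:
    """Published final PK model plus the two significant AE effects.

    The reported per-unit-SMI reductions in severe-AE probability are 85%
    (psoas SMI vs fatigue, OR 0.15) and 48% (back-muscle SMI vs
    polyneuropathy, OR 0.52); intercepts are chosen to give a plausible
    ~30% severe-AE prevalence at the median SMI.
    """
    fat_b1 = math.log(0.15)
    pol_b1 = math.log(0.52)
    logit03 = math.log(0.3 / 0.7)
    return TruthParameters(
        pk=final_model(),
        ae=(
            LogisticTruth("fatigue", "smi_psoas",
                          beta0=logit03 - fat_b1 * 1.48, beta1=fat_b1),
            LogisticTruth("polyneuropathy", "smi_back",
                          beta0=logit03 - pol_b1 * 3.78, beta1=pol_b1),
        ),
    )


def generate_cohort(spec: CohortSpec | None = None,
                    seed: int | np.random.Generator = 0) -> AnalysisDataset:
    """Generate covariates and dosing (no concentrations yet).

    Per-subject dose = dose_per_bsa × BSA per cycle; cycles are 24-h
    infusions starting at t=0 of each cycle (cycle-local time).  SMI
    measures share a latent muscularity factor (correlation
    ``spec.smi_latent_correlation``); all covariates are truncated to the
    published ranges.  Deterministic given the seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects

    rho = spec.smi_latent_correlation
    latent = rng.standard_normal(n)
    smi_names = ("smi_psoas", "smi_back", "smi_total_hu", "smi_total_seg")
    values: dict[str, np.ndarray] = {}
    for name, dist in spec.covariates.items():
        if name in smi_names:
            z = rho * latent + math.sqrt(1 - rho**2) * rng.standard_normal(n)
            values[name] = dist.sample(rng, n, z=z)
        else:
            values[name] = dist.sample(rng, n)
    sex = np.where(rng.random(n) < spec.p_female, "female", "male")
    ct_offset = np.clip(np.rint(rng.normal(0, spec.ct_offset_sd_days, n)),
                        -spec.ct_offset_max_days, spec.ct_offset_max_days)
    n_cycles = rng.choice(np.arange(1, len(spec.cycle_probs) + 1), size=n,
                          p=spec.cycle_probs)
    dose_per_bsa = spec.dose_per_bsa.sample(rng, n)
    p_two = spec.obs_per_cycle - 1.0

    subjects, doses, observations = [], [], []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        subjects.append(SubjectRecord(
            subject_id=sid, sex=str(sex[i]), age=float(values["age"][i]),
            height=float(values["height"][i]), bsa=float(values["bsa"][i]),
            smi_psoas=float(values["smi_psoas"][i]),
            smi_back=float(values["smi_back"][i]),
            smi_total_hu=float(values["smi_total_hu"][i]),
            smi_total_seg=float(values["smi_total_seg"][i]),
            ct_offset_days=float(ct_offset[i])))
        dose = float(dose_per_bsa[i] * values["bsa"][i])
        for c in range(1, int(n_cycles[i]) + 1):
            doses.append(DoseEvent(subject_id=sid, cycle=c, dose_amount=dose,
                                   infusion_duration=spec.infusion_duration,
                                   start_time=0.0))
            k = 2 if rng.random() < p_two else 1
            for j in range(k):
                observations.append(ConcentrationObservation(
                    subject_id=sid, cycle=c,
                    time=spec.obs_time - 4.0 * j, dv=np.nan,
                    steady_state_flag=True))
    return AnalysisDataset(subjects=subjects, doses=doses,
                           observations=observations)


def simulate_concentrations(dataset: AnalysisDataset,
                            truth: TruthParameters | PopulationModel,
                            seed: int | np.random.Generator = 0
                            ) -> AnalysisDataset:
    """Fill DV with concentrations simulated under the truth model.

    Per subject: η_CL ~ N(0, ω²) (one draw, shared across cycles), an
    optional residual-IIV multiplier, then DV = pred·(1 + ε_prop) + ε_add
    per observation.  Negative simulated concentrations are set missing
    with a warning and dropped.
    """
    model = truth.pk if isinstance(truth, TruthParameters) else truth
    rng = np.random.default_rng(seed)
    dose_by_key = {(d.subject_id, d.cycle): d for d in dataset.doses}
    dose_by_subject: dict[str, list[DoseEvent]] = {}
    for d in dataset.doses:
        dose_by_subject.setdefault(d.subject_id, []).append(d)

    eta: dict[str, float] = {}
    res_mult: dict[str, float] = {}
    cl_typ: dict[str, float] = {}
    for s in dataset.subjects:
        cl_typ[s.subject_id] = typical_clearance(model, s)
        eta[s.subject_id] = rng.normal(0.0, model.omega_cl) \
            if model.omega_cl > 0 else 0.0
        res_mult[s.subject_id] = math.exp(
            rng.normal(0.0, model.residual.iiv_on_residual)) \
            if model.residual.iiv_on_residual > 0 else 1.0

    new_obs = []
    n_dropped = 0
    for o in dataset.observations:
        d = dose_by_key.get((o.subject_id, o.cycle))
        if d is None:
            d = dose_by_subject[o.subject_id][0]
        cl_i = cl_typ[o.subject_id] * math.exp(eta[o.subject_id])
        pred = predict_concentration(cl_i, model.v, d.rate, o.time,
                                     o.steady_state_flag)
        m = res_mult[o.subject_id]
        dv = pred * (1.0 + rng.normal(0.0, model.residual.sigma_prop * m))
        if model.residual.sigma_add > 0:
            dv += rng.normal(0.0, model.residual.sigma_add * m)
        if dv < 0:
            n_dropped += 1
            continue
        new_obs.append(replace(o, dv=float(dv)))
    if n_dropped:
        warnings.warn(f"{n_dropped} simulated concentration(s) were negative "
                      "and set missing", stacklevel=2)
    return AnalysisDataset(subjects=list(dataset.subjects),
                           doses=list(dataset.doses), observations=new_obs,
                           adverse_events=list(dataset.adverse_events))


def simulate_adverse_events(dataset: AnalysisDataset,
                            truth: TruthParameters | Sequence[LogisticTruth],
                            seed: int | np.random.Generator = 0
                            ) -> AnalysisDataset:
    """Attach Bernoulli severe-AE indicators simulated from logistic truths.

    Severe events are emitted as CTCAE grade 2 records, non-severe as
    grade 0, so that :func:`fupk.dataset.dichotomize_grades` recovers the
    simulated binary outcome exactly.
    """
    ae_truths = truth.ae if isinstance(truth, TruthParameters) else tuple(truth)
    rng = np.random.default_rng(seed)
    records = list(dataset.adverse_events)
    for t in ae_truths:
        for s in dataset.subjects:
            x = s.covariate(t.covariate)
            if x is None or not np.isfinite(x):
                raise ValueError(f"subject {s.subject_id!r}: missing "
                                 f"covariate {t.covariate!r}")
            p = 1.0 / (1.0 + math.exp(-(t.beta0 + t.beta1 * x)))
            severe = rng.random() < p
            records.append(AdverseEventRecord(
                subject_id=s.subject_id, ae_type=t.ae_type,
                grade=2 if severe else 0))
    return AnalysisDataset(subjects=list(dataset.subjects),
                           doses=list(dataset.doses),
                           observations=list(dataset.observations),
                           adverse_events=records)
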