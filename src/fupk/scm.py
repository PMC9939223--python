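"""Stepwise covariate modeling and the non-parametric bootstrap.

Forward inclusion adds, one at a time, the candidate covariate effect with
the largest significant OFV drop (likelihood-ratio test at ``alpha_fwd``);
backward elimination then removes retained effects whose removal is *not*
significant at the stricter ``alpha_bwd``.  The bootstrap resamples whole
subjects with replacement (no stratification), refits the model on each
replicate and summarizes parameters by the median and the 2.5/97.5
percentiles; a covariate effect whose 95% CI includes zero is flagged
unreliable — the criterion on which the infusion-time effect was dropped
from the published model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import AnalysisDataset
from .estimation import FitResult, fit as fit_model, lrt
from .model import CovariateEffect, PopulationModel

__all__ = ["ScmStep", "ScmResult", "BootstrapResult", "scm",
           "test_single_covariate", "bootstrap", "DEFAULT_CANDIDATES"]

#: Covariates screened in the study (skipped silently when absent).
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "age", "sex", "infusion_time", "creatinine", "bilirubin", "alt", "ast",
    "ggt", "ldh", "ca19_9", "cea", "bsa",
    "smi_psoas", "smi_back", "smi_total_hu", "smi_total_seg",
)


@dataclass(frozen=True)
class ScmStep:
    phase: str  # "forward" | "backward"
    covariate: str
    form: str
    dofv: float
    df: int
    p_value: float
    decision: str  # "included" | "removed" | "rejected" | "kept" | "skipped"


@dataclass
class ScmResult:
    steps: list[ScmStep]
    final_model: PopulationModel
    final_fit: FitResult | None
    final_covariates: tuple[str, ...]

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def _effect_df(form: str) -> int:
    return 2 if form == "piecewise_linear" else 1


def _initial_theta(form: str):
    return (0.0, 0.0) if form == "piecewise_linear" else 0.0


def _candidate_effect(dataset: AnalysisDataset, covariate: str,
                      form: str) -> CovariateEffect:
    """Candidate effect centered at the observed cohort median."""
    vals = np.asarray([s.covariate(covariate) for s in dataset.subjects],
                      dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(f"covariate {covariate!r} has missing values")
    center = float(np.median(vals))
    if form == "power" and np.any(vals <= 0):
        raise ValueError(f"power form needs positive {covariate!r}")
    return CovariateEffect(covariate, form, _initial_theta(form), center)


def test_single_covariate(
        base_model: PopulationModel, dataset: AnalysisDataset,
        covariate: str, form: str = "linear_proportional",
        base_fit: FitResult | None = None,
        fitter: Callable[[PopulationModel, AnalysisDataset], FitResult]
        | None = None) -> tuple[float, float, FitResult]:
    """LRT of one candidate covariate effect on clearance.

    Returns (ΔOFV, p, fitted extended model).  The fitted result's model
    carries the IIV %CV so the before/after variance decomposition can be
    read off (``model.iiv_cl_cv``).
    """
    fitter = fitter or fit_model
    if base_fit is None:
        base_fit = fitter(base_model, dataset)
    eff = _candidate_effect(dataset, covariate, form)
    ext = fitter(base_fit.model.with_effect(eff), dataset)
    dofv = base_fit.ofv - ext.ofv
    p = lrt(base_fit.ofv, ext.ofv, _effect_df(form))
    return dofv, p, ext


def scm(base_model: PopulationModel, dataset: AnalysisDataset,
        candidates: Sequence[tuple[str, str]] | None = None,
        alpha_fwd: float = 0.05, alpha_bwd: float = 0.01,
        fitter: Callable[[PopulationModel, AnalysisDataset], FitResult]
        | None = None) -> ScmResult:
    """Forward-inclusion / backward-elimination covariate search.

    ``candidates`` is a list of (covariate, form) pairs; candidates naming
    covariates absent from the dataset are skipped with a warning.  Decisions
    depend only on ΔOFV and the two significance thresholds; ties break on
    (ΔOFV, then candidate order).  ``fitter`` may be injected (e.g. a mock
    OFV) for testing.
    """
    fitter = fitter or fit_model
    if candidates is None:
        candidates = [(c, "linear_proportional") for c in DEFAULT_CANDIDATES]
    usable: list[tuple[str, str]] = []
    steps: list[ScmStep] = []
    for cov, form in candidates:
        try:
            _candidate_effect(dataset, cov, form)
        except (ValueError, AttributeError, KeyError):
            warnings.warn(f"candidate {cov!r} not usable on this dataset; "
                          "skipped", stacklevel=2)
            steps.append(ScmStep("forward", cov, form, float("nan"),
                                 _effect_df(form), float("nan"), "skipped"))
            continue
        usable.append((cov, form))

    current_fit = fitter(base_model, dataset)
    included: list[tuple[str, str]] = []
    remaining = list(usable)

    # forward inclusion
    while remaining:
        trials = []
        for cov, form in remaining:
            try:
                dofv, p, ext = test_single_covariate(
                    current_fit.model, dataset, cov, form,
                    base_fit=current_fit, fitter=fitter)
            except Exception as exc:  # inner fit failure: skip candidate
                warnings.warn(f"fit failed for candidate {cov!r}: {exc}",
                              stacklevel=2)
                steps.append(ScmStep("forward", cov, form, float("nan"),
                                     _effect_df(form), float("nan"),
                                     "skipped"))
                remaining.remove((cov, form))
                continue
            trials.append((dofv, p, cov, form, ext))
        significant = [t for t in trials if t[1] < alpha_fwd]
        if not significant:
            for dofv, p, cov, form, _ in trials:
                steps.append(ScmStep("forward", cov, form, dofv,
                                     _effect_df(form), p, "rejected"))
            break
        best = max(significant, key=lambda t: t[0])
        dofv, p, cov, form, ext = best
        steps.append(ScmStep("forward", cov, form, dofv, _effect_df(form), p,
                             "included"))
        included.append((cov, form))
        remaining.remove((cov, form))
        current_fit = ext

    # backward elimination
    while included:
        trials = []
        for cov, form in included:
            reduced_model = current_fit.model.without_effect(cov)
            try:
                red = fitter(reduced_model, dataset)
            except Exception as exc:
                warnings.warn(f"backward fit failed for {cov!r}: {exc}",
                              stacklevel=2)
                continue
            dofv = red.ofv - current_fit.ofv  # cost of removing cov
            p = lrt(red.ofv, current_fit.ofv, _effect_df(form))
            trials.append((dofv, p, cov, form, red))
        removable = [t for t in trials if t[1] >= alpha_bwd]
        if not removable:
            for dofv, p, cov, form, _ in trials:
                steps.append(ScmStep("backward", cov, form, dofv,
                                     _effect_df(form), p, "kept"))
            break
        worst = min(removable, key=lambda t: t[0])
        dofv, p, cov, form, red = worst
        steps.append(ScmStep("backward", cov, form, dofv, _effect_df(form), p,
                             "removed"))
        included.remove((cov, form))
        current_fit = red

    return ScmResult(steps=steps, final_model=current_fit.model,
                     final_fit=current_fit,
                     final_covariates=tuple(c for c, _ in included))


# ---------------------------------------------------------------------------
# Non-parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    n_requested: int
    n_failed: int
    replicates: pd.DataFrame  # one row per successful replicate
    summary: pd.DataFrame  # index: parameter; median, ci_lower, ci_upper
    unreliable: dict[str, bool]  # per covariate-effect: 95% CI includes 0

    @property
    def n_successful(self) -> int:
        return len(self.replicates)


def _resample(dataset: AnalysisDataset,
              rng: np.random.Generator) -> AnalysisDataset:
    """Resample subjects with replacement; duplicates get fresh ids."""
    ids = [s.subject_id for s in dataset.subjects]
    picks = rng.integers(0, len(ids), size=len(ids))
    subj_map = {s.subject_id: s for s in dataset.subjects}
    doses_by, obs_by, ae_by = {}, {}, {}
    for d in dataset.doses:
        doses_by.setdefault(d.subject_id, []).append(d)
    for o in dataset.observations:
        obs_by.setdefault(o.subject_id, []).append(o)
    for a in dataset.adverse_events:
        ae_by.setdefault(a.subject_id, []).append(a)
    subjects, doses, observations, aes = [], [], [], []
    for k, idx in enumerate(picks):
        old = ids[int(idx)]
        new = f"B{k + 1:04d}"
        subjects.append(replace(subj_map[old], subject_id=new))
        doses += [replace(d, subject_id=new) for d in doses_by.get(old, [])]
        observations += [replace(o, subject_id=new)
                         for o in obs_by.get(old, [])]
        aes += [replace(a, subject_id=new) for a in ae_by.get(old, [])]
    return AnalysisDataset(subjects=subjects, doses=doses,
                           observations=observations, adverse_events=aes)


def bootstrap(model: PopulationModel, dataset: AnalysisDataset,
              n_replicates: int = 1000,
              seed: int | np.random.Generator = 0,
              fitter: Callable[[PopulationModel, AnalysisDataset], FitResult]
              | None = None) -> BootstrapResult:
    """Subject-level non-parametric bootstrap of a fitted model.

    ``model`` supplies the starting values (use the point-estimate fit).
    Non-converging replicates are counted and excluded from the
    percentiles.
    """
    if fitter is None:
        def fitter(m, d):
            return fit_model(m, d, compute_rse=False)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_replicates):
        rep = _resample(dataset, rng)
        try:
            res = fitter(model, rep)
        except Exception:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        rows.append(res.estimates)
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise RuntimeError("all bootstrap replicates failed")
    summary = pd.DataFrame({
        "median": reps.median(),
        "ci_lower": reps.quantile(0.025),
        "ci_upper": reps.quantile(0.975),
    })
    unreliable = {}
    for name in reps.columns:
        if name.startswith("theta_"):
            lo = summary.loc[name, "ci_lower"]
            hi = summary.loc[name, "ci_upper"]
            unreliable[name] = bool(np.sign(lo) * np.sign(hi) <= 0)
    return BootstrapResult(n_requested=n_replicates, n_failed=n_failed,
                           replicates=reps, summary=summary,
                           unreliable=unreliable)
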