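"""Population (nonlinear mixed-effects) estimation of the drug-disease model.

Hierarchical model: for subject *i* the drug-effect slope carries a
log-normal inter-individual random effect, ``SLP_i = SLP_tv * exp(eta_i)``,
and the transfusion conversion rate CRT carries a log-normal inter-occasion
effect, multiplied by ``exp(kappa_ik)`` within occasion *k* (consecutive
one-year windows by default).  Residual error is proportional,
``Y_ij = F_ij * (1 + eps_ij)`` with ``eps ~ N(0, sigma^2)``.

The marginal likelihood over the random effects is approximated by the
Laplace method: the per-subject mode of the joint density is located by a
damped Gauss-Newton iteration with exact forward-sensitivity gradients, and
the Gauss-Newton curvature stands in for the Hessian in the determinant
term (a FOCE-like approximation).  The population objective reported is
-2 log-likelihood, comparable across nested models via the likelihood-ratio
test.

Exposure during estimation is the adherence-corrected constant
``TCss_av = Css_av(weight) * (1 - CMPL)`` — the compliance covariate route,
not the forward-looking dosing-calendar engine used by the scenario module.

The first ferritin observation of each subject anchors the initial
condition of the trajectory and is excluded from the residual likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _fastode
from .disease import DiseaseParameters, DrugEffectParameters
from .exceptions import ComputationalError, DomainError
from .pk import DEFAULT_PK, InfusionRegimen, PKParameters, css_average
from .scenarios import HOURS_PER_YEAR

#: Integration step bound (h) for the estimation fast path; the model's time
#: constants are of the order of months, so 10-day RK4 steps are accurate to
#: well below the residual error.
ESTIMATION_H_MAX = 240.0

_PENALTY = 1e12


@dataclass(frozen=True)
class SubjectRecord:
    """One patient's covariates, exposure inputs and ferritin observations."""

    id: int
    weight: float
    dose_per_kg: float
    cmpl: float
    obs_times: np.ndarray  # hours, strictly increasing
    obs: np.ndarray        # ferritin, ug/L
    dosing_days_per_week: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "obs_times",
                           np.asarray(self.obs_times, dtype=float))
        object.__setattr__(self, "obs", np.asarray(self.obs, dtype=float))
        if self.obs_times.size == 0 or self.obs_times.size != self.obs.size:
            raise DomainError("obs_times and obs must be non-empty and parallel")
        if np.any(np.diff(self.obs_times) <= 0):
            raise DomainError("obs_times must be strictly increasing")
        if not 0.0 <= self.cmpl <= 1.0:
            raise DomainError("cmpl must lie in [0, 1]")

    @property
    def baseline(self) -> float:
        return float(self.obs[0])


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, random-effect variances and residual error.

    ``omega_iiv`` and ``omega_iov`` are variances of the log-normal effects
    (the corresponding CV is roughly ``sqrt(exp(omega) - 1)``); ``sigma`` is
    the proportional residual SD (reported as a magnitude — the sign of this
    parameter is indeterminate in common estimation tools).
    """

    slope: float = 4.81
    omega_iiv: float = 0.082
    omega_iov: float = 0.252
    sigma: float = 0.173
    disease: DiseaseParameters = field(default_factory=DiseaseParameters)
    pk: PKParameters = DEFAULT_PK
    occasion_length_years: float = 1.0

    def __post_init__(self) -> None:
        if self.omega_iiv < 0 or self.omega_iov < 0:
            raise DomainError("random-effect variances must be non-negative")
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")
        if self.slope < 0:
            raise DomainError("slope must be non-negative")

    @property
    def drug(self) -> DrugEffectParameters:
        return DrugEffectParameters(slope=self.slope)


@dataclass
class FitResult:
    """Outcome of a population fit."""

    pop: PopulationModel
    ofv: float                      # -2 log-likelihood (Laplace)
    estimates: dict
    se: dict
    converged: bool
    n_evals: int
    eb_estimates: list              # per-subject [eta, kappa_1..kappa_K]
    start_ofvs: list
    message: str = ""


def subject_exposure(subject: SubjectRecord, pop: PopulationModel) -> float:
    """Adherence-corrected constant exposure TCss_av for one subject."""
    regimen = InfusionRegimen(dose_per_kg=subject.dose_per_kg,
                              body_weight=subject.weight,
                              dosing_days_per_week=subject.dosing_days_per_week)
    css = css_average(pop.pk, regimen).css_av
    return css * (1.0 - subject.cmpl)


def _occasion_bounds(subject: SubjectRecord, window_hours: float):
    """Consecutive occasion-window boundaries spanning the observation span."""
    t0, t1 = subject.obs_times[0], subject.obs_times[-1]
    if t1 <= t0:
        return np.array([t0, t0 + 1.0]), 1
    bounds = np.arange(t0, t1, window_hours)
    bounds = np.append(bounds, t1)
    return bounds, bounds.size - 1


class _PackedCohort:
    """Concatenated per-subject arrays in the layout of the compiled kernels."""

    def __init__(self, subjects: Sequence[SubjectRecord], pop: PopulationModel):
        window = pop.occasion_length_years * HOURS_PER_YEAR
        y_parts, t_parts, f0s = [], [], []
        sb_parts, sl_parts, so_parts = [], [], []
        obs_off, seg_off, bounds_off, b_off = [0], [0], [0], [0]
        self.K = []
        for s in subjects:
            expo = subject_exposure(s, pop)
            bounds, K = _occasion_bounds(s, window)
            y_parts.append(s.obs[1:])
            t_parts.append(s.obs_times[1:])
            f0s.append(s.baseline)
            sb_parts.append(bounds)
            sl_parts.append(np.full(K, expo))
            so_parts.append(np.arange(K, dtype=np.int64))
            self.K.append(K)
            obs_off.append(obs_off[-1] + s.obs.size - 1)
            seg_off.append(seg_off[-1] + K)
            bounds_off.append(bounds_off[-1] + K + 1)
            b_off.append(b_off[-1] + 1 + K)
        self.y = np.concatenate(y_parts) if y_parts else np.empty(0)
        self.t = np.concatenate(t_parts) if t_parts else np.empty(0)
        self.f0 = np.asarray(f0s)
        self.seg_bounds = np.concatenate(sb_parts)
        self.seg_levels = np.concatenate(sl_parts)
        self.seg_occ = np.concatenate(so_parts)
        self.obs_off = np.asarray(obs_off, dtype=np.int64)
        self.seg_off = np.asarray(seg_off, dtype=np.int64)
        self.bounds_off = np.asarray(bounds_off, dtype=np.int64)
        self.b_off = np.asarray(b_off, dtype=np.int64)
        self.b = np.zeros(b_off[-1])
        self.n_obs = int(self.y.size)

    def neg2ll(self, slope, omega_iiv, omega_iov, sigma, disease,
               h_max=ESTIMATION_H_MAX, max_iter=40):
        om1 = max(omega_iiv, 1e-10)
        om2 = max(omega_iov, 1e-10)
        try:
            total, ok = _fastode.cohort_neg2ll(
                self.y, self.t, self.obs_off, self.f0,
                self.seg_bounds, self.seg_levels, self.seg_occ,
                self.seg_off, self.bounds_off, self.b, self.b_off,
                slope, om1, om2, sigma,
                disease.kin, disease.kout, disease.scl_ref, disease.shp_ref,
                disease.theta_scl, disease.theta_shp, disease.ferritin_med,
                h_max, max_iter)
        except np.linalg.LinAlgError:
            # a pathological parameter point drove an inner curvature matrix
            # singular; treat as an invalid (penalised) objective value
            self.b[:] = 0.0
            return np.inf, False
        return total, ok

    def eb_list(self):
        return [self.b[self.b_off[i]:self.b_off[i + 1]].copy()
                for i in range(self.f0.size)]


def marginal_loglik(subjects: Sequence[SubjectRecord],
                    pop: PopulationModel,
                    h_max: float = ESTIMATION_H_MAX) -> float:
    """Laplace-approximate -2 log marginal likelihood of the cohort."""
    if not pop.sigma > 0:
        raise DomainError("sigma must be strictly positive for estimation")
    for s in subjects:
        if s.obs.size < 1:
            raise DomainError(f"subject {s.id} has no observations")
    packed = _PackedCohort(subjects, pop)
    total, ok = packed.neg2ll(pop.slope, pop.omega_iiv, pop.omega_iov,
                              pop.sigma, pop.disease, h_max=h_max)
    if not ok or not np.isfinite(total):
        raise ComputationalError(
            "non-finite marginal likelihood (a subject's predicted ferritin "
            "collapsed); check parameter values")
    return float(total)


def individual_prediction(subject: SubjectRecord, pop: PopulationModel,
                          eta: float = 0.0,
                          kappa: Optional[np.ndarray] = None,
                          h_max: float = ESTIMATION_H_MAX) -> np.ndarray:
    """Predicted ferritin at the subject's observation times.

    ``eta = 0`` and all-zero ``kappa`` give the population prediction (PRED);
    empirical-Bayes values give the individual prediction (IPRED).  The first
    entry equals the observed baseline (the trajectory anchor).
    """
    window = pop.occasion_length_years * HOURS_PER_YEAR
    bounds, K = _occasion_bounds(subject, window)
    kap = np.zeros(K) if kappa is None else np.asarray(kappa, dtype=float)
    if kap.size != K:
        raise DomainError(f"expected {K} occasion effects, got {kap.size}")
    expo = subject_exposure(subject, pop)
    d = pop.disease
    bvec = np.concatenate([[eta], kap])
    F, _ = _fastode.integrate_sens(
        subject.baseline, bounds, np.full(K, expo),
        np.arange(K, dtype=np.int64), bvec, pop.slope,
        d.kin, d.kout, d.scl_ref, d.shp_ref, d.theta_scl, d.theta_shp,
        d.ferritin_med, subject.obs_times, h_max)
    return F


_DEFAULT_ESTIMATE = ("slope", "omega_iiv", "omega_iov", "sigma")

#: Neutral starting values used when no init model is supplied.
_DEFAULT_INIT = dict(slope=2.0, omega_iiv=0.1, omega_iov=0.1, sigma=0.3)

#: Multiplicative perturbation factors for the multi-start strategy.
_START_FACTORS = (1.0, 0.4, 2.5)


def fit_population(subjects: Sequence[SubjectRecord],
                   init: Optional[PopulationModel] = None,
                   estimate: Sequence[str] = _DEFAULT_ESTIMATE,
                   n_starts: int = 3,
                   maxfev: int = 400,
                   h_max: float = ESTIMATION_H_MAX,
                   compute_se: bool = True) -> FitResult:
    """Maximise the Laplace marginal likelihood over the unfixed parameters.

    Parameters are optimised on the log scale (guaranteeing positivity) with
    a Nelder-Mead simplex, restarted from ``n_starts`` multiplicatively
    perturbed initial points to guard against local minima.  Disease-model
    constants are fixed throughout (they are reference values, not estimated
    here); ``estimate`` selects which of slope / omega_iiv / omega_iov /
    sigma are free.
    """
    if init is None:
        init = PopulationModel(**_DEFAULT_INIT)
    if not init.sigma > 0:
        raise DomainError("initial sigma must be strictly positive")
    names = list(estimate)
    for n in names:
        if n not in _DEFAULT_ESTIMATE:
            raise DomainError(f"unknown estimable parameter {n!r}")
    packed = _PackedCohort(subjects, init)
    base = {n: getattr(init, n) for n in _DEFAULT_ESTIMATE}

    def objective(x):
        vals = dict(base)
        vals.update({n: float(np.exp(xi)) for n, xi in zip(names, x)})
        if vals["slope"] > 1e4 or vals["sigma"] > 1e2:
            return _PENALTY
        total, ok = packed.neg2ll(vals["slope"], vals["omega_iiv"],
                                  vals["omega_iov"], vals["sigma"],
                                  init.disease, h_max=h_max)
        if not ok or not np.isfinite(total):
            return _PENALTY
        return total

    best = None
    start_ofvs = []
    n_evals = 0
    for factor in _START_FACTORS[:max(1, n_starts)]:
        x0 = np.log([base[n] * factor for n in names])
        packed.b[:] = 0.0  # fresh inner warm start per outer start
        res = minimize(objective, x0, method="Nelder-Mead",
                       options=dict(maxfev=maxfev, xatol=1e-4, fatol=1e-4))
        n_evals += res.nfev
        start_ofvs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    vals = dict(base)
    vals.update({n: float(np.exp(xi)) for n, xi in zip(names, best.x)})
    pop = replace(init, **{n: vals[n] for n in _DEFAULT_ESTIMATE})
    # refresh EB modes at the optimum
    packed.b[:] = 0.0
    ofv, ok = packed.neg2ll(pop.slope, pop.omega_iiv, pop.omega_iov,
                            pop.sigma, pop.disease, h_max=h_max)

    se = {}
    if compute_se:
        se = _standard_errors(objective, best.x, names, vals)

    return FitResult(
        pop=pop, ofv=float(ofv),
        estimates={n: vals[n] for n in names},
        se=se,
        converged=bool(best.success and ok and best.fun < _PENALTY),
        n_evals=n_evals,
        eb_estimates=packed.eb_list(),
        start_ofvs=start_ofvs,
        message=best.message,
    )


def _standard_errors(objective: Callable, x_opt: np.ndarray,
                     names: Sequence[str], vals: dict,
                     step: float = 1e-3) -> dict:
    """Delta-method SEs from a finite-difference observed information.

    The objective is -2 log L, so the information matrix is half its Hessian
    (on the log-parameter scale); SEs transform back by ``theta * se_log``.
    Returns an empty dict when the Hessian is not positive definite.
    """
    k = len(x_opt)
    H = np.empty((k, k))
    f0 = objective(x_opt)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            fpp = objective(x_opt + ei + ej)
            fpm = objective(x_opt + ei - ej)
            fmp = objective(x_opt - ei + ej)
            fmm = objective(x_opt - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
    try:
        cov = np.linalg.inv(0.5 * H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return {}
        return {n: float(vals[n] * np.sqrt(d)) for n, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {}


def bootstrap(subjects: Sequence[SubjectRecord],
              init: Optional[PopulationModel] = None,
              n_samples: int = 100,
              seed: int = 0,
              sampler: Optional[Callable] = None,
              **fit_kwargs) -> dict:
    """Nonparametric bootstrap: resample subjects with replacement and refit.

    Returns a dict with the replicate estimate table, per-parameter mean and
    CV%, and the number of non-converged replicates (excluded from the
    summary).  ``sampler(rng, n) -> indices`` may override the resampling
    rule (used for testing).
    """
    if n_samples < 1:
        raise DomainError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(subjects)
    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("n_starts", 1)
    rows, failures = [], 0
    for _ in range(n_samples):
        idx = (sampler(rng, n) if sampler is not None
               else rng.integers(0, n, size=n))
        resampled = [replace(subjects[i], id=j)
                     for j, i in enumerate(idx)]
        fit = fit_population(resampled, init=init, **fit_kwargs)
        if not fit.converged:
            failures += 1
            continue
        rows.append(fit.estimates)
    table = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "mean": table.mean(),
        "cv_percent": 100.0 * table.std(ddof=1) / table.mean()
        if len(table) > 1 else np.nan,
    }) if not table.empty else pd.DataFrame()
    return {"replicates": table, "summary": summary,
            "n_failed": failures, "n_samples": n_samples}


def simulate_observations(subjects: Sequence[SubjectRecord],
                          pop: PopulationModel,
                          rng: np.random.Generator,
                          h_max: float = ESTIMATION_H_MAX) -> list:
    """One replicate dataset at the subjects' design points (times, baselines).

    Draws fresh random effects and proportional residuals; baselines are kept
    at their observed values.  Returns a list of observation arrays parallel
    to ``subjects``.
    """
    out = []
    for s in subjects:
        window = pop.occasion_length_years * HOURS_PER_YEAR
        _, K = _occasion_bounds(s, window)
        eta = rng.normal(0.0, np.sqrt(pop.omega_iiv))
        kappa = rng.normal(0.0, np.sqrt(pop.omega_iov), size=K)
        F = individual_prediction(s, pop, eta=eta, kappa=kappa, h_max=h_max)
        y = F * (1.0 + rng.normal(0.0, pop.sigma, size=F.size))
        y[0] = s.obs[0]
        out.append(np.maximum(y, 1.0))
    return out


def visual_predictive_check(subjects: Sequence[SubjectRecord],
                            pop: PopulationModel,
                            n_sim: int = 200,
                            seed: int = 0,
                            n_bins: int = 8,
                            percentiles: Sequence[float] = (5.0, 50.0, 95.0),
                            ci: float = 95.0) -> pd.DataFrame:
    """Visual predictive check summary.

    Simulates ``n_sim`` replicate datasets at the observed design points and
    compares, per time bin, the observed percentiles of ferritin with the
    percentile-method confidence band of the same percentiles across
    replicates.

    Returns a tidy frame with one row per (bin, percentile).
    """
    if n_sim < 100:
        raise DomainError("n_sim must be at least 100 for stable bands")
    rng = np.random.default_rng(seed)
    t_all = np.concatenate([s.obs_times for s in subjects])
    y_all = np.concatenate([s.obs for s in subjects])
    edges = np.quantile(t_all, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1.0
    bin_idx = np.clip(np.searchsorted(edges, t_all, side="right") - 1,
                      0, n_bins - 1)

    sim_pcts = np.empty((n_sim, n_bins, len(percentiles)))
    for r in range(n_sim):
        y_sim = np.concatenate(simulate_observations(subjects, pop, rng))
        for b in range(n_bins):
            mask = bin_idx == b
            sim_pcts[r, b] = (np.percentile(y_sim[mask], percentiles)
                              if mask.any() else np.nan)
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    rows = []
    for b in range(n_bins):
        mask = bin_idx == b
        if not mask.any():
            continue
        obs_p = np.percentile(y_all[mask], percentiles)
        for j, p in enumerate(percentiles):
            rows.append({
                "bin": b,
                "t_mid_years": float(np.median(t_all[mask]) / HOURS_PER_YEAR),
                "percentile": p,
                "observed": float(obs_p[j]),
                "sim_lo": float(np.percentile(sim_pcts[:, b, j], lo_q)),
                "sim_hi": float(np.percentile(sim_pcts[:, b, j], hi_q)),
                "n_obs": int(mask.sum()),
            })
    return pd.DataFrame(rows)
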