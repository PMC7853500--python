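"""Variational Laplace inversion of the conductance model.

Fits one subject's three-condition evoked responses by an
expectation-maximisation scheme: Gauss-Newton/Levenberg updates of the
posterior mean using central finite-difference sensitivities of the
concatenated predicted waveform, a closed-form Laplace posterior covariance,
and a MAP update of the observation-noise precision between parameter steps.
The objective is the variational free energy

    F = accuracy - complexity
      = E_q[ln p(y | q, tau)] - KL( q(params) || priors ) + ln p(tau)

which lower-bounds the log model evidence; differences in F between
candidate models are log-Bayes factors.  Steps are accepted only if F does
not decrease, so the recorded F trace is non-decreasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ModelSpec
from .observation import (
    ConditionDesign,
    ObservationParams,
    ParameterVector,
    free_quantities,
    simulate_erp,
)

__all__ = [
    "PriorSet",
    "Posterior",
    "InversionSettings",
    "default_priors",
    "free_energy",
    "invert",
]

_LN2PI = np.log(2.0 * np.pi)


@dataclass
class InversionSettings:
    """Numerical controls for the inversion.

    ``theta_subset`` restricts which subject-level log-scalings are
    estimated (None = all free quantities); condition effects are estimated
    for every design effect row over ``design.effect_targets``.
    """

    dt: float = 0.25            # integration step (ms)
    max_iter: int = 64
    tol: float = 0.01           # nats; convergence threshold on delta-F
    patience: int = 3
    fd_step: float = 1e-3       # central-difference step in log space
    estimate_gain: bool = True
    estimate_timing: bool = False
    theta_subset: tuple | None = None
    lm_init: float = 1e-4       # initial Levenberg damping
    max_halvings: int = 8


@dataclass
class PriorSet:
    """Gaussian priors over the estimable quantities plus the noise hyperprior.

    ``noise_gamma`` is the (shape, scale) of a Gamma prior on the observation
    precision; ``fixed_precision`` pins the precision instead (no hyperprior),
    in which case F is the exact evidence for linear problems.
    """

    names: tuple
    mean: np.ndarray
    var: np.ndarray
    noise_gamma: tuple | None = (2.0, None)   # scale None -> set from data variance
    fixed_precision: float | None = None

    def __post_init__(self):
        if np.any(self.var < 0):
            raise ValueError("prior variances must be >= 0")


# prior variances: connection and decay log-scalings 1/16, condition effects
# 1/8, observation parameters 1/8 (documented package defaults).
_PRIOR_VAR = {"t": 1.0 / 16.0, "b": 1.0 / 8.0, "o": 1.0 / 8.0}


def _free_param_names(spec: ModelSpec, dsgn: ConditionDesign,
                      settings: InversionSettings) -> list:
    """Estimable-quantity names: 't:<q>', 'b<row>:<q>', 'o:<obs field>'."""
    quantities = free_quantities(spec)
    theta = quantities if settings.theta_subset is None else tuple(settings.theta_subset)
    for name in theta:
        if name not in quantities:
            raise ValueError(f"theta_subset entry {name!r} is not a free quantity")
    targets = quantities if dsgn.effect_targets is None else tuple(dsgn.effect_targets)
    for name in targets:
        if name not in quantities:
            raise ValueError(f"effect target {name!r} is not a free quantity")
    names = [f"t:{q}" for q in theta]
    names += [f"b{k}:{q}" for k in range(dsgn.n_effects) for q in targets]
    if settings.estimate_gain:
        names.append("o:lgain")
    if settings.estimate_timing:
        names += ["o:lonset", "o:lwidth"]
    return names


def default_priors(spec: ModelSpec, dsgn: ConditionDesign,
                   settings: InversionSettings | None = None) -> PriorSet:
    settings = settings or InversionSettings()
    names = _free_param_names(spec, dsgn, settings)
    var = np.array([_PRIOR_VAR[n[0]] for n in names])
    return PriorSet(names=tuple(names), mean=np.zeros(len(names)), var=var)


@dataclass
class Posterior:
    """Laplace posterior over the estimable quantities for one subject."""

    names: tuple
    mean: np.ndarray
    cov: np.ndarray
    lam: float                  # log observation precision
    F: float                    # free energy (nats)
    F_trace: np.ndarray
    fitted: np.ndarray          # (n_conditions, n_time) predicted waveforms
    explained_variance: float
    accuracy: float
    complexity: float
    design: str = ""
    model_label: str = ""
    n_iter: int = 0

    def parameter_vector(self, spec: ModelSpec, dsgn: ConditionDesign) -> ParameterVector:
        """Posterior-mean ParameterVector (theta and beta on the full free set)."""
        pv = ParameterVector.zeros(spec, dsgn)
        for name, value in zip(self.names, self.mean):
            tag, _, quantity = name.partition(":")
            if tag == "t":
                pv.theta[pv.names.index(quantity)] = value
            elif tag.startswith("b"):
                pv.beta[int(tag[1:]), pv.names.index(quantity)] = value
        return pv

    def to_dict(self) -> dict:
        return {
            "schema": "fit.result.v1",
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "lam": self.lam,
            "F": self.F,
            "F_trace": self.F_trace.tolist(),
            "fitted": self.fitted.tolist(),
            "explained_variance": self.explained_variance,
            "accuracy": self.accuracy,
            "complexity": self.complexity,
            "design": self.design,
            "model_label": self.model_label,
            "n_iter": self.n_iter,
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def load(cls, path) -> "Posterior":
        d = json.loads(Path(path).read_text())
        if d.pop("schema", None) != "fit.result.v1":
            raise ValueError("not a fit.result.v1 file")
        return cls(
            names=tuple(d["names"]), mean=np.array(d["mean"]), cov=np.array(d["cov"]),
            lam=d["lam"], F=d["F"], F_trace=np.array(d["F_trace"]),
            fitted=np.array(d["fitted"]), explained_variance=d["explained_variance"],
            accuracy=d["accuracy"], complexity=d["complexity"], design=d["design"],
            model_label=d["model_label"], n_iter=d["n_iter"],
        )


@dataclass
class FreeEnergyParts:
    total: float
    accuracy: float
    complexity: float


def free_energy(residuals: np.ndarray, mu: np.ndarray, cov: np.ndarray,
                priors: PriorSet, tau: float, J: np.ndarray | None = None,
                active: np.ndarray | None = None) -> FreeEnergyParts:
    """Free energy of a posterior candidate: accuracy minus complexity.

    accuracy  = -tau/2 (r'r + tr(J cov J')) + N/2 ln(tau/2pi)
    complexity = KL( N(mu, cov) || N(prior mean, prior var) )

    The trace term is included when the sensitivity matrix ``J`` is given.
    ``active`` selects the estimated subset of the prior (zero-variance
    entries are fixed and excluded).
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    n = r.size
    m0 = priors.mean if active is None else priors.mean[active]
    v0 = priors.var if active is None else priors.var[active]
    p = len(m0)
    ev = np.linalg.eigvalsh(cov)
    if np.any(ev < -1e-10 * max(1.0, ev.max(initial=0.0))):
        raise ValueError("posterior covariance candidate is not PSD")
    ss = float(r @ r)
    if J is not None:
        ss += float(np.sum((J @ cov) * J))
    accuracy = -0.5 * tau * ss + 0.5 * n * (np.log(tau) - _LN2PI)
    if p:
        d = mu - m0
        sign, logdet_cov = np.linalg.slogdet(cov)
        kl = 0.5 * (np.sum(np.diag(cov) / v0) + np.sum(d * d / v0) - p
                    + np.sum(np.log(v0)) - logdet_cov)
    else:
        kl = 0.0
    return FreeEnergyParts(total=accuracy - kl, accuracy=accuracy, complexity=kl)


class _Predictor:
    """Maps an estimable-parameter vector to concatenated condition waveforms."""

    def __init__(self, spec, obs, dsgn, names, t_grid, dt):
        self.spec = spec
        self.obs = obs
        self.dsgn = dsgn
        self.names = names
        self.t_grid = t_grid
        self.dt = dt
        self.quantities = free_quantities(spec)
        self._rest_cache: dict = {}

    def param_vector(self, q: np.ndarray) -> tuple:
        pv = ParameterVector(
            names=self.quantities,
            theta=np.zeros(len(self.quantities)),
            beta=np.zeros((self.dsgn.n_effects, len(self.quantities))),
        )
        obs = ObservationParams(**{**self.obs.__dict__})
        for name, value in zip(self.names, q):
            tag, _, quantity = name.partition(":")
            if tag == "t":
                pv.theta[self.quantities.index(quantity)] = value
            elif tag.startswith("b"):
                pv.beta[int(tag[1:]), self.quantities.index(quantity)] = value
            elif quantity == "lgain":
                obs.gain = self.obs.gain * np.exp(value)
            elif quantity == "lonset":
                obs.input_onset = self.obs.input_onset * np.exp(value)
            elif quantity == "lwidth":
                obs.input_width = self.obs.input_width * np.exp(value)
        return pv, obs

    def __call__(self, q: np.ndarray) -> np.ndarray:
        pv, obs = self.param_vector(q)
        y = simulate_erp(self.spec, pv, obs, self.dsgn, self.t_grid, dt=self.dt,
                         rest_cache=self._rest_cache)
        return y.ravel()


def _jacobian(predict, q, h):
    cols = []
    for p in range(len(q)):
        qp = q.copy(); qp[p] += h
        qm = q.copy(); qm[p] -= h
        cols.append((predict(qp) - predict(qm)) / (2.0 * h))
    return np.column_stack(cols)


def invert(data: np.ndarray, spec: ModelSpec | None = None,
           obs: ObservationParams | None = None,
           dsgn: ConditionDesign | None = None, priors: PriorSet | None = None,
           settings: InversionSettings | None = None,
           t_grid: np.ndarray | None = None, forward=None) -> Posterior:
    """Fit one subject's per-condition waveforms; returns the Laplace posterior.

    ``data`` is (n_conditions, n_time) on ``t_grid`` (default 1-ms grid over
    the data length).  All condition waveforms share the grid.  Deterministic:
    identical inputs give identical output.

    ``forward`` replaces the conductance-model predictor with an arbitrary
    map from the full parameter vector to a flat prediction (``priors`` must
    then name the parameters); used for analytically tractable problems.
    """
    settings = settings or InversionSettings()
    data = np.asarray(data, dtype=float)
    if forward is None:
        if data.ndim != 2 or data.shape[0] != dsgn.n_conditions:
            raise ValueError("data must be (n_conditions, n_time)")
        if t_grid is None:
            t_grid = np.arange(data.shape[1], dtype=float)
        if priors is None:
            priors = default_priors(spec, dsgn, settings)
        names = _free_param_names(spec, dsgn, settings)
        if tuple(priors.names) != tuple(names):
            raise ValueError("priors do not cover the estimable quantities of this design")
    else:
        if priors is None:
            raise ValueError("custom forward models require explicit priors")
        names = list(priors.names)
        data = np.atleast_2d(data)

    active = priors.var > 0
    m0 = priors.mean[active]
    v0 = priors.var[active]
    p0 = 1.0 / v0
    n_par = int(active.sum())
    y = data.ravel()
    n = y.size

    predictor = forward if forward is not None else _Predictor(
        spec, obs, dsgn, names, t_grid, settings.dt)

    def predict(q_active):
        q = priors.mean.copy()
        q[active] = q_active
        return np.asarray(predictor(q), dtype=float).ravel()

    q = m0.copy()
    yhat = predict(q)
    if not np.all(np.isfinite(yhat)):
        raise RuntimeError("non-finite prediction at the prior mean; check priors")
    r = y - yhat

    # noise precision: fixed, or MAP under Gamma(shape, scale)
    if priors.fixed_precision is not None:
        a_g = b_g = None
        tau = float(priors.fixed_precision)
    else:
        a_g, b_g = priors.noise_gamma
        if b_g is None:
            b_g = 1.0 / (a_g * max(np.var(y), 1e-12))
        tau = (0.5 * n + a_g - 1.0) / (0.5 * float(r @ r) + 1.0 / b_g)

    def tau_update(ss):
        if priors.fixed_precision is not None:
            return tau
        return (0.5 * n + a_g - 1.0) / (0.5 * ss + 1.0 / b_g)

    def posterior_cov(J, tau_):
        H = tau_ * (J.T @ J) + np.diag(p0)
        # regularise near-singular curvature
        jitter = 0.0
        while True:
            try:
                cov = np.linalg.inv(H + jitter * np.eye(n_par))
                if np.all(np.isfinite(cov)):
                    return cov, H
            except np.linalg.LinAlgError:
                pass
            jitter = max(jitter * 10.0, 1e-8)

    def fe(r_, cov, q_, tau_, J):
        parts = free_energy(r_, q_, cov, priors, tau_, J=J, active=active)
        if priors.fixed_precision is None:
            # Gamma log-prior on the MAP precision (constant-free form)
            parts.total += (a_g - 1.0) * np.log(tau_) - tau_ / b_g
        return parts

    F_trace = []
    best = None
    lm = settings.lm_init
    stall = 0
    F_prev = -np.inf
    n_iter = 0

    for n_iter in range(1, settings.max_iter + 1):
        J = _jacobian(predict, q, settings.fd_step)
        # precision / covariance fixed-point refinement
        for _ in range(3):
            cov, H = posterior_cov(J, tau)
            ss = float(r @ r) + float(np.sum((J @ cov) * J))
            tau = tau_update(ss)
        cov, H = posterior_cov(J, tau)
        parts = fe(r, cov, q, tau, J)
        F_cur = parts.total
        if F_cur < F_prev - 1e-9:
            # relinearisation lowered F: keep the previous accepted state
            break
        if best is None or F_cur >= best["F"]:
            best = dict(F=F_cur, q=q.copy(), cov=cov, tau=tau, r=r.copy(),
                        parts=parts, yhat=yhat.copy())
        F_trace.append(F_cur)
        if F_prev > -np.inf and abs(F_cur - F_prev) < settings.tol:
            stall += 1
            if stall >= settings.patience:
                F_prev = F_cur
                break
        else:
            stall = 0
        F_prev = F_cur

        grad = tau * (J.T @ r) - p0 * (q - m0)
        accepted = False
        for _ in range(settings.max_halvings):
            Hd = H + lm * np.diag(np.diag(H))
            try:
                dq = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                lm = max(lm * 10.0, 1e-6)
                continue
            q_try = q + dq
            y_try = predict(q_try)
            if np.all(np.isfinite(y_try)):
                r_try = y - y_try
                F_try = fe(r_try, cov, q_try, tau, J).total
                if F_try >= F_cur - 1e-12:
                    q, r, yhat = q_try, r_try, y_try
                    accepted = True
                    lm = max(lm / 2.0, 1e-8)
                    break
            lm = min(lm * 4.0, 1e8)
        if not accepted:
            break

    # final state = best accepted
    qb = best["q"]
    fitted = predict(qb).reshape(data.shape)
    rb = y - fitted.ravel()
    ss_res = float(rb @ rb)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    mean_full = priors.mean.copy()
    mean_full[active] = qb
    cov_full = np.zeros((len(names), len(names)))
    cov_full[np.ix_(active, active)] = best["cov"]

    return Posterior(
        names=tuple(names), mean=mean_full, cov=cov_full,
        lam=float(np.log(best["tau"])), F=float(best["F"]),
        F_trace=np.array(F_trace), fitted=fitted,
        explained_variance=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        accuracy=float(best["parts"].accuracy),
        complexity=float(best["parts"].complexity),
        design=dsgn.name if dsgn is not None else "", n_iter=n_iter,
    )
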