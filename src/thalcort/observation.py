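"""Observation model and condition-contrast designs.

The measured signal is a single source-level channel: a fixed lead field
weighting the population depolarisations (dominated by superficial pyramidal
cells, with smaller deep-layer contributions), times an estimable output
gain.  The stimulus is a Gaussian-bump volley entering the thalamic relay
population (or layer IV directly, for the cortex-only variant).

Condition-specific effects follow a general-linear-model parameterisation:
each estimable quantity q is scaled by exp(theta_q + sum_k beta_kq X[k, c])
where X is the between-condition contrast matrix.  Three designs are
supported, columns ordered (pre, early-post, late-post):

* ``nonlinear``   X = [-1  1  0]  — change peaking early post-tetanus (STP-like)
* ``linear``      X = [-1  0  1]  — change growing to the late block (LTP-like)
* ``combination`` X = [-1 1 0; -1 0 1] — both components
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CHANNELS, ModelSpec, Trajectory, find_steady_state, integrate

__all__ = [
    "CONDITION_LABELS",
    "ObservationParams",
    "ConditionDesign",
    "ParameterVector",
    "design",
    "free_quantities",
    "condition_model",
    "exogenous_input",
    "simulate_erp",
    "cortex_only_variant",
]

CONDITION_LABELS = ("pre", "early_post", "late_post")

_DESIGNS = {
    "nonlinear": np.array([[-1.0, 1.0, 0.0]]),
    "linear": np.array([[-1.0, 0.0, 1.0]]),
    "combination": np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]]),
}

_DEFAULT_LEAD = {"sp": 0.8, "dp": 0.1, "tp": 0.1}


@dataclass
class ObservationParams:
    """Lead field, output gain and stimulus timing."""

    lead_weights: dict = field(default_factory=lambda: dict(_DEFAULT_LEAD))
    gain: float = 1.0
    input_onset: float = 64.0       # ms
    input_width: float = 16.0       # ms
    input_amplitude: float = 6.0    # drive units
    baseline_offset: float = 0.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("output gain must be > 0")
        if any(w < 0 for w in self.lead_weights.values()):
            raise ValueError("lead weights must be non-negative")

    def lead_vector(self, spec: ModelSpec) -> np.ndarray:
        w = np.zeros(spec.n_pop)
        for pop, weight in self.lead_weights.items():
            if pop in spec.populations:
                w[spec.index(pop)] = weight
        return w


def free_quantities(spec: ModelSpec) -> tuple:
    """Canonical names of the estimable quantities: connection gains then decays."""
    names = [f"g:{s}->{t}" for s, t in spec.free_mask]
    names += [f"d:{k}" for k in spec.free_decay]
    return tuple(names)


@dataclass
class ConditionDesign:
    """Between-condition contrast matrix and the quantities its rows modulate.

    ``effect_targets`` is the subset of free-quantity names carrying condition
    effects (default: all of them).
    """

    name: str
    X: np.ndarray
    effect_targets: tuple | None = None

    @property
    def n_effects(self) -> int:
        return self.X.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.X.shape[1]


def design(name: str, effect_targets: tuple | None = None) -> ConditionDesign:
    if name not in _DESIGNS:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(_DESIGNS)}")
    return ConditionDesign(name=name, X=_DESIGNS[name].copy(), effect_targets=effect_targets)


@dataclass
class ParameterVector:
    """Subject-level log-scalings (theta) and condition effects (beta).

    ``theta`` has one entry per free quantity; ``beta`` is (n_effect_rows,
    n_free).  theta = beta = 0 reproduces the default model exactly.
    """

    names: tuple
    theta: np.ndarray
    beta: np.ndarray

    @classmethod
    def zeros(cls, spec: ModelSpec, dsgn: ConditionDesign) -> "ParameterVector":
        names = free_quantities(spec)
        return cls(names=names, theta=np.zeros(len(names)),
                   beta=np.zeros((dsgn.n_effects, len(names))))

    def with_effects(self, dsgn: ConditionDesign, effects: dict, row: int = 0) -> "ParameterVector":
        """Return a copy with ``effects`` (name -> size) written into beta row."""
        beta = self.beta.copy()
        for name, size in effects.items():
            if name not in self.names:
                raise ValueError(f"effect on non-free quantity {name!r}")
            beta[row, self.names.index(name)] = size
        return ParameterVector(names=self.names, theta=self.theta.copy(), beta=beta)


def _condition_scales(params: ParameterVector, dsgn: ConditionDesign,
                      condition_index: int) -> np.ndarray:
    if not 1 <= condition_index <= dsgn.n_conditions:
        raise ValueError(f"condition_index must be in 1..{dsgn.n_conditions}")
    if params.beta.shape[0] != dsgn.n_effects:
        raise ValueError("beta row count does not match design")
    if dsgn.effect_targets is not None:
        allowed = set(dsgn.effect_targets)
        for q, name in enumerate(params.names):
            if name not in allowed and np.any(params.beta[:, q] != 0):
                raise ValueError(f"beta on {name!r} which is not an effect target")
    x = dsgn.X[:, condition_index - 1]
    return np.exp(params.theta + x @ params.beta)


def condition_model(spec: ModelSpec, params: ParameterVector, dsgn: ConditionDesign,
                    condition_index: int) -> ModelSpec:
    """Model for one condition: free gains and decay rates scaled multiplicatively.

    Each free quantity q is scaled by exp(theta_q + sum_k beta_kq X[k, c]);
    fixed parameters are untouched and the input spec is not modified.
    """
    scales = _condition_scales(params, dsgn, condition_index)
    out = spec.copy()
    for q, name in enumerate(params.names):
        if name.startswith("g:"):
            src, tgt = name[2:].split("->")
            out.gains[:, spec.index(tgt), spec.index(src)] *= scales[q]
        elif name.startswith("d:"):
            out.kappa[CHANNELS.index(name[2:])] *= scales[q]
        else:
            raise ValueError(f"unknown free quantity {name!r}")
    return out


def exogenous_input(obs: ObservationParams, t) -> np.ndarray:
    """Gaussian-bump drive: amplitude * exp(-(t - onset)^2 / (2 width^2))."""
    if obs.input_width <= 0:
        raise ValueError("input_width must be > 0")
    t = np.asarray(t, dtype=float)
    return obs.input_amplitude * np.exp(-0.5 * ((t - obs.input_onset) / obs.input_width) ** 2)


def _drive_array(spec: ModelSpec, obs: ObservationParams, dt: float, n_steps: int) -> np.ndarray:
    th = np.arange(2 * n_steps + 1) * (dt / 2.0)
    u = np.tile(spec.u_baseline, (2 * n_steps + 1, 1))
    u[:, spec.index(spec.input_population)] += exogenous_input(obs, th)
    return u


def simulate_erp(spec: ModelSpec, params: ParameterVector, obs: ObservationParams,
                 dsgn: ConditionDesign, t_grid: np.ndarray, dt: float = 0.25,
                 return_trajectories: bool = False, rest_cache: dict | None = None):
    """Predicted one-channel evoked response for every condition.

    For each condition the condition-specific model is built, its resting
    state found under the tonic background drive, the delayed dynamics
    integrated under the stimulus volley, and the lead field applied to the
    depolarisations around rest.  Deterministic. Returns (n_conditions,
    len(t_grid)).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be a 1-D grid")
    step = t_grid[1] - t_grid[0]
    if not np.allclose(np.diff(t_grid), step):
        raise ValueError("t_grid must be uniform")
    stride = int(round(step / dt))
    if not np.isclose(stride * dt, step):
        raise ValueError("t_grid step must be a multiple of dt")
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0")
    n_steps = int(round(t_grid[-1] / dt))

    out = np.empty((dsgn.n_conditions, len(t_grid)))
    trajs = []
    for c in range(1, dsgn.n_conditions + 1):
        cspec = condition_model(spec, params, dsgn, c)
        guess = rest_cache.get(c) if rest_cache is not None else None
        rest = find_steady_state(cspec, cspec.u_baseline, v_guess=guess)
        if rest_cache is not None:
            rest_cache[c] = rest.V.copy()
        u = _drive_array(cspec, obs, dt, n_steps)
        traj = integrate(cspec, u, t_grid[-1], dt=dt, init=rest)
        w = obs.lead_vector(cspec)
        y = obs.gain * ((traj.V - rest.V) @ w) + obs.baseline_offset
        out[c - 1] = y[::stride]
        if return_trajectories:
            trajs.append(traj)
    return (out, trajs) if return_trajectories else out


def cortex_only_variant(spec: ModelSpec) -> ModelSpec:
    """The same column without the thalamic compartment.

    Removes the relay and reticular populations and every edge touching
    them; the stimulus volley is rerouted into layer IV spiny stellates.
    """
    keep = [p for p in spec.populations if p not in ("rl", "rt")]
    idx = np.array([spec.index(p) for p in keep])
    out = spec.copy()
    out.populations = tuple(keep)
    out.gains = spec.gains[:, idx[:, None], idx[None, :]].copy()
    out.C = spec.C[idx].copy()
    out.Sigma = spec.Sigma[idx].copy()
    out.mh_target = spec.mh_target[:, idx].copy()
    out.u_baseline = spec.u_baseline[idx].copy()
    out.free_mask = tuple((s, t) for s, t in spec.free_mask if s in keep and t in keep)
    out.input_population = "ss"
    out.validate()
    return out
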