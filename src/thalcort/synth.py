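"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Stands in for an (undeposited) visual-LTP study: each subject contributes
three-condition evoked responses (pre-, early- and late-post-tetanus, 0-300
ms at 1 kHz) generated from the thalamocortical model itself.  Subject-level
connectivity varies as log-normal draws around the default column; condition
effects follow a chosen contrast design; white Gaussian observation noise is
scaled to a target signal-to-noise ratio per condition.

Randomness: one integer seed; subject i draws from ``default_rng([seed, i])``
so a subject's data is invariant to cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __version__
from .io import EvokedDataset
from .model import ModelSpec, build_default_model
from .observation import (
    ConditionDesign,
    ObservationParams,
    ParameterVector,
    design,
    free_quantities,
)
from .observation import simulate_erp

__all__ = ["GroundTruth", "SyntheticCohort", "generate_cohort", "canonical_ltp_scenario"]

# subject-level log-scaling dispersion: matches the default prior (var 1/16)
_THETA_SD = 0.25


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic cohort."""

    design: str
    theta: np.ndarray          # (n_subjects, n_quantities)
    beta: np.ndarray           # (n_subjects, n_effect_rows, n_quantities)
    quantity_names: tuple
    snr: float
    seed: int
    effect_spec: tuple         # one {name: size} mapping per effect row

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "quantity_names": list(self.quantity_names),
            "snr": None if np.isinf(self.snr) else self.snr,
            "seed": self.seed,
            "effect_spec": [dict(e) for e in self.effect_spec],
        }


@dataclass
class SyntheticCohort:
    dataset: EvokedDataset
    truth: GroundTruth
    spec: ModelSpec
    obs: ObservationParams
    dsgn: ConditionDesign


def _normalise_effects(effect_spec, dsgn: ConditionDesign, names) -> tuple:
    if effect_spec is None:
        effect_spec = {}
    if isinstance(effect_spec, dict):
        rows = [effect_spec] + [{} for _ in range(dsgn.n_effects - 1)]
    else:
        rows = list(effect_spec)
        if len(rows) != dsgn.n_effects:
            raise ValueError("effect_spec must give one mapping per design effect row")
    for row in rows:
        for name in row:
            if name not in names:
                raise ValueError(f"effect on non-free quantity {name!r}")
    return tuple(rows)


def generate_cohort(n_subjects: int, dsgn: ConditionDesign | str,
                    effect_spec=None, snr: float = 5.0, seed: int = 0,
                    spec: ModelSpec | None = None,
                    obs: ObservationParams | None = None,
                    t_stop: float = 300.0, fs: float = 1000.0,
                    dt: float = 0.25, theta_sd: float = _THETA_SD,
                    effect_sd: float = 0.0,
                    pink_noise: bool = False) -> SyntheticCohort:
    """Generate a seeded cohort of three-condition evoked responses.

    ``effect_spec`` maps free-quantity names to condition-effect sizes (log
    units); a list of mappings assigns one per design row.  ``effect_sd``
    adds per-subject variation around each nonzero effect.  ``snr`` is
    signal-variance / noise-variance per condition (np.inf disables noise).
    ``pink_noise`` substitutes 1/f-shaped noise of the same variance
    (robustness testing only).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not snr > 0:
        raise ValueError("snr must be > 0")
    if isinstance(dsgn, str):
        dsgn = design(dsgn)
    spec = spec if spec is not None else build_default_model()
    obs = obs if obs is not None else ObservationParams(gain=20.0)
    names = free_quantities(spec)
    nq = len(names)
    t_grid = np.arange(0.0, t_stop + 1e-9, 1000.0 / fs)

    rows = _normalise_effects(effect_spec, dsgn, names)
    beta_mean = np.zeros((dsgn.n_effects, nq))
    for k, row in enumerate(rows):
        for name, size in row.items():
            beta_mean[k, names.index(name)] = size

    thetas = np.empty((n_subjects, nq))
    betas = np.empty((n_subjects, dsgn.n_effects, nq))
    waves = []
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i])
        theta = rng.normal(0.0, theta_sd, nq)
        beta = beta_mean.copy()
        if effect_sd > 0:
            jitter = rng.normal(0.0, effect_sd, beta.shape)
            beta = np.where(beta_mean != 0, beta_mean + jitter, 0.0)
        thetas[i] = theta
        betas[i] = beta
        pv = ParameterVector(names=names, theta=theta, beta=beta)
        clean = simulate_erp(spec, pv, obs, dsgn, t_grid, dt=dt)
        if np.isinf(snr):
            noisy = clean
        else:
            noise_sd = np.sqrt(clean.var(axis=1, keepdims=True) / snr)
            if pink_noise:
                white = rng.normal(0.0, 1.0, clean.shape)
                f = np.fft.rfftfreq(clean.shape[1], d=1.0 / fs)
                shape = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
                pink = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, clean.shape[1], axis=1)
                pink /= pink.std(axis=1, keepdims=True)
                noisy = clean + noise_sd * pink
            else:
                noisy = clean + rng.normal(0.0, 1.0, clean.shape) * noise_sd
        waves.append(noisy)

    dataset = EvokedDataset(
        subject_ids=[f"sub-{i + 1:02d}" for i in range(n_subjects)],
        waveforms=np.stack(waves), fs=fs, t0=0.0,
        provenance={
            "generator": "thalcort.synth.generate_cohort",
            "version": __version__,
            "seed": seed,
            "design": dsgn.name,
            "snr": None if np.isinf(snr) else snr,
        },
    )
    truth = GroundTruth(design=dsgn.name, theta=thetas, beta=betas,
                        quantity_names=names, snr=snr, seed=seed, effect_spec=rows)
    return SyntheticCohort(dataset=dataset, truth=truth, spec=spec, obs=obs, dsgn=dsgn)


# Effect pattern mirroring the qualitative laminar finding profile of
# visually induced LTP: late (linear) potentiation of thalamocortical and
# granular-to-superficial coupling, early (nonlinear) changes in superficial
# wiring with a deep-projection decrease and slowed AMPA decay.
_CANONICAL_LINEAR = {"g:rl->ss": 0.2, "g:ss->sp": 0.2, "g:sp->sp": 0.2, "g:si->ss": 0.2}
_CANONICAL_NONLINEAR = {"g:ss->sp": 0.2, "g:ss->si": 0.2, "g:sp->dp": -0.2, "d:AMPA": 0.2}


def canonical_ltp_scenario(seed: int = 0, n_subjects: int = 20,
                           snr: float = 5.0, **kwargs) -> SyntheticCohort:
    """The reference LTP cohort: combination design, 20 subjects, SNR 5."""
    return generate_cohort(
        n_subjects=n_subjects, dsgn=design("combination"),
        effect_spec=[_CANONICAL_NONLINEAR, _CANONICAL_LINEAR],
        snr=snr, seed=seed, **kwargs,
    )
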