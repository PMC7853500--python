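# thalcort

Model-based analysis of how long-term potentiation (LTP) changes laminar
connectivity in visual cortex, as seen through the evoked potential.
High-frequency ("photic tetanus") visual stimulation potentiates components
of the human visual evoked potential; `thalcort` asks *where in the
thalamocortical microcircuit* that change lives, by fitting a biophysical
generative model to pre-, early-post- and late-post-tetanus evoked
responses and testing which synaptic parameters the experimental condition
modulates.

The package is aimed at computational and cognitive neuroscientists working
with source-level evoked responses.  It provides, end to end:

* **A conductance neural-mass model** of one cortical column plus thalamus
  (8 populations; AMPA/NMDA/GABA_A/GABA_B channels, M-/H-currents on
  layer-VI and relay cells, voltage-gated NMDA magnesium block, 3 ms / 8 ms
  thalamocortical conduction delays):

      C dV/dt = g_L(V_L − V) + Σ_n g_n (V_n − V) + g_NMDA f_MG(V)(V_NMDA − V) + u
      dg_n/dt = κ_n (ς_n − g_n),   ς_n = Σ_j γ_ij σ(V_j)

* **Condition-contrast inversion**: the three conditions are fitted
  jointly, with each free quantity scaled by exp(θ + Σ_k β_k X[k, c]) under
  a contrast design X — nonlinear [−1 1 0], linear [−1 0 1], or their
  combination — by variational Laplace, yielding parameter posteriors and a
  free-energy approximation F to the log model evidence.
* **Bayesian model selection** across designs and across architectures
  (thalamocortical vs cortex-only), fixed-effects (summed F) and
  random-effects (variational Dirichlet; protected exceedance
  probabilities and the Bayesian omnibus risk).
* **Group statistics**: repeated-measures MANOVA (Wilks' λ) on
  condition-specific parameter values, per-parameter RM-ANOVAs with
  Benjamini–Hochberg FDR correction.
* **A seeded synthetic-cohort generator** so the whole chain is testable
  against known ground truth without any data download.

See `docs/methods.md` for the model, priors, and numerical choices.

## Worked example

Generate a 6-subject cohort with known late (linear) potentiation of the
thalamocortical (rl→ss) and granular-to-superficial (ss→sp) connections,
fit it, and compare contrast designs:

```python
import numpy as np
from thalcort.synth import generate_cohort
from thalcort.inversion import invert, InversionSettings

cohort = generate_cohort(6, "linear", {"g:rl->ss": 0.2, "g:ss->sp": 0.2},
                         snr=5.0, seed=1)
settings = InversionSettings(dt=0.5, max_iter=24)
fits = [invert(cohort.dataset.subject(i), cohort.spec, cohort.obs,
               cohort.dsgn, settings=settings, t_grid=cohort.dataset.t_grid)
        for i in range(6)]
names = list(fits[0].names)
ev = np.mean([p.explained_variance for p in fits])
b_rl = np.mean([p.mean[names.index("b0:g:rl->ss")] for p in fits])
b_sp = np.mean([p.mean[names.index("b0:g:ss->sp")] for p in fits])
print(f"mean explained variance {ev:.3f}")
print(f"mean effect on rl->ss  {b_rl:+.3f}   (true +0.200)")
print(f"mean effect on ss->sp  {b_sp:+.3f}   (true +0.200)")
```

prints:

```
mean explained variance 0.837
mean effect on rl->ss  +0.204   (true +0.200)
mean effect on ss->sp  +0.180   (true +0.200)
```

The fits explain 84% of the waveform variance at SNR 5 (the noise ceiling
is ~83%), and both injected condition effects are recovered at the cohort
level with the right sign and magnitude (single-subject estimates show
some cross-talk between the two pathways; averaging resolves it).  Running
all subjects under competing designs and feeding the free energies to
`rfx_bms(EvidenceTable(...))` yields the fixed-effects winner, protected
exceedance probabilities and the omnibus risk; `thalcort.stats` then tests
which parameters carry the condition effect.

The same stages are available from the shell:

```bash
thalcort synth --out cohort.json --seed 1 --n-subjects 6 --design linear
thalcort fit --dataset cohort.json --design linear --out fits/
thalcort bms --fits fits/ --out bms.json
thalcort stats --fits fits/ --design linear --out stats.csv
thalcort run --config analysis.yaml     # the full pipeline from one config
```

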