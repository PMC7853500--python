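# Methods

## The generative model

`thalcort` models one column of visual cortex coupled to its thalamic
partner as eight interacting neural masses: layer IV spiny stellates (`ss`),
superficial pyramidal (`sp`) and inhibitory (`si`) populations in layer
II/III, deep pyramidal (`dp`) and inhibitory (`di`) populations in layer V,
corticothalamic projection pyramids (`tp`) in layer VI, and excitatory relay
(`rl`) with inhibitory reticular (`rt`) cells in thalamus.  Each population
is described by its mean membrane potential and a set of channel
conductances:

    C dV/dt = g_L (V_L − V) + Σ_n g_n (V_n − V)
              + g_NMDA f_MG(V) (V_NMDA − V) + u
    dg_n/dt = κ_n (ς_n − g_n),      ς_{n,i} = Σ_j γ_ij σ(V_j)

Excitatory afferents act through AMPA and NMDA channels, inhibitory
afferents through GABA_A and GABA_B; slow M- and H-currents exist only on
`tp` and `rl`.  The NMDA conductance is gated by the magnesium-block
sigmoid f_MG(V) = 1 / (1 + 0.2 exp(−α V)) with α = 0.06 mV⁻¹.  The firing
sigmoid σ is the Gaussian cumulative distribution of the presynaptic
depolarisation around a threshold V_R = −40 mV with dispersion Σ = 4 mV
(the transition spans roughly ±8 mV).  Thalamus→cortex volleys are delayed
by 3 ms and cortex→thalamus volleys by 8 ms; all other connections are
instantaneous.

Twelve connection gains (rl→ss, ss→ss, ss→sp, ss→si, si→sp, si→si, sp→sp,
sp→si, si→ss, sp→dp, dp→tp, tp→rl) and the AMPA and NMDA decay rates are
estimable; the remaining wiring (deep-layer and intrathalamic loops:
ss→dp, dp→dp, dp→di, di→dp, di→di, di→tp, tp→rt, rl→rt, rt→rl, rt→rt) is
fixed.  The fixed set is a package choice made so that every population
sits inside a closed excitation/inhibition loop consistent with the
laminar description of the canonical microcircuit.

### Numerical conventions and defaults

* Driving forces are written g_n (V_rev − V) so that excitatory channels
  depolarise; a leak conductance g_L = 1 toward V_L = −70 mV gives every
  isolated population a well-defined rest.
* Decay time constants (ms): AMPA 4, GABA_A 16, NMDA 100, GABA_B 200,
  M 160, H 100 (κ = 1/τ).  Reversal potentials (mV): AMPA 60, NMDA 10,
  GABA_A −90, GABA_B −100, M −70, H −30.  These are conventions of the
  conductance-model family, exposed as configuration, not fitted facts.
* Each anatomical edge carries one gain γ split over its receptor pair
  (NMDA at 0.25× the AMPA weight, GABA_B at 0.2× the GABA_A weight).
* A tonic background drive (u_baseline = 18 per population) sets the
  operating point near −50 mV, where the column responds gradedly to
  thalamic volleys.  The default gains were calibrated jointly with this
  drive so that the resting state is stable under ±20 % gain perturbations
  and log-normal subject variation (SD 0.25); without background drive the
  column is silent and parameter-insensitive, with too much it ignites
  regeneratively.
* Integration: fixed-step explicit 4th-order Runge–Kutta, dt = 0.25 ms by
  default (0.5 ms in the cohort experiments), with delayed terms read from
  a step-resolution voltage history (linear interpolation) and frozen
  across the four stages of each step.  Degenerate spans and steps are
  rejected, not clamped.  Resting states are found by reducing the
  equilibrium conditions to the voltages (g_n = ς_n at a fixed point) and
  root-finding with MINPACK's damped hybrid scheme; residuals above 1e−9
  are an error.

## Observation model and condition effects

The measured channel is a fixed lead field over population depolarisations
— superficial pyramidal cells dominate (weight 0.8) with small deep
contributions (dp 0.1, tp 0.1) — times an estimable log-gain.  The
stimulus is a Gaussian bump (onset 64 ms, width 16 ms, amplitude 6)
entering `rl` (or `ss` in the cortex-only variant).  Onset and width are
fixed by default and estimable by flag; the defaults place the response in
the window where visual evoked components are analysed.

Condition effects follow a general linear model in log space: each free
quantity q is scaled by exp(θ_q + Σ_k β_kq X[k, c]) where X is the
between-condition contrast — nonlinear [−1 1 0] (early, STP-like change),
linear [−1 0 1] (late, LTP-like change), or both rows (combination).
Multiplicative log-scaling keeps gains and rates positive for any real
effect size.

## Inversion

Per subject, the three condition waveforms are fitted jointly by
variational Laplace: Gauss–Newton/Levenberg updates of the posterior mean
with central finite-difference sensitivities (step 1e−3 in log space),
closed-form Laplace covariance, and a MAP update of a single Gaussian
observation precision (Gamma hyperprior, shape 2, scale set from the data
variance) between parameter steps.  The objective is the free energy
F = accuracy − complexity; a step is accepted only if F does not decrease
(with step halving otherwise), so the recorded trace is non-decreasing by
construction, and a relinearisation that lowers F terminates the fit at
the best previous state.  Priors: zero-mean Gaussians with variance 1/16
for connection and decay log-scalings, 1/8 for condition effects and
observation parameters.  Initialisation at the prior mean; tolerance 0.01
nats with patience 3, at most 64 iterations (16–24 in the experiment
batteries).  For linear-Gaussian problems with fixed precision this F
equals the exact log evidence, which the test suite verifies to 1e−6.

The noise model is white Gaussian with one precision per subject — the
analysis targets trial-averaged evoked responses, where averaging has
already whitened much of the noise.  No temporal autocorrelation or
hierarchical group prior is modelled.

## Model selection

Fixed-effects BMS sums F over subjects; posterior model probabilities are
a softmax of group F under a uniform model prior, and ΔF is reported
against the weakest model and against the runner-up.  Differences in
parameter count need no extra handling: they enter through the complexity
term of F.  Random-effects BMS fits a variational Dirichlet over model
frequencies (uniform Dirichlet prior, α₀ = 1); exceedance probabilities
come from 1e5 seeded Monte-Carlo draws of the posterior Dirichlet; the
Bayesian omnibus risk is BOR = 1/(1 + exp(F₁ − F₀)) with F₁ the
variational evidence bound of the heterogeneous-frequency model and F₀ the
exact evidence of the equal-frequency null, and
pxp = ep·(1 − BOR) + BOR/K.

Known limitation: on small, strongly heterogeneous evidence tables the
variational expected frequencies are overconfident by up to ~0.1 relative
to the exact posterior (verified against exhaustive enumeration), and the
variational BOR is conservative (F₁ is a lower bound).  The protected
exceedance probabilities — the quantity reported — track an independent
Gibbs/enumeration oracle within 0.05 on unselected 5×3 tables.

## Group statistics

Condition-specific parameter values (coupling strengths, and decay
time constants in ms, i.e. reciprocal rates) are assembled per subject
from the posterior means.  The omnibus condition test is a
repeated-measures MANOVA on within-subject difference scores
(early−pre and late−pre per parameter): Wilks' λ = det(E)/det(E+H) with
Rao's F transformation, exact for this one-sample structure; it requires
more subjects than difference variables, so parameter subsets are used on
small cohorts.  Follow-ups are per-parameter one-way repeated-measures
ANOVAs (Greenhouse–Geisser-corrected by default, uncorrected and
multivariate p-values also reported), with Benjamini–Hochberg FDR across
parameters.

## Synthetic cohorts

The generator emulates a visual-LTP study: per subject, free-quantity
log-scalings θ ~ N(0, 0.25²) (matching the subject-level prior), condition
effects per the chosen design, forward-simulated waveforms (0–300 ms at
1 kHz), and additive white Gaussian noise scaled to a target per-condition
SNR (variance ratio).  Default effect magnitude is 0.2 log units — large
enough to be visible at SNR 5, small enough that recovery is non-trivial.
Subject i draws from `default_rng([seed, i])`, so a subject's data does
not depend on cohort size.  The canonical LTP scenario (20 subjects,
SNR 5, combination design) places late/linear effects on rl→ss, ss→sp,
sp→sp and si→ss and early/nonlinear effects on ss→sp, ss→si, sp→dp
(negative) and the AMPA decay, mirroring the qualitative laminar pattern
reported for potentiation of the visual evoked response.

What the generator does not emulate: trial-level variability, 1/f
background spectra (a pink-noise flag exists for robustness checks only),
eye movements or sensor-level volume conduction.  Passing recovery tests
therefore demonstrates internal consistency of the estimation chain under
the stated noise model, not robustness to every feature of empirical EEG.

## Known limitations of the estimation chain

Two limitations surface clearly in the synthetic recovery experiments and
should be kept in mind when interpreting fits to real data:

* **Per-subject cross-talk between adjacent pathways.**  Condition effects
  on rl→ss and ss→sp — successive links of the same feedforward chain —
  produce similar waveform changes, so their joint posterior is strongly
  anti-correlated at realistic noise levels.  Single-subject effect
  estimates therefore trade off against each other (one may absorb most of
  the other's share), while cohort-mean estimates are nearly unbiased: in
  the recovery battery the correlation between the true and cohort-mean
  estimated effect patterns is ≈0.95 and the truly modulated pathways rank
  above every unmodulated one, but per-subject rank correlations over the
  modulated pair reach only ≈0.4.  Conclusions about *which subject* has
  the larger effect on *which specific link* are not reliable; conclusions
  about the group-level pattern are.

* **Significance inflation on shrunken estimates.**  The group follow-up
  ANOVAs treat posterior means as data.  Shrinkage makes those estimates
  very consistent across subjects, and the likelihood trade-off described
  above leaks a small sign-consistent fraction (~0.01–0.04 log units) of
  the true effects into correlated null pathways; together these give the
  repeated-measures tests enough power to flag pathways that carry no true
  effect (≈1–2 extra detections per 12 null pathways at q = 0.05 in the
  recovery battery).  FDR-significant sets should be read as candidate
  sets, with effect sizes inspected, not as proof of selective modulation.
  This is a general caveat of frequentist tests applied to regularised
  estimates rather than an implementation defect; it was verified to be
  independent of integration step and optimizer tolerance.

## Experiment battery sizes

The seeded validation experiments use reduced problem sizes chosen as a
deliberate trade-off between statistical resolution and runtime: parameter
recovery uses ten cohorts of ten subjects at SNR 5, with effects of 0.2
log units on rl→ss and ss→sp and per-subject effect variation of SD 0.1
(between-subject variability in potentiation magnitude is the norm
empirically, and without it per-subject recovery metrics are degenerate);
design identification
ten cohorts of two subjects per generating design (effects on rl→ss,
ss→sp and the AMPA decay, with a six-quantity subject-level free set);
architecture identification ten cohorts of two subjects.  Group
log-evidence differences between architectures are two orders of magnitude
larger than between contrast designs, which is why two subjects suffice
there.
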