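# pulseswitch

Transcription in single cells proceeds in pulses: a promoter switches
between periods of different transcriptional activity, and live-cell
luminescence reporters (e.g. luciferase driven by a hormone-gene promoter)
make those switches visible — blurred by protein lifetime, molecular noise
and measurement error.  `pulseswitch` implements a variable-rate analysis
of such recordings for quantitative biologists: instead of forcing a binary
on/off telegraph, transcription is a piecewise-constant rate β(t) that may
switch to *any* level at any time, and the number, timing and size of the
switches are inferred from the data.

The pipeline, end to end:

1. **Simulation** — exact Gillespie realisations of the reporter cascade
   ∅ →β(t) mRNA →δm ∅, mRNA →α mRNA + Protein →δp ∅, observed as
   Y(t) = κP(t) + N(0, σ²) every 15 min over ~48 h; cohort generators with
   known ground truth (single-pulse and pulsatile laws).
2. **Half-lives** — δp from cycloheximide decays (dP/dt = c_p − δpP), δm
   from actinomycin D decays through the two-exponential cascade solution;
   replicate fits pool into log-normal priors.
3. **Switch inference** — the linear noise approximation turns the cascade
   into a Gaussian state-space model; the joint posterior over
   (K, s₁…s_K, β₁…β_{K+1}, δm, δp, α, σ²) is sampled by reversible-jump
   MCMC (birth/death/shift/rate/parameter moves).
4. **Post-processing** — a Gaussian mixture over the pooled posterior
   switch times yields discrete switch candidates; candidate subsets
   sampled by the chain become weighted sub-models; the median-probability
   model is the consensus profile.
5. **Phase statistics** — up/down switch counts (the activation/
   deactivation asymmetry), ln rate vs ln duration regression, switch-pair
   amplitude correlations, binary vs graded classification,
   posterior-predictive mRNA counts, pooled 1-h pairwise correlations.
6. **Refractory model** — inactive durations (down-switch run → next
   up-switch) are fitted by a censored hypoexponential likelihood: an off
   (refractory) state of mean T1 and a primed state of mean T2, T1 < T2,
   with f_d(t) = λ₁λ₂/(λ₂−λ₁)(e^{−λ₁t} − e^{−λ₂t}); on-periods by a
   censored exponential (closed form).  Bootstrap over cells gives the
   refractory-period spread.

See `docs/methods.md` for the model details and design choices.

## Worked example

The `analysis/` drivers run the whole pipeline on a simulated pulsatile
cohort (12 cells, 48 h, 15-min sampling, 5,000 MCMC iterations per cell —
a few minutes on one core):

```sh
python analysis/01_simulate_cohort.py --seed 1 --n-cells 12
python analysis/02_fit_halflives.py
python analysis/03_infer_switches.py --seed 1
python analysis/04_postprocess_profiles.py
python analysis/05_phase_statistics.py
python analysis/06_refractory_model.py --seed 1
```

prints (abridged):

```
simulated 12 cells over 48.0 h (193 samples each); switches per cell: min 4, median 8, max 11
protein: 3 fits, rate median 0.346/h (half-life 2.01 h, log-sd 0.10)
mRNA:    3 fits, rate median 0.690/h (half-life 1.00 h, log-sd 0.19)
inference finished for 12/12 cells (5000 iterations each, burn-in 1666)
consensus extracted for 12 cells; switch-count distribution: {3: 2, 4: 2, 5: 3, 6: 2, 7: 2, 8: 1}
12 cells (BSA): up 2.08 +/- 0.19, down 3.17 +/- 0.34 (down:up 1.52)
ln(rate)-ln(duration): r = -0.581 (p = 8e-06, n = 51)
class fractions: {'graded-decrease': 0.92, 'binary': 0.08}
three-state fit over 12 cells (13 complete + 9 censored inactive durations):
  on period        T0 = 5.45 h
  refractory (off) T1 = 10.24 h [bootstrap median 10.39, IQR 9.47-11.35]
  primed           T2 = 10.24 h
```

Reading the numbers: the decay fits recover the simulated half-lives
(protein 2 h, mRNA 1 h — the generator's truth) and become the degradation
priors; the consensus profiles show more down- than up-switches per cell
with a graded-decrease majority — the generator deactivates in graded
steps, and the inference preserves that asymmetry; the ln-ln regression's
negative r says high-rate phases are short-lived.  The three-state fit
lands on the T1 = T2 (Erlang) boundary here and warns about it: on
consensus profiles the inactive duration includes the graded descent, a
near-constant offset that a two-exponential sum can only absorb by making
its components equal — an instructive limitation of applying the discrete
on/off/primed model to graded deactivation (the duration-level recovery
tests, which sample the three-state law directly, recover T1 < T2
cleanly).  All outputs land as tidy CSV/JSON under `results/`.

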