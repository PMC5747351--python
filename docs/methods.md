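# Methods

## The model

A reporter gene is transcribed at a piecewise-constant rate β(t): a cell's
transcriptional history is a set of K switch times s₁ < … < s_K inside the
observation window and K+1 rates β₁ … β_{K+1}, with βᵢ applying on
[s_{i−1}, s_i).  No restriction is placed on the rate levels — a binary
(telegraph) promoter is the two-level special case.  The molecular system is
the standard two-stage cascade

    ∅ →β(t) mRNA →δm ∅,   mRNA →α mRNA + Protein,   Protein →δp ∅

observed through luminescence Y(t) = κ·P(t) + ε, ε ~ N(0, σ²), sampled every
15 min over ~48 h.

## Likelihood: linear noise approximation as a Gaussian state space

The chemical master equation is approximated by the LNA: the macroscopic
mean m(t) = (m_M, m_P) follows the rate ODEs, and fluctuations ξ = (M, P) − m
follow a linear Gaussian SDE with drift A = [[−δm, 0], [α, −δp]] and
diffusion D(t) = diag(β + δm·m_M, α·m_M + δp·m_P) evaluated along the mean.
Together with the linear observation this is a Gaussian state-space model
and the likelihood is a scalar Kalman recursion.

Because β(t) is piecewise constant, the joint system
(1, m_M, m_P, q_MM, q_MP, q_PP) — mean plus accumulated process covariance —
is linear with *constant* coefficients inside each segment, so propagation
between observations uses exact matrix exponentials of a 6×6 lower-
triangular generator; intervals crossed by a switch are split at the switch
and the piece propagators composed.  There is no ODE discretisation error;
the recursion agrees with a brute-force joint-Gaussian evaluation (all
cross-covariances by direct high-accuracy ODE integration) to < 1e-8 on
random instances, and with a bootstrap particle filter on exact-SSA data to
within 2 % per observation in the large-count regime.

The 6×6 exponential is computed by the Parlett recurrence (the generator is
lower triangular with known diagonal); when two eigenvalues come within 1 %
of each other (e.g. δm ≈ 2δp makes the recurrence ill-conditioned) the code
falls back to `scipy.linalg.expm`.  Latent moments are initialised at the
stationary law of the first segment's rate, since cells are recorded
mid-expression.

**Identifiability.** Luminescence units are arbitrary, so κ is fixed to 1
and the overall scale is absorbed by α and the β's.  With κ fixed, α is
identifiable through the noise structure (translational amplification), but
weakly: posterior α can drift a factor ~1.5 from truth on single traces,
rescaling the inferred rates without affecting switch times or counts.
Informative log-normal priors are placed on δm and δp only, built from
inhibitor-decay experiments (below).

## Posterior sampling: reversible-jump MCMC

The joint posterior over (K, s, β, δm, δp, α, σ²) is sampled with a
Green-type trans-dimensional sampler.  Moves (default mixture):

* **birth** (0.20): a new switch time uniform on the window; the enclosing
  log-rate x is split into (x+u, x−u) with u ~ N(0, 0.6²); Jacobian 2.
* **death** (0.20): a uniformly chosen switch is removed and its two
  log-rates averaged (exact reverse of birth).
* **position shift** (0.20): Gaussian random walk (sd 0.75 h) on one switch
  time — or, for 30 % of shifts, a uniform reposition within the
  neighbouring switch interval (both symmetric; the independence move
  frees switches stuck in local placements).
* **rate update** (0.20): log-scale random walk (sd 0.35) on one segment.
* **parameter update** (remaining 0.20): log-scale random walk on one of
  δm, δp, α, σ².

The birth/death weights are deliberately high: transient surplus switches
born during early exploration must also die within a short chain, and the
consensus inclusion frequencies are only meaningful once the
trans-dimensional moves mix well.

Priors: truncated Poisson(4) on K (max 20); uniform order statistics for
switch times; log-normal for rates and kinetic parameters; inverse-gamma
for σ².  The rate-prior median and the σ² scale are set from the data
(stationary relation for the mean; median absolute first difference for the
noise floor) — an empirical-Bayes default.  Correctness checks: with the
likelihood disabled the chain reproduces the K prior (χ²); on a frozen
two-observation problem with kinetics pinned, the switch-time marginal
matches a quadrature-integrated direct posterior in total variation < 0.05.

Chains start from a greedy binary-segmentation fit of the raw trace (BIC
penalty, ≤ 4 changepoints) converted to rates; this initialisation only
shortens burn-in — the first third of iterations is discarded regardless.
The cohort runner performs a pilot pass, re-estimates the population α and
σ² hyperparameters from per-cell posterior medians (the hierarchical
assumption: kinetic parameters vary little within a dataset), and reruns
final chains; per-cell seeds are spawned deterministically from one master
seed.

## Post-processing into discrete switch profiles

The pooled posterior switch times of a cell form a multimodal marginal.  A
Gaussian mixture is fitted (EM; component count by BIC), with two
refinements found necessary on simulated data:

* components closer than **1.0 h** are merged — BIC happily splits one
  heavy posterior mode into two overlapping Gaussians, and switches nearer
  than the temporal resolution describe one event;
* adjacent candidates that almost never co-occur in the same iteration
  (co-occurrence < 0.2 of the rarer one) are collapsed: genuinely distinct
  switches are sampled *together*, while mutually exclusive components are
  alternative placements of one uncertain switch.

Each iteration's switch set is assigned to candidates by maximum mixture
responsibility (assignments with responsibility < 0.5 fall back to the
nearest candidate and are counted); every distinct candidate subset is a
sub-model weighted by its sampling frequency, so weights sum to one.

**Consensus.**  The default consensus is the *median-probability model*: a
candidate is included iff its inclusion frequency over the weighted
sub-models exceeds 0.5.  The modal ("MAP") sub-model is available as an
option but proved unstable: its weight fragments over many near-null-switch
subsets, and on model-matched data it selected junk switches whose subset
narrowly out-weighed the clean one.  Candidates within 1 h of a window edge
are never included in the consensus — with less than the resolution's worth
of data on one side a switch is unidentifiable and posterior mass pools at
the edges where the likelihood is indifferent.  Consensus segment rates are
sub-model-weighted posterior means of β at segment midpoints.

The raw sub-model table is kept alongside for probability-weighted
statistics.

## Degradation rates and priors

Cycloheximide (translation block) leaves dP/dt = c_p − δp·P, fitted as a
single exponential with a non-negative floor; actinomycin D (transcription
block) leaves the two-exponential cascade solution, fitted with δp fixed
from the cycloheximide fit.  Fits use bounded least squares with three
starts (parameter tolerance 1e-10); a fitted δm within 2 % of δp is
rejected as degenerate (the t·e^{−δt} confluent form applies there).
Replicate fits pool into a log-normal prior: median = geometric mean of the
rates, log-sd = replicate spread floored at 0.1.  One prior per cell line,
shared across conditions (degradation is assumed unchanged by stimulation).

## Phase statistics

Consensus profiles are cut into phases (one per segment; the first phase is
entered at recording start and carries no direction; first/last phases are
censored).  Downstream: per-cell up/down switch counts with condition
mean ± SEM; OLS of ln(duration) on ln(rate) over uncensored phases;
consecutive switch-pair amplitudes labelled Up-Down / Down-Down / Down-Up /
Up-Up with per-scenario Pearson correlations on absolute amplitudes
(scenarios with < 3 pairs reported as undefined); posterior-predictive mRNA
counts (the mRNA marginal started at Poisson stays Poisson at the mean of
the rate ODE, so draws are Poisson at the posterior-sampled mean);
pooled 1-h-window pairwise Pearson correlations between cells; and the
population mean β(t).

**Binary vs graded classification** (the rule is a design decision; the
notion is otherwise informal): a profile is *graded-decrease* if it
contains a Down-Down pair of consecutive switches, else *graded-increase*
if it contains an Up-Up pair, else *binary*.  It depends only on the
direction sequence.

## The three-state refractory model

The inactive period between a down-switch and the next up-switch is
modelled as an exponential off (refractory) sojourn of mean T1 followed by
an exponential primed sojourn of mean T2; their sum is hypoexponential

    f_d(t) = λ1·λ2/(λ2 − λ1) · (e^{−λ1 t} − e^{−λ2 t}),  λᵢ = 1/Tᵢ,

symmetric in λ1 ↔ λ2 and replaced by the Erlang-2 limit λ²·t·e^{−λt} when
the rates are within 1e-6 (relative).  On-periods are exponential with
mean T0.

Runs of consecutive same-direction switches are merged into a single
inter-switch duration before fitting (the continuous model's graded
decreases correspond to one inactive period of the discrete model);
durations ending at the recording edge are right-censored.  The fit
maximises the censored log-likelihood Σ log f_d (complete) +
Σ log(1 − F_d) (right-censored) — right-censoring contributes survival
probability; treating *every* duration as censored would make the MLE
degenerate.  T1 < T2 is enforced by parameterising (log T1, log(T2 − T1));
optimisation is multi-start Nelder-Mead, cross-checked against an
exhaustive grid in tests.  The censored exponential for T0 is closed form:
rate = (#complete) / (sum of all durations).  T1, the smaller mean, is
reported as the refractory period.  Uncertainty comes from a bootstrap that
resamples *cells* (not durations) to respect within-cell dependence.

## The synthetic cohort

The generator is the study-conditions oracle for every downstream test:
48-h windows at 0.25-h sampling; per cell a single all-or-nothing up-switch
(time ~ U(8, 20) h; fold ~ U(10, 20) over a baseline near 6 mRNA/h)
followed by 2–4 graded down-switches (gaps ~ U(5, 9) h, each dividing the
rate by U(3, 6), so amplitudes decrease); exact Gillespie simulation of the
cascade (initial state drawn from the stationary law of the first segment);
Gaussian measurement noise added to κ·P at the grid.

Default kinetics: δm = 0.6 h⁻¹ (mRNA half-life ≈ 1.2 h), δp = 0.35 h⁻¹
(protein half-life ≈ 2 h — a destabilised luciferase), α = 5 h⁻¹, κ = 1,
σ = 10 luminescence units.  The baseline transcription rate is chosen so
the *low* state still holds ~10 mRNA molecules and up-states hold ~100–200,
matching single-molecule count scales for a strong reporter; at counts much
below this the low state's stochastic bursts are statistically
indistinguishable from genuine rate switches and single-cell switch
recovery degrades — an informative property of the method, but not the
regime the recordings represent.  The instrument's true noise magnitude and
κ scale are unknown; both are free configuration parameters.

What the generator does *not* emulate: photon integration over the 15-min
exposure (the measurement is instantaneous; integration is absorbed into
σ), cell division and lineage tracking, drift or background structure in
the optics, and extrinsic parameter variability beyond optional log-normal
jitter on α.  Passing tests therefore demonstrate correctness of the
inference machinery under the stated stochastic kinetics, not robustness to
instrument systematics.

## Problem sizes used by the test suite and acceptance script

Likelihood agreement: 100 random instances of ≤ 5 observations.  Switch
recovery: 20 cells × 192 observations × 5,000 MCMC iterations (the
production setting of 30,000 iterations behaves equivalently on these
traces; 5,000 keeps the whole suite desk-scale).  Three-state recovery:
20 cohorts × 100 cells.  Prior recovery: 200,000 prior-only iterations
thinned by 150.  Bootstrap: 200 replicates.

## Known limitations

* The consensus rule (median-probability model), the component merge
  resolution (1 h), and the edge guard (1 h) are fixed choices; cells whose
  true switches fall within 1 h of each other or of the window edges are
  not resolvable by construction.
* Weak identifiability of α with κ fixed rescales rate magnitudes; rate
  *ratios*, switch times and counts are the reliable outputs.
* Final down-switches whose remaining evidence is marginal (small absolute
  rates, overlap with the protein response of the previous switch) carry
  posterior inclusion near 0.5 and are sometimes dropped, and sustained
  stochastic bursts in low-rate tails are sometimes kept; on the default
  synthetic conditions the consensus switch count matches the generating
  truth in roughly 70–75 % of cells, with matched switch times accurate to
  ~0.2 h (median).  Longer chains do not change this: it reflects the
  information actually present in a single 48-h trace at these copy
  numbers, not sampler error.
* The LNA is Gaussian; at very low copy numbers (< ~5 mRNA) its likelihood
  is an approximation to the skewed exact law.
* The hierarchical pass is empirical-Bayes (two-stage), not a joint
  sampler over cells.
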