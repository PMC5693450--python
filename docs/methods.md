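# Methods

This note documents the models implemented in `ktom`, the numerical choices
behind them, and what the synthetic validation does and does not establish.

## Game and decision rule

All agents play repeated two-action games defined by a payoff table
U(a_self, a_op). Hide-and-seek uses a ±1/2 utility scale: the seeker earns
+0.5 when it matches the hider's hand and −0.5 otherwise; the hider earns
the opposite (anti-symmetric competitive tables), and the cooperative
variant rewards both players for matching (symmetric table). This scale
satisfies U(1,1) − U(0,1) = U(0,0) − U(1,0) = 1, so the seeker's expected
payoff difference is ΔV = 2·p_op − 1, where p_op is the predicted
probability that the opponent plays option 1.

Every model shares the softmax policy P(a_self = 1) = s(ΔV/β + bias), with
temperature β > 0 and a log-odds bias. Models differ only in how they form
p_op (or, for the value-learning heuristics, ΔV directly):

* **BN** (biased Nash): ΔV = 0; choice probability is s(bias). β is not
  identifiable at ΔV = 0 and is fixed to 1 during fitting.
* **WS** (win-stay/lose-switch): chosen value ← R, unchosen ← −R.
* **RL**: Rescorla–Wagner update of the chosen value only,
  V ← V + α(R − V). Note WS and RL are *not* nested: RL at α = 1 copies the
  reward into the chosen value but leaves the unchosen value stale, so the
  two rules produce similar but not identical behaviour, and on
  near-deterministic WS data their evidences can differ by tens of nats.
* **0-ToM**: Gaussian belief (μ, Σ) over the opponent's choice log-odds,
  assumed to drift with volatility σ⁰; one Laplace-style update per trial
  (Σ′ = 1/(1/(Σ+σ⁰) + s(μ)(1−s(μ))), μ′ = μ + Σ′(a_op − s(μ))). At σ⁰ → 0
  this is fictitious play. The predictive choice probability is
  E[s(x)] ≈ s(μ/√(1 + aΣ)) with a = 3/π² (logistic–probit moment
  matching; the logistic distribution has variance π²/3).
* **Influence learning (Inf)**: a delta-rule tracker of p_op with a
  heuristic correction for how one's own action shifts the opponent's
  strategy, p′ = p + η(a_op − p) − λ·p(1−p)·(2a_self + (2I_comp−1)·β·s⁻¹(p)
  + I_comp), clamped to [ε, 1−ε]. The competitive (I_comp = 1) and
  cooperative (I_comp = 0) variants are separate candidate models, and the
  β inside the correction defaults to the agent's policy temperature. The
  update is implemented exactly as written above; note the correction is
  not symmetric in a_self.
* **k-ToM (k = 1, 2)**: recursive meta-Bayesian learners described next.

## k-ToM: joint filtering of the opponent's belief and parameters

A k-ToM agent entertains one sub-model per possible opponent sophistication
level κ < k and a posterior λ over levels, updated by Bayes rule from each
sub-model's predicted probability of the observed opponent action.

Each sub-model is a Gaussian filter over three hidden states: the modeled
opponent's *belief log-odds* about my own next action, and the opponent's
transformed volatility and temperature (log σ_op, log β_op). The design
choice to filter the belief jointly with the parameters (rather than
treating the belief as a deterministic replay given the parameters) is
essential: it lets the innovation term correct the tendency estimate
directly, which is what produces the characteristic k-ToM behaviours — a
competitive 1-ToM exploiting a 0-ToM hider close to the oracle bound, and a
cooperative 1-ToM locking onto one hand against a biased-random opponent.
With parameters-only hidden states those signatures collapse to chance.

Per trial the sub-model performs:

1. **Prediction.** The opponent action logit v = ΔV_op(p̂_me)/β_op is read
   out of the nested opponent machine (for κ = 0, p̂_me = s(b/√(1 + aV))
   with b the belief state and V the opponent's own posterior variance,
   propagated as an auxiliary quantity; for κ = 1, a full nested 1-ToM
   machine whose bottom-level belief is kept in sync with the filtered
   state). The observation gradient W has closed forms: the chain rule
   through the moment-matched sigmoid for the belief component and
   ∂v/∂log β = −v for the temperature; both vanish where the logit is
   clamped. The predictive probability applies the same moment matching to
   v with variance WᵀSW. The level-mixed prediction is p_op = Σ_κ λ_κ p_κ.
2. **Measurement.** A level-weighted Laplace update of (m, S): the
   precision gains the rank-one term s′(v)·λ_κ·WWᵀ (implemented by the
   Sherman–Morrison identity, so S stays positive definite by
   construction) and the mean moves by λ_κ·S·W·(a_op − s(v)). The level
   posterior is updated first and its new value weights the state update,
   following the level-weighted reading of the update equations.
3. **Evolution.** The modeled opponent digests *my* action through its own
   learning rule; the filter mean is propagated through that mapping and
   the covariance through its Jacobian (central finite differences with
   step 10⁻⁴). The agent's own volatility parameter σᵏ then inflates the
   *belief* component of the covariance only. Diffusing the parameter
   components as well creates an absorbing "the opponent is pure noise"
   state (β̂_op → ∞ zeroes the observation gradient permanently), so the
   opponent's parameters are treated as static quantities whose
   uncertainty shrinks as evidence accumulates.

Beliefs start uninformative (means 0, identity covariances, uniform level
posterior). Logits of modeled opponents are clamped so the implied
probability stays within [ε, 1−ε], ε = 10⁻⁴ — the same clamp applied to
every probability used in a likelihood or inverted through the logit.
2-ToM's second sub-model identifies its volatility only weakly (its
one-step readout is insensitive to log σ¹); this mirrors the generally
poor identifiability of volatility parameters from short binary sequences.

## Opponents and protocol

The simulated protocol reproduces the study design: 12 sessions of 60
trials, 4 per opponent condition, condition order counterbalanced across
individuals by Latin-square rotation, sessions shorter than 20 trials
flagged excluded, inter-session gaps drawn from {1, 2, 3} days. The three
opponents are: **RB**, a pre-drawn i.i.d. sequence with a 65% bias for one
hand (favoured side counterbalanced across sessions); **OTOM** and
**ITOM**, online competitive 0-ToM/1-ToM hiders that hide where they
predict the subject will not seek. The opponents' parameters are σ = 0.5,
β = 1; nothing in the acceptance properties depends on their exact values
(all performance checks are sign-based).

For *simulated subject* agents (performance signatures, Volterra
reducibility, optimal-kernel references) the package uses σ = 0.5 and
β = 0.05: volatility matching the opponents and near-greedy play. This is
the regime in which the model family expresses its qualitative signatures
(0-ToM's graded performance decline; cooperative 1-ToM above chance against
RB and below chance against both online opponents; influence learning
beating 0-ToM while losing to 1-ToM — the latter with η = 0.7, λ = 0.5,
β = 0.2). At temperatures β ≳ 0.4 all of these effects shrink towards
chance, as expected when policies become nearly random.

## Model inversion

Each model maps transformed parameters (log scale for σ, β, λ; logit scale
for α, η; natural scale for biases) to a per-trial choice-probability
sequence by replaying the session. Fitting maximizes the log-joint
(Bernoulli likelihood × independent Gaussian prior: N(0, 3) on log/logit
parameters, N(0, 10) on biases) with a damped Gauss–Newton scheme whose
curvature is the logistic-GLM approximation Σ p(1−p)ggᵀ, with per-trial
logit gradients from central finite differences (step 10⁻³) evaluated in
one batched replay. Four fixed starts (the prior mean plus three seeded
perturbations) run in parallel inside the same batch; a step is accepted
only if the Laplace free energy

F = log p(a|θ*) + log p(θ*) + (d/2)·log 2π + ½·log det S*

does not decrease, making each start's F-trace monotone by construction.
Convergence is |ΔF| < 10⁻³ nats, at most 64 outer iterations; the best
start is returned. On one-parameter models F agrees with Gauss–Hermite
quadrature of the exact marginal likelihood to well under 0.5 nats.

Sessions of one opponent condition are pooled (shared parameters, state
reset at session boundaries); the three condition-level free energies are
summed into the model's log-evidence for that individual.

## Model comparison

Within subject, log-evidences are normalized under a uniform prior over
the ten models; pToM is the posterior mass on the six-model ToM family
(equal evidences give pToM = 0.6). A uniform-over-families prior is
available as an option. Species-level pToM averages individual family
posteriors within species.

The group-level random-effects scheme is the variational
Dirichlet-multinomial update (subject-wise model posteriors alternating
with Dirichlet counts, α₀ = 1), with exceedance probabilities from 10⁵
Monte-Carlo Dirichlet draws and protected exceedance probabilities mixing
with the equal-frequency null through the Bayesian omnibus risk. Against
an importance-sampling estimate of the exact posterior the variational
expected frequencies agree to < 0.02 when subject-level evidence is
decisive (gaps ≳ 2 nats); in the weak-evidence regime the variational
approximation is known to overshoot towards the extremes. The
between-group comparison fits independent Dirichlet posteriors per group
and reports the Monte-Carlo probability that group A's frequency-weighted
mean sophistication rank (BN < WS < RL < 0ToM < Inf < 1ToM < 2ToM,
cooperative/competitive variants tied; the mapping is configurable)
exceeds group B's.

## Volterra decomposition

Choices are regressed on exponentially parameterized histories of both
players' actions: q_t = s(ω₀ + Σ_τ A_op·e^(−λ_op·τ)·(2a_op,t−τ−1) + Σ_τ
A_self·e^(−λ_self·τ)·(2a_self,t−τ−1)), τ = 1..15 (a kernel with λ ≥ 0.3 is
below 1% of its magnitude beyond lag 15; lag 0 of the opponent action is
excluded as not causally available). Decays are fitted on the log scale
with prior mean log 0.5 and variance 1; magnitudes and bias carry N(0, 10)
priors. Fits use the same Laplace machinery as model inversion, per
session, and are averaged within individual and condition for group-level
analyses. The fitter also accepts fractional targets, which is how the
noiseless round-trip calibration (recovering planted (A, λ) within 5%)
is run. "Optimal" reference kernels are obtained by simulating the optimal
responder of each condition (0-ToM vs RB, competitive 1-ToM vs the 0-ToM
hider, competitive 2-ToM vs the 1-ToM hider) over long games.

## Group statistics

Session win rates are adjusted per individual by regressing out session
index and inter-session gap (ordinary least squares; residuals plus the
individual mean, an idempotent operation). Condition-level scores then
enter nested-model F-tests: the opponent effect is tested within subject
(subject intercepts, plus covariate-by-opponent interactions when
covariates are supplied), the species-by-opponent interaction over the
opponent model, and the species effect — and the ECV/group-size linear
contrasts on log features — in the between-subject stratum on individual
mean scores. The degrees of freedom therefore follow the two-stratum
design (e.g. F[2, 2(n−1)−…] for the opponent effect at n individuals),
not any particular published layout. Under a null generator the opponent
test's type-I error is calibrated (within [0.03, 0.07] at nominal 0.05
over 2000 simulations).

The Sobel mediation test uses z = ab/√(a²·se_b² + b²·se_a²) from the two
regressions (mediator ~ x; y ~ x + mediator) with a two-sided normal
p-value. It is calibrated on the boundary null (mediator independent of x,
real mediator→outcome path); at the complete null (both paths zero) the
classical test is conservative by construction.

No multiple-testing correction is applied anywhere; tests are reported
unadjusted. Phylogenetic correction of species-level correlations is out
of scope (the feature-regression report notes that with 7 species it would
be advisable on real data).

## Synthetic cohorts

The generator emulates the study design: 7 species, 5 individuals each by
default (the printed per-species sample sizes 7/6/5/4/5/9/4, mean 5.7 ±
1.8, are available as an option), 12 sessions of 60 trials, counterbalanced
conditions, optional session truncation with the > 20-trials inclusion
rule. Each individual draws a generating model from a per-species mixture
(default: ToM-family weight rising linearly from 0.2 to 0.8 with ECV rank,
uniform within family) and parameters from log-/logit-normal distributions
centred on σ = 0.5, β = 0.1, α ≈ 0.6, η ≈ 0.7, λ = 0.5, bias ~ N(0, 0.3).
The packaged species-feature table is synthetic (plausible placeholder
values, clearly labelled); real analyses should supply their own table.

What passing the synthetic suites shows: the pipeline is internally
consistent (simulate → invert → compare recovers generating models and
planted associations at desk scale). What it does not show: anything about
real animals — real choice sequences have motivational lapses, session
non-stationarity, individual heterogeneity beyond the modelled covariates,
and no ground-truth generating model.

## Problem sizes used by the test and acceptance suites

Chosen to keep the full validation on one CPU in minutes: the confusion
harness runs the *full* study design (4 sessions of 60 trials per
condition) with 5 individuals per generating model — identifiability of
the biased-Nash and influence models against their flexible neighbours
needs the full trial budget (their evidence margins sit within a nat at
half the data, because the flexible sequential models gain trajectory
overfit from identifiable directions while their flat directions carry
almost no Occam penalty); parallel-session replay keeps this affordable.
The end-to-end pToM–ECV check uses 3 individuals per species at 2
sessions of 40 trials per condition; Volterra reducibility uses 50
two-hundred-trial games per agent × opponent pairing; calibration suites
use 2000 simulations.

## Known limitations

* k-ToM is implemented for k ≤ 2, two actions, within-session learning
  only (state resets at session boundaries), as scoped.
* The 2-ToM filter propagates its nested 1-ToM model at the posterior
  mean; volatility of the modeled 1-ToM is essentially prior-driven.
* The variational group-level comparison inherits the known optimism of
  Dirichlet-multinomial variational bounds under weak evidence.
* The influence-learning correction term is implemented exactly as
  specified, including its asymmetry in the agent's own action; its
  tournament advantage over 0-ToM is real but small (≈ 0.52 win rate) and
  expressed in the high-η, low-β regime.
* Identifiability of the biased-Nash null model is intrinsically fragile:
  every other candidate contains it (large β or zero learning weights
  reduce them to a constant-p policy), so on BN-generated data the
  flexible models' best-mode Laplace evidences sit within about a nat of
  BN's, and taking the maximum over six ToM models can flip the family
  assignment. The confusion harness reports this honestly; the other nine
  generating models are re-identified at or above the 80% level at the
  full design.
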