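# Methods

## Task model

An experimental run is a finite partially observable Markov decision process.
The hidden state component `s1 ∈ {1, 2}` encodes the currently lucrative shape
(1 = square); the observable component `s2 ∈ {1, 2}` encodes the layout
(1 = square on the informative side). The layout determines the available
action pair: `{1, 4}` under `s2 = 1` (square/informative vs
triangle/non-informative) and `{2, 3}` under `s2 = 2`. Choosing the lucrative
shape returns +1 with probability `p_reward_lucrative` (default 0.85) and −1
otherwise; the detrimental shape has the reversed probabilities. The
observation function is deterministic: informative actions map the reward to
a revealed outcome (−1 → 1, +1 → 2), non-informative actions always show the
masked outcome 3.

The sequence generator treats the design constraints as a sampling problem:

- Block lengths (trials between reversals) are drawn uniformly by rejection
  from the compositions of `trials_per_run` into `reversals_per_run + 1` parts
  within `[block_length_min, block_length_max]`. When the run length is even
  and the alternation permits it, the compositions are further constrained so
  each shape is lucrative on exactly half the trials, matching the balanced
  design and making the layout counterbalance achievable with integer counts.
- The initially lucrative shape is a fair seeded draw; `s1` alternates across
  blocks; runs are generated independently and concatenated, with per-run
  trial indices and the run index kept alongside.
- Within the trials of a run sharing an `s1` value, the two layouts are
  assigned in a half/half shuffle, rejected until no `(s1, s2)` combination
  repeats more than `max_consecutive_same_option` (default 5) times in a row.

An independent validator (`validate_state_sequence`) re-checks every
constraint by recounting, and is exercised against the generator in the test
suite. The original experiment used one fixed pre-generated sequence for all
participants; the package treats sequences as data — any fixed sequence can be
replayed by constructing a `StateSequence` or loading a dataset CSV that
carries `s1`.

## Belief-state filter

The Bayesian agents reduce inference about `s1` to a scalar belief
`b = p(s1 = 1 | history)`, initialized at 0.5 per run. Each trial applies a
Bayes step with the observation likelihoods (flat for the masked outcome) and
then mixes with the symmetric reversal kernel
`b' = stay · b_post + switch · (1 − b_post)`, with `switch = 0.0375` by
default (three reversals in 80 trials — agents know the rate, not the times).
Under masked outcomes the update is the pure transition, so `b − 0.5`
contracts by `stay − switch = 0.925` per trial; starting from 0.5 the belief
therefore never leaves roughly `[0.045, 0.955]`. The filter is verified
against a brute-force oracle that enumerates the joint distribution of all
hidden-state paths for every action/observation history up to length five
(agreement to 1e−12).

## Valence functions and decision rules

- **C1** assigns 0.5 to both available actions.
- **C2** (win-stay–lose-switch) keeps a shape-valence pair in {0, 0.5, 1}:
  a revealed win sets the chosen shape to 1, a revealed loss to 0 (the other
  shape gets the complement); masked outcomes carry the allocation over, and
  the pair maps onto whatever actions currently offer each shape.
- **A1** values actions by belief-weighted expected reward; with the default
  reward probabilities the lucrative shape is worth `2·0.85 − 1 = 0.7` in
  expectation, so square actions get `0.7(2b − 1)` and triangle actions the
  negative. Expected rewards are derived from the task configuration, not
  hard-coded, so sensitivity analyses only need a different `TaskConfig`.
- **A2** values an action by its expected Bayesian surprise: the
  posterior-predictive-weighted KL divergence between the would-be next
  belief and the current one, using the two-point KL
  `(1−b')ln((1−b')/(1−b)) + b' ln(b'/b)`. Surprise depends only on whether
  the action is informative, is non-negative, is mirror-symmetric in
  `b ↔ 1−b`, and dominates the non-informative action everywhere on the
  interior grid. Its maximum over `b = 0.01 … 0.99` is ≈0.227 nats (0.23 at
  two decimals).
- **A3** takes the convex combination `λ·vA1 + (1−λ)·vA2`; λ = 1 and λ = 0
  recover A1 and A2 exactly.

Numerical conventions for the KL: `0·ln 0 := 0`, and beliefs are clipped to
`[1e−12, 1 − 1e−12]` before logarithms. The clipping matters only for
user-supplied endpoint beliefs — the KL prior term diverges at `b ∈ {0, 1}`,
which is unreachable from `b₁ = 0.5`. Valence-landscape evaluations
(including the reported A2 maximum) use the interior grid `[0.01, 0.99]`
because the divergence makes the supremum over the open unit interval
unbounded.

The agents as defined are deterministic: an argmax decision rule with exact
ties broken by a seeded fair draw (`decide_argmax`). Data generation instead
uses the stochastic softmax policy of the data-analysis models — the two
policies are distinct, documented operations, and the simulator deliberately
uses the one the recovery analyses assume.

## Simulation

`simulate_dataset` runs the closed loop: valences → softmax action sampling at
the agent's τ (uniform for C1) → reward draw → observation → state update,
resetting the agent at run boundaries. Simulated agents always respond, so
synthetic data contain no invalid trials — one structural difference from real
participants, whose occasional misses the likelihood machinery handles but the
generator does not emulate. Rewards are re-sampled per dataset. Seeds follow a
`SeedSequence` spawn hierarchy (master → dataset → trial stream), so cohorts
are bit-reproducible and individual datasets replayable. By default a cohort
shares one state sequence, as in the experiment; `shared_sequence=False` gives
each dataset its own.

What passing tests on these synthetic data do **not** show about real data:
the generator contains no response-time structure, no missed trials, no
learning or fatigue drift, and its choice noise is exactly the softmax the
analysis assumes, so recovery results bound what the pipeline can do when the
model class is correct, not model misspecification on human data.

## Likelihood, estimation, model evidence

The conditional log likelihood replays a dataset trial by trial, driving the
agent's internal state with the *recorded* actions and observations, and sums
log softmax choice probabilities over valid trials only. Across an invalid
trial the belief state advances by the transition-only update and the C2
preference is carried over unchanged — a documented default (the alternative
of freezing the belief is a one-line change) since no observation was made.
Any automatically registered penalty reward on missed trials affects earnings
only and never enters the likelihood.

Estimation minimizes the negative conditional log likelihood with L-BFGS-B
under the box constraints τ ∈ [0.01, 2.5] (and λ ∈ [0, 1] for the hybrid),
from 10 uniform-random start points by default (tolerances 1e−6); the best
restart is kept and all restarts are logged in the `FitResult`. C1 needs no
optimization: ℓ = N ln 0.5. The softmax is max-stabilized so temperatures at
the lower bound are safe.

Model evidence is approximated by `BIC = ℓ(θ̂) − (k/2) ln N` with `k` free
parameters and `N` valid choices. This is on the **log-evidence scale**
(higher is better); it differs from the common deviance-scale BIC by a factor
of −2. Evidence tables keep the fixed column order (C1, C2, A1, A2, A3).

## Random-effects model selection

`rfx_bms` re-implements group-level random-effects selection rather than
wrapping an external toolbox. A variational scheme with a uniform Dirichlet
prior (α₀ = 1 per model) alternates responsibilities
`g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))` and the update `α = α₀ + Σ_n g_n`, to
tolerance 1e−8 on α. Exceedance probabilities are Monte-Carlo argmax
frequencies over the fitted Dirichlet (default 10⁶ samples, seeded; the
recovery harness defaults to 10⁵). The Bayesian omnibus risk compares the
variational free energy of the random-effects model with that of the
equal-frequency null, `bor = 1/(1 + exp(F₁ − F₀))`, with `bor := 1` on a
numerical tie; protected exceedance probabilities apply
`pep = ep·(1 − bor) + bor/K`. For two models the exceedance probability has a
closed Beta-marginal form, used in the tests as an independent oracle.

## Recovery studies

`RecoveryGridSpec` encodes the full study design as data: generating models
(C1; C2/A1/A2 over τ = 0.05…2.5 in steps of 0.05; A3 additionally over
λ ∈ {0.1, 0.25, 0.3, 0.5, 0.7, 0.9}), 24 datasets per cell, 10 repeats, one
shared sequence per cell. Desk-scale runs restrict the spec (never the code);
the acceptance checks use τ = 0.1 with 8 datasets × 2 repeats per cell, which
completes in about a minute per study on one CPU, while the full grid is a
long-running configuration (hours of CPU). Model recovery reports mean PEPs
over repeats; parameter recovery reports mean and SEM of the generating
model's estimates on its own cohorts; `posthoc_validation` simulates at
fitted participant-level parameters, averages descriptive rates over repeats
(default 100) and re-fits as an identifiability check.

A known identifiability boundary, reproduced rather than hidden by the
package: win-stay–lose-switch valences are exactly {0, 1}, so at low
generating noise (τ ≈ 0.1) a deviation from the heuristic occurs with
probability `1/(1 + e^{1/τ})` ≈ 4.5e−5 per trial and nearly every 160-trial
dataset is deviation-free. On such data the likelihood increases monotonically
as τ → 0, the estimate pins at the 0.01 bound, and the C2 temperature is not
point-identified below roughly τ ≈ 0.3 — unlike A1/A2/A3, whose valence gaps
shrink near `b = 0.5` and keep τ identifiable at 0.1. Model recovery of C2 is
unaffected (near-deterministic WSLS data still single out C2 decisively).

## Descriptive analyses

Actions are labeled lucrative/detrimental (chosen shape vs `s1`) and
informative/non-informative (chosen action side); trial type I (`s1 = s2`)
offers L∧I vs D∧N, type II offers L∧N vs D∧I. Nine per-participant summary
rates (overall and per-type valid rates, the four conjunction rates, the
lucrative and informative rates) are averaged with SEM across participants.
Trialwise group rates divide each trial's action counts by its valid choosers,
so each trial carries one complementary rate pair. Reversal-locked averages
align trials by position since the last reversal — run starts count as block
starts (a documented, switchable choice; whether the pre-first-reversal block
belongs in the average is ambiguous in the source design) — average each
series over the blocks contributing that position (later positions aggregate
fewer blocks), and report the L∧I − L∧N difference. Missing-rate trials are
excluded, not imputed. The L∧I vs L∧N comparison is a two-sided paired t-test
with explicit degenerate contracts: all-zero differences give t = 0, a
constant nonzero difference gives a signed infinite-t sentinel, both with
warnings.

## Interfaces

Datasets travel as tidy CSV (one row per trial: participant, run, 1-based
trial, `s2`, action, reward, observation, validity, plus `s1` for synthetic
data; invalid trials have empty action/reward/observation) with a JSON
metadata sidecar; schema violations are reported with row numbers, and
action/observation consistency with the observation function is enforced on
read and write so real participant exports can be ingested safely. Task
configuration is JSON with unknown-key rejection. The `revbandit` CLI exposes
`simulate`, `fit`, `compare`, `recover`, `describe`, `validate` and
`valences`; every stochastic command requires `--seed`, and each run logs the
package version, configuration hash and seed to stderr.

## Limitations

- No optimal POMDP planner and no random-exploration (e.g. Thompson-sampling)
  agents: the softmax here models post-decision noise, not a strategy.
- No hierarchical or fully Bayesian parameter estimation; per-dataset ML only.
- Synthetic data idealize responding (no misses, no timing), as above.
- The exact participant-facing trial sequence of the original experiment is
  not bundled; a constraint-respecting generated sequence stands in, and any
  fixed sequence can be supplied as data.
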