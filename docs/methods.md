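# Methods

## The task

An agent searches for a target hidden at one of the 8 leaves of a complete
binary tree with three internal levels (nodes 1–7 internal, 8–15 leaves in
heap order). Each internal node carries a latent motion direction
d ∈ {left, right} and a motion strength (coherence)
c ∈ {3.2, 6.4, 12.8, 25.6, 51.2}%, drawn independently and uniformly per
node at the start of a trial and fixed throughout it. The target is the
leaf reached by following the true direction at every bifurcation. With 10
states per node and 7 nodes the latent space has 10⁷ states.

Querying an internal node costs 1 point and returns one scalar evidence
pulse; choosing a wrong leaf costs 3 points and reveals only that it was
wrong; finding the target earns 10 points and ends the trial. A pulse from
a node with coherence c and direction d is Gaussian,

    e ~ N(κ·d·c·t,  t·(1 + c·γ)),    t = 0.227 s,

with signal-to-noise κ and variance slope γ. Coherences are proportions
internally (0.032 … 0.512); configuration files may use percent.

Simulation runs in *spatial* coordinates (children of node i are 2i and
2i+1, left/right). Analyses use the *canonical* (target-relative)
relabeling, a per-trial bijection under which the true direction reads
rightward everywhere, the target is node 15 and its error path is
(1, 3, 7). The relabeling is analysis-time only: agents never see it.

## The detection (extrema) choice model

After a query the pulse is compared against two symmetric criteria at ±Φ.
Beyond +Φ the right child is chosen, below −Φ the left child; otherwise
the sample is discarded and the node is queried again. The criterion

    Φ(ℓ, n_q) = φ_ℓ · (1 + exp(−λ·n_q))

depends on the tree level ℓ through a base criterion φ_ℓ and collapses
from 2φ_ℓ toward φ_ℓ with the streak counter n_q, the number of
immediately preceding queries of the same node (0 on the first query of a
streak; interrupting the streak resets it). The trinomial probabilities
are the Gaussian tail masses

    p_right = ½·erfc((Φ−μ)/(√2σ)),  p_left = ½·erfc((Φ+μ)/(√2σ)),
    p_requery = 1 − p_right − p_left.

The six parameters (κ, γ, φ₁, φ₂, φ₃, λ) are fitted by maximum likelihood
to the choices made after internal-node queries, restricted to queries
followed by a re-query or by a child query. Optimization uses stratified
(Latin-hypercube) multi-starts refined with bounded Nelder–Mead; eight
starts by default, deterministic given the seed and invariant to row
order.

Variants for model comparison tie or free parameters of the same
likelihood: a single criterion with per-level κ (`1phi3kappa`), per-level
κ and φ (`3phi3kappa`), constant variance (`gamma0`), and a criterion that
decays with the order of the query in the trial rather than with level and
streak (`query_order`, φ = φ∞ + (φ₀−φ∞)e^{η(q−1)}).

### Integration variant

The optimality-inspired alternative accumulates evidence within a streak:
the running sum of pulses is compared against the same criterion schedule
(the n_q-dependence applied to the running sum at each pulse). Its
likelihood propagates the surviving (truncated) density of the sum on a
uniform evidence grid — spanning ±(2φ_ℓ + |μ| + 8σ), 2,001 points by
default — via FFT convolution with the pulse kernel; exit masses are read
from the interpolated cumulative sum so the likelihood is smooth in φ
(a hard grid-cell truncation makes it piecewise constant and stalls the
simplex search). Grid resolution is validated against Monte-Carlo
simulation of the cumulative sums in the test suite. Because detection and
integration share a parameterization, the integration fit starts from the
detection optimum plus stratified random starts; this informed start is
what makes the model comparison affordable, and in every tested case it
reaches a likelihood at or above the generating parameters'.

## Exact belief engine

The posterior over the latent state factorizes over nodes until the first
leaf error: each node carries a 5×2 table P_i(c, d | E_i) updated by
Bayes' rule with the Gaussian likelihood. Leaf feedback conditions on a
collider (the implied target), coupling the direction marginals. The
engine handles this by eliminating every one of the 2⁷ direction
combinations whose implied target is a visited wrong leaf and
renormalizing. Because combinations partition exactly by implied target,
the renormalized target belief B(T | E, V) equals the factorized product
of ancestor direction-marginals, zeroed on visited leaves and
renormalized; the agents use that closed form, the explicit enumeration is
kept as a public method, and the test suite asserts their equality (and,
on depth-2 trees, equality with exhaustive enumeration of all 10³ joint
states, to 1e−10). Post-error direction marginals P_i(d | E, V) are
computed by decomposing over the target: ancestors of T point toward it,
non-ancestors keep their local marginals.

Choice confidence — used by the heuristic agent — is the posterior
probability of the chosen direction given only the last pulse at the node,
under a uniform prior over the 10 (c, d) cells. An accumulated-posterior
prior is available as an option but off by default.

## Rollout planner

Before each real action the planner samples a latent state s* from the
posterior (directions from the renormalized combination distribution,
coherences from P(c|d)), assumes it true, and plays out a constrained
random policy from each candidate action until s*'s target is found: with
probability 7/15 a uniformly random internal node is queried, otherwise
the unvisited leaf with the highest current target belief is chosen (ties
uniform). A private copy of the belief is updated after every imagined
observation. Costs use the planner's payoff set, which the subjective-cost
variants scale (internal queries at 30%, or queries at 50% with immediate
re-queries at 5%); the environment always charges true payoffs. 2,000
rollouts per candidate action by default; tests use reduced rollout counts
(100–200) where only qualitative behavior is asserted. The candidate equal
to the previously executed action is charged the re-query cost on its
first step, so re-query discounts are visible to the planner.

Numerical choices: rollouts are capped at 200 steps, after which the
worst-case remaining cost (all remaining wrong leaves, then the target) is
charged; candidate actions exclude leaves already known wrong; exact
cost ties are broken uniformly. The inner loop runs on an array mirror of
the belief state whose distributional equivalence with the reference
implementation is tested.

On a reduced task (one internal node of known coherence, two leaves) the
planner is compared against an exact value-iteration solution of the
belief MDP over a grid spanning all coherences and direction beliefs; it
selects a DP-optimal action on ≥90% of the grid. Remaining disagreements
sit at hairline decision boundaries (action values within ~0.2 points),
where the random-continuation bias of plain rollouts is of the same order
as the margin.

## Shallow sampling norms

Probability gain, information gain and impact score every candidate action
by the expected change of B(T | E, V): expected increase of the posterior
maximum, expected entropy reduction, and expected summed absolute change.
Leaf queries have two outcomes weighted by B(T) and 1−B(T); internal-node
expectations integrate over the pulse's predictive density — a
10-component Gaussian mixture weighted by P(c|d,E_i)·P_i(d|E,V) — by
trapezoid quadrature on a 401-point grid spanning ±(μ_max + 8σ_max),
validated against Monte Carlo. The scores never read payoffs, so the
policies are payoff-insensitive by construction.

Ties are broken uniformly at random, restricted to leaf actions whenever a
leaf is among the top-scored candidates. The restriction matters in
resolved states: when the belief already identifies the target every
action scores zero, and an unrestricted uniform tie-break would wander
through worthless internal queries that none of these policies is meant to
make; preferring the (tied) leaves lets the policy exploit what it knows.
The emergent behaviors — probability gain and information gain never query
internal nodes and earn the −0.5 points/trial of blind leaf search; impact
makes exactly one root query and then searches the favored branch —
are asserted by tests, not hard-coded.

## Heuristic agent

The heuristic agent couples the detection model's querying rules with
confidence-based credit assignment after leaf errors. For the three
decisions on the error path it compares the confidence (last pulse,
uniform prior) in the direction that led to the wrong leaf against a
threshold ω:

* ≥2 eligible low-confidence decisions → blame the highest-level one and
  re-query it (*on-path*);
* otherwise → blame the least-confident eligible decision and query its
  child off the error path (*off-path*);
* no eligible path node → choose a random unvisited leaf (*fallback*).

A blamed node becomes ineligible until new evidence is obtained from it.
Visited leaves are remembered and never re-queried: a level-3 choice
pointing at a known-wrong leaf counts as that error, triggers blame, and
charges nothing. Nodes never yet queried carry confidence 0.5.

ω is the model's only free parameter, fitted by matching the proportion of
on-path post-error queries (on-path count over all leaf errors) between
model and data. The search is a two-stage grid (coarse over (0,1), then
refined around the coarse minimizer) with common random numbers —
every evaluation re-seeds the 20,000-trial simulator identically, making
the objective deterministic and near-monotone in ω.

### The reference observer

No empirical dataset ships with the package, so a single reference
parameter set stands in for a typical observer in all end-to-end
simulations: κ = 16, γ = 1.5, φ = (0.45, 0.35, 0.25), λ = 1, chosen so
that single-pulse accuracy spans roughly 60% at the weakest to ~100% at
the strongest coherence, the criterion relaxes with depth, and weak motion
draws substantial re-querying. The reference ω = 0.92 is calibrated, with
the package's own fitting machinery, to the regime in which on-path and
off-path post-error queries are about equally frequent — the balance the
fitted models in this paradigm exhibit. Quantities that are
participant-conditioned in origin (the impact agent's mean reward, the
blame-rate figures) are reproduced under this observer; the test suite
states the published values it compares against, and deviations there
reflect the reference observer standing in for per-participant fits rather
than implementation error. In particular the blame-rate ratio between
weakest and strongest motion is steeper under the reference observer than
the published ~4×, as expected when a single synthetic observer with a
clean criterion hierarchy replaces an average over four fitted
participants.

### Recovery harness

The recovery harness generates with known parameters, refits, and compares
at tolerances of 10% (κ, φ_ℓ) and 25% (γ, λ) for the detection model at
10⁴ queries, and ±0.05 for ω at 2×10⁴ trials. Its generating parameters
set γ = 6 rather than the reference 1.5: γ's information comes only from
how the evidence spread scales with coherence, and at 10⁴ queries the
maximum-likelihood estimate's relative sampling error around small γ
values exceeds the stated tolerance, so the harness generates where the
parameter is identifiable at the tested scale.

## Behavioral analyses

All analyses run on the canonical numbering and apply identically to
simulated or external logs in the same schema: node- and level-level
transition matrices (counts M_u, row-normalized W_u(j|i), cross-subject
means; level transitions split before/after the first leaf error of a
trial and normalized per subject); action classification (post-internal
queries into correct child / incorrect child / re-query / other same
level / other lower level / higher level; post-error actions into on-path
/ off-path / other); blame statistics conditioned on coherence and level
(from the model's own blame annotations, or inferred for data-format logs
from the next query — the on-path target node, or the parent of an
off-path query); reward and query-count summaries (SEM over trials for
rewards, over subjects for per-level counts); and the six logistic
regressions relating choices, re-queries, on-path rates, pulse influence
and blame to signed strength, coherence, level and the evidence samples,
with subject indicator dummies and likelihood-ratio tests for the stated
nulls. For simulated data the model's evidence samples stand in for
stimulus motion-energy residuals in the pulse-influence regressions; no
multiple-testing correction is applied.

## What the synthetic data do and do not emulate

The generators reproduce the task's statistical structure — per-node
uniform coherences and directions, Gaussian single-pulse evidence, payoff
bookkeeping, streak-resolved query tables — and the agents' full decision
processes. They do not emulate pixel-level dot kinematograms,
motion-energy filtering, gaze or timing, inter-participant variability
(single reference observer), or learning across blocks (all parameters
stationary). Passing tests therefore certify the inference machinery and
the emergent policy structure, not participant-level quantitative fits.

## Problem sizes

Default test and acceptance scales: 10⁵ draws for Monte-Carlo moment and
threshold checks; 10⁴ queries for detection recovery; 5×10³ queries and
three replicate datasets per generator for the BIC cross-recovery; 2×10⁴
trials per evaluation for ω fitting; 5×10⁴ heuristic trials for blame
statistics; 2×10³ impact-agent trials; 60 planner trials at 150
rollouts/action for qualitative planner behavior and the full 2,000
rollouts/action where the planner is compared to dynamic programming.

## Known limitations

* The planner's rollout continuation is the paper-style constrained random
  policy; near decision boundaries its action values are biased by the
  random continuation, which caps agreement with exact DP below 100%.
* The reference observer is a stand-in, not a fit to human data; numbers
  that average over fitted participants are approximated, not reproduced.
* The ω objective is a simulation-based step function smoothed only by
  common random numbers; its grid search resolves ω to ~0.005, which is
  well inside the ±0.05 recovery tolerance but not arbitrary precision.
* Belief updates are exact and discrete; no leaky, sampled or amortized
  approximations are provided.
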