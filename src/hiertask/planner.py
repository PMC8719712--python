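"""Approximately optimal planning by posterior sampling and Monte-Carlo
rollouts.

Before each action the agent samples a full latent state from its posterior,
assumes it is true, and plays out a constrained random policy from each
candidate next action until that state's target is found, tallying the cost.
Averaging over many rollouts per candidate gives a cost estimate; the agent
executes the candidate with the lowest mean cost. The rollout policy queries
a uniformly random internal node with the prior probability of an internal
node (7/15 on the default tree) and otherwise picks the not-yet-visited leaf
with the highest current target belief, updating a private copy of the
belief after every imagined observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beliefs import BeliefState, init_beliefs
from .task import (COHERENCES, EvidenceParams, Payoffs, SessionLog,
                   SessionRecorder, TreeSpec, TrialEnv, TrialState,
                   sample_trial)


@dataclass
class RolloutConfig:
    """Configuration of the rollout planner.

    ``payoffs`` are the payoffs the planner *imagines* (cost-scaled variants
    model subjective rewards); the environment always charges true payoffs.
    ``p_internal`` defaults to n_internal/(n_internal+n_leaves).
    """

    n_rollouts: int = 2000
    p_internal: float | None = None
    max_depth: int = 200
    payoffs: Payoffs = field(default_factory=Payoffs)

    def __post_init__(self):
        if self.n_rollouts < 1:
            raise ValueError("need at least one rollout per action")
        if self.p_internal is not None and not (0 <= self.p_internal <= 1):
            raise ValueError("p_internal must be a probability")


class _RolloutKernel:
    """Array-level snapshot of a belief for fast repeated rollouts.

    Mirrors the :class:`BeliefState` update rules on raw arrays so that the
    many thousand imagined playouts per decision stay cheap.
    """

    def __init__(self, belief: BeliefState, config: RolloutConfig):
        tree = belief.tree
        self.tree = tree
        self.cfg = config
        self.tab0 = belief.tables.copy()
        self.m0 = self.tab0.sum(axis=1)
        self.visited0 = np.zeros(tree.n_leaves, dtype=bool)
        for leaf in belief.visited:
            self.visited0[leaf - tree.leaves[0]] = True
        c = belief.coherences
        evid = belief.evid
        self.mu = evid.kappa * c * evid.t
        self.sd = np.sqrt(evid.t * (1.0 + c * evid.gamma))
        self.leaf_anc = tree.leaf_anc
        self.leaf_dir = tree.leaf_dir
        self.p_int = (config.p_internal if config.p_internal is not None
                      else tree.n_internal / (tree.n_internal + tree.n_leaves))
        self.n_int = tree.n_internal
        self.n_leaf = tree.n_leaves

    def sample_state(self, rng, full: bool = False):
        """Directions from the renormalized combination distribution,
        coherences from P(c|d); returns (mu_per_node, sd_per_node,
        target_leaf_index) or, with ``full``, additionally the direction
        and coherence index arrays."""
        w = self.m0[self.leaf_anc, self.leaf_dir].prod(axis=1)
        w[self.visited0] = 0.0
        cw = np.cumsum(w)
        t_idx = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
        t_idx = min(t_idx, self.n_leaf - 1)
        d_idx = (rng.random(self.n_int) < self.m0[:, 1]).astype(np.intp)
        d_idx[self.leaf_anc[t_idx]] = self.leaf_dir[t_idx]
        pc = self.tab0[np.arange(self.n_int), :, d_idx]
        cum = np.cumsum(pc, axis=1)
        u = rng.random(self.n_int) * cum[:, -1]
        c_idx = (cum > u[:, None]).argmax(axis=1)
        sign = np.where(d_idx == 1, 1.0, -1.0)
        if full:
            return self.mu[c_idx] * sign, self.sd[c_idx], t_idx, d_idx, c_idx
        return self.mu[c_idx] * sign, self.sd[c_idx], t_idx

    def rollout(self, first_action: int, mu_s, sd_s, t_idx: int, rng,
                last_real_action=None) -> float:
        tree = self.tree
        pay = self.cfg.payoffs
        tab = self.tab0.copy()
        marg = self.m0.copy()
        visited = self.visited0.copy()
        leaf0 = tree.leaves[0]
        cost = 0.0
        action = first_action
        prev = last_real_action
        for _ in range(self.cfg.max_depth):
            if action >= leaf0:
                j = action - leaf0
                if j == t_idx:
                    return cost - pay.target
                cost += pay.wrong_leaf
                visited[j] = True
            else:
                cost += pay.query_cost(is_requery=action == prev)
                i = action - 1
                e = rng.normal(mu_s[i], sd_s[i])
                row = tab[i]
                row[:, 1] *= np.exp(-0.5 * ((e - self.mu) / self.sd) ** 2) / self.sd
                row[:, 0] *= np.exp(-0.5 * ((e + self.mu) / self.sd) ** 2) / self.sd
                row /= row.sum()
                marg[i] = row.sum(axis=0)
            prev = action
            if rng.random() < self.p_int:
                action = 1 + int(rng.integers(self.n_int))
            else:
                w = marg[self.leaf_anc, self.leaf_dir].prod(axis=1)
                w[visited] = 0.0
                ties = np.flatnonzero(w == w.max())
                action = leaf0 + int(ties[rng.integers(len(ties))])
        n_unvisited = self.n_leaf - int(visited.sum())
        return cost + pay.wrong_leaf * (n_unvisited - 1) - pay.target


def sample_state(belief: BeliefState, rng: np.random.Generator) -> TrialState:
    """Draw a latent state from the posterior.

    Directions are drawn from the renormalized combination distribution
    (equivalently: target from B(T|E,V), ancestor directions toward it,
    non-ancestor directions from their marginals), then coherences from
    P(c|d, E_i) per node.
    """
    tree = belief.tree
    kern = _RolloutKernel(belief, RolloutConfig(n_rollouts=1))
    _, _, t_idx, d_idx, c_idx = kern.sample_state(rng, full=True)
    directions = {node: (1 if d_idx[node - 1] == 1 else -1)
                  for node in tree.internal_nodes}
    coherences = {node: float(belief.coherences[c_idx[node - 1]])
                  for node in tree.internal_nodes}
    return TrialState(tree, coherences, directions)


def rollout(first_action: int, state: TrialState, belief: BeliefState,
            config: RolloutConfig, rng: np.random.Generator,
            last_real_action: int | None = None) -> float:
    """One imagined playout from ``first_action`` under latent state
    ``state``; returns the accumulated cost (negative is good).

    Reference implementation on a full :class:`BeliefState`; the planner's
    inner loop uses the equivalent array kernel.
    """
    tree = belief.tree
    target = state.target
    pay = config.payoffs
    p_int = (config.p_internal if config.p_internal is not None
             else tree.n_internal / (tree.n_internal + tree.n_leaves))
    evid = belief.evid
    internal = tree.internal_nodes
    cost = 0.0
    action = first_action
    prev = last_real_action
    for _ in range(config.max_depth):
        if tree.is_leaf(action):
            if action == target:
                return cost - pay.target
            cost += pay.wrong_leaf
            belief.add_visited(action)
        else:
            cost += pay.query_cost(is_requery=action == prev)
            e = rng.normal(evid.mean(state.coherence[action],
                                     state.direction[action]),
                           evid.sd(state.coherence[action]))
            belief.update(action, float(e))
        prev = action
        if rng.random() < p_int:
            action = internal[rng.integers(tree.n_internal)]
        else:
            B = belief.target_beliefs()
            ties = np.flatnonzero(B == B.max())
            action = tree.leaves[ties[rng.integers(len(ties))]]
    n_unvisited = tree.n_leaves - len(belief.visited)
    return cost + pay.wrong_leaf * (n_unvisited - 1) - pay.target


def candidate_actions(belief: BeliefState):
    """Internal nodes plus not-yet-visited leaves."""
    tree = belief.tree
    return list(tree.internal_nodes) + [
        T for T in tree.leaves if T not in belief.visited]


def action_costs(belief: BeliefState, config: RolloutConfig,
                 rng: np.random.Generator,
                 last_action: int | None = None) -> dict:
    """Mean rollout cost per candidate next action.

    ``last_action`` is the agent's previously executed action, so that a
    candidate equal to it is charged the re-query cost on its first step.
    """
    kern = _RolloutKernel(belief, config)
    costs = {}
    for a in candidate_actions(belief):
        total = 0.0
        for _ in range(config.n_rollouts):
            mu_s, sd_s, t_idx = kern.sample_state(rng)
            total += kern.rollout(a, mu_s, sd_s, t_idx, rng,
                                  last_real_action=last_action)
        costs[a] = total / config.n_rollouts
    return costs


def select_action(belief: BeliefState, config: RolloutConfig,
                  rng: np.random.Generator,
                  last_action: int | None = None) -> int:
    """Cost-minimizing action; exact ties broken uniformly at random."""
    costs = action_costs(belief, config, rng, last_action=last_action)
    best = min(costs.values())
    argmins = [a for a, v in costs.items() if v == best]
    return int(argmins[rng.integers(len(argmins))]) if len(argmins) > 1 \
        else int(argmins[0])


def run_bayes_agent(n_trials: int, rng: np.random.Generator,
                    tree: TreeSpec | None = None,
                    evid: EvidenceParams | None = None,
                    payoffs: Payoffs | None = None,
                    config: RolloutConfig | None = None,
                    coherences=COHERENCES,
                    subject: str = "bayes",
                    max_actions: int = 200) -> SessionLog:
    """Simulate full sessions of the rollout-planning agent.

    ``payoffs`` are the true environment payoffs; ``config.payoffs`` may
    differ for the subjective-cost variants.
    """
    tree = tree or TreeSpec()
    evid = evid or EvidenceParams()
    payoffs = payoffs or Payoffs()
    config = config or RolloutConfig()
    rec = SessionRecorder(subject, meta={"agent": "bayes",
                                         "n_rollouts": config.n_rollouts})
    for trial_idx in range(n_trials):
        trial = sample_trial(tree, rng, coherences)
        env = TrialEnv(trial, payoffs, evid, rng)
        belief = init_beliefs(tree, evid, coherences)
        step = 0
        done = False
        while not done and step < max_actions:
            action = select_action(belief, config, rng,
                                   last_action=env.last_action)
            obs, delta, done = env.step(action)
            if tree.is_leaf(action):
                if obs == "negative":
                    belief.add_visited(action)
            else:
                belief.update(action, obs)
            rec.record_step(trial_idx, step, env, action, obs, delta)
            step += 1
        rec.record_trial(trial_idx, trial, env)
    return rec.to_log()
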