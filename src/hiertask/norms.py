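"""Myopic active-sensing policies: probability gain, information gain,
impact.

Each candidate action is scored by the expected change it induces in the
target belief B(T|E,V): the expected increase of the posterior maximum
(probability gain), the expected entropy reduction (information gain), or
the expected summed absolute belief change (impact). Leaf queries have two
outcomes weighted by B(T) and 1−B(T); internal queries require an
expectation over the evidence pulse, whose marginal density is a
10-component Gaussian mixture weighted by P(c|d,E_i)·P_i(d|E,V), evaluated
by deterministic trapezoid quadrature. None of the scores reads payoffs, so
the resulting policies are payoff-insensitive by construction.
"""

from __future__ import annotations

import numpy as np

from .beliefs import BeliefState, init_beliefs
from .task import (COHERENCES, EvidenceParams, Payoffs, SessionRecorder,
                   TreeSpec, TrialEnv, sample_trial)

NORMS = ("pg", "ig", "impact")

#: Quadrature resolution for internal-node expectations.
QUAD_POINTS = 401


def _entropy_bits(p: np.ndarray, axis=-1) -> np.ndarray:
    q = np.where(p > 0, p, 1.0)
    return -(np.where(p > 0, p, 0.0) * np.log2(q)).sum(axis=axis)


def observation_likelihood(belief: BeliefState, node: int,
                           n_points: int = QUAD_POINTS):
    """Predictive distribution of the observation from querying ``node``.

    For a leaf T, returns the two-outcome probabilities
    (B(T|E,V), 1−B(T|E,V)). For an internal node, returns (grid, density):
    the mixture density over the evidence pulse on a uniform quadrature
    grid, with mixture weights P(c|d,E_i)·P_i(d|E,V) (the direction
    marginal conditioned on past leaf errors).
    """
    tree = belief.tree
    if tree.is_leaf(node):
        b = belief.target_beliefs()[node - tree.leaves[0]]
        return np.array([b, 1.0 - b])
    evid = belief.evid
    c = belief.coherences
    mu = evid.kappa * c * evid.t
    sd = np.sqrt(evid.t * (1.0 + c * evid.gamma))
    span = float(mu.max() + 8.0 * sd.max())
    grid = np.linspace(-span, span, n_points)
    pd_cond = belief.conditional_direction_marginal(node)      # (2,)
    pc_d = belief.coherence_given_direction(node)              # (nc, 2)
    w = pc_d * pd_cond[None, :]                                # (nc, 2)
    # component means ±mu; column 0 leftward
    comp = np.stack([-mu, mu], axis=1)                         # (nc, 2)
    dens = np.einsum(
        "cd,gcd->g", w,
        np.exp(-0.5 * ((grid[:, None, None] - comp[None]) / sd[None, :, None]) ** 2)
        / (sd[None, :, None] * np.sqrt(2 * np.pi)))
    return grid, dens


def _posterior_beliefs_on_grid(belief: BeliefState, node: int,
                               grid: np.ndarray) -> np.ndarray:
    """B(T | E ∪ {e}, V) for every grid value of a pulse at ``node``.

    Returns an (n_points, n_leaves) array. Only node's own marginal depends
    on the pulse, so the factorized product is updated in one factor.
    """
    tree = belief.tree
    i = node - 1
    c = belief.coherences
    evid = belief.evid
    mu = evid.kappa * c * evid.t
    sd = np.sqrt(evid.t * (1.0 + c * evid.gamma))
    comp = np.stack([-mu, mu], axis=1)
    like = np.exp(-0.5 * ((grid[:, None, None] - comp[None]) / sd[None, :, None]) ** 2) \
        / (sd[None, :, None] * np.sqrt(2 * np.pi))              # (G, nc, 2)
    post = like * belief.tables[i][None]
    post /= post.sum(axis=(1, 2), keepdims=True)
    m_new = post.sum(axis=1)                                    # (G, 2)

    m = belief.direction_marginals()
    factors = m[tree.leaf_anc, tree.leaf_dir]                   # (L, depth)
    anc_pos = {}
    for j, anc_row in enumerate(tree.leaf_anc):
        pos = np.flatnonzero(anc_row == i)
        anc_pos[j] = int(pos[0]) if len(pos) else -1
    B = np.empty((len(grid), tree.n_leaves))
    for j in range(tree.n_leaves):
        k = anc_pos[j]
        if k < 0:
            B[:, j] = factors[j].prod()
        else:
            excl = np.delete(factors[j], k).prod()
            B[:, j] = excl * m_new[:, tree.leaf_dir[j, k]]
    for leaf in belief.visited:
        B[:, leaf - tree.leaves[0]] = 0.0
    B /= np.maximum(B.sum(axis=1, keepdims=True), 1e-300)
    return B


def score(norm: str, belief: BeliefState, action: int,
          n_points: int = QUAD_POINTS) -> float:
    """Score of one candidate action under a sampling norm."""
    if norm not in NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    tree = belief.tree
    B0 = belief.target_beliefs()
    if tree.is_leaf(action):
        j = action - tree.leaves[0]
        b = B0[j]
        # outcome 1: target found -> belief degenerate at action
        B_hit = np.zeros_like(B0)
        B_hit[j] = 1.0
        # outcome 2: error -> zero and renormalize
        B_miss = B0.copy()
        B_miss[j] = 0.0
        tot = B_miss.sum()
        B_miss = B_miss / tot if tot > 0 else B_miss
        if b >= 1.0 - 1e-15:
            return 0.0  # belief already degenerate here: nothing can change
        outcomes = [(b, B_hit), (1.0 - b, B_miss)]
        if norm == "pg":
            return float(sum(w * Bn.max() for w, Bn in outcomes) - B0.max())
        if norm == "ig":
            h0 = _entropy_bits(B0)
            return float(h0 - sum(w * _entropy_bits(Bn) for w, Bn in outcomes))
        return float(sum(w * np.abs(Bn - B0).sum() for w, Bn in outcomes))
    grid, dens = observation_likelihood(belief, action, n_points)
    wts = np.gradient(grid) * dens
    wts /= wts.sum()
    Bn = _posterior_beliefs_on_grid(belief, action, grid)       # (G, L)
    if norm == "pg":
        return float(wts @ Bn.max(axis=1) - B0.max())
    if norm == "ig":
        return float(_entropy_bits(B0) - wts @ _entropy_bits(Bn, axis=1))
    return float(wts @ np.abs(Bn - B0[None, :]).sum(axis=1))


def score_all(norm: str, belief: BeliefState,
              n_points: int = QUAD_POINTS) -> dict:
    """Scores for every internal node and unvisited leaf."""
    tree = belief.tree
    acts = list(tree.internal_nodes) + [T for T in tree.leaves
                                        if T not in belief.visited]
    return {a: score(norm, belief, a, n_points) for a in acts}


def run_norm_agent(norm: str, n_trials: int, rng: np.random.Generator,
                   tree: TreeSpec | None = None,
                   evid: EvidenceParams | None = None,
                   payoffs: Payoffs | None = None,
                   coherences=COHERENCES, subject: str | None = None,
                   max_actions: int = 400):
    """Simulate the greedy policy of a sampling norm.

    At each step the argmax-score action is executed; ties (within 1e-12
    relative) are broken uniformly at random with the session rng.
    """
    tree = tree or TreeSpec()
    evid = evid or EvidenceParams()
    payoffs = payoffs or Payoffs()
    rec = SessionRecorder(subject or norm, meta={"agent": norm})
    for trial_idx in range(n_trials):
        trial = sample_trial(tree, rng, coherences)
        env = TrialEnv(trial, payoffs, evid, rng)
        belief = init_beliefs(tree, evid, coherences)
        step, done = 0, False
        while not done and step < max_actions:
            scores = score_all(norm, belief)
            vals = np.array(list(scores.values()))
            best = vals.max()
            tol = 1e-12 * max(1.0, abs(best))
            ties = [a for a, v in scores.items() if v >= best - tol]
            # when leaves are among the top-scored actions, stay among
            # them: with no information to gain (all-zero scores at a
            # resolved belief) the policy exploits rather than queries
            leaf_ties = [a for a in ties if tree.is_leaf(a)]
            pool = leaf_ties or ties
            action = int(pool[rng.integers(len(pool))])
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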