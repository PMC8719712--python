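"""Detection-model querying plus confidence-based blame assignment.

The agent explores top-down following the detection model's rules (query,
compare the pulse to the collapsing criterion, re-query or descend). After
an error at a leaf it assigns blame among the three error-path decisions by
comparing their choice confidences — the posterior probability, from the
last pulse at each node under a uniform (c, d) prior, that the direction
leading to the wrong leaf was correct:

* if at least two eligible error-path decisions were made with confidence
  below the threshold ω, the highest-level one is blamed and re-queried
  (an *on-path* query);
* otherwise the least-confident eligible decision is blamed and its child
  off the error path is queried next (an *off-path* query);
* a blamed node becomes ineligible until new evidence is obtained from it;
  if no error-path node is eligible, a random unvisited leaf is chosen
  (a *fallback*, always directed at a leaf).

The agent remembers visited leaves and never queries one twice: a level-3
choice that points at a known-wrong leaf is treated as that error without
charging the leaf cost. ω is the model's only free parameter; it is fitted
by matching the proportion of on-path queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beliefs import confidence
from .detection import DetectionParams
from .task import (COHERENCES, Payoffs, SessionLog, SessionRecorder,
                   TreeSpec, TrialEnv, sample_trial)


@dataclass(frozen=True)
class HeuristicParams:
    """Detection parameters plus the confidence threshold ω."""

    omega: float = 0.92
    detection: DetectionParams = field(default_factory=DetectionParams)

    def __post_init__(self):
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must lie in [0, 1]")


def assign_blame(tree: TreeSpec, error_leaf: int, confidences: dict,
                 eligibility: dict, omega: float, rng: np.random.Generator,
                 visited: set):
    """Blame one error-path decision and choose the next query.

    ``confidences`` maps internal node -> confidence that the direction
    toward ``error_leaf`` was correct (0.5 where the node was never
    queried). Returns (blamed_node_or_None, next_query, path_type) with
    path_type in {"on", "off", "fallback"}.
    """
    path = tree.ancestors[error_leaf]
    eligible = [a for a in path if eligibility.get(a, True)]
    if not eligible:
        unvisited = [T for T in tree.leaves if T not in visited]
        nxt = int(unvisited[rng.integers(len(unvisited))])
        return None, nxt, "fallback"
    low = [a for a in eligible if confidences.get(a, 0.5) < omega]
    if len(low) >= 2:
        blamed = min(low, key=lambda a: tree.level[a])  # highest tree level
        return blamed, blamed, "on"
    blamed = min(eligible, key=lambda a: confidences.get(a, 0.5))
    nxt = tree.counterfactual[error_leaf][blamed]
    return blamed, nxt, "off"


def run_heuristic_agent(params: HeuristicParams, n_trials: int,
                        rng: np.random.Generator,
                        tree: TreeSpec | None = None,
                        payoffs: Payoffs | None = None,
                        coherences=COHERENCES, subject: str = "heuristic",
                        max_actions: int = 1000,
                        record: bool = True) -> SessionLog:
    """Simulate full sessions of the heuristic agent.

    The log records, on each post-error action row, the path type
    (on/off/fallback) and the blamed node in canonical numbering; synthetic
    errors (level-3 choices pointing at known-wrong leaves) appear as
    zero-cost rows with feedback ``"synthetic"``.
    """
    tree = tree or TreeSpec()
    payoffs = payoffs or Payoffs()
    det = params.detection
    evid = det.evidence
    rec = SessionRecorder(subject, meta={"agent": "heuristic",
                                         "omega": params.omega})
    if not record:
        rec.record_step = lambda *a, **k: None
        rec.rows = _NullList()
    n_on = n_off = n_fallback = n_errors = 0
    for trial_idx in range(n_trials):
        trial = sample_trial(tree, rng, coherences)
        env = TrialEnv(trial, payoffs, evid, rng)
        conf_right: dict[int, float] = {}   # confidence in a rightward choice
        eligibility: dict[int, bool] = {}
        step = 0
        done = False
        pending = 1  # next node to act on (root to start)
        # annotation for the row that executes a post-error decision
        path_type, blamed_canon = None, None
        while not done and step < max_actions:
            node = pending
            if tree.is_leaf(node):
                if node in env.visited:
                    # synthetic error: known-wrong leaf, no query, no cost
                    n_errors += 1
                    blamed, nxt, ptype = _blame_step(
                        tree, node, conf_right, eligibility, params.omega,
                        rng, env.visited)
                    rec.rows.append(_synthetic_row(rec.subject, trial_idx,
                                                   step, trial, tree, node,
                                                   env, path_type,
                                                   blamed_canon))
                    step += 1
                    n_on, n_off, n_fallback = _tally(ptype, n_on, n_off,
                                                     n_fallback)
                    path_type = ptype
                    blamed_canon = trial.canon[blamed] if blamed else -1
                    pending = nxt
                    continue
                obs, delta, done = env.step(node)
                rec.record_step(trial_idx, step, env, node, obs, delta,
                                path_type=path_type, blamed=blamed_canon)
                path_type, blamed_canon = None, None
                step += 1
                if obs == "negative":
                    n_errors += 1
                    blamed, nxt, ptype = _blame_step(
                        tree, node, conf_right, eligibility, params.omega,
                        rng, env.visited)
                    n_on, n_off, n_fallback = _tally(ptype, n_on, n_off,
                                                     n_fallback)
                    path_type = ptype
                    blamed_canon = trial.canon[blamed] if blamed else -1
                    pending = nxt
                continue
            # internal node: detection streak until the pulse clears ±Φ
            choice = None
            while choice is None and step < max_actions:
                obs, delta, _ = env.step(node)
                rec.record_step(trial_idx, step, env, node, obs, delta,
                                path_type=path_type, blamed=blamed_canon)
                path_type, blamed_canon = None, None
                step += 1
                phi = det.phi[tree.level[node] - 1] * \
                    (1.0 + np.exp(-det.lam * env.n_q))
                if obs > phi:
                    choice = +1
                elif obs < -phi:
                    choice = -1
            if choice is None:
                break
            conf_right[node] = confidence(obs, evid, +1, coherences)
            eligibility[node] = True  # fresh evidence restores blameability
            pending = tree.child_toward(node, choice)
        rec.record_trial(trial_idx, trial, env)
    rec.meta.update({"n_errors": n_errors, "n_on": n_on, "n_off": n_off,
                     "n_fallback": n_fallback,
                     "p_on": n_on / n_errors if n_errors else np.nan})
    return rec.to_log()


def _blame_step(tree, error_leaf, conf_right, eligibility, omega, rng,
                visited):
    # confidence in the direction that leads to the error leaf
    confs = {}
    for k, a in enumerate(tree.ancestors[error_leaf]):
        if a in conf_right:
            d_to_leaf = tree.leaf_dir[error_leaf - tree.leaves[0], k]
            confs[a] = conf_right[a] if d_to_leaf == 1 else 1.0 - conf_right[a]
    blamed, nxt, ptype = assign_blame(tree, error_leaf, confs, eligibility,
                                      omega, rng, visited)
    if blamed is not None:
        eligibility[blamed] = False
    return blamed, nxt, ptype


def _tally(ptype, n_on, n_off, n_fb):
    return (n_on + (ptype == "on"), n_off + (ptype == "off"),
            n_fb + (ptype == "fallback"))


def _synthetic_row(subject, trial_idx, step, trial, tree, leaf, env,
                   path_type=None, blamed_canon=None):
    return {"subject": subject, "trial": trial_idx, "step": step,
            "node": leaf, "node_canon": trial.canon[leaf],
            "level": tree.level[leaf], "c": np.nan, "d": np.nan,
            "e": np.nan, "feedback": "synthetic", "points": 0.0,
            "n_q": 0, "visited": ";".join(map(str, sorted(env.visited))),
            "path_type": path_type if path_type is not None else "",
            "blamed_canon": blamed_canon if blamed_canon is not None else -1}


def p_on_path(log: SessionLog) -> float:
    """Proportion of on-path post-error queries (on / all errors)."""
    meta = log.meta
    if "n_errors" in meta and meta["n_errors"]:
        return meta["n_on"] / meta["n_errors"]
    q = log.queries
    errors = q["feedback"].isin(["negative", "synthetic"]).sum()
    n_on = (q["path_type"] == "on").sum()
    return n_on / errors if errors else np.nan


def fit_omega(observed_p_on: float, det: DetectionParams,
              n_trials: int = 20000, seed: int = 0,
              coarse: int = 25, fine: int = 25,
              tree: TreeSpec | None = None) -> tuple[float, float]:
    """Fit ω by matching the on-path proportion of simulated sessions.

    Two-stage grid search (coarse over (0, 1), then refined around the
    coarse minimizer) with common random numbers: every evaluation re-seeds
    the simulator identically so the objective |p_on(ω) − target| is a
    deterministic, near-monotone function of ω. Returns (ω̂, err).
    """
    if not (0.0 <= observed_p_on <= 1.0):
        raise ValueError("observed_p_on must be in [0, 1]")

    def err(omega):
        log = run_heuristic_agent(HeuristicParams(omega, det), n_trials,
                                  np.random.default_rng(seed), tree=tree)
        return abs(p_on_path(log) - observed_p_on)

    grid = np.linspace(0.0, 1.0, coarse)
    errs = [err(w) for w in grid]
    k = int(np.argmin(errs))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, coarse - 1)]
    grid2 = np.linspace(lo, hi, fine)
    errs2 = [err(w) for w in grid2]
    k2 = int(np.argmin(errs2))
    best = min(errs[k], errs2[k2])
    omega = grid2[k2] if errs2[k2] <= errs[k] else grid[k]
    return float(omega), float(best)


def reward_maximizing_omega(det: DetectionParams, n_trials: int = 5000,
                            seed: int = 0, n_grid: int = 21,
                            tree: TreeSpec | None = None) -> tuple[float, float]:
    """Scan ω for maximum mean reward (common random numbers)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    rewards = []
    for w in grid:
        log = run_heuristic_agent(HeuristicParams(w, det), n_trials,
                                  np.random.default_rng(seed), tree=tree)
        rewards.append(log.trials["reward"].mean())
    k = int(np.argmax(rewards))
    return float(grid[k]), float(rewards[k])


class _NullList(list):
    """Swallows appends when step recording is disabled."""

    def append(self, item):  # noqa: D401
        pass
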