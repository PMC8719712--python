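"""Binary decision-tree search task with noisy motion queries.

The task: a target is hidden at one of the leaves of a complete binary tree.
Each internal node carries a latent direction of motion (left/right) and a
motion strength (coherence). Querying an internal node costs points and
returns one noisy scalar evidence pulse; choosing a wrong leaf costs points
and reveals only that it was wrong; finding the target ends the trial with a
positive reward. The target is the leaf reached by following the true
direction at every bifurcation from the root.

Everything here is simulated in *spatial* coordinates (heap numbering,
children of node i are 2i (left) and 2i+1 (right)). The target-relative
*canonical* numbering used for analysis (target relabeled to the highest
leaf id, its path to (1, 3, 7) on the default depth-3 tree) is a per-trial
bijection available from :class:`TrialState`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Motion strengths used in the task, as proportions of coherently moving dots.
COHERENCES = (0.032, 0.064, 0.128, 0.256, 0.512)

#: Duration of one motion pulse in seconds.
PULSE_DURATION_S = 0.227

LEFT, RIGHT = -1, +1


# ---------------------------------------------------------------------------
# Tree geometry
# ---------------------------------------------------------------------------

class TreeSpec:
    """Complete binary tree in heap order, with path/ancestor bookkeeping.

    Parameters
    ----------
    depth : int
        Number of internal levels. The default task has depth 3: internal
        nodes 1-7 on levels 1-3, leaves 8-15 on level 4.
    """

    def __init__(self, depth: int = 3):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        self.internal_nodes = tuple(range(1, 2 ** depth))
        self.leaves = tuple(range(2 ** depth, 2 ** (depth + 1)))
        self.n_internal = len(self.internal_nodes)
        self.n_leaves = len(self.leaves)
        self.all_nodes = self.internal_nodes + self.leaves
        self.level = {i: i.bit_length() for i in self.all_nodes}
        self.children = {i: (2 * i, 2 * i + 1) for i in self.internal_nodes}
        # ancestors(leaf): the internal nodes from level 1 down to level depth
        # on the path from the root to that leaf.
        self.ancestors = {
            T: tuple(T >> k for k in range(depth, 0, -1)) for T in self.leaves
        }
        # counterfactual child: for a node on the error path of leaf T, its
        # child that is *not* on the path to T (flip the last bit of the
        # on-path child).
        self.counterfactual = {
            T: {a: (T >> (depth - self.level[a])) ^ 1 for a in self.ancestors[T]}
            for T in self.leaves
        }
        # Vectorized lookups for belief computations: for leaf index j,
        # leaf_anc[j, k] is the 0-based internal index of its level-(k+1)
        # ancestor and leaf_dir[j, k] in {0, 1} the direction (0=left,
        # 1=right) taken at that ancestor toward the leaf.
        self.leaf_anc = np.array(
            [[a - 1 for a in self.ancestors[T]] for T in self.leaves], dtype=np.intp
        )
        self.leaf_dir = np.array(
            [[(T >> (depth - self.level[a])) & 1 for a in self.ancestors[T]]
             for T in self.leaves],
            dtype=np.intp,
        )

    def child_toward(self, node: int, d: int) -> int:
        """Child of an internal node in direction ``d`` (−1 left, +1 right)."""
        return 2 * node + (1 if d == RIGHT else 0)

    def is_leaf(self, node: int) -> bool:
        return node >= 2 ** self.depth

    def n_states(self, n_per_node: int = len(COHERENCES) * 2) -> int:
        """Number of latent problem states (per-node states ** internal nodes)."""
        return n_per_node ** self.n_internal


def build_tree(depth: int = 3) -> TreeSpec:
    """Build the task's decision tree (default: 3 internal levels, 8 leaves)."""
    return TreeSpec(depth)


# ---------------------------------------------------------------------------
# Payoffs and evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Payoffs:
    """Point values of the three event types, as positive magnitudes.

    ``internal_mult`` and ``requery_mult`` scale the cost of internal-node
    queries (all of them, and immediate re-queries specifically) for the
    cheap-sampling planner variants; both default to 1 (standard payoffs).
    """

    query: float = 1.0
    wrong_leaf: float = 3.0
    target: float = 10.0
    internal_mult: float = 1.0
    requery_mult: float = 1.0

    def __post_init__(self):
        if min(self.query, self.wrong_leaf, self.target) <= 0:
            raise ValueError("payoff magnitudes must be positive")
        if not (0 < self.internal_mult <= 1 and 0 < self.requery_mult <= 1):
            raise ValueError("cost multipliers must lie in (0, 1]")

    def query_cost(self, is_requery: bool = False) -> float:
        m = self.requery_mult if is_requery else self.internal_mult
        return self.query * m


PAYOFF_VARIANTS = {
    "standard": Payoffs(),
    "cheap30": Payoffs(internal_mult=0.3, requery_mult=0.3),
    "requery5": Payoffs(internal_mult=0.5, requery_mult=0.05),
}


@dataclass(frozen=True)
class EvidenceParams:
    """Sensory parameters of the momentary-evidence distribution.

    A pulse from a node with coherence ``c`` and direction ``d`` is Gaussian
    with mean κ·d·c·t and variance t·(1+c·γ), where t is the pulse duration.
    """

    kappa: float = 16.0
    gamma: float = 1.5
    t: float = PULSE_DURATION_S

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma < 0 or self.t <= 0:
            raise ValueError("gamma must be >= 0 and t > 0")

    def mean(self, c, d):
        return self.kappa * np.asarray(d) * np.asarray(c) * self.t

    def sd(self, c):
        return np.sqrt(self.t * (1.0 + np.asarray(c) * self.gamma))


def sample_evidence(c, d, evid: EvidenceParams, rng: np.random.Generator):
    """Draw one evidence pulse e ~ N(κ·d·c·t, t(1+cγ))."""
    if np.any(np.asarray(c) < 0):
        raise ValueError("coherence must be nonnegative")
    return rng.normal(evid.mean(c, d), evid.sd(c))


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass
class TrialState:
    """Ground truth of one trial: per-internal-node coherence and direction.

    ``coherence`` and ``direction`` map spatial internal node id -> value.
    ``target`` is the spatial id of the target leaf. ``canon``/``inv_canon``
    are the spatial<->canonical relabelings under which the target becomes
    the highest-numbered leaf (computed lazily; they are analysis-time
    conveniences, not part of the simulated world).
    """

    tree: TreeSpec
    coherence: dict
    direction: dict
    target: int = field(init=False)

    def __post_init__(self):
        node = 1
        for _ in range(self.tree.depth):
            node = self.tree.child_toward(node, self.direction[node])
        self.target = node
        self._canon = None

    @property
    def canon(self) -> dict:
        if self._canon is None:
            self._canon = _canonical_map(self.tree, self.direction)
        return self._canon

    @property
    def inv_canon(self) -> dict:
        return {v: k for k, v in self.canon.items()}


def _canonical_map(tree: TreeSpec, direction: dict) -> dict:
    """Relabel nodes so the true direction reads 'rightward' everywhere.

    At each internal node the child in the true direction receives the
    right-child label; the target therefore maps to the highest leaf id and
    its path to the right spine of the tree.
    """
    canon = {1: 1}
    stack = [1]
    while stack:
        s = stack.pop()
        if tree.is_leaf(s):
            continue
        m = canon[s]
        c_true = tree.child_toward(s, direction[s])
        c_other = c_true ^ 1
        canon[c_other] = 2 * m
        canon[c_true] = 2 * m + 1
        stack.extend(tree.children[s])
    return canon


def sample_trial(tree: TreeSpec, rng: np.random.Generator,
                 coherences=COHERENCES) -> TrialState:
    """Draw a trial: i.i.d. uniform coherence and direction at every node."""
    if len(coherences) == 0:
        raise ValueError("coherence list must be nonempty")
    if np.any(np.asarray(coherences) < 0):
        raise ValueError("invalid coherence values")
    coh = {i: float(rng.choice(coherences)) for i in tree.internal_nodes}
    dirn = {i: int(rng.choice((LEFT, RIGHT))) for i in tree.internal_nodes}
    return TrialState(tree, coh, dirn)


class TrialEnv:
    """Stateful wrapper around one trial: stepping, payoffs, bookkeeping."""

    def __init__(self, trial: TrialState, payoffs: Payoffs,
                 evid: EvidenceParams, rng: np.random.Generator,
                 allow_leaf_revisit: bool = False):
        self.trial = trial
        self.tree = trial.tree
        self.payoffs = payoffs
        self.evid = evid
        self.rng = rng
        self.allow_leaf_revisit = allow_leaf_revisit
        self.visited: set[int] = set()   # wrong leaves queried so far
        self.done = False
        self.last_action: int | None = None
        self.n_q = 0                      # streak counter at last_action
        self.points = 0.0
        self.n_internal_queries = 0
        self.n_leaf_errors = 0
        # evidence moments per internal node, precomputed for the hot loop
        self._mu = {i: float(evid.mean(trial.coherence[i], trial.direction[i]))
                    for i in self.tree.internal_nodes}
        self._sd = {i: float(evid.sd(trial.coherence[i]))
                    for i in self.tree.internal_nodes}

    def step(self, action: int):
        """Execute an action. Returns (observation, points_delta, done).

        The observation is an evidence float for internal queries, or one of
        the feedback strings ``"negative"`` / ``"target"`` for leaves.
        """
        if self.done:
            raise RuntimeError("trial already terminated")
        if action not in self.tree.all_nodes:
            raise ValueError(f"invalid node id {action}")
        tree = self.tree
        if tree.is_leaf(action):
            if action in self.visited and not self.allow_leaf_revisit:
                raise ValueError(f"leaf {action} already known to be wrong")
            self.last_action, self.n_q = action, 0
            if action == self.trial.target:
                self.done = True
                delta = self.payoffs.target
                self.points += delta
                return "target", delta, True
            self.visited.add(action)
            self.n_leaf_errors += 1
            delta = -self.payoffs.wrong_leaf
            self.points += delta
            return "negative", delta, False
        # internal query
        is_requery = action == self.last_action
        self.n_q = self.n_q + 1 if is_requery else 0
        self.last_action = action
        self.n_internal_queries += 1
        e = float(self.rng.normal(self._mu[action], self._sd[action]))
        delta = -self.payoffs.query_cost(is_requery)
        self.points += delta
        return e, delta, False


# ---------------------------------------------------------------------------
# Session logs
# ---------------------------------------------------------------------------

QUERY_COLUMNS = [
    "subject", "trial", "step", "node", "node_canon", "level", "c", "d",
    "e", "feedback", "points", "n_q", "visited", "path_type", "blamed_canon",
]


class SessionLog:
    """Ordered per-query records plus per-trial ground truth.

    ``queries`` has one row per action (see :data:`QUERY_COLUMNS`);
    ``trials`` has one row per trial with the canonical-order coherences and
    directions of the internal nodes and the trial reward. ``meta`` carries
    the generating configuration and seed.
    """

    def __init__(self, queries: pd.DataFrame, trials: pd.DataFrame, meta: dict):
        self.queries = queries.reset_index(drop=True)
        self.trials = trials.reset_index(drop=True)
        self.meta = dict(meta)

    def __len__(self):
        return len(self.queries)

    @property
    def n_trials(self):
        return len(self.trials)

    def save(self, prefix: str):
        """Write ``<prefix>_queries.csv``, ``<prefix>_trials.csv`` and
        ``<prefix>_meta.json``."""
        self.queries.to_csv(f"{prefix}_queries.csv", index=False)
        self.trials.to_csv(f"{prefix}_trials.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, prefix: str) -> "SessionLog":
        queries = pd.read_csv(f"{prefix}_queries.csv")
        for col in ("visited", "path_type"):
            if col in queries:
                queries[col] = queries[col].fillna("").astype(str)
        trials = pd.read_csv(f"{prefix}_trials.csv")
        try:
            with open(f"{prefix}_meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(queries, trials, meta)

    @classmethod
    def concat(cls, logs) -> "SessionLog":
        logs = list(logs)
        return cls(pd.concat([lg.queries for lg in logs], ignore_index=True),
                   pd.concat([lg.trials for lg in logs], ignore_index=True),
                   {"concatenated": [lg.meta for lg in logs]})


class SessionRecorder:
    """Accumulates rows for a :class:`SessionLog` during simulation."""

    def __init__(self, subject, meta=None):
        self.subject = subject
        self.rows = []
        self.trial_rows = []
        self.meta = meta or {}

    def record_step(self, trial_idx, step_idx, env: TrialEnv, action, obs,
                    delta, path_type=None, blamed=None):
        trial = env.trial
        tree = env.tree
        is_leaf = tree.is_leaf(action)
        self.rows.append({
            "subject": self.subject,
            "trial": trial_idx,
            "step": step_idx,
            "node": action,
            "node_canon": trial.canon[action],
            "level": tree.level[action],
            "c": np.nan if is_leaf else trial.coherence[action],
            "d": np.nan if is_leaf else trial.direction[action],
            "e": obs if not is_leaf else np.nan,
            "feedback": obs if is_leaf else "none",
            "points": delta,
            "n_q": env.n_q,
            "visited": ";".join(map(str, sorted(env.visited))),
            "path_type": path_type if path_type is not None else "",
            "blamed_canon": blamed if blamed is not None else -1,
        })

    def record_trial(self, trial_idx, trial: TrialState, env: TrialEnv):
        row = {"subject": self.subject, "trial": trial_idx,
               "reward": env.points,
               "n_internal_queries": env.n_internal_queries,
               "n_leaf_errors": env.n_leaf_errors,
               "target_canon": trial.canon[trial.target]}
        for i in trial.tree.internal_nodes:
            s = trial.inv_canon[i]
            row[f"c{i}"] = trial.coherence[s]
            row[f"d{i}"] = trial.direction[s]
        self.trial_rows.append(row)

    def to_log(self) -> SessionLog:
        cols = QUERY_COLUMNS
        queries = pd.DataFrame(self.rows, columns=cols)
        trials = pd.DataFrame(self.trial_rows)
        return SessionLog(queries, trials, self.meta)


def expected_random_leaf_reward(tree: TreeSpec, payoffs: Payoffs) -> float:
    """Expected reward of the no-query policy that picks unvisited leaves
    uniformly at random until hitting the target.

    Computed by enumeration: with the target uniform over the N leaves and
    the draw order uniform, the target appears at position k with
    probability 1/N, incurring k−1 wrong-leaf penalties.
    """
    n = tree.n_leaves
    expected_wrong = sum((k - 1) / n for k in range(1, n + 1))
    return payoffs.target - payoffs.wrong_leaf * expected_wrong


def simulate_random_leaf_policy(tree: TreeSpec, payoffs: Payoffs,
                                n_trials: int, rng: np.random.Generator) -> float:
    """Monte-Carlo mean reward of uniform random leaf search (no queries)."""
    n = tree.n_leaves
    # target position within a uniformly random draw order is uniform on 1..n
    positions = rng.integers(1, n + 1, size=n_trials)
    rewards = payoffs.target - payoffs.wrong_leaf * (positions - 1)
    return float(np.mean(rewards))
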