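"""Exact discrete Bayesian inference over the task's latent state.

The latent state is the (coherence, direction) pair at each internal node;
with 5 coherences, 2 directions and 7 internal nodes the default task has
10^7 states. Before any leaf error the posterior factorizes over nodes.
Leaf feedback conditions on a collider (the implied target), coupling the
otherwise independent per-node direction marginals: the engine handles this
by eliminating every direction combination whose implied target is a
visited wrong leaf and renormalizing.

Because the direction combinations partition exactly by their implied
target, the renormalized target belief reduces to the factorized product of
ancestor direction-marginals, zeroed on visited leaves and renormalized;
the engine uses that closed form, and also exposes the explicit
2^n-combination enumeration so the equivalence can be verified directly.
"""

from __future__ import annotations

import numpy as np

from .task import COHERENCES, EvidenceParams, TreeSpec

_SQRT2PI = np.sqrt(2.0 * np.pi)


def gaussian_likelihood_table(e: float, evid: EvidenceParams,
                              coherences=COHERENCES) -> np.ndarray:
    """Likelihood N(e; μ_{c,d}, σ_c) over the (coherence × direction) grid.

    Returns an array of shape (n_coherences, 2); column 0 is leftward
    (d = −1), column 1 rightward (d = +1).
    """
    c = np.asarray(coherences, float)
    mu = evid.kappa * c * evid.t          # rightward mean, leftward is −mu
    sd = np.sqrt(evid.t * (1.0 + c * evid.gamma))
    like = np.empty((len(c), 2))
    like[:, 1] = np.exp(-0.5 * ((e - mu) / sd) ** 2) / (sd * _SQRT2PI)
    like[:, 0] = np.exp(-0.5 * ((e + mu) / sd) ** 2) / (sd * _SQRT2PI)
    return like


def confidence(last_e: float, evid: EvidenceParams, chosen_direction: int,
               coherences=COHERENCES, prior: np.ndarray | None = None) -> float:
    """Posterior probability that the chosen direction is correct, given
    only the last evidence sample.

    The default prior is uniform over the (coherence, direction) grid, as
    the heuristic agent assumes; an accumulated posterior table may be
    passed instead.
    """
    like = gaussian_likelihood_table(last_e, evid, coherences)
    w = like if prior is None else like * prior
    total = w.sum()
    if total <= 0:
        return 0.5
    conf_right = w[:, 1].sum() / total
    return float(conf_right if chosen_direction > 0 else 1.0 - conf_right)


class BeliefState:
    """Per-node posteriors, visited-leaf set, and target beliefs.

    ``tables[i]`` is the (n_coherences, 2) posterior P_i(c, d | E_i) of the
    internal node with spatial id ``i+1`` (column 0 = leftward). ``visited``
    holds the spatial ids of leaves known not to be the target.
    """

    def __init__(self, tree: TreeSpec, evid: EvidenceParams,
                 coherences=COHERENCES):
        self.tree = tree
        self.evid = evid
        self.coherences = np.asarray(coherences, float)
        n, nc = tree.n_internal, len(self.coherences)
        self.tables = np.full((n, nc, 2), 1.0 / (nc * 2))
        self.history: list[list[float]] = [[] for _ in range(n)]
        self.visited: set[int] = set()
        # per-leaf ancestor structure for vectorized marginals
        self._anc_mask = np.zeros((tree.n_leaves, n), dtype=bool)
        self._anc_dir = np.zeros((tree.n_leaves, n), dtype=np.intp)
        rows = np.arange(tree.n_leaves)[:, None]
        self._anc_mask[rows, tree.leaf_anc] = True
        self._anc_dir[rows, tree.leaf_anc] = tree.leaf_dir

    # -- state management ---------------------------------------------------

    def copy(self) -> "BeliefState":
        new = object.__new__(BeliefState)
        new.tree, new.evid, new.coherences = self.tree, self.evid, self.coherences
        new.tables = self.tables.copy()
        new.history = [list(h) for h in self.history]
        new.visited = set(self.visited)
        new._anc_mask, new._anc_dir = self._anc_mask, self._anc_dir
        return new

    def update(self, node: int, e: float) -> None:
        """Bayes update of node ``node``'s table with evidence sample ``e``."""
        if self.tree.is_leaf(node):
            raise ValueError("evidence updates apply to internal nodes")
        i = node - 1
        like = gaussian_likelihood_table(e, self.evid, self.coherences)
        post = self.tables[i] * like
        self.tables[i] = post / post.sum()
        self.history[i].append(float(e))

    def add_visited(self, leaf: int) -> None:
        if not self.tree.is_leaf(leaf):
            raise ValueError(f"{leaf} is not a leaf")
        self.visited.add(leaf)

    # -- marginals and target beliefs ---------------------------------------

    def direction_marginals(self) -> np.ndarray:
        """P_i(d | E_i), shape (n_internal, 2); no conditioning on errors."""
        return self.tables.sum(axis=1)

    def coherence_given_direction(self, node: int) -> np.ndarray:
        """P(c | d, E_i), columns over direction; shape (n_coherences, 2)."""
        t = self.tables[node - 1]
        colsum = t.sum(axis=0, keepdims=True)
        return t / np.maximum(colsum, 1e-300)

    def target_beliefs(self) -> np.ndarray:
        """B(T | E, V) over the leaves, in leaf-id order.

        Factorized ancestor product, zeroed on visited leaves, renormalized
        (equal to the explicit combination enumeration; see module doc).
        """
        m = self.direction_marginals()
        unnorm = m[self.tree.leaf_anc, self.tree.leaf_dir].prod(axis=1)
        for leaf in self.visited:
            unnorm[leaf - self.tree.leaves[0]] = 0.0
        total = unnorm.sum()
        if total <= 0.0:
            raise ValueError("all direction combinations eliminated")
        return unnorm / total

    def combination_probs(self, renormalized: bool = True):
        """Explicit enumeration over the 2^n direction combinations.

        Returns (probs, implied_target) where probs has shape (2^n,) and
        implied_target gives the target leaf id per combination. With
        ``renormalized=True``, combinations whose implied target is in the
        visited set are zeroed and the rest renormalized.
        """
        tree = self.tree
        n = tree.n_internal
        m = self.direction_marginals()
        bits = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)  # (K, n)
        probs = m[np.arange(n), bits].prod(axis=1)
        # implied target: follow the combination's directions from the root
        node = np.ones(2 ** n, dtype=np.intp)
        for _ in range(tree.depth):
            node = 2 * node + bits[np.arange(2 ** n), node - 1]
        if renormalized:
            bad = np.isin(node, list(self.visited)) if self.visited else \
                np.zeros(len(node), bool)
            probs = np.where(bad, 0.0, probs)
            total = probs.sum()
            if total <= 0:
                raise ValueError("all direction combinations eliminated")
            probs = probs / total
        return probs, node

    def conditional_direction_marginal(self, node: int) -> np.ndarray:
        """P_i(d | E, V): direction marginal conditioned on leaf errors.

        Computed by decomposing over the target: given target T, the
        directions at T's ancestors are those pointing toward T, while
        non-ancestor nodes keep their unconditioned marginals.
        """
        i = node - 1
        B = self.target_beliefs()
        m = self.direction_marginals()
        is_anc = self._anc_mask[:, i]
        p_right = float(np.sum(B * np.where(is_anc, self._anc_dir[:, i], m[i, 1])))
        return np.array([1.0 - p_right, p_right])

    def conditional_direction_marginals(self) -> np.ndarray:
        """All nodes at once; shape (n_internal, 2)."""
        B = self.target_beliefs()
        m = self.direction_marginals()
        pr = np.sum(B[:, None] * np.where(self._anc_mask, self._anc_dir,
                                          m[None, :, 1]), axis=0)
        return np.stack([1.0 - pr, pr], axis=1)

    def entropy_bits(self) -> float:
        """Shannon entropy of the target belief, in bits."""
        B = self.target_beliefs()
        nz = B[B > 0]
        return float(-(nz * np.log2(nz)).sum())


def init_beliefs(tree: TreeSpec | None = None,
                 evid: EvidenceParams | None = None,
                 coherences=COHERENCES) -> BeliefState:
    """Uniform prior beliefs: 1/(5·2) per (c, d) cell, B(T) = 1/n_leaves."""
    return BeliefState(tree or TreeSpec(), evid or EvidenceParams(), coherences)
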