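"""Descriptive and statistical analyses of session logs.

All analyses work on the canonical (target-relative) node numbering, under
which the true direction of motion reads rightward at every bifurcation,
the target is the highest-numbered leaf, and its error path is the right
spine. They apply uniformly to logs simulated by any of the package's
agents or to externally supplied logs in the same schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import COHERENCES, SessionLog, TreeSpec

POST_INTERNAL_CATEGORIES = ("correct_child", "incorrect_child", "requery",
                            "other_same_level", "other_lower_level",
                            "higher_level")
POST_ERROR_CATEGORIES = ("on", "off", "other")

_ERROR_FEEDBACK = ("negative", "synthetic")


def _nanmean(arr, axis=None):
    # all-NaN slices (e.g. nodes a subject never left) are legitimately NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(arr, axis=axis)


# ---------------------------------------------------------------------------
# Transition statistics
# ---------------------------------------------------------------------------

@dataclass
class TransitionStats:
    """Node- and level-level transition statistics.

    ``counts`` maps subject -> (n_nodes, n_nodes) count matrix M_u (index =
    canonical node id − 1); ``conditional`` maps subject -> row-normalized
    W_u(j|i); ``mean_conditional`` is the cross-subject mean W(j|i).
    ``level_pre``/``level_post`` are the cross-subject mean normalized
    level-transition matrices before/after the first leaf error of a trial.
    """

    counts: dict
    conditional: dict
    mean_conditional: np.ndarray
    level_pre: np.ndarray
    level_post: np.ndarray
    node_display_threshold: float = 0.075
    level_display_threshold: float = 0.05


def transition_stats(log: SessionLog, tree: TreeSpec | None = None) -> TransitionStats:
    tree = tree or TreeSpec()
    q = log.queries
    if len(q) == 0:
        raise ValueError("empty log")
    q = q[q["feedback"] != "synthetic"]
    n = len(tree.all_nodes)
    counts, conds = {}, {}
    level_pre_list, level_post_list = [], []
    for subj, sq in q.groupby("subject"):
        M = np.zeros((n, n))
        lv_pre = np.zeros((tree.depth + 1, tree.depth + 1))
        lv_post = np.zeros_like(lv_pre)
        for _, tq in sq.groupby("trial"):
            nodes = tq["node_canon"].to_numpy(int)
            fb = tq["feedback"].to_numpy()
            errored = np.cumsum(fb == "negative") > 0
            for t in range(len(nodes) - 1):
                i, j = nodes[t] - 1, nodes[t + 1] - 1
                M[i, j] += 1
                li = tree.level[nodes[t]] - 1
                lj = tree.level[nodes[t + 1]] - 1
                (lv_post if errored[t] else lv_pre)[li, lj] += 1
        counts[subj] = M
        with np.errstate(invalid="ignore", divide="ignore"):
            W = M / M.sum(axis=1, keepdims=True)
        conds[subj] = W
        for lv, acc in ((lv_pre, level_pre_list), (lv_post, level_post_list)):
            tot = lv.sum()
            acc.append(lv / tot if tot > 0 else np.full_like(lv, np.nan))
    meanW = _nanmean(np.stack(list(conds.values())), axis=0)
    return TransitionStats(counts, conds, meanW,
                           _nanmean(np.stack(level_pre_list), axis=0),
                           _nanmean(np.stack(level_post_list), axis=0))


# ---------------------------------------------------------------------------
# Action classification
# ---------------------------------------------------------------------------

def classify_actions(log: SessionLog, tree: TreeSpec | None = None) -> pd.DataFrame:
    """Classify every action by what preceded it.

    Actions following an internal-node query get one of the six child/level
    categories; actions following a leaf error get on-path / off-path /
    other. Returns one row per classified action with columns (subject,
    trial, step, context, category, node_canon, prev_canon).
    """
    tree = tree or TreeSpec()
    rows = []
    for (subj, trial), tq in log.queries.groupby(["subject", "trial"]):
        recs = tq.to_dict("records")
        for t in range(1, len(recs)):
            prev, cur = recs[t - 1], recs[t]
            if cur["feedback"] == "synthetic":
                continue
            a = int(cur["node_canon"])
            la = tree.level[a]
            if prev["feedback"] == "none":          # after an internal query
                m = int(prev["node_canon"])
                lm = tree.level[m]
                if a == m:
                    cat = "requery"
                elif a == 2 * m + 1:
                    cat = "correct_child"
                elif a == 2 * m:
                    cat = "incorrect_child"
                elif la == lm:
                    cat = "other_same_level"
                elif la > lm:
                    cat = "other_lower_level"
                else:
                    cat = "higher_level"
                ctx = "post_internal"
            elif prev["feedback"] in _ERROR_FEEDBACK:  # after a leaf error
                T = int(prev["node_canon"])
                path = tree.ancestors[T]
                if a in path:
                    cat = "on"
                elif a in tree.counterfactual[T].values():
                    cat = "off"
                else:
                    cat = "other"
                ctx = "post_error"
            else:
                continue  # after the target: trial over
            rows.append({"subject": subj, "trial": trial,
                         "step": cur["step"], "context": ctx, "category": cat,
                         "node_canon": a, "prev_canon": int(prev["node_canon"])})
    return pd.DataFrame(rows, columns=["subject", "trial", "step", "context",
                                       "category", "node_canon", "prev_canon"])


# ---------------------------------------------------------------------------
# Blame statistics
# ---------------------------------------------------------------------------

def _error_frame(log: SessionLog, tree: TreeSpec, mode: str) -> pd.DataFrame:
    """One row per leaf error with the error-path coherences per level,
    the blamed level and the path type of the following query.

    Blame comes from the log's own annotations in ``"model"`` mode, or is
    inferred from the next query (the on-path target node, or the parent
    of an off-path query) in ``"data"`` mode.
    """
    q = log.queries
    grp = q.groupby(["subject", "trial"], sort=False)
    nxt_node = grp["node_canon"].shift(-1)
    frame = q[["subject", "trial", "node_canon", "feedback"]].copy()
    frame["next_node"] = nxt_node
    if mode == "model":
        frame["next_ptype"] = grp["path_type"].shift(-1)
        frame["next_blamed"] = grp["blamed_canon"].shift(-1)
    err = frame[frame["feedback"].isin(_ERROR_FEEDBACK)
                & frame["next_node"].notna()].copy()
    if len(err) == 0:
        return pd.DataFrame(columns=["subject", "trial", "T", "ptype",
                                     "blamed_level"]
                            + [f"path_c{l}" for l in range(1, tree.depth + 1)])
    T = err["node_canon"].to_numpy(int)
    depth = tree.depth
    anc = np.stack([T >> k for k in range(depth, 0, -1)], axis=1)  # (n, depth)
    merged = err.merge(log.trials[["subject", "trial"]
                                  + [f"c{i}" for i in tree.internal_nodes]],
                       on=["subject", "trial"], how="left")
    c_mat = merged[[f"c{i}" for i in tree.internal_nodes]].to_numpy(float)
    path_c = c_mat[np.arange(len(err))[:, None], anc - 1]         # (n, depth)
    if mode == "model":
        ptype = err["next_ptype"].fillna("").to_numpy()
        ptype = np.where(np.isin(ptype, ("on", "off", "fallback")), ptype, "")
        blamed = err["next_blamed"].fillna(-1).to_numpy(int)
        blamed_level = np.where(blamed > 0,
                                np.floor(np.log2(np.maximum(blamed, 1))) + 1,
                                0).astype(int)
    else:
        a = err["next_node"].to_numpy(int)
        on_hit = (anc == a[:, None])
        # counterfactual child of the level-l path node: flip the last bit
        # of the on-path child (which is the level-(l+1) path node, or T)
        cf = np.stack([T >> k for k in range(depth - 1, -1, -1)], axis=1) ^ 1
        off_hit = (cf == a[:, None])
        is_on = on_hit.any(axis=1)
        is_off = ~is_on & off_hit.any(axis=1)
        ptype = np.where(is_on, "on", np.where(is_off, "off", ""))
        lvl_on = on_hit.argmax(axis=1) + 1
        lvl_off = off_hit.argmax(axis=1) + 1
        blamed_level = np.where(is_on, lvl_on, np.where(is_off, lvl_off, 0))
    out = pd.DataFrame({"subject": err["subject"].to_numpy(),
                        "trial": err["trial"].to_numpy(),
                        "T": T, "ptype": ptype,
                        "blamed_level": blamed_level})
    for l in range(1, depth + 1):
        out[f"path_c{l}"] = path_c[:, l - 1]
    return out


def blame_stats(log: SessionLog, mode: str = "model",
                tree: TreeSpec | None = None,
                coherences=COHERENCES) -> dict:
    """Blame proportions conditioned on coherence and tree level.

    Returns a dict with:

    * ``"by_coherence"``: Series over coherence c of P(blamed node has
      coherence c | a node with coherence c is in the error path);
    * ``"on_by_level"`` / ``"off_by_level"``: (level × coherence) tables of
      P(on-/off-path query at level ℓ | the level-ℓ path node has
      coherence c).

    Proportions are computed per subject and averaged across subjects.
    """
    if mode not in ("model", "data"):
        raise ValueError("mode must be 'model' or 'data'")
    tree = tree or TreeSpec()
    cohs = list(coherences)
    levels = list(range(1, tree.depth + 1))
    err = _error_frame(log, tree, mode)
    if len(err) == 0:
        raise ValueError("no classifiable errors in log")
    path_cols = [f"path_c{l}" for l in levels]
    path_c = err[path_cols].to_numpy(float)
    classified = err["ptype"].isin(["on", "off"]).to_numpy()
    blamed_c = np.where(
        classified & (err["blamed_level"] > 0),
        path_c[np.arange(len(err)),
               np.maximum(err["blamed_level"].to_numpy(int), 1) - 1],
        np.nan)
    subj_ids = err["subject"].to_numpy()
    subjects = pd.unique(subj_ids)
    A = np.full((len(subjects), len(cohs)), np.nan)
    Bmat = np.full((len(subjects), len(levels), len(cohs)), np.nan)
    Cmat = np.full_like(Bmat, np.nan)
    ptype = err["ptype"].to_numpy()
    blamed_level = err["blamed_level"].to_numpy(int)
    for si, subj in enumerate(subjects):
        rows = subj_ids == subj
        for ci, c in enumerate(cohs):
            in_path = (path_c[rows] == c).any(axis=1)
            if in_path.sum():
                A[si, ci] = np.mean((blamed_c[rows] == c)[in_path])
            for li, l in enumerate(levels):
                at_level = path_c[rows][:, li] == c
                if at_level.sum():
                    on_here = (ptype[rows] == "on") & (blamed_level[rows] == l)
                    off_here = (ptype[rows] == "off") & (blamed_level[rows] == l)
                    Bmat[si, li, ci] = on_here[at_level].mean()
                    Cmat[si, li, ci] = off_here[at_level].mean()
    return {"by_coherence": pd.Series(_nanmean(A, axis=0), index=cohs),
            "on_by_level": pd.DataFrame(_nanmean(Bmat, axis=0),
                                        index=levels, columns=cohs),
            "off_by_level": pd.DataFrame(_nanmean(Cmat, axis=0),
                                         index=levels, columns=cohs)}


# ---------------------------------------------------------------------------
# Reward and query summaries
# ---------------------------------------------------------------------------

def summarize(log: SessionLog, tree: TreeSpec | None = None) -> dict:
    """Mean reward per trial (SEM over trials) and per-level query counts
    and leaf errors per trial (averaged within, then across subjects)."""
    tree = tree or TreeSpec()
    trials = log.trials
    reward = trials["reward"].to_numpy(float)
    q = log.queries[log.queries["feedback"] != "synthetic"]
    per_subj = []
    for subj, sq in q.groupby("subject"):
        ntr = log.trials[log.trials["subject"] == subj]["trial"].nunique()
        row = {"subject": subj}
        for l in range(1, tree.depth + 1):
            row[f"queries_level{l}"] = (sq["level"] == l).sum() / ntr
        row["leaf_errors"] = (sq["feedback"] == "negative").sum() / ntr
        per_subj.append(row)
    per_subj = pd.DataFrame(per_subj).set_index("subject")
    return {
        "mean_reward": float(reward.mean()),
        "sem_reward": float(reward.std(ddof=1) / np.sqrt(len(reward)))
        if len(reward) > 1 else 0.0,
        "per_subject": per_subj,
        "queries_per_level": per_subj[[c for c in per_subj.columns
                                       if c.startswith("queries")]].mean(),
        "leaf_errors_per_trial": float(per_subj["leaf_errors"].mean()),
    }


def expected_leaf_costs(p_correct: float, payoffs=None) -> tuple[float, float]:
    """Expected immediate leaf-choice cost with and without a level-3 query.

    With the level-1/2 decisions taken as certain, choosing a leaf after a
    level-3 query that is correct with probability p yields expected cost
    (1−p)·(−wrong); guessing without querying yields ½·(−wrong). Returns
    (cost_with_query, cost_without); the query fee itself is not included.
    """
    from .task import Payoffs
    payoffs = payoffs or Payoffs()
    return (-(1.0 - p_correct) * payoffs.wrong_leaf,
            -0.5 * payoffs.wrong_leaf)


# ---------------------------------------------------------------------------
# Logistic regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Logistic-regression fit with likelihood-ratio tests."""

    tag: str
    params: pd.Series
    bse: pd.Series
    loglik: float
    bic: float
    n_obs: int
    lr_pvalues: dict = field(default_factory=dict)
    separation: bool = False


_MODEL_TERMS = {
    "choice": (["s", "s_level"], "right"),
    "requery": (["c", "level"], "requery"),
    "onpath": (["c_blamed", "c_other_prod"], "on"),
    "pulse_single": (["s", "level", "m"], "right"),
    "pulse_pair": (["s", "level", "m1", "m2"], "right"),
    "blame": (["c", "level"], "blamed"),
}

_DEFAULT_NULLS = {
    "choice": ["s", "s_level"], "requery": ["c", "level"],
    "onpath": ["c_other_prod"], "pulse_single": ["m"], "pulse_pair": ["m1", "m2"],
    "blame": ["c", "level"],
}


def _design(table: pd.DataFrame, terms):
    X = table[terms].astype(float).copy()
    subj = table["subject"].astype(str)
    if subj.nunique() > 1:
        dummies = pd.get_dummies(subj, prefix="subj", drop_first=True,
                                 dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_logistic(tag: str, table: pd.DataFrame,
                 null_terms=None) -> RegressionResult:
    """Fit one of the behavioral logistic regressions.

    ``table`` must contain the tag's term columns, the response column and
    a ``subject`` column (subject indicator dummies are added
    automatically). Likelihood-ratio p-values are computed for each term in
    ``null_terms`` (defaults per model) by refitting without that column.
    """
    if tag not in _MODEL_TERMS:
        raise ValueError(f"unknown model tag {tag!r}")
    terms, ycol = _MODEL_TERMS[tag]
    y = table[ycol].astype(float).to_numpy()
    X = _design(table, terms)

    def _fit(Xd):
        model = sm.Logit(y, Xd)
        return model.fit(disp=0, maxiter=500, method="lbfgs")

    res = _fit(X)
    separation = not np.all(np.isfinite(res.bse))
    lr_p = {}
    for term in (null_terms if null_terms is not None else _DEFAULT_NULLS[tag]):
        res0 = _fit(X.drop(columns=[term]))
        lr = 2.0 * (res.llf - res0.llf)
        lr_p[term] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return RegressionResult(tag=tag, params=res.params, bse=res.bse,
                            loglik=float(res.llf), bic=float(res.bic),
                            n_obs=len(table), lr_pvalues=lr_p,
                            separation=separation)


# -- table builders from session logs ---------------------------------------

def make_choice_table(log: SessionLog, tree: TreeSpec | None = None) -> pd.DataFrame:
    """Per-streak-terminating rows for the choice regressions (tags
    `choice`, `pulse_single`, `pulse_pair`) and the re-query regression
    (`requery`).

    One row per internal query that was followed by a re-query or a child
    query, with the spatial choice (`right`), signed strength ``s = c·d``,
    streak bookkeeping and the evidence samples of the last two pulses.
    """
    tree = tree or TreeSpec()
    rows = []
    for (subj, trial), tq in log.queries.groupby(["subject", "trial"]):
        recs = [r for r in tq.to_dict("records") if r["feedback"] != "synthetic"]
        for t in range(len(recs) - 1):
            cur, nxt = recs[t], recs[t + 1]
            node, nnode = int(cur["node"]), int(nxt["node"])
            if tree.is_leaf(node):
                continue
            requery = nnode == node
            child = nnode in tree.children[node]
            if not (requery or child):
                continue
            right_child = nnode == 2 * node + 1
            rows.append({
                "subject": subj, "trial": trial, "step": cur["step"],
                "node": node, "level": int(cur["level"]),
                "c": float(cur["c"]), "d": int(cur["d"]),
                "s": float(cur["c"]) * int(cur["d"]),
                "s_level": float(cur["c"]) * int(cur["d"]) * int(cur["level"]),
                "n_q": int(cur["n_q"]),
                "e": float(cur["e"]),
                "e_prev": float(recs[t - 1]["e"])
                if t > 0 and int(recs[t - 1]["node"]) == node
                and not tree.is_leaf(node) else np.nan,
                "requery": int(requery),
                "right": int(right_child) if child else np.nan,
                "correct": int(right_child == (int(cur["d"]) > 0))
                if child else np.nan,
            })
    return pd.DataFrame(rows)


def make_pulse_tables(choice_table: pd.DataFrame):
    """Split the choice table into the one-pulse and two-pulse
    regression tables, using the model evidence samples as the stand-in for
    stimulus motion energy."""
    t = choice_table
    choices = t[t["right"].notna()]
    one = choices[choices["n_q"] == 0].copy()
    one["m"] = one["e"]
    two = choices[(choices["n_q"] == 1) & choices["e_prev"].notna()].copy()
    two["m1"] = two["e_prev"]
    two["m2"] = two["e"]
    return one, two


def make_blame_table(log: SessionLog, mode: str = "model",
                     tree: TreeSpec | None = None):
    """Tables for the on- vs off-path regression (`onpath`) and the
    which-node-is-blamed regression (`blame`)."""
    tree = tree or TreeSpec()
    err = _error_frame(log, tree, mode)
    err = err[err["ptype"].isin(["on", "off"]) & (err["blamed_level"] > 0)]
    levels = list(range(1, tree.depth + 1))
    path_c = err[[f"path_c{l}" for l in levels]].to_numpy(float)
    bl = err["blamed_level"].to_numpy(int)
    n = len(err)
    c_blamed = path_c[np.arange(n), bl - 1]
    prod_all = path_c.prod(axis=1)
    tab8 = pd.DataFrame({
        "subject": err["subject"].to_numpy(),
        "on": (err["ptype"] == "on").astype(int).to_numpy(),
        "c_blamed": c_blamed,
        "c_other_prod": prod_all / c_blamed,
    })
    rows11 = pd.DataFrame({
        "subject": np.repeat(err["subject"].to_numpy(), len(levels)),
        "c": path_c.ravel(),
        "level": np.tile(levels, n),
        "blamed": (np.tile(levels, n)
                   == np.repeat(bl, len(levels))).astype(int),
        "path_type": np.repeat(err["ptype"].to_numpy(), len(levels)),
    })
    return tab8, rows11
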