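"""Transition statistics, action classification, regressions, summaries."""

import numpy as np
import pandas as pd
import pytest

import hiertask as ht


def toy_log(rows, trial_rows=None, subject="s1"):
    """Hand-built session log from (trial, node_canon, feedback) tuples."""
    recs = []
    for i, (trial, node, feedback) in enumerate(rows):
        level = node.bit_length()
        recs.append({
            "subject": subject, "trial": trial, "step": i, "node": node,
            "node_canon": node, "level": level, "c": 0.128, "d": 1,
            "e": 0.5 if level <= 3 else np.nan,
            "feedback": feedback, "points": 0.0, "n_q": 0, "visited": "",
            "path_type": "", "blamed_canon": -1})
    queries = pd.DataFrame(recs, columns=ht.task.QUERY_COLUMNS)
    if trial_rows is None:
        trials = pd.DataFrame([
            {"subject": subject, "trial": t, "reward": 2.0,
             "n_internal_queries": 0, "n_leaf_errors": 0, "target_canon": 15,
             **{f"c{i}": 0.128 for i in range(1, 8)},
             **{f"d{i}": 1 for i in range(1, 8)}}
            for t in sorted({r[0] for r in rows})])
    else:
        trials = pd.DataFrame(trial_rows)
    return ht.SessionLog(queries, trials, {})


class TestTransitionStats:
    def test_root_requeries_only(self):
        log = toy_log([(0, 1, "none")] * 4)
        ts = ht.transition_stats(log)
        assert ts.mean_conditional[0, 0] == 1.0

    def test_rows_normalize(self, heuristic_log):
        ts = ht.transition_stats(heuristic_log)
        W = next(iter(ts.conditional.values()))
        sums = np.nansum(W, axis=1)
        visited_rows = ~np.isnan(W).all(axis=1)
        assert np.allclose(sums[visited_rows], 1.0)

    def test_hand_tabulated_counts(self):
        # 6-step toy: 1 -> 1 -> 3 -> 7 -> 14(err) -> 7
        log = toy_log([(0, 1, "none"), (0, 1, "none"), (0, 3, "none"),
                       (0, 7, "none"), (0, 14, "negative"), (0, 7, "none")])
        ts = ht.transition_stats(log)
        M = ts.counts["s1"]
        assert M[0, 0] == 1 and M[0, 2] == 1 and M[2, 6] == 1
        assert M[6, 13] == 1 and M[13, 6] == 1
        assert M.sum() == 5

    def test_level_split_sums_to_one(self, heuristic_log):
        ts = ht.transition_stats(heuristic_log)
        assert np.nansum(ts.level_pre) == pytest.approx(1.0)
        assert np.nansum(ts.level_post) == pytest.approx(1.0)

    def test_empty_log_rejected(self):
        log = toy_log([(0, 1, "none")])
        log.queries = log.queries.iloc[0:0]
        with pytest.raises(ValueError):
            ht.transition_stats(log)


class TestClassifyActions:
    def test_post_error_categories(self):
        # errors at canonical leaf 11 (path 1, 2, 5; counterfactual 3, 4, 10)
        log = toy_log([(0, 11, "negative"), (0, 5, "none"),
                       (1, 11, "negative"), (1, 10, "none"),
                       (2, 11, "negative"), (2, 13, "negative")])
        cls = ht.classify_actions(log)
        post_err = cls[cls["context"] == "post_error"]
        assert post_err["category"].tolist() == ["on", "off", "other"]

    def test_post_internal_categories(self):
        log = toy_log([(0, 2, "none"), (0, 5, "none"),    # correct child
                       (1, 2, "none"), (1, 4, "none"),    # incorrect child
                       (2, 2, "none"), (2, 2, "none"),    # re-query
                       (3, 2, "none"), (3, 3, "none"),    # other same level
                       (4, 2, "none"), (4, 7, "none"),    # other lower level
                       (5, 2, "none"), (5, 1, "none")])   # higher level
        cls = ht.classify_actions(log)
        got = cls[cls["context"] == "post_internal"]["category"].tolist()
        assert got == ["correct_child", "incorrect_child", "requery",
                       "other_same_level", "other_lower_level", "higher_level"]

    def test_categories_exhaustive_and_exclusive(self, heuristic_log):
        cls = ht.classify_actions(heuristic_log)
        assert set(cls.loc[cls.context == "post_internal", "category"]) \
            <= set(ht.analysis.POST_INTERNAL_CATEGORIES)
        assert set(cls.loc[cls.context == "post_error", "category"]) \
            <= set(ht.analysis.POST_ERROR_CATEGORIES)
        # one classification per classified action
        assert not cls.duplicated(["subject", "trial", "step"]).any()


class TestBlameStats:
    def test_single_error_single_cell(self):
        log = toy_log([(0, 11, "negative"), (0, 5, "none")])
        stats = ht.blame_stats(log, mode="data")
        # blame inferred at node 5 (level 3), coherence 0.128 everywhere
        assert stats["on_by_level"].loc[3, 0.128] == 1.0
        assert stats["by_coherence"][0.128] == 1.0

    def test_brute_force_recount(self, heuristic_log, tree):
        stats = ht.blame_stats(heuristic_log, mode="model")
        err = ht.analysis._error_frame(heuristic_log, tree, "model")
        c = 0.032
        in_path = err[[f"path_c{l}" for l in (1, 2, 3)]].eq(c).any(axis=1)
        blamed_here = err.apply(
            lambda r: r["ptype"] in ("on", "off") and r["blamed_level"] > 0
            and r[f"path_c{int(r['blamed_level'])}"] == c, axis=1)
        expected = blamed_here[in_path].mean()
        assert stats["by_coherence"][c] == pytest.approx(expected)


class TestSummaries:
    def test_single_trial(self):
        log = toy_log([(0, 1, "none"), (0, 15, "target")])
        s = ht.summarize(log)
        assert s["mean_reward"] == 2.0 and s["sem_reward"] == 0.0

    def test_per_level_counts_on_toy(self):
        log = toy_log([(0, 1, "none"), (0, 1, "none"), (0, 3, "none"),
                       (0, 15, "target")])
        s = ht.summarize(log)
        assert s["queries_per_level"]["queries_level1"] == 2.0
        assert s["queries_per_level"]["queries_level2"] == 1.0
        assert s["queries_per_level"]["queries_level3"] == 0.0

    def test_worked_example_leaf_costs(self):
        with_q, without_q = ht.expected_leaf_costs(0.8)
        assert with_q == pytest.approx(-0.6)
        assert without_q == pytest.approx(-1.5)


class TestRegressions:
    def test_known_coefficients_recovered(self, rng):
        # synthetic logistic data with known coefficients
        n = 20000
        s = rng.choice([-0.5, -0.1, 0.1, 0.5], size=n)
        level = rng.integers(1, 4, size=n)
        eta = 0.3 + 4.0 * s - 1.0 * s * level
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        tab = pd.DataFrame({"subject": "x", "s": s, "level": level,
                            "s_level": s * level, "right": y.astype(int)})
        res = ht.fit_logistic("choice", tab)
        assert abs(res.params["s"] - 4.0) < 2 * 2 * res.bse["s"]
        assert abs(res.params["s_level"] + 1.0) < 2 * 2 * res.bse["s_level"]

    def test_choice_signs_on_detection_simulation(self, heuristic_log):
        tab = ht.make_choice_table(heuristic_log)
        choices = tab[tab["right"].notna()]
        res = ht.fit_logistic("choice", choices)
        assert res.params["s"] > 0          # stronger motion, more rightward
        assert res.params["s_level"] < 0    # accuracy falls with depth
        res7 = ht.fit_logistic("requery", tab)
        assert res7.params["c"] < 0         # re-query when motion weak
        assert res7.params["level"] < 0     # fewer re-queries deeper
        assert res7.lr_pvalues["c"] < 1e-6

    def test_first_pulse_informative_only_with_integration(self, det_params):
        def tables(integrate, seed):
            tab = ht.generate_query_dataset(det_params, 50000,
                                            np.random.default_rng(seed),
                                            integrate=integrate)
            sizes = tab.groupby("streak")["n_q"].transform("size")
            two = tab[sizes == 2]
            first = two[two["n_q"] == 0]
            second = two[two["n_q"] == 1]
            return pd.DataFrame({
                "subject": "sim",
                "s": second["c"].to_numpy() * second["d"].to_numpy(),
                "level": second["level"].to_numpy(),
                "m1": first["e"].to_numpy(),
                "m2": second["e"].to_numpy(),
                "right": (second["outcome"] == "right").astype(int).to_numpy(),
            })
        res_det = ht.fit_logistic("pulse_pair", tables(False, 10))
        res_int = ht.fit_logistic("pulse_pair", tables(True, 10))
        assert res_det.lr_pvalues["m1"] > 0.05      # discarded pulse
        assert res_det.lr_pvalues["m2"] < 1e-8
        assert res_int.lr_pvalues["m1"] < 1e-4      # accumulated pulse
        assert res_int.params["m1"] > 0

    def test_onpath_regression_sign_on_heuristic_simulation(self, heuristic_log):
        tab8, tab11 = ht.make_blame_table(heuristic_log, mode="model")
        res = ht.fit_logistic("onpath", tab8)
        # weaker unblamed nodes -> more on-path queries
        assert res.params["c_other_prod"] < 0
        res11 = ht.fit_logistic("blame", tab11)
        assert res11.params["c"] < 0  # weak motion attracts blame

    def test_subject_ordering_invariance(self, det_params):
        log1 = ht.run_heuristic_agent(
            ht.HeuristicParams(0.92, det_params), 300,
            np.random.default_rng(1), subject="a")
        log2 = ht.run_heuristic_agent(
            ht.HeuristicParams(0.92, det_params), 300,
            np.random.default_rng(2), subject="b")
        s12 = ht.summarize(ht.SessionLog.concat([log1, log2]))
        s21 = ht.summarize(ht.SessionLog.concat([log2, log1]))
        assert s12["mean_reward"] == pytest.approx(s21["mean_reward"])
        assert s12["leaf_errors_per_trial"] == pytest.approx(
            s21["leaf_errors_per_trial"])
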