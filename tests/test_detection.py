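"""Detection-model criterion, choice probabilities, likelihoods and fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hiertask as ht
from hiertask.detection import OUTCOMES


class TestCriterion:
    def test_first_query_doubles_base(self, det_params):
        assert ht.criterion(1, 0, det_params) == pytest.approx(
            2 * det_params.phi[0])

    def test_limit_is_base_criterion(self, det_params):
        assert ht.criterion(2, 500, det_params) == pytest.approx(
            det_params.phi[1])

    def test_lambda_zero_keeps_criterion_flat(self):
        p = ht.DetectionParams(lam=0.0)
        for nq in (0, 3, 10):
            assert ht.criterion(3, nq, p) == pytest.approx(2 * p.phi[2])

    def test_strictly_decreasing_in_streak(self, det_params):
        vals = ht.criterion(1, np.arange(6), det_params)
        assert np.all(np.diff(vals) < 0)


class TestChoiceProbs:
    def test_sum_to_one(self, det_params):
        pr, pl, pq = ht.choice_probs(0.128, 1, 2, 1, det_params)
        assert pr + pl + pq == pytest.approx(1.0, abs=1e-12)

    @given(kappa=st.floats(1, 40), gamma=st.floats(0, 5),
           phi=st.floats(0.01, 2), lam=st.floats(0, 4),
           ci=st.integers(0, 4), level=st.integers(1, 3),
           nq=st.integers(0, 8))
    @settings(max_examples=60, deadline=None)
    def test_sum_to_one_over_parameter_grid(self, kappa, gamma, phi, lam,
                                            ci, level, nq):
        p = ht.DetectionParams(kappa, gamma, (phi, phi * 0.8, phi * 0.6), lam)
        pr, pl, pq = ht.choice_probs(ht.COHERENCES[ci], -1, level, nq, p)
        assert 0 <= pr <= 1 and 0 <= pl <= 1 and 0 <= pq <= 1
        assert pr + pl + pq == pytest.approx(1.0, abs=1e-12)

    def test_zero_criterion_kills_requery(self):
        p = ht.DetectionParams(phi=(0.0, 0.0, 0.0))
        _, _, pq = ht.choice_probs(0.064, 1, 1, 0, p)
        assert pq == pytest.approx(0.0, abs=1e-12)

    def test_zero_coherence_is_symmetric(self, det_params):
        pr, pl, _ = ht.choice_probs(0.0, 1, 2, 0, det_params)
        assert pr == pytest.approx(pl)

    def test_matches_monte_carlo_thresholding(self, det_params, rng):
        n = 100000
        for c, lvl, nq in ((0.064, 1, 0), (0.256, 3, 2)):
            e = ht.sample_evidence(np.full(n, c), 1, det_params.evidence, rng)
            phi = float(ht.criterion(lvl, nq, det_params))
            emp = np.array([(e > phi).mean(), (e < -phi).mean()])
            pr, pl, _ = ht.choice_probs(c, 1, lvl, nq, det_params)
            se = np.sqrt(np.maximum(emp * (1 - emp), 1e-6) / n)
            assert abs(pr - emp[0]) < 4 * se[0]
            assert abs(pl - emp[1]) < 4 * se[1]

    def test_requery_prob_monotonicity(self, det_params):
        # nonincreasing in coherence at fixed criterion, and in n_q at fixed c
        pqs = [ht.choice_probs(c, 1, 1, 0, det_params)[2]
               for c in ht.COHERENCES]
        assert all(a >= b for a, b in zip(pqs, pqs[1:]))
        pqs = [ht.choice_probs(0.064, 1, 1, nq, det_params)[2]
               for nq in range(6)]
        assert all(a >= b for a, b in zip(pqs, pqs[1:]))

    def test_accuracy_pattern(self, det_params):
        # accuracy given a choice rises with coherence and, with
        # phi1>phi2>phi3, falls with depth
        def acc(c, lvl):
            pr, pl, _ = ht.choice_probs(c, 1, lvl, 0, det_params)
            return pr / (pr + pl)
        accs = [acc(c, 2) for c in ht.COHERENCES]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        by_level = [acc(0.128, lvl) for lvl in (1, 2, 3)]
        assert by_level[0] > by_level[1] > by_level[2]


class TestDetectionLoglik:
    def test_empty_table_is_zero(self, det_params):
        empty = pd.DataFrame(columns=["c", "d", "level", "n_q", "outcome"])
        assert ht.detection_loglik(empty, det_params) == 0.0

    def test_matches_naive_row_loop(self, det_params, detection_queries):
        tab = detection_queries.head(300)
        naive = 0.0
        for row in tab.itertuples():
            probs = dict(zip(OUTCOMES, ht.choice_probs(
                row.c, row.d, row.level, row.n_q, det_params)))
            naive += np.log(probs[row.outcome])
        assert ht.detection_loglik(tab, det_params) == pytest.approx(naive)

    def test_generating_params_beat_perturbed(self, det_params,
                                              detection_queries):
        ll_true = ht.detection_loglik(detection_queries, det_params)
        worse = ht.DetectionParams(det_params.kappa * 1.5, det_params.gamma,
                                   det_params.phi, det_params.lam)
        assert ll_true > ht.detection_loglik(detection_queries, worse)

    def test_rejects_unknown_outcome(self, det_params):
        tab = pd.DataFrame({"c": [0.1], "d": [1], "level": [1], "n_q": [0],
                            "outcome": ["sideways"]})
        with pytest.raises(ValueError):
            ht.detection_loglik(tab, det_params)


class TestFit:
    def test_fit_beats_truth_and_ignores_row_order(self, det_params):
        tab = ht.generate_query_dataset(det_params, 3000,
                                        np.random.default_rng(5))
        fit = ht.fit_detection(tab, seed=0, n_starts=4)
        assert fit.loglik >= ht.detection_loglik(tab, det_params) - 1e-6
        shuffled = tab.sample(frac=1.0, random_state=1)
        fit2 = ht.fit_detection(shuffled, seed=0, n_starts=4)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)
        assert fit2.params == pytest.approx(fit.params)

    def test_bic_formula(self, det_params):
        tab = ht.generate_query_dataset(det_params, 500,
                                        np.random.default_rng(6))
        fit = ht.fit_detection(tab, seed=0, n_starts=2)
        assert fit.bic == pytest.approx(
            fit.n_params * np.log(len(tab)) - 2 * fit.loglik)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_variant_parameter_counts(self):
        assert len(ht.VARIANTS["detection"]) == 6
        assert len(ht.VARIANTS["gamma0"]) == 5
        assert len(ht.VARIANTS["3phi3kappa"]) == 8

    def test_tied_variants_fit_smoke(self, det_params):
        tab = ht.generate_query_dataset(det_params, 1500,
                                        np.random.default_rng(7))
        for variant in ("1phi3kappa", "gamma0"):
            fit = ht.fit_detection(tab, variant, seed=0, n_starts=2)
            assert np.isfinite(fit.loglik)
            assert fit.n_params == len(ht.VARIANTS[variant])

    def test_query_order_variant_needs_q(self, det_params):
        tab = ht.generate_query_dataset(det_params, 100,
                                        np.random.default_rng(8))
        with pytest.raises(ValueError, match="q"):
            ht.fit_detection(tab, "query_order", seed=0, n_starts=1)


class TestIntegration:
    def test_single_pulse_equals_detection(self, det_params):
        probs = ht.integration_probs(0.128, 1, 2, det_params, 1)
        pr, pl, pq = ht.choice_probs(0.128, 1, 2, 0, det_params)
        assert probs[0] == pytest.approx([pr, pl, pq], abs=1e-9)

    def test_exit_probs_match_monte_carlo(self, det_params):
        rng = np.random.default_rng(17)
        c, lvl, K, n = 0.128, 2, 5, 100000
        probs = ht.integration_probs(c, 1, lvl, det_params, K)
        evid = det_params.evidence
        e = rng.normal(float(evid.mean(c, 1)), float(evid.sd(c)), (n, K))
        S = e.cumsum(axis=1)
        alive = np.ones(n, bool)
        for k in range(K):
            phi = det_params.phi[lvl - 1] * (1 + np.exp(-det_params.lam * k))
            right = alive & (S[:, k] > phi)
            left = alive & (S[:, k] < -phi)
            for emp, model in ((right.mean(), probs[k, 0]),
                               (left.mean(), probs[k, 1])):
                se = np.sqrt(max(emp * (1 - emp), 1e-7) / n)
                assert abs(model - emp) < 4 * se
            alive &= ~(right | left)

    def test_grid_resolution_guard(self, det_params):
        with pytest.raises(ValueError, match="coarse"):
            ht.integration_probs(0.1, 1, 1, det_params, 2, grid_points=50)

    def test_mirror_symmetry(self, det_params):
        p_r = ht.integration_probs(0.256, 1, 1, det_params, 3)
        p_l = ht.integration_probs(0.256, -1, 1, det_params, 3)
        assert np.allclose(p_r[:, 0], p_l[:, 1])
        assert np.allclose(p_r[:, 2], p_l[:, 2])

    def test_loglik_consistent_with_probs(self, det_params):
        tab = pd.DataFrame({"c": [0.128] * 3, "d": [1] * 3, "level": [2] * 3,
                            "n_q": [0, 1, 2],
                            "outcome": ["requery", "requery", "right"]})
        cond = ht.integration_probs(0.128, 1, 2, det_params, 3,
                                    _conditional=True)
        expected = (np.log(cond[0, 2]) + np.log(cond[1, 2])
                    + np.log(cond[2, 0]))
        assert ht.integration_loglik(tab, det_params) == pytest.approx(
            expected, rel=1e-6)
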