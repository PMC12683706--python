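import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escapes.hmm import (
    STATE_NAMES,
    CovariateHMM,
    HMMFit,
    HMMParams,
    _emission_logdens,
    _trans_batch,
    foraging_segregation,
    forward_loglik,
    transition_curves,
    transition_matrix,
    viterbi,
)


def toy_params(beta=None):
    b = np.zeros((3, 3))
    if beta is not None:
        b[:] = beta
        np.fill_diagonal(b, 0.0)
    return HMMParams(
        means=[5.0, 1200.0, 5200.0],
        sds=[5.0, 1300.0, 2900.0],
        mus=[0.4, -0.05, 0.03],
        kappas=[0.07, 0.89, 1.62],
        alpha=[[0, -2, -1], [-2, 0, -2], [-1, -2, 0]],
        beta=b,
    )


def toy_steps(T, seed=0, track_breaks=()):
    rng = np.random.default_rng(seed)
    turns = rng.vonmises(0, 1, T)
    turns[0] = np.nan
    track = np.zeros(T, dtype=int)
    for br in track_breaks:
        track[br:] += 1
        turns[br] = np.nan
    return pd.DataFrame({"length": rng.gamma(2, 800, T), "turn": turns, "track_id": track})


def enumerate_loglik_and_best(params, steps, log_hri):
    logB = _emission_logdens(params, steps["length"].to_numpy(), steps["turn"].to_numpy())
    trans = _trans_batch(params, np.asarray(log_hri, dtype=float))
    T = len(steps)
    tot = -np.inf
    best_path, best_v = None, -np.inf
    for path in itertools.product(range(3), repeat=T):
        v = np.log(1 / 3) + logB[0, path[0]]
        for t in range(1, T):
            v += np.log(trans[t, path[t - 1], path[t]]) + logB[t, path[t]]
        tot = np.logaddexp(tot, v)
        if v > best_v:
            best_v, best_path = v, path
    return tot, best_path


class TestTransitionMatrix:
    def test_zero_slopes_constant_in_covariate(self):
        p = toy_params()
        np.testing.assert_allclose(transition_matrix(p, -2.0), transition_matrix(p, 3.0))

    def test_zero_intercepts_uniform_rows(self):
        p = toy_params()
        p.alpha[:] = 0.0
        np.testing.assert_allclose(transition_matrix(p, 0.7), np.full((3, 3), 1 / 3))

    def test_positive_slope_monotone_increasing(self):
        p = toy_params()
        p.beta[2, 1] = 1.0
        grid = np.linspace(-2, 2, 9)
        probs = _trans_batch(p, grid)[:, 2, 1]
        assert np.all(np.diff(probs) > 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50))
    def test_rows_always_stochastic(self, seed, log_hri):
        rng = np.random.default_rng(seed)
        p = toy_params()
        p.alpha[:] = rng.normal(0, 3, (3, 3))
        p.beta[:] = rng.normal(0, 2, (3, 3))
        M = transition_matrix(p, log_hri)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0)


class TestForward:
    def test_single_state_reduces_to_iid_sum(self):
        p = HMMParams(means=[800.0], sds=[500.0], mus=[0.1], kappas=[1.0], alpha=[[0.0]], beta=[[0.0]])
        steps = toy_steps(20, seed=1)
        ll = forward_loglik(p, steps, np.zeros(20))
        logB = _emission_logdens(p, steps["length"].to_numpy(), steps["turn"].to_numpy())
        assert ll == pytest.approx(float(logB.sum()), abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration(self, seed):
        p = toy_params()
        p.beta[2, 1] = 1.0
        steps = toy_steps(6, seed=seed)
        log_hri = np.random.default_rng(seed).normal(0, 0.5, 6)
        ll = forward_loglik(p, steps, log_hri)
        ll_enum, _ = enumerate_loglik_and_best(p, steps, log_hri)
        assert ll == pytest.approx(ll_enum, abs=1e-8)

    def test_multi_track_is_product_of_tracks(self):
        p = toy_params()
        steps = toy_steps(8, seed=4, track_breaks=(5,))
        lh = np.linspace(-0.5, 0.5, 8)
        ll = forward_loglik(p, steps, lh)
        ll_a = forward_loglik(p, steps.iloc[:5].copy(), lh[:5])
        ll_b = forward_loglik(p, steps.iloc[5:].copy(), lh[5:])
        assert ll == pytest.approx(ll_a + ll_b, abs=1e-8)

    def test_label_permutation_invariance(self):
        p = toy_params()
        steps = toy_steps(30, seed=5)
        lh = np.zeros(30)
        perm = np.array([2, 0, 1])
        ll = forward_loglik(p, steps, lh)
        ll_perm = forward_loglik(p.relabeled(perm), steps, lh)
        assert ll == pytest.approx(ll_perm, abs=1e-8)

    def test_zero_lengths_require_zero_inflation(self):
        p = toy_params()
        steps = toy_steps(5, seed=0)
        steps.loc[2, "length"] = 0.0
        with pytest.raises(ValueError):
            forward_loglik(p, steps, np.zeros(5))
        pz = HMMParams(
            means=p.means, sds=p.sds, mus=p.mus, kappas=p.kappas,
            alpha=p.alpha, beta=p.beta, zero_mass=[0.3, 0.01, 0.01],
        )
        assert np.isfinite(forward_loglik(pz, steps, np.zeros(5)))


class TestViterbi:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_T5(self, seed):
        p = toy_params()
        p.beta[0, 1] = 0.5
        steps = toy_steps(5, seed=seed)
        lh = np.random.default_rng(100 + seed).normal(0, 0.5, 5)
        _, best = enumerate_loglik_and_best(p, steps, lh)
        fit = HMMFit(params=p, loglik=0.0, restarts=pd.DataFrame(), converged=True)
        np.testing.assert_array_equal(viterbi(fit, steps, lh), best)

    def test_dominant_state_constant_path(self):
        p = toy_params()
        steps = toy_steps(15, seed=3)
        # lengths deep in the traveling state's bulk and implausible elsewhere
        steps["length"] = np.random.default_rng(0).normal(5200, 100, 15)
        path = viterbi(p, steps, np.zeros(15))
        assert np.all(path == 2)


class TestFit:
    def _simulate(self, n_tracks=4, T=150, seed=0, beta=None):
        """Direct emission/transition sampler, independent of simulate_tracks."""
        p = HMMParams(
            means=[10.0, 1000.0, 5000.0],
            sds=[8.0, 600.0, 2000.0],
            mus=[0.0, 0.0, 0.0],
            kappas=[0.5, 1.0, 2.0],
            alpha=[[0, -2, -2], [-2, 0, -2], [-2, -2, 0]],
            beta=np.zeros((3, 3)) if beta is None else beta,
        )
        rng = np.random.default_rng(seed)
        shape, scale = p.gamma_shape_scale()
        rows, lhs = [], []
        for tr in range(n_tracks):
            lh = rng.normal(0, 0.8, T)
            s = rng.integers(0, 3)
            for t in range(T):
                if t > 0:
                    P = _trans_batch(p, lh[t : t + 1])[0]
                    s = rng.choice(3, p=P[s])
                rows.append(
                    {
                        "length": rng.gamma(shape[s], scale[s]),
                        "turn": np.nan if t == 0 else rng.vonmises(p.mus[s], p.kappas[s]),
                        "track_id": tr,
                        "true_state": s,
                    }
                )
            lhs.append(lh)
        return p, pd.DataFrame(rows), np.concatenate(lhs)

    def test_same_seed_identical_restart_table(self):
        _, steps, lh = self._simulate(n_tracks=2, T=80, seed=1)
        kw = dict(n_restarts=3, maxiter_restart=10, maxiter=20, compute_vcov=False, random_state=9)
        a = CovariateHMM(**kw).fit(steps, lh)
        b = CovariateHMM(**kw).fit(steps, lh)
        pd.testing.assert_frame_equal(a.restarts_, b.restarts_)
        assert a.loglik_ == b.loglik_

    def test_states_sorted_by_mean_step_length(self):
        _, steps, lh = self._simulate(seed=2)
        m = CovariateHMM(n_restarts=3, maxiter_restart=40, maxiter=150, compute_vcov=False, random_state=0)
        m.fit(steps, lh)
        assert np.all(np.diff(m.params_.means) > 0)

    def test_emission_recovery_well_separated(self):
        truth, steps, lh = self._simulate(n_tracks=6, T=200, seed=3)
        m = CovariateHMM(n_restarts=5, maxiter_restart=40, maxiter=300, compute_vcov=False, random_state=1)
        m.fit(steps, lh)
        np.testing.assert_allclose(m.params_.means, truth.means, rtol=0.15)
        acc = (m.predict(steps, lh) == steps["true_state"].to_numpy()).mean()
        assert acc > 0.8

    def test_restart_consensus_on_separated_data(self):
        # the surface has spurious local optima (e.g. empty-state solutions);
        # the multi-restart protocol relies on a clear majority of converged
        # restarts agreeing on the dominant optimum
        _, steps, lh = self._simulate(n_tracks=3, T=120, seed=4)
        m = CovariateHMM(n_restarts=10, maxiter_restart=500, maxiter=500, compute_vcov=False, random_state=2)
        m.fit(steps, lh)
        best = m.restarts_["loglik"].max()
        frac = (m.restarts_["loglik"] >= best - 1.0).mean()
        assert frac >= 0.6
        assert m.loglik_ >= best - 1e-6  # reported optimum at least as good as any restart

    def test_likelihood_at_truth_beats_perturbed(self):
        truth, steps, lh = self._simulate(n_tracks=6, T=200, seed=5)
        ll_true = forward_loglik(truth, steps, lh)
        worse = truth.relabeled(np.array([0, 1, 2]))
        worse.means = truth.means * 1.5
        ll_pert = forward_loglik(worse, steps, lh)
        assert ll_true > ll_pert

    def test_too_few_steps_rejected(self):
        steps = toy_steps(4)
        with pytest.raises(ValueError):
            CovariateHMM().fit(steps, np.zeros(4))


class TestTransitionCurves:
    def _fit(self):
        p = toy_params()
        p.beta[2, 1] = 1.0
        p.beta[0, 2] = -0.5
        vcov = np.eye(4 * 3 + 12) * 0.01
        return HMMFit(params=p, loglik=0.0, restarts=pd.DataFrame(), converged=True, vcov=vcov)

    def test_rows_sum_to_three_everywhere(self):
        curves = transition_curves(self._fit(), np.linspace(-2, 2, 7))
        sums = curves.groupby("log_hri")["prob"].sum()
        np.testing.assert_allclose(sums, 3.0, atol=1e-9)

    def test_monotonicity_matches_slope_sign(self):
        curves = transition_curves(self._fit(), np.linspace(-2, 2, 9))
        tf = curves[(curves["from"] == "traveling") & (curves["to"] == "foraging")]
        assert np.all(np.diff(tf["prob"]) > 0)
        sd = curves[(curves["from"] == "stationary") & (curves["to"] == "traveling")]
        assert np.all(np.diff(sd["prob"]) < 0)

    def test_ci_bounds_bracket_estimate(self):
        curves = transition_curves(self._fit(), np.linspace(-1, 1, 5))
        assert (curves["ci_lo"] <= curves["prob"] + 1e-12).all()
        assert (curves["ci_hi"] >= curves["prob"] - 1e-12).all()

    def test_bootstrap_fallback_without_vcov(self):
        fit = self._fit()
        fit.vcov = None
        curves = transition_curves(fit, np.linspace(-1, 1, 3), seed=0)
        assert curves["ci_hi"].notna().all()

    def test_slope_table_ci_covering_zero_reported(self):
        fit = self._fit()
        table = fit.slope_table().set_index(["from", "to"])
        row = table.loc[("stationary", "foraging")]
        assert row["ci_lo"] < 0 < row["ci_hi"]  # zero-covering CI kept as-is


class TestForagingSegregation:
    def _frame(self, cells_by_colony):
        rows = []
        for colony, cells in cells_by_colony.items():
            for (ix, iy) in cells:
                rows.append({"colony": colony, "state": "foraging", "x": ix * 1000 + 500, "y": iy * 1000 + 500})
        return pd.DataFrame(rows)

    def test_identical_sets_full_overlap(self):
        df = self._frame({"A": [(0, 0), (1, 1)], "B": [(0, 0), (1, 1)]})
        out = foraging_segregation(df)
        assert out.loc["A", "B"] == 1.0

    def test_disjoint_sets_zero(self):
        df = self._frame({"A": [(0, 0)], "B": [(5, 5)]})
        assert foraging_segregation(df).loc["A", "B"] == 0.0

    def test_hand_computed_half(self):
        df = self._frame({"A": [(0, 0), (1, 0), (2, 0)], "B": [(1, 0), (2, 0), (3, 0)]})
        # 2 shared of 4 union
        assert foraging_segregation(df).loc["A", "B"] == pytest.approx(0.5)

    def test_requires_two_colonies(self):
        df = self._frame({"A": [(0, 0)]})
        with pytest.raises(ValueError):
            foraging_segregation(df)
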