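import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from escapes.escape_map import EScape
from escapes.raster import Raster
from escapes.ssf import MovementKernel, StepSelectionFunction, fit_issf, fit_kernel, make_controls, rss

from .test_escape_map import make_iei_table


def synth_steps(n=200, seed=0, kernel=MovementKernel(2.0, 500.0, 0.0, 1.0)):
    """A step series with headings consistent with recorded turns."""
    rng = np.random.default_rng(seed)
    lengths = rng.gamma(kernel.shape, kernel.scale, n)
    turns = np.r_[np.nan, rng.vonmises(kernel.mu, kernel.kappa, n - 1)]
    heading = np.zeros(n)
    heading[0] = rng.uniform(-np.pi, np.pi)
    for i in range(1, n):
        heading[i] = heading[i - 1] + turns[i]
    x0 = np.zeros(n)
    y0 = np.zeros(n)
    x0[1:] = np.cumsum(lengths[:-1] * np.cos(heading[:-1]))
    y0[1:] = np.cumsum(lengths[:-1] * np.sin(heading[:-1]))
    return pd.DataFrame(
        {
            "x0": x0,
            "y0": y0,
            "x1": x0 + lengths * np.cos(heading),
            "y1": y0 + lengths * np.sin(heading),
            "length": lengths,
            "heading": heading,
            "turn": turns,
            "bird_id": "b1",
            "trip_id": "t0",
            "year": 2019,
            "stratum": np.arange(n),
        }
    )


def random_control_table(n_strata, K, beta_hri, seed):
    """Choice sets sampled from a fixed kernel with the case selected by a
    multinomial in exp(beta * logHRI) — the generative model of the fit."""
    rng = np.random.default_rng(seed)
    sl = rng.gamma(2, 1500, (n_strata, K + 1))
    turn = rng.vonmises(0, 0.5, (n_strata, K + 1))
    lh = rng.normal(0, 0.5, (n_strata, K + 1))
    eta = beta_hri * lh
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    case_idx = (p.cumsum(axis=1) > rng.uniform(size=(n_strata, 1))).argmax(axis=1)
    case = np.zeros((n_strata, K + 1), dtype=int)
    case[np.arange(n_strata), case_idx] = 1
    df = pd.DataFrame(
        {
            "stratum": np.repeat(np.arange(n_strata), K + 1),
            "case": case.ravel(),
            "length": sl.ravel(),
            "cos_turn": np.cos(turn).ravel(),
            "log_hri": lh.ravel(),
            "bird_id": "b1",
            "year": 2019,
        }
    )
    df["log_length"] = np.log(df["length"])
    return df


class TestFitKernel:
    def test_gamma_recovery_within_5pct(self):
        steps = synth_steps(n=5000, seed=1)
        k = fit_kernel(steps)
        assert k.shape == pytest.approx(2.0, rel=0.05)
        assert k.scale == pytest.approx(500.0, rel=0.05)

    def test_uniform_turns_give_kappa_near_zero(self):
        rng = np.random.default_rng(2)
        steps = synth_steps(n=2000, seed=2)
        steps["turn"] = np.r_[np.nan, rng.uniform(-np.pi, np.pi, len(steps) - 1)]
        k = fit_kernel(steps)
        assert k.kappa < 0.1

    def test_vonmises_kappa_recovery(self):
        steps = synth_steps(n=5000, seed=3, kernel=MovementKernel(2.0, 500.0, 0.3, 2.5))
        k = fit_kernel(steps)
        assert k.kappa == pytest.approx(2.5, rel=0.1)
        assert k.mu == pytest.approx(0.3, abs=0.1)

    def test_degenerate_lengths_rejected(self):
        steps = synth_steps(n=50, seed=0)
        steps["length"] = 100.0
        with pytest.raises(ValueError):
            fit_kernel(steps)

    def test_too_few_turns_rejected(self):
        with pytest.raises(ValueError):
            fit_kernel(synth_steps(n=5))


class TestMakeControls:
    kernel = MovementKernel(2.0, 500.0, 0.0, 1.0)

    def test_structure_and_determinism(self):
        steps = synth_steps(n=40)
        a = make_controls(steps, self.kernel, K=10, seed=5)
        b = make_controls(steps, self.kernel, K=10, seed=5)
        pd.testing.assert_frame_equal(a, b)
        per = a.groupby("stratum")["case"].agg(["sum", "count"])
        assert (per["sum"] == 1).all()
        assert (per["count"] == 11).all()

    def test_deterministic_limit_collapses_straight_ahead(self):
        # near-zero gamma variance and huge kappa -> controls at the point
        # one mean-length straight ahead of the start
        steps = synth_steps(n=20)
        kern = MovementKernel(shape=1e6, scale=1000.0 / 1e6, mu=0.0, kappa=1e6)
        ctrl = make_controls(steps, kern, K=5, seed=0)
        ctrl = ctrl[ctrl["case"] == 0]
        merged = ctrl.merge(steps, left_on="stratum", right_on="stratum", suffixes=("", "_obs"))
        prev_heading = merged["heading"] - merged["turn"]
        ex = merged["x0"] + 1000.0 * np.cos(prev_heading)
        ey = merged["y0"] + 1000.0 * np.sin(prev_heading)
        # residual spread: ~1 m length SD plus ~2 m lateral jitter at kappa=1e6
        np.testing.assert_allclose(merged["x"], ex, atol=10.0)
        np.testing.assert_allclose(merged["y"], ey, atol=10.0)

    def test_strata_with_uncovered_endpoints_dropped(self):
        steps = synth_steps(n=30)
        tiny = EScape(hri=Raster(np.full((1, 1), 1.5), cell_size=100.0), iei=make_iei_table([1, 1, 1]))
        with pytest.raises(ValueError):
            # kernel throws every endpoint outside the 100 m E-scape
            make_controls(steps, self.kernel, K=5, escape=tiny, seed=0)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            make_controls(synth_steps(20), self.kernel, K=0)


class TestConditionalLikelihood:
    def brute_force(self, df, beta):
        X = df[["length", "log_length", "cos_turn", "log_hri"]].to_numpy()
        ll = 0.0
        grad = np.zeros(4)
        for s in pd.unique(df["stratum"]):
            sel = (df["stratum"] == s).to_numpy()
            eta = X[sel] @ beta
            lz = logsumexp(eta)
            pi = np.exp(eta - lz)
            i_case = np.argmax(df.loc[sel, "case"].to_numpy())
            ll += eta[i_case] - lz
            grad += X[sel][i_case] - pi @ X[sel]
        return ll, grad

    def test_matches_enumeration_to_1e8(self):
        df = random_control_table(5, 2, 1.0, seed=3)
        model = StepSelectionFunction()
        strata = df["stratum"].to_numpy()
        codes, order, n_strata = model._group_structures(strata)
        X = df[["length", "log_length", "cos_turn", "log_hri"]].to_numpy()
        case = df["case"].to_numpy().astype(bool)
        for beta in (np.zeros(4), np.array([1e-4, 0.2, -0.3, 0.8])):
            ll, _, grad, _ = model._loglik_parts(beta, X, case, codes, n_strata, 0.0, 0)
            ll_bf, grad_bf = self.brute_force(df, beta)
            assert ll == pytest.approx(ll_bf, abs=1e-8)
            np.testing.assert_allclose(grad, grad_bf, atol=1e-8)

    def test_invariant_to_stratum_constant_offset(self):
        df = random_control_table(8, 4, 0.5, seed=4)
        model = StepSelectionFunction()
        codes, _, n_strata = model._group_structures(df["stratum"].to_numpy())
        case = df["case"].to_numpy().astype(bool)
        X = df[["length", "log_length", "cos_turn", "log_hri"]].to_numpy()
        beta = np.array([0.0, 0.1, -0.2, 0.7])
        ll0 = model._loglik_parts(beta, X, case, codes, n_strata, 0.0, 0)[0]
        X2 = X.copy()
        X2[:, 3] += codes * 3.7  # stratum-constant shift of the covariate
        ll1 = model._loglik_parts(beta, X2, case, codes, n_strata, 0.0, 0)[0]
        assert ll0 == pytest.approx(ll1, abs=1e-8)


class TestFitISSF:
    def test_null_covariate_within_2se_of_zero(self):
        df = random_control_table(500, 20, 0.0, seed=6)
        fit = fit_issf(df)
        assert abs(fit.coef["log_hri"]) <= 2 * fit.se["log_hri"]
        assert fit.converged

    def test_parameter_recovery_beta_one(self):
        df = random_control_table(3000, 20, 1.0, seed=7)
        fit = fit_issf(df)
        assert abs(fit.coef["log_hri"] - 1.0) <= 2 * fit.se["log_hri"]
        assert fit.se["log_hri"] > 0

    def test_requires_one_case_per_stratum(self):
        df = random_control_table(5, 3, 0.0, seed=0)
        df.loc[df["stratum"] == 0, "case"] = 0
        with pytest.raises(ValueError):
            fit_issf(df)

    def test_deviation_terms_reported_and_shrunk(self):
        df = random_control_table(400, 10, 1.0, seed=8)
        df["bird_id"] = np.repeat(
            np.where(np.arange(400) % 2 == 0, "a", "b"), 11
        )
        fit = fit_issf(df, {"individual_deviations": True, "ridge": 10.0})
        assert set(fit.individual_dev) == {"a", "b"}
        assert fit.ridge == 10.0
        # heavy shrinkage keeps deviations small relative to the fixed slope
        assert all(abs(v) < abs(fit.coef["log_hri"]) for v in fit.individual_dev.values())

    def test_auto_ridge_selects_from_grid(self):
        df = random_control_table(300, 10, 1.0, seed=9)
        df["year"] = np.repeat(np.where(np.arange(300) % 2 == 0, 2019, 2021), 11)
        model = StepSelectionFunction(year_deviations=True, ridge="auto", ridge_grid=(0.1, 1.0, 10.0))
        model.fit(df)
        assert model.fit_.ridge in (0.1, 1.0, 10.0)


class TestRSS:
    def _fit(self):
        return fit_issf(random_control_table(500, 10, 1.0, seed=10))

    def test_zero_delta_is_one(self):
        assert rss(self._fit(), 0.0) == pytest.approx(1.0)

    def test_multiplicativity(self):
        fit = self._fit()
        assert rss(fit, 0.7) * rss(fit, 0.5) == pytest.approx(float(rss(fit, 1.2)))

    def test_threefold_increase_at_study_coefficient(self):
        # a slope of 1.05 corresponds to RSS exp(1.05) = 2.857 per unit log(HRI)
        fit = self._fit()
        fit.coef["log_hri"] = 1.05
        assert float(rss(fit, 1.0)) == pytest.approx(2.857, abs=0.001)
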