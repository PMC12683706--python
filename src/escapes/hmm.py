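"""Hidden Markov movement model with covariate-dependent transitions.

A three-state HMM over step series: each behavioral state emits a gamma step
length (parameterized by mean and SD) and a von Mises turning angle, and the
transition probabilities between states depend on the local log habitat
resource index through a multinomial-logit link,

    eta_ij(t) = alpha_ij + beta_ij * logHRI(t)   (j != i, diagonal = 0)
    P_ij(t)   = softmax_j over {0, eta_ij(t)},

so a positive beta on, say, the traveling->foraging transition means birds
become more likely to switch into foraging where menhaden resource quality is
high. Fitting uses the scaled forward recursion, quasi-Newton maximization
from many random starts (the study's protocol: 50 restarts with starting
step-length means/SDs uniform on 1-2000 m and turning-angle means/SDs on
0-2 rad), and states are relabeled in ascending mean step length
(stationary < foraging < traveling). Decoding uses the Viterbi algorithm
under the covariate-dependent chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "HMMFit",
    "CovariateHMM",
    "transition_matrix",
    "forward_loglik",
    "fit_hmm",
    "viterbi",
    "transition_curves",
    "foraging_segregation",
    "STATE_NAMES",
]

STATE_NAMES = ("stationary", "foraging", "traveling")

try:  # optional numba acceleration of the recursion core
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in normal installs
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@dataclass
class HMMParams:
    """Emission and transition parameters of the covariate HMM.

    ``alpha``/``beta`` are (S, S) with the diagonal fixed at 0 (reference
    category of the multinomial logit). ``zero_mass`` is an optional per-state
    point mass on zero step lengths (off by default).
    """

    means: np.ndarray
    sds: np.ndarray
    mus: np.ndarray
    kappas: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    zero_mass: np.ndarray | None = None

    def __post_init__(self):
        for name in ("means", "sds", "mus", "kappas", "alpha", "beta"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.means <= 0) or np.any(self.sds <= 0):
            raise ValueError("gamma means and SDs must be > 0")
        if np.any(self.kappas < 0):
            raise ValueError("von Mises kappa must be >= 0")
        if self.zero_mass is not None:
            zm = np.asarray(self.zero_mass, dtype=float)
            if np.any(zm < 0) or np.any(zm >= 1):
                raise ValueError("zero_mass must be in [0, 1)")
            object.__setattr__(self, "zero_mass", zm)

    @property
    def n_states(self) -> int:
        return len(self.means)

    def gamma_shape_scale(self) -> tuple[np.ndarray, np.ndarray]:
        shape = self.means**2 / self.sds**2
        scale = self.sds**2 / self.means
        return shape, scale

    def relabeled(self, perm: np.ndarray) -> "HMMParams":
        """Permute state indices (used to sort by mean step length)."""
        return HMMParams(
            means=self.means[perm],
            sds=self.sds[perm],
            mus=self.mus[perm],
            kappas=self.kappas[perm],
            alpha=self.alpha[np.ix_(perm, perm)],
            beta=self.beta[np.ix_(perm, perm)],
            zero_mass=None if self.zero_mass is None else self.zero_mass[perm],
        )


def transition_matrix(params: HMMParams, log_hri: float) -> np.ndarray:
    """Row-stochastic transition matrix at one covariate value."""
    return _trans_batch(params, np.array([float(log_hri)]))[0]


def _trans_batch(params: HMMParams, log_hri: np.ndarray) -> np.ndarray:
    """(T, S, S) transition matrices along a covariate series."""
    S = params.n_states
    eta = params.alpha[None, :, :] + params.beta[None, :, :] * log_hri[:, None, None]
    eta = eta.copy()
    idx = np.arange(S)
    eta[:, idx, idx] = 0.0
    eta -= eta.max(axis=2, keepdims=True)  # overflow guard
    ez = np.exp(eta)
    return ez / ez.sum(axis=2, keepdims=True)


def _emission_logdens(params: HMMParams, lengths: np.ndarray, turns: np.ndarray) -> np.ndarray:
    """(T, S) per-step emission log densities; missing turns contribute the
    length-only density."""
    shape, scale = params.gamma_shape_scale()
    T = len(lengths)
    S = params.n_states
    logB = np.zeros((T, S))
    pos = lengths > 0
    L = lengths[pos, None]
    gl = (shape - 1) * np.log(L) - L / scale - shape * np.log(scale) - special.gammaln(shape)
    if params.zero_mass is not None:
        gl = gl + np.log1p(-params.zero_mass)[None, :]
        log_zm = np.full(S, -np.inf)
        nz = params.zero_mass > 0
        log_zm[nz] = np.log(params.zero_mass[nz])
        logB[~pos] += log_zm[None, :]
    elif np.any(~pos):
        raise ValueError("zero step lengths require zero_inflation=True")
    logB[pos] += gl
    ok = np.isfinite(turns)
    tv = turns[ok, None]
    vm = params.kappas[None, :] * np.cos(tv - params.mus[None, :]) - (
        np.log(2 * np.pi) + np.log(special.i0e(params.kappas)) + params.kappas
    )[None, :]
    logB[ok] += vm
    return logB


@_njit(cache=True)
def _forward_core(B, m, trans, starts, init):  # pragma: no cover - exercised via wrapper
    T, S = B.shape
    a = np.zeros(S)
    ll = 0.0
    for t in range(T):
        if starts[t]:
            for s in range(S):
                a[s] = init[s] * B[t, s]
        else:
            tmp = np.zeros(S)
            for s in range(S):
                acc = 0.0
                for r in range(S):
                    acc += a[r] * trans[t, r, s]
                tmp[s] = acc * B[t, s]
            a = tmp
        c = 0.0
        for s in range(S):
            c += a[s]
        if c <= 0.0 or not np.isfinite(c):
            return -1.0e300
        ll += np.log(c) + m[t]
        for s in range(S):
            a[s] /= c
    return ll


def _forward_core_py(B, m, trans, starts, init):
    T, S = B.shape
    a = np.zeros(S)
    ll = 0.0
    for t in range(T):
        if starts[t]:
            a = init * B[t]
        else:
            a = (a @ trans[t]) * B[t]
        c = a.sum()
        if c <= 0 or not np.isfinite(c):
            return -1.0e300
        ll += np.log(c) + m[t]
        a = a / c
    return ll


def _prepare_series(steps: pd.DataFrame, log_hri) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    lengths = steps["length"].to_numpy(dtype=float)
    turns = steps["turn"].to_numpy(dtype=float) if "turn" in steps else np.full(len(steps), np.nan)
    log_hri = np.asarray(log_hri, dtype=float)
    if log_hri.shape != lengths.shape:
        raise ValueError("log_hri must align with the step series")
    if not np.all(np.isfinite(log_hri)):
        raise ValueError("log_hri must be finite (impute or drop missing covariates upstream)")
    if "track_id" in steps:
        tid = steps["track_id"].to_numpy()
    elif "trip_id" in steps:
        tid = steps["trip_id"].to_numpy()
    else:
        tid = np.zeros(len(steps))
    starts = np.zeros(len(steps), dtype=np.bool_)
    if len(steps):
        starts[0] = True
        starts[1:] = tid[1:] != tid[:-1]
    return lengths, turns, log_hri, starts


def forward_loglik(params: HMMParams, steps: pd.DataFrame, log_hri) -> float:
    """Forward-algorithm log-likelihood of a step series.

    Tracks (``track_id`` or ``trip_id`` column) are independent; each starts
    from a uniform initial state distribution. The covariate value for the
    transition into step t is logHRI at the start of step t.
    """
    lengths, turns, log_hri, starts = _prepare_series(steps, log_hri)
    return _loglik_arrays(params, lengths, turns, log_hri, starts)


def _loglik_arrays(params, lengths, turns, log_hri, starts) -> float:
    logB = _emission_logdens(params, lengths, turns)
    m = logB.max(axis=1)
    m = np.where(np.isfinite(m), m, 0.0)
    B = np.exp(logB - m[:, None])
    trans = _trans_batch(params, log_hri)
    init = np.full(params.n_states, 1.0 / params.n_states)
    core = _forward_core if _HAVE_NUMBA else _forward_core_py
    return float(core(B, m, np.ascontiguousarray(trans), starts, init))


# -- parameter packing ---------------------------------------------------

def _offdiag_index(S: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(S) for j in range(S) if i != j]


def _pack(params: HMMParams) -> np.ndarray:
    off = _offdiag_index(params.n_states)
    parts = [
        np.log(params.means),
        np.log(params.sds),
        params.mus,
        np.log(np.maximum(params.kappas, 1e-8)),
        np.array([params.alpha[i, j] for i, j in off]),
        np.array([params.beta[i, j] for i, j in off]),
    ]
    if params.zero_mass is not None:
        z = np.clip(params.zero_mass, 1e-8, 1 - 1e-8)
        parts.append(np.log(z / (1 - z)))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, S: int, zero_inflation: bool) -> HMMParams:
    k = 0
    means = np.exp(theta[k : k + S]); k += S
    sds = np.exp(theta[k : k + S]); k += S
    mus = theta[k : k + S]; k += S
    kappas = np.exp(theta[k : k + S]); k += S
    n_off = S * (S - 1)
    alpha = np.zeros((S, S))
    beta = np.zeros((S, S))
    for idx, (i, j) in enumerate(_offdiag_index(S)):
        alpha[i, j] = theta[k + idx]
        beta[i, j] = theta[k + n_off + idx]
    k += 2 * n_off
    zm = None
    if zero_inflation:
        zm = 1.0 / (1.0 + np.exp(-theta[k : k + S]))
    return HMMParams(means=means, sds=sds, mus=mus, kappas=kappas, alpha=alpha, beta=beta, zero_mass=zm)


@dataclass
class HMMFit:
    """Best multi-restart optimum of the covariate HMM."""

    params: HMMParams
    loglik: float
    restarts: pd.DataFrame
    converged: bool
    vcov: np.ndarray | None = None
    theta: np.ndarray | None = None
    zero_inflation: bool = False

    @property
    def n_states(self) -> int:
        return self.params.n_states

    def slope_table(self) -> pd.DataFrame:
        """Transition-slope estimates with 95% delta-method CIs."""
        S = self.params.n_states
        off = _offdiag_index(S)
        n_off = len(off)
        rows = []
        for idx, (i, j) in enumerate(off):
            est = self.params.beta[i, j]
            se = np.nan
            if self.vcov is not None:
                pos = 4 * S + n_off + idx
                se = float(np.sqrt(max(self.vcov[pos, pos], 0.0)))
            rows.append(
                {
                    "from": STATE_NAMES[i] if S == 3 else str(i),
                    "to": STATE_NAMES[j] if S == 3 else str(j),
                    "slope": est,
                    "se": se,
                    "ci_lo": est - 1.96 * se,
                    "ci_hi": est + 1.96 * se,
                }
            )
        return pd.DataFrame(rows)


class CovariateHMM:
    """Multi-restart covariate-transition HMM estimator (sklearn-style).

    Parameters
    ----------
    n_states : int, default 3
    n_restarts : int, default 50
        Random restarts; starting values are drawn from uniform ranges
        (below) and each restart runs a capped quasi-Newton maximization
        before the best is polished to convergence.
    step_range : (lo, hi), default (1, 2000)
        Uniform range (m) for starting step-length means and SDs.
    turn_mean_range, turn_sd_range : (lo, hi), default (0, 2)
        Uniform ranges (rad) for starting turn means and SDs (the SD start
        is converted to a von Mises concentration kappa ~ 1/sd^2).
    zero_inflation : bool, default False
        Estimate a per-state point mass on zero step lengths.
    random_state : int or None

    Attributes
    ----------
    fit_ : HMMFit
    params_ : HMMParams (states sorted by ascending mean step length)
    loglik_ : float
    restarts_ : DataFrame
    """

    _param_names = (
        "n_states",
        "n_restarts",
        "step_range",
        "turn_mean_range",
        "turn_sd_range",
        "maxiter_restart",
        "maxiter",
        "tol",
        "zero_inflation",
        "compute_vcov",
        "random_state",
    )

    def __init__(
        self,
        n_states: int = 3,
        n_restarts: int = 50,
        step_range=(1.0, 2000.0),
        turn_mean_range=(0.0, 2.0),
        turn_sd_range=(0.0, 2.0),
        maxiter_restart: int = 30,
        maxiter: int = 500,
        tol: float = 1e-8,
        zero_inflation: bool = False,
        compute_vcov: bool = True,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.step_range = step_range
        self.turn_mean_range = turn_mean_range
        self.turn_sd_range = turn_sd_range
        self.maxiter_restart = maxiter_restart
        self.maxiter = maxiter
        self.tol = tol
        self.zero_inflation = zero_inflation
        self.compute_vcov = compute_vcov
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _draw_start(self, rng: np.random.Generator) -> HMMParams:
        S = self.n_states
        means = np.sort(rng.uniform(*self.step_range, S))
        sds = rng.uniform(*self.step_range, S)
        mus = rng.uniform(*self.turn_mean_range, S)
        turn_sd = np.maximum(rng.uniform(*self.turn_sd_range, S), 0.15)
        kappas = 1.0 / turn_sd**2
        alpha = np.full((S, S), -2.0)
        np.fill_diagonal(alpha, 0.0)
        beta = np.zeros((S, S))
        zm = np.full(S, 0.01) if self.zero_inflation else None
        return HMMParams(means=means, sds=sds, mus=mus, kappas=kappas, alpha=alpha, beta=beta, zero_mass=zm)

    def fit(self, steps: pd.DataFrame, log_hri):
        lengths, turns, log_hri, starts = _prepare_series(steps, log_hri)
        if len(lengths) < self.n_states * 2:
            raise ValueError("too few steps to fit the HMM")
        if np.any(lengths <= 0) and not self.zero_inflation:
            raise ValueError("zero step lengths present; enable zero_inflation or filter")
        S = self.n_states

        def nll(theta):
            try:
                p = _unpack(theta, S, self.zero_inflation)
            except ValueError:
                return 1.0e300
            return -_loglik_arrays(p, lengths, turns, log_hri, starts)

        n_off = S * (S - 1)
        bounds = (
            [(np.log(1e-2), np.log(1e7))] * S  # log mean
            + [(np.log(1e-2), np.log(1e7))] * S  # log sd
            + [(-2 * np.pi, 2 * np.pi)] * S  # mu
            + [(np.log(1e-4), np.log(1e3))] * S  # log kappa
            + [(-20.0, 20.0)] * (2 * n_off)  # alpha, beta
        )
        if self.zero_inflation:
            bounds += [(-12.0, 6.0)] * S

        rng = np.random.default_rng(self.random_state)
        rows = []
        best = None
        for r in range(self.n_restarts):
            start = self._draw_start(rng)
            theta0 = _pack(start)
            res = optimize.minimize(
                nll,
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.maxiter_restart, "ftol": 1e-10},
            )
            rows.append(
                {
                    "restart": r,
                    "start_means": tuple(np.round(start.means, 2)),
                    "start_sds": tuple(np.round(start.sds, 2)),
                    "start_mus": tuple(np.round(start.mus, 3)),
                    "start_kappas": tuple(np.round(start.kappas, 3)),
                    "loglik": -res.fun,
                    "converged": bool(res.success),
                    "n_iter": int(res.nit),
                }
            )
            if best is None or -res.fun > -best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("all HMM restarts failed")

        polish = optimize.minimize(
            nll,
            best.x,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.maxiter, "ftol": self.tol / max(abs(best.fun), 1.0), "gtol": 1e-8},
        )
        theta_hat = polish.x
        loglik = -polish.fun
        params = _unpack(theta_hat, S, self.zero_inflation)
        perm = np.argsort(params.means)
        params = params.relabeled(perm)
        theta_hat = _pack(params)  # re-pack in sorted label order

        vcov = None
        if self.compute_vcov:
            vcov = self._numeric_vcov(nll, theta_hat)
        restarts = pd.DataFrame(rows)
        self.fit_ = HMMFit(
            params=params,
            loglik=float(loglik),
            restarts=restarts,
            converged=bool(polish.success),
            vcov=vcov,
            theta=theta_hat,
            zero_inflation=self.zero_inflation,
        )
        self.params_ = params
        self.loglik_ = float(loglik)
        self.restarts_ = restarts
        self.converged_ = bool(polish.success)
        return self

    @staticmethod
    def _numeric_vcov(nll, theta, h: float = 1e-4) -> np.ndarray | None:
        """Covariance from the finite-difference observed information."""
        p = len(theta)
        H = np.zeros((p, p))
        f0 = nll(theta)
        steps = np.maximum(np.abs(theta) * h, h)
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            e = np.zeros(p)
            e[i] = steps[i]
            fp[i] = nll(theta + e)
            fm[i] = nll(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p); ei[i] = steps[i]
                ej = np.zeros(p); ej[j] = steps[j]
                fpp = nll(theta + ei + ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (steps[i] * steps[j])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            logger.warning("singular observed information; no covariance available")
            return None

    def predict(self, steps: pd.DataFrame, log_hri) -> np.ndarray:
        """Viterbi-decoded state index per step (0 = shortest-step state)."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("CovariateHMM is not fitted")
        return viterbi(self.fit_, steps, log_hri)


def fit_hmm(
    steps: pd.DataFrame,
    log_hri,
    n_restarts: int = 50,
    start_ranges: dict | None = None,
    seed: int | None = None,
    **kwargs,
) -> HMMFit:
    """Functional wrapper over :class:`CovariateHMM`."""
    ranges = start_ranges or {}
    model = CovariateHMM(
        n_restarts=n_restarts,
        step_range=ranges.get("step", (1.0, 2000.0)),
        turn_mean_range=ranges.get("turn_mean", (0.0, 2.0)),
        turn_sd_range=ranges.get("turn_sd", (0.0, 2.0)),
        random_state=seed,
        **kwargs,
    )
    model.fit(steps, log_hri)
    return model.fit_


def viterbi(fit: HMMFit | HMMParams, steps: pd.DataFrame, log_hri) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index."""
    params = fit.params if isinstance(fit, HMMFit) else fit
    lengths, turns, log_hri, starts = _prepare_series(steps, log_hri)
    logB = _emission_logdens(params, lengths, turns)
    with np.errstate(divide="ignore"):
        logT = np.log(_trans_batch(params, log_hri))
    T, S = logB.shape
    log_init = np.full(S, -np.log(S))
    delta = np.zeros((T, S))
    psi = np.zeros((T, S), dtype=int)
    for t in range(T):
        if starts[t]:
            delta[t] = log_init + logB[t]
        else:
            cand = delta[t - 1][:, None] + logT[t]
            psi[t] = np.argmax(cand, axis=0)  # argmax -> lowest index on ties
            delta[t] = cand[psi[t], np.arange(S)] + logB[t]
    path = np.zeros(T, dtype=int)
    # backtrace within each track
    track_ends = list(np.nonzero(starts)[0][1:] - 1) + [T - 1]
    track_starts = list(np.nonzero(starts)[0])
    for s0, e0 in zip(track_starts, track_ends):
        path[e0] = int(np.argmax(delta[e0]))
        for t in range(e0, s0, -1):
            path[t - 1] = psi[t, path[t]]
    return path


def transition_curves(fit: HMMFit, log_hri_grid, n_boot: int = 0, seed: int | None = None) -> pd.DataFrame:
    """All 9 transition probabilities along a logHRI grid with 95% CIs.

    CIs are delta-method by default (finite-difference Jacobian against the
    fitted covariance); with ``n_boot`` > 0 or a missing/singular covariance,
    a parametric bootstrap over the transition coefficients is used.
    """
    grid = np.asarray(log_hri_grid, dtype=float)
    params = fit.params
    S = params.n_states
    n_off = S * (S - 1)
    off = _offdiag_index(S)
    t0 = 4 * S  # offset of alpha block in packed theta

    def probs_at(alpha_beta: np.ndarray) -> np.ndarray:
        alpha = np.zeros((S, S))
        beta = np.zeros((S, S))
        for idx, (i, j) in enumerate(off):
            alpha[i, j] = alpha_beta[idx]
            beta[i, j] = alpha_beta[n_off + idx]
        p = replace(params, alpha=alpha, beta=beta)
        return _trans_batch(p, grid)  # (G, S, S)

    ab_hat = np.concatenate(
        [np.array([params.alpha[i, j] for i, j in off]), np.array([params.beta[i, j] for i, j in off])]
    )
    P = probs_at(ab_hat)

    lo = np.full_like(P, np.nan)
    hi = np.full_like(P, np.nan)
    cov_ok = fit.vcov is not None
    if cov_ok:
        idx_cov = np.r_[t0 : t0 + n_off, t0 + n_off : t0 + 2 * n_off]
        cov = fit.vcov[np.ix_(idx_cov, idx_cov)]
        cov_ok = bool(np.all(np.isfinite(cov)) and np.all(np.linalg.eigvalsh((cov + cov.T) / 2) > -1e-8))
    if cov_ok and n_boot == 0:
        # delta method with finite-difference Jacobian
        h = 1e-5
        J = np.zeros(P.shape + (2 * n_off,))
        for k in range(2 * n_off):
            e = np.zeros(2 * n_off)
            e[k] = h
            J[..., k] = (probs_at(ab_hat + e) - probs_at(ab_hat - e)) / (2 * h)
        var = np.einsum("...k,kl,...l->...", J, cov, J)
        sd = np.sqrt(np.clip(var, 0, None))
        lo = np.clip(P - 1.96 * sd, 0, 1)
        hi = np.clip(P + 1.96 * sd, 0, 1)
    else:
        if not cov_ok:
            logger.warning("transition_curves: covariance unavailable; using parametric bootstrap")
        n_boot = n_boot or 500
        if fit.vcov is not None:
            idx_cov = np.r_[t0 : t0 + n_off, t0 + n_off : t0 + 2 * n_off]
            cov = (fit.vcov[np.ix_(idx_cov, idx_cov)] + fit.vcov[np.ix_(idx_cov, idx_cov)].T) / 2
            w, V = np.linalg.eigh(cov)
            cov = (V * np.clip(w, 0, None)) @ V.T
        else:
            cov = np.eye(2 * n_off) * 0.01
        rng = np.random.default_rng(seed)
        sims = rng.multivariate_normal(ab_hat, cov, size=n_boot)
        Ps = np.stack([probs_at(s) for s in sims])
        lo = np.quantile(Ps, 0.025, axis=0)
        hi = np.quantile(Ps, 0.975, axis=0)

    rows = []
    for g, v in enumerate(grid):
        for i in range(S):
            for j in range(S):
                rows.append(
                    {
                        "log_hri": v,
                        "from": STATE_NAMES[i] if S == 3 else str(i),
                        "to": STATE_NAMES[j] if S == 3 else str(j),
                        "prob": P[g, i, j],
                        "ci_lo": lo[g, i, j],
                        "ci_hi": hi[g, i, j],
                    }
                )
    return pd.DataFrame(rows)


def foraging_segregation(
    decoded: pd.DataFrame,
    colony_col: str = "colony",
    state_col: str = "state",
    unit: float = 1000.0,
    foraging_label="foraging",
) -> pd.DataFrame:
    """Jaccard overlap of foraging-area cells between colonies.

    ``decoded`` needs columns x, y, the decoded state and a colony label;
    foraging points are binned to ``unit``-sized grid cells and each colony
    pair scored by |intersection| / |union| of occupied cells.
    """
    colonies = list(pd.unique(decoded[colony_col]))
    if len(colonies) < 2:
        raise ValueError("need at least 2 colonies")
    cells: dict[str, set] = {}
    for c in colonies:
        sub = decoded[(decoded[colony_col] == c) & (decoded[state_col] == foraging_label)]
        ix = np.floor(sub["x"].to_numpy(dtype=float) / unit).astype(int)
        iy = np.floor(sub["y"].to_numpy(dtype=float) / unit).astype(int)
        cells[c] = set(zip(ix.tolist(), iy.tolist()))
        if not cells[c]:
            logger.warning("colony %s has no foraging points; overlap defined as 0", c)
    out = pd.DataFrame(np.eye(len(colonies)), index=colonies, columns=colonies)
    for a in range(len(colonies)):
        for b in range(a + 1, len(colonies)):
            sa, sb = cells[colonies[a]], cells[colonies[b]]
            union = sa | sb
            jac = len(sa & sb) / len(union) if union else 0.0
            out.iloc[a, b] = out.iloc[b, a] = jac
    return out
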